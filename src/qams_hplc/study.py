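"""End-to-end synthetic QAMS study: configuration, pipeline stages, reports.

The default study emulates the published assay design: six analytes
(matrine, gallic acid, oxymatrine, catechin, rutin, ferulic acid) resolved
on a 53-minute gradient and detected at four wavelengths (210/225/256/320
nm), with gallic acid as the single internal reference.  Each stage mirrors
one bench procedure:

* serial dilution of a mixed stock (0.1–3 mL aliquots into 5 mL) →
  per-analyte calibration curves with LOD/LOQ;
* repeated injection of the 10-fold-diluted mixed standard at 3–20 µL →
  multipoint relative correction factors;
* five sample batches quantified both by external standard (ES) and by the
  single-marker route (QAMS), compared through signed RE%;
* the validation battery (precision, stability, repeatability, recovery,
  RCF robustness across instruments/columns/flow/temperature, and the
  localization-method comparison).

Ground-truth batch compositions are taken from the shipped reference
content table, so the synthetic study operates in the assay's real
concentration regime.  Detector response factors are anchored to the
published calibration slopes (slope / 5 µL).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationCurve, StandardSeries, es_content, estimate_lod_loq, fit_calibration
from .chromsim import AnalytePeakModel, SimulationConfig, simulate_chromatogram
from .peaks import Chromatogram, Peak, detect_peaks, estimate_noise
from .qams import (
    ContentResult,
    RCFEstimate,
    RelativeRetention,
    locate_peaks_by_rtr,
    mass_fraction,
    multipoint_rcf,
    qams_content,
    relative_retention,
)
from .tables import ANALYTES, BATCHES, INTERNAL_REFERENCE, load_calibration_table, load_content_table
from .validation import (
    DEFAULT_RCF_RSD_THRESHOLD,
    DEFAULT_RECOVERY_RANGE,
    DEFAULT_RSD_THRESHOLD,
    RobustnessGrid,
    compare_localization_methods,
    rcf_robustness,
    recovery_rate,
    rsd,
    run_precision_suite,
)

__all__ = ["StudyAnalyte", "StudyConfig", "default_study", "run_pipeline", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report convention; avoids banker's ties)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(master: int, *tags) -> int:
    """Stable 31-bit child seed from a master seed and a tag path."""
    digest = hashlib.sha256(repr((int(master),) + tags).encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class StudyAnalyte:
    """One analyte's role in the study plus its simulation ground truth."""

    name: str
    wavelength: float  # nm, quantification channel
    stock_concentration: float  # µg·mL⁻¹
    retention_time: float  # minutes
    sigma: float  # minutes
    tau: float  # minutes
    response_factor: float  # response·s per (µg·mL⁻¹ · µL), at its channel
    is_reference: bool = False


@dataclass
class StudyConfig:
    """Everything needed to run the whole synthetic study."""

    analytes: list[StudyAnalyte]
    injection_volumes: list[float] = field(default_factory=lambda: [3.0, 5.0, 10.0, 15.0, 20.0])
    series_aliquots: list[float] = field(default_factory=lambda: [0.1, 0.25, 0.5, 1.0, 2.0, 3.0])
    mixed_standard_aliquot: float = 0.5  # mL of stock into final_volume
    final_volume: float = 5.0  # mL
    batches: dict[str, dict[str, float]] = field(default_factory=dict)  # batch -> analyte -> true mass %
    sample_mass_g: float = 5.0
    extract_volume_ml: float = 10.0
    sample_injection_volume: float = 5.0  # µL
    channels: tuple[float, ...] = (210.0, 225.0, 256.0, 320.0)
    run_length: float = 53.0  # minutes
    sampling_rate: float = 5.0  # Hz
    noise_sd: float = 0.02  # response units
    baseline_drift: float = 0.01  # response units per minute
    retention_jitter_sd: float = 0.01  # minutes
    rtr_tolerance: float = 0.05
    min_snr: float = 5.0
    stability_timepoints_h: list[float] = field(default_factory=lambda: [0.0, 2.0, 4.0, 8.0, 12.0, 24.0])
    stability_degradation_per_h: float = 0.0  # fractional loss per hour
    n_replicates: int = 6
    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "precision_rsd": DEFAULT_RSD_THRESHOLD,
            "stability_rsd": DEFAULT_RSD_THRESHOLD,
            "repeatability_rsd": DEFAULT_RSD_THRESHOLD,
            "recovery_low": DEFAULT_RECOVERY_RANGE[0],
            "recovery_high": DEFAULT_RECOVERY_RANGE[1],
            "rcf_robustness_rsd": DEFAULT_RCF_RSD_THRESHOLD,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")
        refs = [a.name for a in self.analytes if a.is_reference]
        if len(refs) != 1:
            raise ValueError(f"exactly one internal reference required, got {refs}")
        for a in self.analytes:
            if a.wavelength not in self.channels:
                raise ValueError(f"{a.name}: wavelength {a.wavelength} not in configured channels")

    # -- accessors -------------------------------------------------------
    @property
    def reference(self) -> StudyAnalyte:
        return next(a for a in self.analytes if a.is_reference)

    def analyte(self, name: str) -> StudyAnalyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def mixed_standard_concentrations(self) -> dict[str, float]:
        """Concentrations in the working mixed standard (stock × 0.5 / 5)."""
        f = self.mixed_standard_aliquot / self.final_volume
        return {a.name: a.stock_concentration * f for a in self.analytes}

    def expected_rtr(self, name: str) -> float:
        return relative_retention(self.analyte(name).retention_time, self.reference.retention_time)

    def batch_concentrations(self, batch_id: str) -> dict[str, float]:
        """True extract concentrations (µg·mL⁻¹) implied by a batch's mass %."""
        fractions = self.batches[batch_id]
        factor = self.sample_mass_g * 1e4 / self.extract_volume_ml
        return {name: mf * factor for name, mf in fractions.items()}

    # -- (de)serialisation ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "analytes" not in raw:
            raise ValueError("study config must be a mapping with an 'analytes' list")
        raw["analytes"] = [StudyAnalyte(**a) for a in raw["analytes"]]
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(asdict(self)).encode()).hexdigest()[:12]


#: channel assignment of each analyte (quantification wavelength, nm).
DEFAULT_WAVELENGTHS = {
    "matrine": 210.0,
    "oxymatrine": 210.0,
    "catechin": 210.0,
    "gallic_acid": 225.0,
    "rutin": 256.0,
    "ferulic_acid": 320.0,
}

#: elution program ground truth for the simulator: apex minutes, Gaussian
#: width and tail (minutes).  Retention times are free design parameters of
#: the synthetic gradient; widths grow with retention as on real columns.
DEFAULT_ELUTION = {
    "gallic_acid": (6.8, 0.050, 0.015),
    "matrine": (8.2, 0.055, 0.017),
    "oxymatrine": (11.4, 0.065, 0.020),
    "catechin": (15.6, 0.075, 0.023),
    "rutin": (27.5, 0.110, 0.033),
    "ferulic_acid": (33.9, 0.130, 0.040),
}

#: stock standard concentrations (µg·mL⁻¹) chosen so the 0.1–3 mL / 5 mL
#: dilution scheme spans each analyte's published linear range.
DEFAULT_STOCKS = {
    "matrine": 1191.8,
    "gallic_acid": 44.4,
    "oxymatrine": 11552.6,
    "catechin": 5.7,
    "rutin": 17.3,
    "ferulic_acid": 548.2,
}


def default_study(seed: int = 0) -> StudyConfig:
    """The standard six-analyte study with published anchors as ground truth."""
    calib = load_calibration_table()
    analytes = []
    for name in ANALYTES:
        rt, sigma, tau = DEFAULT_ELUTION[name]
        analytes.append(
            StudyAnalyte(
                name=name,
                wavelength=DEFAULT_WAVELENGTHS[name],
                stock_concentration=DEFAULT_STOCKS[name],
                retention_time=rt,
                sigma=sigma,
                tau=tau,
                response_factor=float(calib.loc[name, "slope"]) / 5.0,  # slope measured at 5 µL
                is_reference=(name == INTERNAL_REFERENCE),
            )
        )
    contents = load_content_table()
    batches = {
        batch: {name: float(contents.loc[(batch, "ES"), name]) for name in ANALYTES}
        for batch in BATCHES
    }
    return StudyConfig(analytes=analytes, batches=batches, seed=seed)


# ---------------------------------------------------------------------------
# simulation plumbing
# ---------------------------------------------------------------------------

def _models(study: StudyConfig, retention_scale: float = 1.0, retention_offset: float = 0.0,
            response_perturbation: dict[str, float] | None = None) -> list[AnalytePeakModel]:
    models = []
    for a in study.analytes:
        rf = a.response_factor * (1.0 + (response_perturbation or {}).get(a.name, 0.0))
        models.append(
            AnalytePeakModel(
                analyte_name=a.name,
                retention_time=a.retention_time * retention_scale + retention_offset,
                sigma=a.sigma,
                tau=a.tau,
                response_factors={a.wavelength: rf},
            )
        )
    return models


def simulation_config(study: StudyConfig, concentrations: dict[str, float], injection_volume: float,
                      seed: int, **model_kwargs) -> SimulationConfig:
    """Build a single-injection simulation from the study-wide settings."""
    return SimulationConfig(
        analyte_models=_models(study, **model_kwargs),
        concentrations=concentrations,
        injection_volume=injection_volume,
        channels=study.channels,
        run_length=study.run_length,
        sampling_rate=study.sampling_rate,
        noise_sd=study.noise_sd,
        baseline_drift=study.baseline_drift,
        retention_jitter_sd=study.retention_jitter_sd,
        random_seed=seed,
    )


def _measure_known(study: StudyConfig, sim: SimulationConfig,
                   expected_rt: dict[str, float] | None = None) -> dict[str, Peak]:
    """Measure each analyte's peak on its channel by proximity to the known
    retention time (standard runs, where identity is known by design)."""
    expected = expected_rt or {a.name: a.retention_time for a in study.analytes}
    found: dict[str, Peak] = {}
    for channel in study.channels:
        names = [a.name for a in study.analytes if a.wavelength == channel]
        if not names:
            continue
        chrom = simulate_chromatogram(sim, channel)
        peaks = detect_peaks(chrom, min_snr=study.min_snr)
        for name in names:
            if sim.concentrations.get(name, 0.0) <= 0:
                continue
            near = [p for p in peaks if abs(p.apex_time - expected[name]) < 0.5]
            if near:
                found[name] = min(near, key=lambda p: abs(p.apex_time - expected[name]))
    return found


# ---------------------------------------------------------------------------
# stage 1: calibration
# ---------------------------------------------------------------------------

def run_calibration(study: StudyConfig) -> tuple[dict[str, CalibrationCurve], pd.DataFrame]:
    """Simulate the serial-dilution series and fit every analyte's curve.

    One mixed-dilution injection per level (all analytes share the run, as
    on the bench); LOD/LOQ from the lowest level's noise and peak height.
    """
    level_areas: dict[str, list[float]] = {a.name: [] for a in study.analytes}
    lowest_height: dict[str, float] = {}
    lowest_noise: dict[str, float] = {}
    for i, aliquot in enumerate(study.series_aliquots):
        conc = {a.name: a.stock_concentration * aliquot / study.final_volume for a in study.analytes}
        sim = simulation_config(study, conc, injection_volume=5.0, seed=derive_seed(study.seed, "calib", i))
        peaks = _measure_known(study, sim)
        for a in study.analytes:
            peak = peaks.get(a.name)
            level_areas[a.name].append(peak.area if peak else 0.0)
            if i == 0 and peak is not None:
                lowest_height[a.name] = peak.height
                chrom = simulate_chromatogram(sim, a.wavelength)
                lowest_noise[a.name] = estimate_noise(chrom)

    curves: dict[str, CalibrationCurve] = {}
    rows = []
    for a in study.analytes:
        series = StandardSeries(
            analyte_name=a.name,
            stock_concentration=a.stock_concentration,
            aliquot_volumes=list(study.series_aliquots),
            final_volume=study.final_volume,
            areas=np.asarray(level_areas[a.name]),
        )
        curve = fit_calibration(series)
        if a.name in lowest_height and lowest_noise.get(a.name, 0.0) > 0:
            hpc = lowest_height[a.name] / series.concentrations[0]
            estimate_lod_loq(curve, lowest_noise[a.name], hpc)
        curves[a.name] = curve
        rows.append(
            {
                "analyte": a.name,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r": curve.r,
                "range_low_ug_per_ml": curve.linear_range[0],
                "range_high_ug_per_ml": curve.linear_range[1],
                "lod_ug_per_ml": curve.lod,
                "loq_ug_per_ml": curve.loq,
            }
        )
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 2: multipoint RCF
# ---------------------------------------------------------------------------

def run_rcf(study: StudyConfig) -> tuple[dict[str, RCFEstimate], pd.DataFrame]:
    """Inject the mixed standard at each configured volume and compute the
    multipoint RCF of every non-reference analyte against the reference."""
    ref = study.reference
    conc = study.mixed_standard_concentrations()
    areas_by_volume: list[dict[str, float]] = []
    for v, volume in enumerate(study.injection_volumes):
        sim = simulation_config(study, conc, injection_volume=volume, seed=derive_seed(study.seed, "rcf", v))
        peaks = _measure_known(study, sim)
        areas_by_volume.append({name: p.area for name, p in peaks.items()})

    estimates: dict[str, RCFEstimate] = {}
    for a in study.analytes:
        if a.is_reference:
            continue
        injections = [(areas[ref.name], areas[a.name]) for areas in areas_by_volume]
        estimates[a.name] = multipoint_rcf(
            injections,
            ref_conc=conc[ref.name],
            k_conc=conc[a.name],
            analyte_name=a.name,
            internal_reference=ref.name,
            wavelength=a.wavelength,
        )

    names = [a.name for a in study.analytes if not a.is_reference]
    table = pd.DataFrame(
        [
            {"injection_volume_uL": str(int(v))} | {n: round_half_up(estimates[n].per_injection_values[i]) for n in names}
            for i, v in enumerate(study.injection_volumes)
        ]
        + [
            {"injection_volume_uL": "Mean"} | {n: round_half_up(estimates[n].mean_rcf) for n in names},
            {"injection_volume_uL": "RSD%"} | {n: round_half_up(estimates[n].rsd_percent) for n in names},
        ]
    )
    return estimates, table


# ---------------------------------------------------------------------------
# stage 3: sample quantification (ES vs. QAMS)
# ---------------------------------------------------------------------------

def quantify_sample(
    study: StudyConfig,
    curves: dict[str, CalibrationCurve],
    rcfs: dict[str, RCFEstimate],
    concentrations: dict[str, float],
    seed: int,
    batch_id: str = "",
) -> list[ContentResult]:
    """Quantify one sample injection by both routes.

    The reference peak anchors localization; the five analytes are found by
    relative retention.  ES converts each located area through its own
    curve; QAMS converts through the RCF and the reference's ES
    concentration.  Absent analytes (negative controls) yield no result row.
    """
    sim = simulation_config(study, concentrations, study.sample_injection_volume, seed)
    ref = study.reference
    channel_peaks = {ch: detect_peaks(simulate_chromatogram(sim, ch), min_snr=study.min_snr) for ch in study.channels}

    ref_candidates = [p for p in channel_peaks[ref.wavelength] if abs(p.apex_time - ref.retention_time) < 0.5]
    if not ref_candidates:
        raise ValueError(f"reference peak ({ref.name}) not found in sample run {batch_id!r}")
    ref_peak = min(ref_candidates, key=lambda p: abs(p.apex_time - ref.retention_time))

    located: dict[str, Peak | None] = {ref.name: ref_peak}
    for channel in study.channels:
        targets = [
            RelativeRetention(a.name, study.expected_rtr(a.name), study.rtr_tolerance)
            for a in study.analytes
            if a.wavelength == channel and not a.is_reference
        ]
        if not targets:
            continue
        located.update(locate_peaks_by_rtr(channel_peaks[channel], ref_peak, targets))

    to_fraction = lambda conc: mass_fraction(conc, study.extract_volume_ml, study.sample_mass_g)
    ref_conc_es = es_content(curves[ref.name], ref_peak.area)
    results = [ContentResult(batch_id, ref.name, to_fraction(ref_conc_es), None)]
    for a in study.analytes:
        if a.is_reference:
            continue
        peak = located.get(a.name)
        if peak is None:
            continue
        es_conc = es_content(curves[a.name], peak.area)
        q_conc = qams_content(rcfs[a.name].mean_rcf, peak.area, ref_peak.area, ref_conc_es)
        results.append(ContentResult(batch_id, a.name, to_fraction(es_conc), to_fraction(q_conc)))
    return results


def run_samples(
    study: StudyConfig,
    curves: dict[str, CalibrationCurve],
    rcfs: dict[str, RCFEstimate],
) -> tuple[list[ContentResult], pd.DataFrame]:
    """Quantify every configured batch; emit the ES/QAMS/RE comparison table."""
    all_results: list[ContentResult] = []
    rows = []
    for b, batch_id in enumerate(study.batches):
        conc = study.batch_concentrations(batch_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # edge-of-range ES predictions
            results = quantify_sample(study, curves, rcfs, conc, derive_seed(study.seed, "sample", b), batch_id)
        all_results.extend(results)
        by_name = {r.analyte_name: r for r in results}
        fmt = lambda x: float(f"{x:.4g}") if x is not None and np.isfinite(x) else np.nan
        rows.append({"batch": batch_id, "method": "ES"} | {n: fmt(by_name[n].es_percent) for n in by_name})
        rows.append(
            {"batch": batch_id, "method": "QAMS"}
            | {n: fmt(by_name[n].qams_percent) if by_name[n].qams_percent is not None else np.nan for n in by_name}
        )
        rows.append(
            {"batch": batch_id, "method": "RE"}
            | {n: round_half_up(by_name[n].re_percent) if np.isfinite(by_name[n].re_percent) else np.nan for n in by_name}
        )
    return all_results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 4: validation battery
# ---------------------------------------------------------------------------

def _robustness_conditions(study: StudyConfig) -> dict[str, dict[str, dict]]:
    """One-axis-at-a-time condition grid: each condition perturbs retention
    (scale/offset) and detector response, deterministically from the study
    seed.

    Response changes are modelled as a common-mode gain shift (1% s.d.,
    shared by all analytes — detector gain, effective injection volume)
    plus a small per-analyte differential term (0.2% s.d.); the common mode
    cancels in RCF ratios, which is the premise of the multipoint design.
    """

    def perturb(tag: str, common_sd: float = 0.01, differential_sd: float = 0.002) -> dict[str, float]:
        rng = np.random.default_rng(derive_seed(study.seed, "robust", tag))
        common = float(rng.normal(0.0, common_sd))
        return {a.name: common + float(rng.normal(0.0, differential_sd)) for a in study.analytes}

    axes: dict[str, dict[str, dict]] = {
        "instrument": {
            "instrument_A": dict(retention_offset=0.0, response_perturbation=perturb("iA")),
            "instrument_B": dict(retention_offset=0.06, response_perturbation=perturb("iB")),
        },
        "column": {
            f"column_{c}": dict(
                retention_scale=s, retention_offset=o, response_perturbation=perturb(f"c{c}")
            )
            for c, s, o in (("1", 1.0, 0.0), ("2", 1.015, -0.04), ("3", 0.985, 0.05))
        },
        "flow_rate": {
            f"flow_{f}": dict(retention_scale=1.0 / f, response_perturbation=perturb(f"f{f}"))
            for f in (0.8, 1.0, 1.2)
        },
        "temperature": {
            f"temp_{t}": dict(retention_scale=1.0 - 0.002 * (t - 30), response_perturbation=perturb(f"t{t}"))
            for t in (25, 30, 35)
        },
    }
    return axes


def run_validation(
    study: StudyConfig,
    curves: dict[str, CalibrationCurve],
) -> dict[str, pd.DataFrame]:
    """Run the full validation battery on seeded simulations."""
    ref = study.reference
    mixed = study.mixed_standard_concentrations()
    batch_id = next(iter(study.batches))
    sample_conc = study.batch_concentrations(batch_id)
    names = [a.name for a in study.analytes]
    reports: dict[str, pd.DataFrame] = {}

    # precision: replicate injections of the mixed standard
    areas: dict[str, list[float]] = {n: [] for n in names}
    for r in range(study.n_replicates):
        sim = simulation_config(study, mixed, 5.0, derive_seed(study.seed, "precision", r))
        for name, peak in _measure_known(study, sim).items():
            areas[name].append(peak.area)
    reports["precision"] = run_precision_suite(areas, study.thresholds["precision_rsd"], expected=names)

    # stability: one test solution re-injected over 24 h, optional linear loss
    areas = {n: [] for n in names}
    for k, hour in enumerate(study.stability_timepoints_h):
        decayed = {n: c * max(0.0, 1.0 - study.stability_degradation_per_h * hour) for n, c in sample_conc.items()}
        sim = simulation_config(study, decayed, study.sample_injection_volume, derive_seed(study.seed, "stability", k))
        for name, peak in _measure_known(study, sim).items():
            areas[name].append(peak.area)
    reports["stability"] = run_precision_suite(areas, study.thresholds["stability_rsd"], expected=names)

    # repeatability: parallel preparations of the same batch → mass fractions
    fractions: dict[str, list[float]] = {n: [] for n in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(study.n_replicates):
            sim = simulation_config(study, sample_conc, study.sample_injection_volume, derive_seed(study.seed, "repeat", r))
            for name, peak in _measure_known(study, sim).items():
                conc = es_content(curves[name], peak.area)
                fractions[name].append(mass_fraction(conc, study.extract_volume_ml, study.sample_mass_g))
    reports["repeatability"] = run_precision_suite(fractions, study.thresholds["repeatability_rsd"], expected=names)

    # recovery: spike each analyte at ~100% of the batch content
    spike = dict(sample_conc)
    recoveries: dict[str, list[float]] = {n: [] for n in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base_sim = simulation_config(study, sample_conc, study.sample_injection_volume, derive_seed(study.seed, "recov-base"))
        base_peaks = _measure_known(study, base_sim)
        original = {
            n: es_content(curves[n], base_peaks[n].area) * study.extract_volume_ml for n in names
        }  # µg in the extract
        for r in range(study.n_replicates):
            spiked_conc = {n: sample_conc[n] + spike[n] for n in names}
            sim = simulation_config(study, spiked_conc, study.sample_injection_volume, derive_seed(study.seed, "recov", r))
            for name, peak in _measure_known(study, sim).items():
                found = es_content(curves[name], peak.area) * study.extract_volume_ml
                added = spike[name] * study.extract_volume_ml
                recoveries[name].append(recovery_rate(original[name], added, found))
    lo, hi = study.thresholds["recovery_low"], study.thresholds["recovery_high"]
    reports["recovery"] = pd.DataFrame(
        [
            {
                "analyte": n,
                "n": len(recoveries[n]),
                "mean_recovery_percent": float(np.mean(recoveries[n])),
                "rsd_percent": rsd(recoveries[n]),
                "status": "pass" if lo <= float(np.mean(recoveries[n])) <= hi else "fail",
            }
            for n in names
        ]
    )

    # RCF robustness and localization comparison share the condition grid;
    # each condition's RCF follows the same multipoint (multi-volume) design
    # as the primary estimate.
    grid_values: dict[str, dict[str, dict[str, float]]] = {}
    retention_by_condition: dict[str, dict[str, float]] = {}
    for axis, conditions in _robustness_conditions(study).items():
        grid_values[axis] = {}
        for c, (cond_name, kwargs) in enumerate(conditions.items()):
            scale = kwargs.get("retention_scale", 1.0)
            offset = kwargs.get("retention_offset", 0.0)
            expected_rt = {a.name: a.retention_time * scale + offset for a in study.analytes}
            per_volume: list[dict[str, float]] = []
            for v, volume in enumerate(study.injection_volumes):
                sim = simulation_config(
                    study, mixed, volume, derive_seed(study.seed, "robustcond", axis, c, v), **kwargs
                )
                peaks = _measure_known(study, sim, expected_rt=expected_rt)
                per_volume.append({n: p.area for n, p in peaks.items()})
                if v == 1:  # the 5 µL injection anchors retention bookkeeping
                    retention_by_condition[cond_name] = {n: p.apex_time for n, p in peaks.items()}
            grid_values[axis][cond_name] = {
                a.name: multipoint_rcf(
                    [(areas[ref.name], areas[a.name]) for areas in per_volume if a.name in areas],
                    ref_conc=mixed[ref.name],
                    k_conc=mixed[a.name],
                ).mean_rcf
                for a in study.analytes
                if not a.is_reference
            }
    reports["rcf_robustness"] = rcf_robustness(RobustnessGrid(grid_values), study.thresholds["rcf_robustness_rsd"])
    reports["localization"] = compare_localization_methods(retention_by_condition, ref.name)
    return reports


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(study: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Execute the whole study and (optionally) write the report bundle.

    Stages: calibrate → RCF → quantify every batch (ES and QAMS) → validate.
    Returns a dict with curves, RCF estimates, content results, and all
    report tables; with ``outdir`` set, writes one CSV per table plus a run
    log carrying seed, config hash, and software version.
    """
    curves, calib_table = run_calibration(study)
    rcfs, rcf_table = run_rcf(study)
    contents, content_table = run_samples(study, curves, rcfs)
    validation_reports = run_validation(study, curves)

    bundle = {
        "curves": curves,
        "calibration_table": calib_table,
        "rcfs": rcfs,
        "rcf_table": rcf_table,
        "contents": contents,
        "content_table": content_table,
        "validation": validation_reports,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"seed": study.seed, "config_hash": study.config_hash(), "version": __version__}
        calib_table.to_csv(outdir / "calibration.csv", index=False)
        rcf_table.to_csv(outdir / "rcf.csv", index=False)
        content_table.to_csv(outdir / "contents.csv", index=False)
        for name, report in validation_reports.items():
            report.to_csv(outdir / f"validation_{name}.csv", index=False)
        (outdir / "run_log.json").write_text(json.dumps(meta, indent=1))
    return bundle
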