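"""Single-marker multi-component quantification (QAMS).

One analyte — here gallic acid — serves as the internal reference.  A
relative correction factor (RCF)

    f_s/k = (W_k · A_s) / (W_s · A_k)

is established once from standard solutions (``s`` = reference, ``k`` =
analyte; ``W`` concentration, ``A`` peak area).  Because both areas scale
identically with injection volume and detector gain, the ratio cancels
them, which is why the multipoint design injects the same mixed standard at
several volumes and averages.

In a sample run, the analyte peak is located through its relative retention
time Rt_R = t_Rk / t_Rs against the reference peak, and its concentration is
recovered from the reference's externally calibrated concentration:

    W_k = f_s/k · W_s · A_k / A_s
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peaks import Peak

__all__ = [
    "RCFEstimate",
    "RelativeRetention",
    "ContentResult",
    "AnalyteSpec",
    "compute_rcf",
    "multipoint_rcf",
    "relative_retention",
    "locate_peaks_by_rtr",
    "qams_content",
    "mass_fraction",
    "relative_error",
]


@dataclass
class AnalyteSpec:
    """Configuration of one analyte in the study."""

    name: str
    wavelength: float  # nm, the channel this analyte is quantified on
    standard_concentration: float  # µg·mL⁻¹ in the mixed standard
    expected_rtr: float | None = None  # relative retention vs. the reference

    def __post_init__(self) -> None:
        if self.standard_concentration <= 0:
            raise ValueError(f"{self.name}: standard_concentration must be > 0")
        if self.wavelength not in (210.0, 225.0, 256.0, 320.0):
            raise ValueError(f"{self.name}: wavelength must be one of 210/225/256/320 nm")


@dataclass
class RCFEstimate:
    """Per-injection RCF values for one analyte with mean and RSD."""

    analyte_name: str
    internal_reference: str
    wavelength: float
    per_injection_values: list[float]
    mean_rcf: float = field(init=False)
    rsd_percent: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.per_injection_values, dtype=float)
        if vals.size < 2:
            raise ValueError("RCF RSD undefined for fewer than 2 injections")
        if np.any(vals <= 0):
            raise ValueError("per-injection RCF values must be positive")
        self.mean_rcf = float(vals.mean())
        self.rsd_percent = float(vals.std(ddof=1) / vals.mean() * 100.0)


@dataclass(frozen=True)
class RelativeRetention:
    """Expected relative retention of an analyte against the reference."""

    analyte_name: str
    rtr: float
    tolerance: float = 0.05  # fractional matching window

    def __post_init__(self) -> None:
        if self.rtr <= 0:
            raise ValueError("rtr must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ContentResult:
    """ES vs. QAMS content for one analyte in one batch."""

    batch_id: str
    analyte_name: str
    es_percent: float  # mass %
    qams_percent: float | None  # mass %; None for the internal reference
    re_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.qams_percent is None or self.es_percent == 0:
            self.re_percent = math.nan
        else:
            self.re_percent = relative_error(self.es_percent, self.qams_percent)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


def compute_rcf(ref_conc: float, ref_area: float, k_conc: float, k_area: float) -> float:
    """Relative correction factor f_s/k = (W_k · A_s) / (W_s · A_k)."""
    _require_positive(ref_conc=ref_conc, ref_area=ref_area, k_conc=k_conc, k_area=k_area)
    return (k_conc * ref_area) / (ref_conc * k_area)


def multipoint_rcf(
    injections: list[tuple[float, float]],
    ref_conc: float,
    k_conc: float,
    analyte_name: str = "",
    internal_reference: str = "",
    wavelength: float = float("nan"),
) -> RCFEstimate:
    """RCF from repeated injections of the same mixed standard.

    ``injections`` holds (reference area, analyte area) pairs, one per
    injection volume; per-injection RCFs are averaged and their n−1 RSD
    reported.
    """
    if len(injections) < 2:
        raise ValueError("multipoint RCF needs at least 2 injections")
    values = [compute_rcf(ref_conc, a_s, k_conc, a_k) for a_s, a_k in injections]
    return RCFEstimate(
        analyte_name=analyte_name,
        internal_reference=internal_reference,
        wavelength=wavelength,
        per_injection_values=values,
    )


def relative_retention(t_rk: float, t_rs: float) -> float:
    """Relative retention time Rt_R = t_Rk / t_Rs."""
    _require_positive(t_rk=t_rk, t_rs=t_rs)
    return t_rk / t_rs


def locate_peaks_by_rtr(
    sample_peaks: list[Peak],
    reference_peak: Peak | None,
    targets: list[RelativeRetention],
) -> dict[str, Peak | None]:
    """Assign analytes to peaks by closeness of observed to expected Rt_R.

    Globally greedy: candidate (target, peak) pairs are ranked by relative
    deviation of observed from expected Rt_R; pairs beyond a target's
    tolerance are discarded; each peak is used at most once.  Ties in
    deviation break to the earlier-eluting peak.  Unmatched targets map to
    ``None`` (absence, e.g. in negative controls), never an error.
    """
    if reference_peak is None:
        raise ValueError("reference peak missing: relative-retention localization impossible")
    if not targets:
        raise ValueError("no localization targets given")
    t_rs = reference_peak.apex_time
    candidates: list[tuple[float, float, int, str]] = []
    for target in targets:
        for j, peak in enumerate(sample_peaks):
            observed = peak.apex_time / t_rs
            deviation = abs(observed - target.rtr) / target.rtr
            if deviation <= target.tolerance:
                candidates.append((deviation, peak.apex_time, j, target.analyte_name))
    candidates.sort()
    assignment: dict[str, Peak | None] = {t.analyte_name: None for t in targets}
    used: set[int] = set()
    for deviation, _apex, j, name in candidates:
        if assignment[name] is not None or j in used:
            continue
        assignment[name] = sample_peaks[j]
        used.add(j)
    return assignment


def qams_content(rcf: float, k_area: float, ref_area: float, ref_conc_in_sample: float) -> float:
    """Analyte concentration implied by the single-marker model:
    W_k = f_s/k · W_s · A_k / A_s."""
    _require_positive(rcf=rcf, k_area=k_area, ref_area=ref_area, ref_conc_in_sample=ref_conc_in_sample)
    return rcf * ref_conc_in_sample * k_area / ref_area


def mass_fraction(conc: float, final_volume: float, sample_mass: float) -> float:
    """Mass percentage of the analyte in the solid sample.

    ``conc`` in µg·mL⁻¹ of the extract, ``final_volume`` in mL,
    ``sample_mass`` in g.
    """
    _require_positive(conc=conc, final_volume=final_volume, sample_mass=sample_mass)
    return (conc * final_volume) / (sample_mass * 1e6) * 100.0


def relative_error(es: float, qams: float) -> float:
    """Signed relative error between methods: (ES − QAMS)/ES × 100."""
    if es < 0:
        raise ValueError("es must be >= 0")
    if es == 0:
        return math.nan
    return (es - qams) / es * 100.0
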