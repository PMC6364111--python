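"""Synthetic multi-wavelength HPLC-DAD chromatogram generator.

Every downstream stage (peak picking, calibration, single-marker
quantification, validation statistics) is exercised against traces produced
here, where the ground truth — concentration, injection volume, response
factor, retention time — is known exactly.

Peak shape is an exponentially modified Gaussian (EMG), the standard model
for tailing chromatographic peaks; ``tau = 0`` degenerates to a pure
Gaussian.  Each peak's true integrated area is

    area [response·s] = concentration [µg·mL⁻¹] × injection_volume [µL]
                        × response_factor [response·s per µg·mL⁻¹·µL]

and the EMG is re-centred so its *mode* (apex) sits at the configured
retention time, which keeps apex-based retention bookkeeping honest for
tailed peaks.

Randomness (baseline noise, retention jitter) comes from a generator keyed
by ``(random_seed, channel)`` so each wavelength channel is reproducible
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import exponnorm, norm

from .peaks import Chromatogram

__all__ = ["AnalytePeakModel", "SimulationConfig", "simulate_chromatogram", "simulate_negative_control"]


@dataclass(frozen=True)
class AnalytePeakModel:
    """Shape and detector response of one analyte's chromatographic peak.

    ``response_factors`` maps detection wavelength (nm) to area response per
    (µg·mL⁻¹ · µL injected); a channel absent from the map (or mapped to 0)
    means the analyte does not absorb there.
    """

    analyte_name: str
    retention_time: float  # minutes (apex position)
    sigma: float  # minutes, Gaussian width
    tau: float  # minutes, exponential tail constant; 0 = pure Gaussian
    response_factors: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError(f"{self.analyte_name}: retention_time must be > 0")
        if self.sigma <= 0:
            raise ValueError(f"{self.analyte_name}: sigma must be > 0")
        if self.tau < 0:
            raise ValueError(f"{self.analyte_name}: tau must be >= 0")
        if any(v < 0 for v in self.response_factors.values()):
            raise ValueError(f"{self.analyte_name}: response factors must be >= 0")

    def response_at(self, channel: float) -> float:
        return self.response_factors.get(channel, 0.0)


@dataclass
class SimulationConfig:
    """Full description of one synthetic injection."""

    analyte_models: list[AnalytePeakModel]
    concentrations: dict[str, float]  # µg·mL⁻¹ per analyte
    injection_volume: float = 5.0  # µL
    channels: tuple[float, ...] = (210.0, 225.0, 256.0, 320.0)
    run_length: float = 53.0  # minutes
    sampling_rate: float = 5.0  # points per second
    noise_sd: float = 0.0  # signal units
    baseline_drift: float = 0.0  # signal units per minute
    retention_jitter_sd: float = 0.0  # minutes
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")
        names = [m.analyte_name for m in self.analyte_models]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in analyte_models")
        needed = max((m.retention_time + 5.0 * (m.sigma + m.tau) for m in self.analyte_models), default=0.0)
        if self.run_length < needed:
            raise ValueError(
                f"run_length {self.run_length} min too short to contain all peaks "
                f"(needs >= {needed:.2f} min)"
            )


@lru_cache(maxsize=256)
def _emg_mode_offset(k: float) -> float:
    """Mode of the standard exponnorm(K, loc=0, scale=1) density.

    Used to shift the EMG so its apex lands on the configured retention time.
    """
    if k <= 0:
        return 0.0
    dist = exponnorm(k)
    res = minimize_scalar(lambda x: -dist.pdf(x), bounds=(0.0, 2.0 * k + 2.0), method="bounded")
    return float(res.x)


def _peak_profile(t: np.ndarray, rt: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area peak density (per minute) with apex at ``rt``."""
    if tau <= 1e-12 * sigma:
        return norm.pdf(t, loc=rt, scale=sigma)
    k = tau / sigma
    loc = rt - _emg_mode_offset(k) * sigma
    return exponnorm.pdf(t, k, loc=loc, scale=sigma)


def simulate_chromatogram(config: SimulationConfig, channel: float) -> Chromatogram:
    """Simulate one detector channel: baseline drift + Gaussian noise +
    the sum of the configured analytes' EMG peaks.

    Deterministic for a given ``(random_seed, channel)`` pair.
    """
    if channel not in config.channels:
        raise ValueError(f"channel {channel} nm is not configured (have {list(config.channels)})")
    unknown = set(config.concentrations) - {m.analyte_name for m in config.analyte_models}
    if unknown:
        raise ValueError(f"concentrations given for unknown analytes: {sorted(unknown)}")

    dt_min = 1.0 / (config.sampling_rate * 60.0)
    n = int(round(config.run_length / dt_min)) + 1
    t = np.arange(n) * dt_min

    rng = np.random.default_rng([int(config.random_seed) & 0x7FFFFFFF, int(channel)])
    signal = config.baseline_drift * t
    for model in config.analyte_models:
        # jitter is drawn for every analyte regardless of response so the
        # noise stream stays aligned across negative-control variants.
        jitter = rng.normal(0.0, config.retention_jitter_sd) if config.retention_jitter_sd > 0 else 0.0
        conc = config.concentrations.get(model.analyte_name, 0.0)
        rf = model.response_at(channel)
        if conc <= 0 or rf <= 0:
            continue
        area = conc * config.injection_volume * rf  # response·seconds
        rt = model.retention_time + jitter
        signal = signal + (area / 60.0) * _peak_profile(t, rt, model.sigma, model.tau)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=n)

    return Chromatogram(
        times=t,
        signal=signal,
        wavelength=channel,
        injection_volume=config.injection_volume,
        sample_id=f"sim-seed{config.random_seed}",
    )


def simulate_negative_control(config: SimulationConfig, omit: set[str], channel: float) -> Chromatogram:
    """Simulate with the ``omit`` analytes' concentrations forced to zero,
    mirroring negative-control formulations lacking one herb's constituents."""
    known = {m.analyte_name for m in config.analyte_models}
    bad = set(omit) - known
    if bad:
        raise ValueError(f"unknown analyte(s) in omit: {sorted(bad)}")
    conc = {name: (0.0 if name in omit else c) for name, c in config.concentrations.items()}
    return simulate_chromatogram(replace(config, concentrations=conc), channel)
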