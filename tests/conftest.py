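"""Shared fixtures: the default six-analyte study and one full pipeline run.

The pipeline bundle is session-scoped — every stage's outputs (calibration
curves, RCF estimates, content comparison, validation reports) are computed
once and inspected by many tests.
"""

from __future__ import annotations

import time

import pytest

from qams_hplc.chromsim import AnalytePeakModel, SimulationConfig
from qams_hplc.study import default_study, run_pipeline

STUDY_SEED = 3


@pytest.fixture(scope="session")
def study():
    return default_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def bundle(study):
    """Full pipeline run; ``bundle['elapsed_s']`` records the wall time."""
    t0 = time.perf_counter()
    result = run_pipeline(study)
    result["elapsed_s"] = time.perf_counter() - t0
    return result


def make_simple_config(
    peaks: list[tuple[str, float, float, float, float]],
    concentrations: dict[str, float],
    *,
    channel: float = 210.0,
    run_length: float = 20.0,
    sampling_rate: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Small ad-hoc simulation: ``peaks`` holds (name, rt, sigma, tau, rf)."""
    models = [
        AnalytePeakModel(analyte_name=n, retention_time=rt, sigma=s, tau=tau, response_factors={channel: rf})
        for n, rt, s, tau, rf in peaks
    ]
    return SimulationConfig(
        analyte_models=models,
        concentrations=concentrations,
        channels=(channel,),
        run_length=run_length,
        sampling_rate=sampling_rate,
        noise_sd=noise_sd,
        random_seed=seed,
        **kwargs,
    )
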