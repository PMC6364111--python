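"""Peak processing: detection counts, integration accuracy and additivity,
signal-to-noise, plate number, and resolution."""

import numpy as np
import pytest

from qams_hplc.chromsim import simulate_chromatogram
from qams_hplc.peaks import (
    Chromatogram,
    Peak,
    detect_peaks,
    estimate_noise,
    integrate_peak,
    resolution,
    signal_to_noise,
    theoretical_plates,
)
from qams_hplc.study import simulation_config

from conftest import make_simple_config


def gaussian_trace(area=10.0, rt=5.0, sigma=0.05, run=10.0, rate=5.0, offset=0.0):
    t = np.arange(int(run * rate * 60) + 1) / (rate * 60.0)
    y = offset + (area / 60.0) / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    return Chromatogram(times=t, signal=y, wavelength=210.0)


class TestDetect:
    def test_baseline_only_yields_no_peaks(self):
        cfg = make_simple_config([("a", 5.0, 0.05, 0.0, 1.0)], {"a": 0.0}, noise_sd=0.02, seed=2)
        assert detect_peaks(simulate_chromatogram(cfg, 210.0)) == []

    def test_flat_zero_yields_no_peaks(self):
        t = np.linspace(0, 10, 3001)
        assert detect_peaks(Chromatogram(times=t, signal=np.zeros_like(t), wavelength=210.0)) == []

    def test_study_trace_has_three_peaks_at_210nm(self, study):
        """Only the three 210 nm-responsive analytes appear on that channel."""
        sim = simulation_config(study, study.mixed_standard_concentrations(), 5.0, seed=9)
        peaks = detect_peaks(simulate_chromatogram(sim, 210.0), min_snr=study.min_snr)
        assert len(peaks) == 3

    def test_two_gaussians_ten_sigma_apart(self):
        cfg = make_simple_config(
            [("a", 5.0, 0.05, 0.0, 2.0), ("b", 5.5, 0.05, 0.0, 2.0)], {"a": 1.0, "b": 1.0}
        )
        chrom = simulate_chromatogram(cfg, 210.0)
        peaks = detect_peaks(chrom)
        assert len(peaks) == 2
        dt = chrom.sampling_interval
        assert abs(peaks[0].apex_time - 5.0) <= dt
        assert abs(peaks[1].apex_time - 5.5) <= dt

    def test_min_snr_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_peaks(gaussian_trace(), min_snr=0.0)


class TestIntegrate:
    def test_noiseless_gaussian_within_point1_percent(self):
        chrom = gaussian_trace(area=10.0)
        assert integrate_peak(chrom, (4.5, 5.5)) == pytest.approx(10.0, rel=1e-3)

    def test_zero_signal_region_is_zero(self):
        chrom = gaussian_trace(area=10.0)
        assert integrate_peak(chrom, (7.0, 8.0)) == 0.0

    def test_constant_offset_is_removed_by_chord(self):
        chrom = gaussian_trace(area=0.0, offset=3.0)
        assert integrate_peak(chrom, (2.0, 4.0)) == pytest.approx(0.0, abs=1e-9)

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            integrate_peak(gaussian_trace(), (5.0, 4.0))

    def test_adjacent_intervals_are_additive(self):
        """On a baseline-corrected trace (zero between peaks), splitting at a
        baseline point gives area(A∪B) = area(A) + area(B)."""
        cfg = make_simple_config(
            [("a", 5.0, 0.05, 0.0, 2.0), ("b", 6.0, 0.05, 0.0, 1.0)], {"a": 1.0, "b": 1.0}
        )
        chrom = simulate_chromatogram(cfg, 210.0)
        whole = integrate_peak(chrom, (4.5, 6.5))
        left = integrate_peak(chrom, (4.5, 5.5))
        right = integrate_peak(chrom, (5.5, 6.5))
        assert left + right == pytest.approx(whole, rel=1e-6)

    def test_detect_then_integrate_recovers_truth(self, study):
        """Noiseless study chromatograms give every configured area to 1%."""
        conc = study.mixed_standard_concentrations()
        sim = simulation_config(study, conc, 5.0, seed=0)
        sim.noise_sd = 0.0
        sim.retention_jitter_sd = 0.0
        sim.baseline_drift = 0.0
        for analyte in study.analytes:
            chrom = simulate_chromatogram(sim, analyte.wavelength)
            peaks = detect_peaks(chrom)
            peak = min(peaks, key=lambda p: abs(p.apex_time - analyte.retention_time))
            truth = conc[analyte.name] * 5.0 * analyte.response_factor
            assert peak.area == pytest.approx(truth, rel=1e-2), analyte.name


class TestSignalToNoise:
    def _with_noise_window(self, height, noise_sd, seed=0):
        """Trace whose first 0.5 min is detrended noise with exact s.d."""
        rng = np.random.default_rng(seed)
        chrom = gaussian_trace(area=height * 0.05 * np.sqrt(2 * np.pi) * 60.0)
        mask = chrom.times <= 0.5
        raw = rng.normal(size=mask.sum())
        resid = raw - np.polyval(np.polyfit(chrom.times[mask], raw, 1), chrom.times[mask])
        chrom.signal[mask] = resid / np.std(resid, ddof=1) * noise_sd
        return chrom

    def test_definition(self):
        chrom = self._with_noise_window(height=30.0, noise_sd=10.0)
        peak = Peak(apex_time=5.0, area=1.0, height=30.0, width_half=0.1, bounds=(4, 6))
        assert signal_to_noise(chrom, peak, (0.0, 0.5)) == pytest.approx(3.0, rel=1e-9)

    def test_halving_noise_doubles_snr(self):
        peak = Peak(apex_time=5.0, area=1.0, height=30.0, width_half=0.1, bounds=(4, 6))
        full = signal_to_noise(self._with_noise_window(30.0, 10.0), peak, (0.0, 0.5))
        half = signal_to_noise(self._with_noise_window(30.0, 5.0), peak, (0.0, 0.5))
        assert half == pytest.approx(2.0 * full, rel=1e-9)

    def test_noiseless_window_is_an_error(self):
        chrom = gaussian_trace()
        peak = Peak(apex_time=5.0, area=1.0, height=1.0, width_half=0.1, bounds=(4, 6))
        with pytest.raises(ValueError):
            signal_to_noise(chrom, peak, (0.0, 0.5))

    def test_monte_carlo_matches_amplitude_over_noise(self):
        """Measured S/N tracks amplitude/noise_sd within 15% on average."""
        amplitude, noise_sd = 2.0, 0.05
        area = amplitude * 0.05 * np.sqrt(2 * np.pi) * 60.0
        ratios = []
        for seed in range(30):
            cfg = make_simple_config(
                [("a", 2.0, 0.05, 0.0, 1.0)], {"a": area}, run_length=4.0, noise_sd=noise_sd, seed=seed
            )
            cfg.injection_volume = 1.0
            chrom = simulate_chromatogram(cfg, 210.0)
            peaks = detect_peaks(chrom, min_snr=5.0)
            peak = min(peaks, key=lambda p: abs(p.apex_time - 2.0))
            ratios.append(signal_to_noise(chrom, peak, (0.0, 0.5)))
        assert np.mean(ratios) == pytest.approx(amplitude / noise_sd, rel=0.15)


class TestSuitability:
    def test_plate_number_formula(self):
        peak = Peak(apex_time=10.0, area=1.0, height=1.0, width_half=0.43, bounds=(9, 11))
        assert theoretical_plates(peak) == pytest.approx(2996.2, abs=0.05)

    def test_plate_number_unit_ratio(self):
        peak = Peak(apex_time=2.0, area=1.0, height=1.0, width_half=2.0, bounds=(0, 4))
        assert theoretical_plates(peak) == pytest.approx(5.54)

    def test_halving_width_quadruples_plates(self):
        wide = Peak(apex_time=10.0, area=1.0, height=1.0, width_half=0.4, bounds=(9, 11))
        narrow = Peak(apex_time=10.0, area=1.0, height=1.0, width_half=0.2, bounds=(9, 11))
        assert theoretical_plates(narrow) == pytest.approx(4 * theoretical_plates(wide))

    def test_coeluting_peaks_have_zero_resolution(self):
        p = Peak(apex_time=10.0, area=1.0, height=1.0, width_half=0.4, bounds=(9, 11))
        assert resolution(p, p) == 0.0

    def test_resolution_definition(self):
        w_half = 1.0 / (4.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))))  # base width 1
        p1 = Peak(apex_time=10.0, area=1.0, height=1.0, width_half=w_half, bounds=(9, 11))
        p2 = Peak(apex_time=12.0, area=1.0, height=1.0, width_half=w_half, bounds=(11, 13))
        assert resolution(p1, p2) == pytest.approx(2.0)

    def test_six_sigma_separation_gives_resolution_1_5(self):
        sigma = 0.05
        cfg = make_simple_config(
            [("a", 5.0, sigma, 0.0, 2.0), ("b", 5.0 + 6 * sigma, sigma, 0.0, 2.0)],
            {"a": 1.0, "b": 1.0},
            sampling_rate=20.0,
        )
        peaks = detect_peaks(simulate_chromatogram(cfg, 210.0))
        assert len(peaks) == 2
        assert resolution(peaks[0], peaks[1]) == pytest.approx(1.5, rel=0.05)

    def test_study_system_suitability(self, study):
        """All six analytes show N ≥ 3000 and neighbouring Rs > 1.5."""
        sim = simulation_config(study, study.mixed_standard_concentrations(), 5.0, seed=1)
        for channel in study.channels:
            peaks = detect_peaks(simulate_chromatogram(sim, channel), min_snr=study.min_snr)
            for p in peaks:
                assert theoretical_plates(p) >= 3000
            for p1, p2 in zip(peaks, peaks[1:]):
                assert resolution(p1, p2) > 1.5


def test_csv_round_trip(tmp_path):
    chrom = gaussian_trace()
    chrom.sample_id = "demo"
    chrom.to_csv(tmp_path / "trace.csv")
    back = Chromatogram.from_csv(tmp_path / "trace.csv")
    assert np.allclose(back.signal, chrom.signal)
    assert back.wavelength == 210.0 and back.sample_id == "demo"


def test_noise_estimate_ignores_linear_drift():
    t = np.linspace(0, 1, 301)
    rng = np.random.default_rng(0)
    noise = rng.normal(0, 0.1, t.size)
    flat = Chromatogram(times=t, signal=noise, wavelength=210.0)
    drifting = Chromatogram(times=t, signal=noise + 5.0 * t, wavelength=210.0)
    assert estimate_noise(drifting, (0, 1)) == pytest.approx(estimate_noise(flat, (0, 1)), rel=1e-6)
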