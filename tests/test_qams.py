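"""The single-marker core: relative correction factors, relative-retention
localization, QAMS content, mass fractions, and signed relative error —
anchored to the published RCF and content tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qams_hplc.chromsim import simulate_chromatogram, simulate_negative_control
from qams_hplc.peaks import Peak, detect_peaks
from qams_hplc.qams import (
    RelativeRetention,
    compute_rcf,
    locate_peaks_by_rtr,
    mass_fraction,
    multipoint_rcf,
    qams_content,
    relative_error,
    relative_retention,
)
from qams_hplc.study import round_half_up, simulation_config
from qams_hplc.tables import load_rcf_table

positive = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


class TestComputeRcf:
    def test_reference_against_itself_is_one(self):
        assert compute_rcf(5.0, 123.4, 5.0, 123.4) == 1.0

    def test_hand_evaluation(self):
        assert compute_rcf(ref_conc=2.0, ref_area=100.0, k_conc=1.0, k_area=25.0) == pytest.approx(2.0)

    @given(ref_conc=positive, ref_area=positive, k_conc=positive, k_area=positive, lam=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_joint_area_scaling(self, ref_conc, ref_area, k_conc, k_area, lam):
        base = compute_rcf(ref_conc, ref_area, k_conc, k_area)
        scaled = compute_rcf(ref_conc, ref_area * lam, k_conc, k_area * lam)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_nonpositive_input_names_the_symbol(self):
        with pytest.raises(ValueError, match="k_area"):
            compute_rcf(1.0, 1.0, 1.0, 0.0)


class TestMultipointRcf:
    @staticmethod
    def _from_values(values):
        # encode printed per-injection RCFs as (ref_area, analyte_area) pairs
        return multipoint_rcf([(v, 1.0) for v in values], ref_conc=1.0, k_conc=1.0)

    @pytest.mark.parametrize(
        "analyte,mean,rsd",
        [("matrine", 3.80, 1.17), ("oxymatrine", 3.03, 1.65), ("catechin", 0.39, 1.42), ("rutin", 2.31, 0.66), ("ferulic_acid", 2.38, 0.91)],
    )
    def test_published_per_injection_values_reproduce_summary(self, analyte, mean, rsd):
        per_injection, _, _ = load_rcf_table()
        est = self._from_values(per_injection[analyte].tolist())
        assert round_half_up(est.mean_rcf) == mean
        assert round_half_up(est.rsd_percent) == rsd

    def test_constant_values_give_zero_rsd(self):
        est = self._from_values([2.5] * 5)
        assert est.mean_rcf == pytest.approx(2.5)
        assert est.rsd_percent == 0.0

    def test_single_injection_is_an_error(self):
        with pytest.raises(ValueError):
            multipoint_rcf([(1.0, 1.0)], 1.0, 1.0)


class TestRelativeRetention:
    def test_reference_against_itself(self):
        assert relative_retention(8.0, 8.0) == 1.0

    def test_direct_ratio(self):
        assert relative_retention(20.0, 8.0) == 2.5

    @given(t_rk=positive, t_rs=positive, clock=st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_clock_rescaling(self, t_rk, t_rs, clock):
        assert relative_retention(t_rk * clock, t_rs * clock) == pytest.approx(
            relative_retention(t_rk, t_rs), rel=1e-9
        )

    def test_nonpositive_time_error(self):
        with pytest.raises(ValueError):
            relative_retention(0.0, 1.0)


def _peak(apex, area=10.0):
    return Peak(apex_time=apex, area=area, height=1.0, width_half=0.1, bounds=(apex - 0.5, apex + 0.5))


class TestLocalization:
    def test_full_mixture_all_matched(self, study):
        """Jitter-free study run: every analyte lands on its ground-truth peak."""
        sim = simulation_config(study, study.mixed_standard_concentrations(), 5.0, seed=0)
        sim.retention_jitter_sd = 0.0
        ref = study.reference
        ref_peaks = detect_peaks(simulate_chromatogram(sim, ref.wavelength), min_snr=study.min_snr)
        ref_peak = min(ref_peaks, key=lambda p: abs(p.apex_time - ref.retention_time))
        dt = 1.0 / (sim.sampling_rate * 60.0)
        for channel in study.channels:
            targets = [
                RelativeRetention(a.name, study.expected_rtr(a.name), study.rtr_tolerance)
                for a in study.analytes
                if a.wavelength == channel and not a.is_reference
            ]
            if not targets:
                continue
            peaks = detect_peaks(simulate_chromatogram(sim, channel), min_snr=study.min_snr)
            assignment = locate_peaks_by_rtr(peaks, ref_peak, targets)
            for a in study.analytes:
                if a.wavelength != channel or a.is_reference:
                    continue
                assert assignment[a.name] is not None
                # noise can shift a small peak's argmax by a few samples
                assert abs(assignment[a.name].apex_time - a.retention_time) <= max(3 * dt, 0.02)

    def test_negative_control_reports_absence_not_error(self, study):
        sim = simulation_config(study, study.mixed_standard_concentrations(), 5.0, seed=2)
        ref = study.reference
        ref_peaks = detect_peaks(simulate_chromatogram(sim, ref.wavelength), min_snr=study.min_snr)
        ref_peak = min(ref_peaks, key=lambda p: abs(p.apex_time - ref.retention_time))
        control = simulate_negative_control(sim, {"matrine"}, 210.0)
        peaks = detect_peaks(control, min_snr=study.min_snr)
        targets = [
            RelativeRetention(a.name, study.expected_rtr(a.name), study.rtr_tolerance)
            for a in study.analytes
            if a.wavelength == 210.0
        ]
        assignment = locate_peaks_by_rtr(peaks, ref_peak, targets)
        assert assignment["matrine"] is None
        assert assignment["oxymatrine"] is not None
        assert assignment["catechin"] is not None

    def test_equidistant_candidates_break_to_earlier_peak(self):
        ref = _peak(10.0)
        candidates = [_peak(19.0), _peak(21.0)]  # Rt_R 1.9 and 2.1, target 2.0
        result = locate_peaks_by_rtr(candidates, ref, [RelativeRetention("x", 2.0, 0.1)])
        assert result["x"].apex_time == 19.0

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            locate_peaks_by_rtr([_peak(5.0)], None, [RelativeRetention("x", 1.2)])

    def test_each_peak_used_at_most_once(self):
        ref = _peak(10.0)
        peaks = [_peak(11.9), _peak(12.4)]
        targets = [RelativeRetention("near", 1.2, 0.05), RelativeRetention("far", 1.25, 0.05)]
        result = locate_peaks_by_rtr(peaks, ref, targets)
        assert result["near"] is not result["far"]


class TestQamsContent:
    def test_marker_quantifies_itself(self):
        assert qams_content(1.0, 50.0, 50.0, 7.5) == pytest.approx(7.5)

    def test_closed_loop_is_algebraic_identity(self):
        """RCF from a standard run, applied back to the same run, returns the
        analyte's standard concentration exactly."""
        ref_conc, ref_area, k_conc, k_area = 4.44, 123.456, 1.73, 98.765
        rcf = compute_rcf(ref_conc, ref_area, k_conc, k_area)
        assert qams_content(rcf, k_area, ref_area, ref_conc) == pytest.approx(k_conc, rel=1e-14)

    def test_synthetic_sample_with_independent_standard_rcf(self, bundle, study):
        """QAMS contents track generator truth within 2% when RCFs come from
        the independent standard runs."""
        truth = study.batches
        for result in bundle["contents"]:
            if result.qams_percent is None:
                continue
            expected = truth[result.batch_id][result.analyte_name]
            assert result.qams_percent == pytest.approx(expected, rel=0.02), result.analyte_name

    def test_nonpositive_input_error(self):
        with pytest.raises(ValueError):
            qams_content(1.0, 0.0, 1.0, 1.0)


class TestMassFraction:
    def test_unit_bookkeeping(self):
        assert mass_fraction(1000.0, 10.0, 1.0) == pytest.approx(1.0)

    def test_halving_mass_doubles_fraction(self):
        assert mass_fraction(500.0, 10.0, 2.5) == pytest.approx(2 * mass_fraction(500.0, 10.0, 5.0))

    @given(conc=positive)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_five_gram_ten_ml_simplification(self, conc):
        assert mass_fraction(conc, 10.0, 5.0) == pytest.approx(conc * 2e-4, rel=1e-12)

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            mass_fraction(1.0, 0.0, 1.0)


class TestRelativeError:
    @pytest.mark.parametrize("es,qams,expected", [(0.1190, 0.1170, 1.68), (1.3427, 1.3138, 2.15)])
    def test_published_pairs(self, es, qams, expected):
        assert round_half_up(relative_error(es, qams)) == expected

    def test_equal_methods_give_zero(self):
        assert relative_error(0.5, 0.5) == 0.0

    def test_zero_es_is_undefined_marker(self):
        assert math.isnan(relative_error(0.0, 0.1))
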