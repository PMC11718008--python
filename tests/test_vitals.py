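import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radarvitals as rv
from radarvitals import (GroundTruth, InsufficientBeats, PhysioProfile,
                         classify_morphology, compute_hrv, detect_valleys,
                         evaluate_against_truth, fuse_bins,
                         generate_cardiac_template, generate_displacement)

FS = 20.0


def template_train(kinds, ibi_s=1.0, fs=64.0):
    """Concatenate unit cardiac cycles, each starting at its valley, so
    every valley-to-valley segment holds exactly one cycle kind."""
    n = int(ibi_s * fs)
    shift = int(round(0.8 * n))
    cycles = [np.roll(generate_cardiac_template(k, 0.7, n), -shift)
              for k in kinds]
    trace = np.concatenate(cycles)
    valleys = np.arange(len(kinds)) * ibi_s
    return trace, valleys


class TestDetectValleys:
    def test_sinusoid_valley_count_and_times(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        v = detect_valleys(x, FS)
        assert v.size == 10
        expected = 0.75 + np.arange(10)
        np.testing.assert_allclose(v, expected, atol=0.01)

    def test_clean_template_train_counts_cycles(self):
        profile = PhysioProfile(breathing_amplitude=0.0, mean_ibi=1.0,
                                ibi_sd=20.0, seed=1)
        disp, truth = generate_displacement(profile, None, 60.0, FS)
        from radarvitals.cardiac import bandpass_cardiac
        v = detect_valleys(bandpass_cardiac(disp, FS), FS, expected_rate_hz=1.0)
        assert truth.valley_times.size - 2 <= v.size <= truth.valley_times.size + 2

    def test_shallow_spurious_dip_rejected(self):
        t = np.arange(0, 12, 1 / FS)
        x = -np.cos(2 * np.pi * 1.0 * t)
        # one shallow dip (10 % of cycle amplitude) riding on a crest
        dip = 0.2 * np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2)
        v = detect_valleys(x - 0.0 + 0 * t, FS)
        v_dip = detect_valleys(x - dip, FS)
        assert v_dip.size == v.size

    def test_too_few_valleys_raises(self):
        t = np.arange(0, 1.2, 1 / FS)
        with pytest.raises(InsufficientBeats):
            detect_valleys(np.sin(2 * np.pi * t), FS)


class TestComputeHRV:
    def test_worked_example(self):
        """IBIs 800/860/865/920 ms: diffs (60, 5, 55) give RMSSD 47.08 ms
        and pNN50 66.67 %; population SDRR is 42.48 ms."""
        ibis = np.array([800.0, 860.0, 865.0, 920.0]) / 1000.0
        valleys = np.concatenate([[0.0], np.cumsum(ibis)])
        m = compute_hrv(valleys)
        assert m.rmssd == pytest.approx(47.0815, abs=0.01)
        assert m.pnn50 == pytest.approx(66.6667, abs=0.01)
        assert m.sdrr == pytest.approx(np.std([800, 860, 865, 920]), abs=0.01)
        assert m.hr == pytest.approx(60000.0 / 861.25, abs=0.01)

    def test_constant_series_zero_variability(self):
        valleys = np.arange(10) * 0.9
        m = compute_hrv(valleys)
        assert m.rmssd == pytest.approx(0.0, abs=1e-9)
        assert m.sdrr == pytest.approx(0.0, abs=1e-9)
        assert m.pnn50 == 0.0

    def test_too_few_valleys_rejected(self):
        with pytest.raises(InsufficientBeats):
            compute_hrv([0.0, 0.9, 1.8])

    def test_skipped_beat_screened_out(self):
        times = list(np.arange(20) * 0.8)
        del times[10]          # one missed detection -> 1.6 s interval
        m = compute_hrv(np.array(times))
        assert m.rmssd == pytest.approx(0.0, abs=1e-9)
        assert m.ibi_series.max() < 1000.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        ibis = rng.uniform(0.55, 0.65, 40)
        v1 = np.concatenate([[0], np.cumsum(ibis)])
        v2 = np.concatenate([[0], np.cumsum(2 * ibis)])
        m1, m2 = compute_hrv(v1), compute_hrv(v2)
        assert m2.sdrr == pytest.approx(2 * m1.sdrr, rel=1e-9)
        assert m2.rmssd == pytest.approx(2 * m1.rmssd, rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        ibis = rng.uniform(0.5, 1.2, 20)
        v = np.concatenate([[0.0], np.cumsum(ibis)])
        m = compute_hrv(v)
        shifted = compute_hrv(v + 17.3)
        assert 0.0 <= m.pnn50 <= 100.0
        assert m.rmssd >= 0.0 and m.sdrr >= 0.0
        assert shifted.rmssd == pytest.approx(m.rmssd, rel=1e-9)
        assert shifted.sdrr == pytest.approx(m.sdrr, rel=1e-9)

    def test_sdrr_recovered_from_full_chain(self):
        """300 s recording with 40 ms IBI jitter: estimated SDRR within
        7 ms of the ground-truth value."""
        profile = rv.cohort_profile(3)
        cube, truth = rv.simulate_recording(profile, None, duration=300.0)
        res = rv.run_pipeline(cube)
        sdrr_true = compute_hrv(truth.valley_times).sdrr
        assert abs(res.report.sdrr - sdrr_true) <= 7.0


class TestClassifyMorphology:
    def test_two_peak_train(self):
        trace, valleys = template_train(["two_peak"] * 12)
        assert classify_morphology(trace, 64.0, valleys) == "typical_two_peak"

    def test_three_peak_train(self):
        trace, valleys = template_train(["three_peak"] * 12)
        assert classify_morphology(trace, 64.0, valleys) == "atypical_multi_peak"

    def test_even_mixture_is_indeterminate(self):
        # 13 valleys -> 12 complete cycles, exactly half of each shape
        trace, valleys = template_train(["two_peak", "three_peak"] * 7)
        assert classify_morphology(trace, 64.0, valleys[:13]) == "indeterminate"

    def test_too_few_cycles_indeterminate(self):
        trace, valleys = template_train(["two_peak"] * 4)
        assert classify_morphology(trace, 64.0, valleys) == "indeterminate"


class TestFuseBins:
    def test_corrupted_bin_excluded(self):
        good = np.arange(0.5, 60.0, 0.9)
        trains = [good + e for e in (0.0, 0.005, -0.004, 0.006, -0.002)]
        trains.append(np.arange(0.5, 60.0, 0.45))          # doubled beats
        hrs = [60 / 0.9] * 5 + [60 / 0.45]
        fused, surviving, ref = fuse_bins(trains, hrs)
        assert 5 not in surviving
        assert fused.size == good.size
        np.testing.assert_allclose(fused, good, atol=0.01)

    def test_single_bin_identity(self):
        train = np.arange(0.5, 30.0, 0.8)
        fused, surviving, ref = fuse_bins([train], [75.0])
        np.testing.assert_array_equal(fused, train)

    def test_identical_bins_noop(self):
        train = np.arange(0.5, 30.0, 0.8)
        fused, surviving, _ = fuse_bins([train] * 4, [75.0] * 4)
        np.testing.assert_allclose(fused, train, atol=1e-12)
        assert surviving.size == 4

    def test_minority_spurious_beat_suppressed(self):
        good = np.arange(0.5, 30.0, 0.8)
        bad = np.sort(np.append(good, 10.1))   # one hallucinated beat
        fused, _, _ = fuse_bins([good, good, good, bad], [75.0] * 4)
        assert fused.size == good.size


class TestEvaluateAgainstTruth:
    def make_truth(self, valleys):
        return GroundTruth.from_valleys(valleys, 15.0, np.zeros(10), np.arange(10))

    def test_identity_has_zero_errors(self):
        v = np.arange(0.5, 60.0, 0.85)
        cmp = evaluate_against_truth(v, self.make_truth(v))
        assert cmp.median_abs_ibi_error_ms == 0.0
        assert cmp.n_missed == 0
        assert cmp.hr_relative_error_pct == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_invisible_to_ibi(self):
        v = np.arange(0.5, 60.0, 0.85)
        cmp = evaluate_against_truth(v + 0.020, self.make_truth(v))
        assert cmp.median_abs_ibi_error_ms == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(cmp.valley_offsets_ms, 20.0, atol=1e-6)

    def test_missing_beat_counted(self):
        v = np.arange(0.5, 30.0, 0.85)
        est = np.delete(v, 7)
        cmp = evaluate_against_truth(est, self.make_truth(v))
        assert cmp.n_missed == 1
        assert cmp.n_matched == v.size - 1

    def test_empty_estimate_all_missed(self):
        v = np.arange(0.5, 10.0, 0.85)
        cmp = evaluate_against_truth(np.empty(0), self.make_truth(v))
        assert cmp.n_missed == v.size
        assert np.isnan(cmp.median_abs_ibi_error_ms)
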