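import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks

import radarvitals as rv
from radarvitals import (NoCardiacFound, PhysioProfile, ReconstructionRefused,
                         generate_displacement)
from radarvitals.cardiac import (bandpass_cardiac, reconstruct,
                                 select_harmonics)
from radarvitals.respiration import estimate_br
from radarvitals.vmd import vmd_decompose

FS = 20.0


def tone(freq, duration=120.0):
    t = np.arange(0, duration, 1 / FS)
    return np.sin(2 * np.pi * freq * t)


def decompose(profile, duration=150.0):
    disp, truth = generate_displacement(profile, None, duration, FS)
    resp = estimate_br(disp, FS)
    band = bandpass_cardiac(disp, FS)
    imfs = vmd_decompose(band, fs=FS)
    return imfs, resp, truth


class TestCardiacBandpass:
    def test_low_edge_passes_slow_heart(self):
        """A 0.9 Hz fundamental (54 beats/min) must lose < 3 dB: a higher
        edge would suppress the true HR and report its 2nd harmonic."""
        x = tone(0.9)
        y = bandpass_cardiac(x, FS)
        core = slice(400, -400)
        loss = 20 * np.log10(np.sqrt(np.mean(x[core]**2))
                             / np.sqrt(np.mean(y[core]**2)))
        assert loss < 3.0

    def test_breathing_fundamental_rejected(self):
        x = tone(0.3)
        y = bandpass_cardiac(x, FS)
        core = slice(800, -800)
        atten = 20 * np.log10(np.sqrt(np.mean(x[core]**2))
                              / np.sqrt(np.mean(y[core]**2)))
        assert atten >= 40.0

    def test_mid_band_preserved(self):
        x = tone(2.0)
        y = bandpass_cardiac(x, FS)
        core = slice(400, -400)
        assert np.sqrt(np.mean(y[core]**2)) == pytest.approx(
            np.sqrt(np.mean(x[core]**2)), rel=0.05)


class TestSelectHarmonics:
    def test_shallow_breathing_selects_dominant_cardiac(self):
        """Shallow breathing: the strongest in-band component is the
        cardiac fundamental and is selected directly."""
        profile = PhysioProfile(breathing_rate=17.0, breathing_amplitude=0.4,
                                mean_ibi=1.0, seed=21)
        imfs, resp, truth = decompose(profile)
        plan = select_harmonics(imfs, resp)
        assert plan.fundamental_hz == pytest.approx(1.0, abs=0.08)
        assert 1 in plan.harmonic_orders and len(plan.harmonic_orders) >= 2

    def test_deep_breathing_rejects_breathing_harmonic(self):
        """Deep breathing: the strongest component sits at 2x the
        breathing rate; it must be rejected and the true fundamental
        returned."""
        profile = PhysioProfile(breathing_rate=17.0, breathing_amplitude=4.0,
                                breathing_harmonic_weights=(0.15, 0.005, 0.002),
                                mean_ibi=1 / 1.3, seed=22)
        imfs, resp, truth = decompose(profile)
        # the regime is real: the strongest mode is the breathing 2nd harmonic
        strongest = imfs.center_frequencies[int(np.argmax(imfs.powers))]
        assert strongest == pytest.approx(2 * resp.peak_frequency, abs=0.1)
        plan = select_harmonics(imfs, resp)
        # mode centre is pulled slightly toward the 4th breathing harmonic
        assert plan.fundamental_hz == pytest.approx(1.3, abs=0.12)

    def test_fundamental_on_breathing_multiple_refuses(self):
        """HR locked to exactly 2x BR: the chain must refuse rather than
        report a breathing harmonic as a heartbeat."""
        profile = PhysioProfile(breathing_rate=27.0, breathing_amplitude=1.0,
                                mean_ibi=1 / 0.9, seed=23)
        assert 1 / profile.mean_ibi == pytest.approx(2 * 27.0 / 60.0)
        imfs, resp, _ = decompose(profile)
        with pytest.raises((ReconstructionRefused, NoCardiacFound)):
            select_harmonics(imfs, resp)

    def test_no_breathing_multiple_among_selected(self):
        """No selected component may sit on k x BR (k = 1..4)."""
        cfg = rv.PipelineConfig()
        for seed in (31, 32):
            profile = rv.cohort_profile(seed)
            imfs, resp, _ = decompose(profile)
            plan = select_harmonics(imfs, resp, cfg)
            for comp in plan.components:
                centre = np.average(imfs.center_frequencies[comp],
                                    weights=imfs.powers[comp] + 1e-30)
                for k in range(1, 5):
                    target = k * resp.peak_frequency
                    assert abs(centre - target) > cfg.harmonic_tolerance(target)


class TestReconstruct:
    def test_sum_of_selected_modes(self):
        profile = PhysioProfile(seed=24)
        imfs, resp, _ = decompose(profile)
        plan = select_harmonics(imfs, resp)
        wave = reconstruct(plan, imfs)
        np.testing.assert_array_equal(
            wave.trace, imfs.modes[plan.mode_indices].sum(axis=0))
        assert wave.hr_spectral == pytest.approx(60.0 * wave.fundamental)

    def test_short_plan_refused(self):
        profile = PhysioProfile(seed=24)
        imfs, resp, _ = decompose(profile)
        plan = select_harmonics(imfs, resp)
        plan.mode_indices = plan.mode_indices[:1]
        with pytest.raises(ReconstructionRefused):
            reconstruct(plan, imfs)

    def test_two_peak_cycles_survive_reconstruction(self):
        """Clean two-peak source: at least 80 % of reconstructed cycles
        show two local maxima then the valley."""
        profile = PhysioProfile(breathing_amplitude=0.4, mean_ibi=0.95,
                                ibi_sd=20.0, seed=25)
        imfs, resp, truth = decompose(profile)
        plan = select_harmonics(imfs, resp)
        wave = reconstruct(plan, imfs)
        valleys = rv.detect_valleys(wave.trace, FS,
                                    expected_rate_hz=wave.fundamental)
        good = 0
        total = 0
        for t0, t1 in zip(valleys[:-1], valleys[1:]):
            seg = wave.trace[int(np.ceil(t0 * FS)): int(t1 * FS) + 1]
            if seg.size < 8:
                continue
            pk, _ = find_peaks(seg, prominence=0.2 * np.ptp(seg))
            total += 1
            good += pk.size == 2
        assert total > 100
        assert good / total >= 0.8

    def test_valley_offset_against_truth(self):
        """Median valley offset below 40 ms on clean input (IBI work is
        offset-invariant, but the fiducial must stay put)."""
        profile = PhysioProfile(breathing_amplitude=0.4, mean_ibi=0.95,
                                ibi_sd=20.0, seed=25)
        imfs, resp, truth = decompose(profile)
        plan = select_harmonics(imfs, resp)
        wave = reconstruct(plan, imfs)
        valleys = rv.detect_valleys(wave.trace, FS,
                                    expected_rate_hz=wave.fundamental)
        cmp = rv.evaluate_against_truth(valleys, truth)
        assert abs(np.median(cmp.valley_offsets_ms)) < 40.0

    def test_valley_stability_without_4th_harmonic(self):
        """Valleys are the robust fiducial: dropping the weakest (4th)
        harmonic from the plan moves them by < 10 ms on average."""
        profile = PhysioProfile(breathing_amplitude=0.4, mean_ibi=0.95,
                                ibi_sd=20.0, seed=26)
        imfs, resp, _ = decompose(profile)
        plan = select_harmonics(imfs, resp)
        if 4 not in plan.harmonic_orders:
            pytest.skip("plan did not recruit a 4th harmonic")
        full = reconstruct(plan, imfs)
        keep = [g for o, g in zip(plan.harmonic_orders, plan.components) if o != 4]
        import copy
        reduced = copy.deepcopy(plan)
        reduced.components = keep
        reduced.harmonic_orders = [o for o in plan.harmonic_orders if o != 4]
        reduced.mode_indices = [m for g in keep for m in g]
        part = reconstruct(reduced, imfs)
        v_full = rv.detect_valleys(full.trace, FS, expected_rate_hz=full.fundamental)
        v_part = rv.detect_valleys(part.trace, FS, expected_rate_hz=part.fundamental)
        shifts = []
        for t in v_full:
            j = np.argmin(np.abs(v_part - t))
            if abs(v_part[j] - t) < 0.2:
                shifts.append(abs(v_part[j] - t) * 1000)
        assert np.median(shifts) < 10.0
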