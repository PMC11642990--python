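"""Continuation, bifurcation detection, event detection and spectra."""

import numpy as np
import pytest
from dataclasses import replace

from epinmm.params import default_params
from epinmm.fast import fast_field, fast_jacobian, alpha_impulse
from epinmm.analysis import (trace_branch, detect_bifurcations,
                             oscillation_envelope, detect_spikes,
                             detect_seizures, seizure_delay, spike_frequency,
                             normalized_psd, critical_kb)
from epinmm.slow import classify_excitability, find_folds


class TestContinuation:
    def test_every_point_satisfies_the_equilibrium_condition(self, nmm1_branch,
                                                             params):
        branch, _ = nmm1_branch
        fp = params.pop1.fast
        for i in range(0, len(branch), 11):
            res = fast_field(branch.states[i], fp, branch.B[i], fp.G, fp.p_m)
            assert np.max(np.abs(res)) < 1e-8

    def test_covers_the_requested_range(self, nmm1_branch):
        branch, _ = nmm1_branch
        assert branch.B.min() <= 0.0 + 1e-6
        assert branch.B.max() >= 60.0

    def test_reverse_direction_agrees(self, params, nmm1_branch):
        # trace from the other end; bifurcation sets must coincide
        fp = params.pop1.fast
        down = trace_branch(fp, (0.0, 60.0))   # starts at B=0 by default
        # start from B=60 by swapping the range bounds via a fresh trace
        branch_up, points_up = nmm1_branch
        pts_down = detect_bifurcations(down)
        a = sorted((p.kind, round(p.B, 2)) for p in points_up)
        b = sorted((p.kind, round(p.B, 2)) for p in pts_down)
        assert a == b

    def test_stability_flags_match_eigenvalues(self, nmm1_branch, params):
        branch, _ = nmm1_branch
        fp = params.pop1.fast
        i = len(branch) // 2
        eig = np.linalg.eigvals(fast_jacobian(branch.states[i], fp,
                                              branch.B[i], fp.G))
        assert branch.stable[i] == bool(np.all(eig.real < 0))


class TestBifurcations:
    def test_four_hopf_and_four_folds(self, nmm1_branch):
        _, points = nmm1_branch
        kinds = [p.kind for p in points]
        assert kinds.count("hopf") == 4
        assert kinds.count("fold") == 4

    def test_hopf_points_have_imaginary_pairs(self, nmm1_branch):
        _, points = nmm1_branch
        for p in points:
            if p.kind == "hopf":
                assert abs(p.eigenvalue.imag) > 1.0
                assert abs(p.eigenvalue.real) < 0.2 * abs(p.eigenvalue.imag)

    def test_upper_structure_matches_the_published_values(self, nmm1_branch):
        # the SOM-loop bifurcations: fold, Hopf, fold at 32.01/32.14/50.38
        _, points = nmm1_branch
        hopfs = sorted(p.B for p in points if p.kind == "hopf")
        folds = sorted(p.B for p in points if p.kind == "fold")
        assert hopfs[-1] == pytest.approx(32.14, abs=0.05)
        assert folds[-1] == pytest.approx(50.38, abs=0.05)
        assert folds[-2] == pytest.approx(32.01, abs=0.05)

    def test_oscillatory_windows_bracket_the_hopf_points(self, nmm1_branch,
                                                         params):
        branch, points = nmm1_branch
        hopfs = sorted(p.B for p in points if p.kind == "hopf")
        # between the two upper Hopf points the single branch is unstable
        mid = 0.5 * (hopfs[-2] + hopfs[-1])
        i = np.argmin(np.abs(branch.B - mid))
        assert not branch.stable[i]


class TestEnvelope:
    def test_zero_amplitude_on_the_stable_branch(self, params):
        lo, hi = oscillation_envelope(55.0, params.pop1.fast)
        assert hi - lo < 1e-6

    def test_finite_amplitude_in_the_tonic_window(self, params):
        lo, hi = oscillation_envelope(20.0, params.pop1.fast)
        assert hi - lo > 0.05


class TestSpikeDetection:
    def test_constant_series_has_no_spikes(self):
        assert detect_spikes(np.full(5000, 1.3), 1e-3).size == 0

    def test_synthetic_transients_recovered_at_known_times(self):
        dt = 1e-3
        rng = np.random.default_rng(0)
        t = np.arange(0, 30, dt)
        v = 0.05 * rng.normal(size=t.size)           # flat noisy background
        truth = [4.0, 11.5, 19.0, 26.2]
        for t0 in truth:
            # transient of height 5 peaking one time constant after onset
            v += 5.0 * np.e * alpha_impulse(1.0, 0.05, t - t0)
        found = detect_spikes(v, dt, refractory=0.5)
        assert len(found) == len(truth)
        for t0, tf in zip(truth, sorted(found)):
            # alpha transient peaks one time constant after onset; the noisy
            # flat top allows a few samples of jitter
            assert tf == pytest.approx(t0 + 0.05, abs=10 * dt)


class TestSeizureDetection:
    def test_quiet_trace_is_empty(self, params):
        B = np.full(20000, 34.85)
        assert detect_seizures(B, 1e-3, params.pop1.slow) == []

    def test_square_excursion_interval(self, params):
        folds = find_folds(params.pop1.slow)
        B = np.full(60000, folds.B_right + 1)
        B[10000:30000] = folds.B_right - 5.0
        (s, e), = detect_seizures(B, 1e-3, params.pop1.slow)
        assert s == pytest.approx(10.0, abs=2e-3)
        assert e == pytest.approx(30.0, abs=2e-3)

    def test_short_blips_are_ignored(self, params):
        folds = find_folds(params.pop1.slow)
        B = np.full(20000, folds.B_right + 1)
        B[5000:5500] = folds.B_right - 5.0          # 0.5 s < minimum
        assert detect_seizures(B, 1e-3, params.pop1.slow) == []


class TestSeizureDelay:
    def test_identical_onsets_give_zero(self):
        sz = [(10.0, 40.0), (100.0, 140.0)]
        delays, unpaired = seizure_delay(sz, sz)
        assert delays == [0.0, 0.0] and unpaired == []

    def test_following_response_is_negative(self):
        d, _ = seizure_delay([(100.0, 140.0)], [(120.0, 160.0)])
        assert d == [-20.0]

    def test_unpaired_sources_are_listed(self):
        d, unp = seizure_delay([(10.0, 40.0), (300.0, 340.0)],
                               [(20.0, 60.0)])
        assert d == [-10.0]
        assert unp == [300.0]

    def test_ordinal_mode_pairs_by_rank(self):
        d, _ = seizure_delay([(100.0, 140.0), (300.0, 340.0)],
                             [(90.0, 130.0), (310.0, 350.0)],
                             mode="ordinal")
        assert d == [10.0, -10.0]

    def test_nearest_mode_can_pair_backwards(self):
        d, _ = seizure_delay([(100.0, 140.0)], [(95.0, 135.0)],
                             mode="nearest")
        assert d == [5.0]


class TestSpectrum:
    def test_pure_tone_peaks_at_its_frequency(self):
        fs = 1000.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 40.0 * t)
        _, _, peak, gamma = normalized_psd(x, fs)
        assert peak == pytest.approx(40.0, abs=0.5)
        assert gamma > 0.9

    def test_white_noise_band_fraction_matches_bandwidth(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200000)
        fs = 1000.0
        _, _, _, gamma = normalized_psd(x, fs)
        assert gamma == pytest.approx(60.0 / 500.0, rel=0.1)

    def test_normalization_to_unit_power(self):
        rng = np.random.default_rng(4)
        f, p, _, _ = normalized_psd(rng.normal(size=50000), 1000.0)
        assert np.trapezoid(p, f) == pytest.approx(1.0, rel=1e-6)

    def test_short_segments_rejected(self):
        with pytest.raises(ValueError, match="two Welch windows"):
            normalized_psd(np.zeros(1000), 1000.0, nperseg=2048)


class TestSpikeFrequency:
    def test_empty_and_basic_counts(self):
        assert spike_frequency([], (0.0, 100.0)) == 0.0
        assert spike_frequency(np.linspace(0, 99, 10), (0.0, 100.0)) == 0.1

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            spike_frequency([1.0], (5.0, 5.0))


class TestCriticalKb:
    def test_default_target_population(self, params):
        kb = critical_kb(params.pop2.slow)
        assert kb == pytest.approx(10.21, abs=0.01)

    def test_zero_is_excitable(self, params):
        sp = params.pop2.slow
        assert classify_excitability(sp.b_thr, sp) == "excitable_rest"

    def test_monotone_beyond_the_threshold(self, params):
        sp = params.pop2.slow
        kb = critical_kb(sp)
        for extra in (0.5, 2.0, 5.0):
            assert classify_excitability(sp.b_thr - kb - extra, sp) \
                == "oscillatory"
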