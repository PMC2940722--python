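"""Transfer entropy: quantization, estimator vs closed forms, oracle
equivalence, phase-binned curves, asymmetry, timecourse."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from ctcflow.errors import DataError, ParameterError
from ctcflow.spectral import bin_by_phase
from ctcflow.surrogates import MarkovPairSpec, binary_channel_te, gen_markov_pair
from ctcflow.te import (
    TESettings,
    brute_force_te,
    quantize,
    rise_time_from_curve,
    te_asymmetry,
    te_by_phase_bin,
    te_timecourse,
    transfer_entropy,
    transfer_entropy_segments,
)


class TestQuantize:
    def test_binary_is_sign_split(self):
        v = np.array([-2.5, -0.1, 0.0, 0.1, 2.5])
        assert quantize(v, 2).tolist() == [0, 0, 1, 1, 1]

    def test_midpoint_upper_half_convention(self):
        assert quantize(np.array([0.0]), 4)[0] == 2

    def test_outliers_clip_to_edges(self):
        assert quantize(np.array([-10.0, 10.0]), 4).tolist() == [0, 3]

    def test_resolution_validated(self):
        with pytest.raises(ParameterError):
            quantize(np.zeros(3), 1)

    @given(st.integers(2, 8), st.lists(st.floats(-5, 5), min_size=1, max_size=50))
    @hyp_settings(max_examples=50, deadline=None)
    def test_codomain(self, resolution, values):
        q = quantize(np.array(values), resolution)
        assert q.min() >= 0 and q.max() < resolution


class TestEstimatorClosedForms:
    @pytest.mark.parametrize("p", [0.0, 0.1, 0.25, 0.5])
    def test_binary_channel(self, p):
        """Plug-in TE matches 1 - H2(p) on the noisy copy channel."""
        x, y, analytic = gen_markov_pair(MarkovPairSpec(p, length=100_000, seed=11))
        s = TESettings(resolution=2)
        est, n = transfer_entropy(x, y, s)
        assert n == 100_000 - 1
        assert est == pytest.approx(analytic, abs=0.02)
        bwd, _ = transfer_entropy(y, x, s)
        assert bwd == pytest.approx(0.0, abs=0.01)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 100_000)
        y = rng.integers(0, 2, 100_000)
        est, _ = transfer_entropy(x, y, TESettings(resolution=2))
        assert est <= 0.01

    def test_copy_with_shift_equals_entropy_rate(self):
        """x anticipating y by one step: TE equals y's entropy rate (1 bit)."""
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50_000)
        x = np.roll(y, -1)  # x_t = y_{t+1}
        est, _ = transfer_entropy(x[:-1], y[:-1], TESettings(resolution=2))
        assert est == pytest.approx(1.0, abs=0.02)

    def test_bias_shrinks_with_samples(self):
        """Plug-in bias on independent pairs decays ~1/n."""
        rng = np.random.default_rng(7)
        biases = []
        for n in (2_000, 20_000):
            vals = []
            for _ in range(5):
                x = rng.integers(0, 4, n)
                y = rng.integers(0, 4, n)
                est, _ = transfer_entropy(x, y, TESettings(resolution=4))
                vals.append(est)
            biases.append(np.mean(vals))
        assert biases[1] < biases[0] / 4  # 10x the data, ~10x less bias


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "settings",
        [
            TESettings(),
            TESettings(resolution=2),
            TESettings(k=2, l=1, resolution=3),
            TESettings(k=1, l=3, resolution=2),
            TESettings(lag=3),
        ],
    )
    def test_matches_brute_force(self, settings):
        rng = np.random.default_rng(42)
        x = rng.integers(0, settings.resolution, 600)
        # y depends weakly on x's past so the TE is nontrivial
        y = np.roll(x, 2)
        y[rng.random(600) < 0.3] = rng.integers(0, settings.resolution)
        fast, _ = transfer_entropy(x, y, settings)
        slow = brute_force_te(x, y, settings)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_constant_target_is_zero(self):
        x = np.array([0, 1] * 100)
        y = np.zeros(200, dtype=int)
        assert brute_force_te(x, y, TESettings(resolution=2)) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @hyp_settings(max_examples=15, deadline=None)
    def test_equivalence_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 300))
        x = rng.integers(0, 3, n)
        y = rng.integers(0, 3, n)
        s = TESettings(resolution=3)
        fast, _ = transfer_entropy(x, y, s)
        assert fast == pytest.approx(brute_force_te(x, y, s), abs=1e-12)
        assert fast >= 0.0


class TestSegmentsAndBins:
    def test_segments_never_bridge_boundaries(self):
        """Splitting a pair into segments must drop only boundary tuples."""
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 1000)
        y = np.roll(x, 1)
        s = TESettings(resolution=2)
        whole, n_whole = transfer_entropy_segments([(x, y)], s)
        halves, n_halves = transfer_entropy_segments([(x[:500], y[:500]), (x[500:], y[500:])], s)
        assert n_halves == n_whole - 1  # one tuple straddles the cut
        assert halves == pytest.approx(whole, abs=0.01)

    def test_phase_gated_coupling_peaks_at_gate(self):
        """Symbols coupled only in bin-0 windows -> max TE in bin 0."""
        rng = np.random.default_rng(8)
        phases = np.repeat([0.0, 60.0, 120.0, 180.0, -120.0, -60.0], 10)
        bins = bin_by_phase(phases, mean_deg=0.0, n_bins=6)
        pairs = []
        for ph in phases:
            x = rng.integers(0, 2, 400)
            if ph == 0.0:  # coupling only at zero offset
                y = np.roll(x, 1)
            else:
                y = rng.integers(0, 2, 400)
            pairs.append((x, y))
        out = te_by_phase_bin(pairs, bins, TESettings(resolution=2))
        te_f = [o.te_forward for o in out]
        assert int(np.argmax(te_f)) == 0
        assert te_f[0] > 0.9
        assert max(te_f[1:]) < 0.05

    def test_empty_bin_reported_as_none(self):
        bins = bin_by_phase(np.array([0.0, 1.0]), mean_deg=0.0, n_bins=6)
        pairs = [(np.zeros(50, int), np.zeros(50, int))] * 2
        out = te_by_phase_bin(pairs, bins, TESettings(resolution=2))
        assert out[0] is not None
        assert all(o is None for o in out[1:])


class TestAsymmetry:
    def test_symmetric_is_zero(self):
        assert te_asymmetry(0.4, 0.4) == 0.0

    def test_one_way_saturates_at_two(self):
        assert te_asymmetry(0.5, 0.0) == pytest.approx(2.0)

    def test_mean_normalized_value(self):
        assert te_asymmetry(0.6, 0.3) == pytest.approx(0.667, abs=1e-3)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ParameterError):
            te_asymmetry(0.0, 0.0)


class TestTimecourse:
    def test_immediate_jump_gives_first_window(self):
        lat = np.arange(0, 100.0)
        te = np.where(lat >= 0, 1.0, 0.0)
        rise, ok = rise_time_from_curve(lat, te, te.mean())
        assert ok and rise == 0.0

    def test_linear_ramp_crosses_at_half(self):
        lat = np.arange(0, 101.0)
        te = lat / 100.0  # ramps 0 -> 1; average 0.5, half-level 0.25
        rise, ok = rise_time_from_curve(lat, te, te.mean())
        assert ok
        assert rise == pytest.approx(25.0, abs=1.0)

    def test_no_information_flow_is_undefined(self):
        lat = np.arange(0, 50.0)
        rise, ok = rise_time_from_curve(lat, np.zeros(50), 0.0)
        assert not ok and rise is None

    def test_estimated_timecourse_rises_at_coupling_onset(self):
        """Coupling switched on mid-trial -> rise time near the switch."""
        rng = np.random.default_rng(9)
        onset, n_steps, switch = 100, 500, 150
        pairs = []
        for _ in range(30):
            x = rng.integers(0, 2, n_steps)
            y = rng.integers(0, 2, n_steps)
            y[switch + 1 :] = x[switch:-1]  # perfect copy after the switch
            pairs.append((x, y))
        tc = te_timecourse(pairs, onset, 300, window_steps=20, step=5, settings=TESettings(resolution=2))
        assert tc.rise_defined
        assert 30 <= tc.rise_time_ms <= 70  # switch at 50 steps post-onset

    def test_needs_two_trials(self):
        with pytest.raises(DataError):
            te_timecourse([(np.zeros(10, int), np.zeros(10, int))], 0, 5)
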