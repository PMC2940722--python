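"""Spearman-by-phase analysis: correlations, cosine fit, median split."""

import numpy as np
import pandas as pd
import pytest

from ctcflow.errors import DegenerateInputError, ParameterError
from ctcflow.interaction import (
    cosine_fit,
    median_power_split,
    phase_binned_correlation,
    spearman_rho,
    windowed_band_power,
)
from ctcflow.mua import MuaSeries
from ctcflow.spectral import bin_by_phase
from ctcflow.surrogates import OscillatorySurrogateSpec, gen_oscillatory_mua


def _mua_from_values(values, trial):
    return MuaSeries(np.asarray(values, float), 5.0, 1.0, "S1", trial, np.arange(0))


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        y = rng.random(100)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(5 * x), y**3 + y) == pytest.approx(base, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCosineFit:
    def test_exact_recovery(self):
        phi = np.array([-150.0, -90.0, -30.0, 30.0, 90.0, 150.0])
        values = 0.1 + 0.05 * np.cos(np.radians(phi - 30.0))
        off, amp, peak = cosine_fit(phi, values)
        assert off == pytest.approx(0.1, abs=1e-9)
        assert amp == pytest.approx(0.05, abs=1e-9)
        assert peak == pytest.approx(30.0, abs=1e-7)

    def test_flat_data_zero_amplitude(self):
        phi = np.array([0.0, 60.0, 120.0, 180.0, -120.0, -60.0])
        _, amp, _ = cosine_fit(phi, np.full(6, 0.3))
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_noisy_cosine_within_band(self):
        rng = np.random.default_rng(2)
        phi = np.arange(-180, 180, 15.0)
        truth = 0.2 + 0.3 * np.cos(np.radians(phi + 45.0))
        off, amp, peak = cosine_fit(phi, truth + rng.normal(0, 0.02, phi.size))
        assert off == pytest.approx(0.2, abs=0.02)
        assert amp == pytest.approx(0.3, abs=0.03)
        assert abs((peak + 45.0 + 180) % 360 - 180) < 10

    def test_needs_three_bins(self):
        with pytest.raises(ParameterError):
            cosine_fit(np.array([0.0, 60.0]), np.array([0.1, 0.2]))


class TestMedianSplit:
    def test_even_split(self):
        below, above = median_power_split([1.0, 2.0, 3.0, 4.0])
        assert below.tolist() == [0, 1] and above.tolist() == [2, 3]

    def test_all_equal_goes_low(self):
        below, above = median_power_split([2.0, 2.0, 2.0])
        assert len(below) == 3 and len(above) == 0

    def test_odd_count_median_goes_low(self):
        below, above = median_power_split([5.0, 1.0, 3.0, 2.0, 4.0])
        assert len(below) == 3 and len(above) == 2

    def test_disjoint_and_complete(self):
        rng = np.random.default_rng(3)
        p = rng.random(21)
        below, above = median_power_split(p)
        assert sorted(below.tolist() + above.tolist()) == list(range(21))


class TestWindowedBandPower:
    def test_constant_series_zero_power(self):
        m = [_mua_from_values(np.zeros(1000), 0)]
        df = windowed_band_power(m, m, 0.0, 1000.0, 500.0, 60.0)
        assert np.allclose(df["power_x"], 0.0)

    def test_tone_equal_power_both_pools(self):
        t = np.arange(1500) / 1000.0
        tone = np.sin(2 * np.pi * 60 * t)
        m = [_mua_from_values(tone, 0)]
        df = windowed_band_power(m, m, 0.0, 1500.0, 500.0, 60.0)
        assert len(df) == 3  # floor(span / window)
        assert np.allclose(df["power_x"], df["power_y"], rtol=1e-9)
        assert np.allclose(df["phase_deg"], 0.0, atol=1e-6)

    def test_window_count_follows_span(self):
        m = [_mua_from_values(np.random.default_rng(0).standard_normal(2096), 0)]
        df = windowed_band_power(m, m, 0.0, 2096.0, 500.0, 60.0)
        assert len(df) == 4


class TestPhaseBinnedCorrelation:
    def _stats(self, phases, px, py):
        return pd.DataFrame(
            {
                "trial": np.zeros(len(phases), dtype=int),
                "window_start_ms": np.arange(len(phases)) * 500.0,
                "power_x": px,
                "power_y": py,
                "phase_deg": phases,
            }
        )

    def test_identical_powers_give_rho_one(self):
        rng = np.random.default_rng(4)
        phases = rng.uniform(-180, 180, 120)
        p = rng.random(120)
        bins = bin_by_phase(phases, mean_deg=0.0, n_bins=6)
        curve = phase_binned_correlation(self._stats(phases, p, p), bins)
        defined = np.isfinite(curve.rho)
        assert defined.any()
        assert np.allclose(curve.rho[defined], 1.0)

    def test_independent_powers_stay_small(self):
        """No bin of independent powers shows significant correlation."""
        rng = np.random.default_rng(5)
        n = 240
        phases = rng.uniform(-180, 180, n)
        bins = bin_by_phase(phases, mean_deg=0.0, n_bins=6)
        curve = phase_binned_correlation(
            self._stats(phases, rng.random(n), rng.random(n)), bins
        )
        defined = np.isfinite(curve.rho)
        # ~40 windows per bin; |rho| beyond 3/sqrt(n-1) would be notable
        assert np.all(np.abs(curve.rho[defined]) < 3.0 / np.sqrt(30))

    def test_sparse_bins_undefined(self):
        phases = np.array([0.0, 1.0, 2.0, 120.0])
        bins = bin_by_phase(phases, mean_deg=0.0, n_bins=6)
        curve = phase_binned_correlation(
            self._stats(phases, np.arange(4.0), np.arange(4.0)), bins
        )
        assert np.isfinite(curve.rho[0])
        assert np.isnan(curve.rho[2]) or curve.n_windows[2] < 2

    def test_null_cosine_amplitude_shrinks_with_windows(self):
        """With independent powers the fitted amplitude -> 0 as n grows."""
        rng = np.random.default_rng(6)
        amps = []
        for n in (60, 960):
            phases = rng.uniform(-180, 180, n)
            bins = bin_by_phase(phases, mean_deg=0.0, n_bins=6)
            curve = phase_binned_correlation(
                self._stats(phases, rng.random(n), rng.random(n)), bins
            )
            amps.append(curve.cosine_amplitude)
        assert amps[1] < amps[0]


class TestSurrogateGroundTruth:
    def test_phase_dependent_coupling_maximizes_rho_at_gate(self):
        """Coupling gated on zero offset concentrates correlation there."""
        spec = OscillatorySurrogateSpec(
            phase_lag_deg=0.0,
            coupling_strength=0.6,
            phase_gate_center_deg=0.0,
            phase_gate_halfwidth_deg=40.0,
            phase_jitter_deg=60.0,
            n_trials=30,
            trial_length_ms=2000.0,
            seed=7,
        )
        sur = gen_oscillatory_mua(spec)
        m1, m2 = sur.mua(1), sur.mua(2)
        df = windowed_band_power(m1, m2, 0.0, 2000.0, 500.0, 60.0)
        bins = bin_by_phase(df["phase_deg"].to_numpy(), n_bins=6)
        curve = phase_binned_correlation(df, bins)
        # compare bins with enough windows for a meaningful rank correlation
        rho = np.where(curve.n_windows >= 8, curve.rho, -np.inf)
        assert int(np.argmax(rho)) == 0
        assert curve.rho[0] > 0.15
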