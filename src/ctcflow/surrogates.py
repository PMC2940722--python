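"""Synthetic data with the statistical structure the analyses assume.

These generators exist so every analysis stage can be validated without
running the network: band-limited oscillatory rate modulation with a
controllable inter-pool phase lag, one-way delayed coupling (optionally
gated on the instantaneous phase offset), Poisson spiking noise, and
discrete Markov pairs whose transfer entropy is known in closed form.
They emulate only the statistical structure the analysis consumes, not
conductance dynamics; every generator is deterministic per seed and every
output carries its ground-truth parameters for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .mua import MuaSeries, znormalize

__all__ = [
    "MarkovPairSpec",
    "OscillatorySurrogateSpec",
    "OscillatorySurrogate",
    "binary_channel_te",
    "gen_markov_pair",
    "gen_oscillatory_mua",
    "gen_independent_noise",
]


@dataclass(frozen=True)
class MarkovPairSpec:
    """Binary channel: x i.i.d. uniform bits, y_{t+1} = x_t flipped with
    probability p.  Closed-form TE: forward 1 - H2(p) bits, backward 0."""

    flip_probability: float = 0.0
    length: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 0.5:
            raise ParameterError("flip probability must lie in [0, 0.5]")
        if self.length < 2:
            raise ParameterError("length must be >= 2")


def binary_channel_te(p: float) -> float:
    """1 - H2(p) bits: the analytic forward TE of the binary channel."""
    if p in (0.0, 1.0):
        return 1.0
    h2 = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
    return float(1.0 - h2)


def gen_markov_pair(spec: MarkovPairSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Generate the channel pair; returns (x, y, analytic_forward_te)."""
    rng = np.random.default_rng(spec.seed)
    x = rng.integers(0, 2, size=spec.length)
    flips = rng.random(spec.length) < spec.flip_probability
    y = np.empty_like(x)
    y[0] = rng.integers(0, 2)
    y[1:] = np.bitwise_xor(x[:-1], flips[1:].astype(np.int64))
    return x, y, binary_channel_te(spec.flip_probability)


@dataclass(frozen=True)
class OscillatorySurrogateSpec:
    """Two Poisson-spiking pools with oscillatory rate modulation.

    Pool 1 intensity: base_rate * (1 + modulation_depth * cos(2 pi f t +
    theta_trial)); pool 2 runs ``phase_lag`` degrees behind (plus
    Gaussian per-window phase jitter) and receives an excess intensity
    proportional to pool 1's counts ``coupling_delay`` ms earlier
    (``coupling_strength`` spikes of extra rate per source spike).  With
    ``phase_gate_halfwidth_deg`` set, the coupling is active only in
    windows whose actual offset lies within the gate around
    ``phase_gate_center_deg``.  Counts are Poisson at 1 ms resolution;
    intensities are clipped at zero.
    """

    oscillation_frequency: float = 60.0  # Hz
    modulation_depth: float = 0.6
    base_rate: float = 200.0  # Hz per pool (10 sampled neurons x ~20 Hz)
    phase_lag_deg: float = 90.0
    coupling_strength: float = 0.3
    coupling_delay_ms: float = 4.0
    phase_gate_center_deg: float | None = None
    phase_gate_halfwidth_deg: float = 45.0
    phase_jitter_deg: float = 25.0
    jitter_window_ms: float = 500.0
    n_trials: int = 20
    trial_length_ms: float = 3000.0
    coupling_onset_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth < 1.0:
            raise ParameterError("modulation_depth must lie in [0, 1)")
        if self.base_rate < 0 or self.coupling_strength < 0:
            raise ParameterError("rates and coupling must be >= 0")
        if self.n_trials < 1 or self.trial_length_ms <= 0:
            raise ParameterError("need n_trials >= 1 and a positive trial length")


@dataclass
class OscillatorySurrogate:
    """Generated pair of count series plus ground truth.

    ``counts1``/``counts2``: (n_trials, T) Poisson counts at 1 ms
    resolution; ``offsets_deg``: the realized per-window phase offset of
    pool 2 relative to pool 1 (lag + jitter); ``coupled``: whether the
    coupling was active per window.
    """

    counts1: np.ndarray
    counts2: np.ndarray
    offsets_deg: np.ndarray  # (n_trials, n_jitter_windows)
    coupled: np.ndarray  # bool, same shape
    spec: OscillatorySurrogateSpec

    def mua(self, pool: int, normalize: bool = True) -> list[MuaSeries]:
        """Package counts as 5 ms / 1 ms-step MUA series per trial."""
        counts = self.counts1 if pool == 1 else self.counts2
        out = []
        for trial, c in enumerate(counts):
            win = np.convolve(c, np.ones(5), mode="valid")
            values = znormalize(win) if normalize else win
            out.append(
                MuaSeries(
                    values=values,
                    bin_width=5.0,
                    step=1.0,
                    pool_label="S1" if pool == 1 else "S2",
                    trial_index=trial,
                    sampled_neuron_ids=np.arange(0),
                )
            )
        return out

    def spike_events(self) -> pd.DataFrame:
        """Counts re-expressed as spike events (times uniform in their
        1 ms bin), matching the simulator's event schema."""
        rng = np.random.default_rng(self.spec.seed + 986_131)
        rows = []
        for pool, counts in ((1, self.counts1), (2, self.counts2)):
            label = "S1" if pool == 1 else "S2"
            for trial in range(counts.shape[0]):
                c = counts[trial]
                ms = np.repeat(np.arange(len(c)), c)
                times = ms + rng.random(len(ms))
                for t in times:
                    rows.append((trial, pool, label, float(t)))
        df = pd.DataFrame(rows, columns=["trial", "neuron_id", "pool", "time_ms"])
        return df.sort_values(["trial", "time_ms"], ignore_index=True)


def gen_oscillatory_mua(spec: OscillatorySurrogateSpec) -> OscillatorySurrogate:
    """Generate the coupled oscillatory pool pair."""
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.trial_length_ms))
    t_ms = np.arange(T, dtype=float)
    f_ms = spec.oscillation_frequency / 1000.0  # cycles per ms
    base = spec.base_rate / 1000.0  # spikes per ms
    n_jw = max(int(np.ceil(T / spec.jitter_window_ms)), 1)
    delay = int(round(spec.coupling_delay_ms))

    counts1 = np.empty((spec.n_trials, T), dtype=np.int64)
    counts2 = np.empty((spec.n_trials, T), dtype=np.int64)
    offsets = np.empty((spec.n_trials, n_jw))
    coupled = np.zeros((spec.n_trials, n_jw), dtype=bool)

    for trial in range(spec.n_trials):
        theta = rng.uniform(0.0, 2 * np.pi)
        lam1 = base * (1.0 + spec.modulation_depth * np.cos(2 * np.pi * f_ms * t_ms + theta))
        c1 = rng.poisson(np.clip(lam1, 0.0, None))
        counts1[trial] = c1

        jitter = rng.normal(0.0, spec.phase_jitter_deg, size=n_jw)
        off = spec.phase_lag_deg + jitter
        offsets[trial] = off
        # per-ms phase offset (piecewise constant over jitter windows)
        w_idx = np.minimum((t_ms // spec.jitter_window_ms).astype(int), n_jw - 1)
        off_ms = off[w_idx]
        lam2 = base * (
            1.0
            + spec.modulation_depth
            * np.cos(2 * np.pi * f_ms * t_ms + theta - np.radians(off_ms))
        )
        if spec.coupling_strength > 0:
            gate = np.ones(n_jw, dtype=bool)
            if spec.phase_gate_center_deg is not None:
                d = np.abs((off - spec.phase_gate_center_deg + 180.0) % 360.0 - 180.0)
                gate = d <= spec.phase_gate_halfwidth_deg
            coupled[trial] = gate
            drive = np.zeros(T)
            if delay > 0:
                drive[delay:] = c1[:-delay]
            else:
                drive[:] = c1
            active = gate[w_idx] & (t_ms >= spec.coupling_onset_ms)
            lam2 = lam2 + spec.coupling_strength * drive * active
        counts2[trial] = rng.poisson(np.clip(lam2, 0.0, None))

    return OscillatorySurrogate(
        counts1=counts1, counts2=counts2, offsets_deg=offsets, coupled=coupled, spec=spec
    )


def gen_independent_noise(n: int, length: int, seed: int = 0) -> np.ndarray:
    """(n, length) i.i.d. standard-normal series for null calibration."""
    if n < 1 or length < 1:
        raise ParameterError("n and length must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, length))
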