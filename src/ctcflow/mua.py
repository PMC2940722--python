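"""Multi-unit activity: sampled, binned, z-normalized spike-count series.

The analyses never see raw spikes: they see the MUA of each selective
pool, emulating an electrode's multi-unit signal by summing the spikes of 10
randomly sampled neurons, counting them in sliding 5 ms windows stepped by
1 ms, and z-scoring the resulting series.  Normalization removes rate
scaling so downstream measures respond to temporal structure, not to
firing-rate changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .netsim import SpikeData

__all__ = ["MuaSeries", "sample_neurons", "bin_spikes", "znormalize", "pool_mua"]

DEFAULT_BIN_WIDTH = 5.0  # ms
DEFAULT_STEP = 1.0  # ms
DEFAULT_N_SAMPLED = 10


@dataclass
class MuaSeries:
    """One trial's z-scored MUA for one pool.

    ``values[w]`` covers the half-open time window
    ``[w * step, w * step + bin_width)`` ms; after normalization the series
    has zero mean and unit (population) variance.
    """

    values: np.ndarray
    bin_width: float
    step: float
    pool_label: str
    trial_index: int
    sampled_neuron_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def slice_ms(self, t_start: float, t_stop: float) -> np.ndarray:
        """Values of windows starting in [t_start, t_stop) ms."""
        i0 = int(np.ceil(t_start / self.step))
        i1 = int(np.ceil(t_stop / self.step))
        return self.values[i0:i1]


def sample_neurons(spikes: SpikeData, pool: str, n: int = DEFAULT_N_SAMPLED, seed: int = 0) -> np.ndarray:
    """Choose ``n`` distinct neurons of ``pool`` uniformly without
    replacement, deterministically per seed.

    The same ids are meant to be reused across all trials of a session.
    """
    ids = spikes.pool_neuron_ids(pool)
    if n > len(ids):
        raise ParameterError(f"cannot sample {n} neurons from pool {pool} of size {len(ids)}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(ids, size=n, replace=False))


def bin_spikes(
    times: np.ndarray,
    trial_length: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Sliding-window spike counts.

    Window ``w`` counts spikes with time in ``[w*step, w*step + bin_width)``
    (half-open, anchored at 0); the series has
    ``floor((trial_length - bin_width)/step) + 1`` windows.
    """
    if not (bin_width >= step > 0):
        raise ParameterError("need bin_width >= step > 0")
    times = np.sort(np.asarray(times, dtype=float))
    n_windows = int(np.floor((trial_length - bin_width) / step)) + 1
    if n_windows <= 0:
        raise ParameterError("trial shorter than one bin")
    starts = np.arange(n_windows) * step
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + bin_width, side="left")
    return (hi - lo).astype(np.int64)


def znormalize(series: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization with the population SD.

    Raises :class:`DegenerateInputError` on constant input, which signals
    a silent (or saturated) pool rather than a numerical accident.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ParameterError("need at least 2 samples to normalize")
    sd = series.std()  # population (ddof=0) standard deviation
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("zero-variance series (silent pool?)")
    return (series - series.mean()) / sd


def pool_mua(
    spikes: SpikeData,
    pool: str,
    n_sampled: int = DEFAULT_N_SAMPLED,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    step: float = DEFAULT_STEP,
    normalize: bool = True,
    on_degenerate: str = "raise",
) -> list[MuaSeries]:
    """MUA series of one pool for every trial of a session.

    Samples ``n_sampled`` neurons once (per seed) and reuses them across
    trials; each trial is binned and z-scored independently over its full
    length.  ``on_degenerate`` controls what happens when a trial's
    sampled neurons never fire (zero-variance counts): "raise" surfaces
    the degenerate-input error, "zeros" substitutes an all-zero z-series
    (the trial then carries no information downstream).
    """
    if on_degenerate not in ("raise", "zeros"):
        raise ParameterError("on_degenerate must be 'raise' or 'zeros'")
    chosen = sample_neurons(spikes, pool, n_sampled, seed)
    chosen_set = set(int(i) for i in chosen)
    length = spikes.trial_length
    ev = spikes.events
    ev = ev[(ev["pool"] == pool) & ev["neuron_id"].isin(chosen_set)]
    out = []
    for trial in range(spikes.n_trials):
        t = ev.loc[ev["trial"] == trial, "time_ms"].to_numpy()
        counts = bin_spikes(t, length, bin_width, step)
        if normalize:
            try:
                values = znormalize(counts)
            except DegenerateInputError:
                if on_degenerate == "raise":
                    raise
                values = np.zeros(len(counts))
        else:
            values = counts.astype(float)
        out.append(
            MuaSeries(
                values=values,
                bin_width=bin_width,
                step=step,
                pool_label=pool,
                trial_index=trial,
                sampled_neuron_ids=chosen,
            )
        )
    return out
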