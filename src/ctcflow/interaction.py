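"""Phase-resolved rank correlation of band power between the two pools.

This is the correlation arm of the study: in every 500 ms window the
band power (e.g. at 60 Hz) of each pool's MUA and their cross-spectral
phase are measured; windows are binned by phase offset from the circular
mean, and within each bin the Spearman rank correlation of the two power
series is computed.  A cosine is then fitted to the correlation-vs-offset
curve.  The median-power split recomputes the curve separately for trials
below and above the median band power, controlling that the phase
dependence is not a by-product of power changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError, ParameterError
from .mua import MuaSeries
from .spectral import (
    PhaseBinnedTrials,
    multitaper_cross,
    nearest_bin,
    slepian_tapers,
)

__all__ = [
    "PhaseCorrelationCurve",
    "windowed_band_power",
    "spearman_rho",
    "phase_binned_correlation",
    "cosine_fit",
    "median_power_split",
]

DEFAULT_CORR_WINDOW_MS = 500.0
DEFAULT_TARGET_FREQ = 60.0


@dataclass
class PhaseCorrelationCurve:
    """Spearman rho per phase-offset bin plus its cosine fit.

    ``rho`` is NaN where a bin holds fewer than two windows; the cosine
    fit ``rho(phi) = offset + amplitude * cos(phi - peak_phase)`` uses the
    defined bins only.
    """

    bin_centers: np.ndarray  # degrees offset from mean
    rho: np.ndarray
    n_windows: np.ndarray
    cosine_offset: float | None = None
    cosine_amplitude: float | None = None
    cosine_peak_phase: float | None = None


def windowed_band_power(
    mua_x: list[MuaSeries],
    mua_y: list[MuaSeries],
    t_start: float,
    t_stop: float,
    window_ms: float = DEFAULT_CORR_WINDOW_MS,
    f: float = DEFAULT_TARGET_FREQ,
    fs: float = 1000.0,
) -> pd.DataFrame:
    """Per-window power at ``f`` for both pools plus their phase relation.

    Non-overlapping windows of ``window_ms`` tile [t_start, t_stop) of
    every trial; each row holds (trial, window_start_ms, power_x, power_y,
    phase_deg).  Power is the multitaper estimate at the grid bin nearest
    ``f``; phase is the angle of the cross spectrum there (positive: pool
    y lags pool x).
    """
    if len(mua_x) != len(mua_y):
        raise ParameterError("need the same number of trials for both pools")
    if not mua_x:
        raise DataError("no trials supplied")
    step = mua_x[0].step
    w_steps = int(round(window_ms / step * fs / 1000.0))
    n_windows = int((t_stop - t_start) // window_ms)
    if n_windows < 1:
        raise ParameterError("analysis span shorter than one window")
    tapers = slepian_tapers(w_steps)
    rows = []
    for sx, sy in zip(mua_x, mua_y):
        for w in range(n_windows):
            w_start = t_start + w * window_ms
            x = sx.slice_ms(w_start, w_start + window_ms)[:w_steps]
            y = sy.slice_ms(w_start, w_start + window_ms)[:w_steps]
            if len(x) < w_steps or len(y) < w_steps:
                continue
            est = multitaper_cross(x, y, fs=fs, tapers=tapers)
            k = nearest_bin(est.frequencies, f)
            py = (np.abs(np.fft.rfft(tapers * y[None, :], axis=1)) ** 2).mean(axis=0)[k]
            rows.append(
                {
                    "trial": sx.trial_index,
                    "window_start_ms": w_start,
                    "power_x": float(est.power[k]),
                    "power_y": float(py),
                    "phase_deg": float(np.degrees(np.angle(est.cross[k]))),
                }
            )
    return pd.DataFrame(rows)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ParameterError("need two equal-length series of length >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def phase_binned_correlation(
    window_stats: pd.DataFrame,
    bins: PhaseBinnedTrials,
    fit: bool = True,
) -> PhaseCorrelationCurve:
    """Spearman rho of the two pools' power within each phase bin.

    Windows of all trials assigned to a bin are pooled; bins with fewer
    than two windows (or degenerate power values) report NaN.
    """
    if len(window_stats) != len(bins.assignment):
        raise ParameterError("window_stats and phase bins disagree in length")
    rho = np.full(bins.n_bins, np.nan)
    n_win = np.zeros(bins.n_bins, dtype=int)
    px = window_stats["power_x"].to_numpy()
    py = window_stats["power_y"].to_numpy()
    for b in range(bins.n_bins):
        idx = bins.windows_in_bin(b)
        n_win[b] = len(idx)
        if len(idx) < 2:
            continue
        try:
            rho[b] = spearman_rho(px[idx], py[idx])
        except DegenerateInputError:
            pass
    curve = PhaseCorrelationCurve(bin_centers=bins.bin_centers.copy(), rho=rho, n_windows=n_win)
    if fit:
        defined = np.isfinite(rho)
        if defined.sum() >= 3:
            off, amp, peak = cosine_fit(curve.bin_centers[defined], rho[defined])
            curve.cosine_offset, curve.cosine_amplitude, curve.cosine_peak_phase = off, amp, peak
    return curve


def cosine_fit(bin_centers_deg: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of ``offset + amplitude * cos(phi - peak_phase)``.

    Linear in (offset, A cos peak, A sin peak); returns amplitude >= 0 and
    the peak phase in (-180, 180] degrees.
    """
    phi = np.radians(np.asarray(bin_centers_deg, dtype=float))
    v = np.asarray(values, dtype=float)
    if phi.size < 3:
        raise ParameterError("cosine fit needs at least 3 bins")
    design = np.column_stack([np.ones_like(phi), np.cos(phi), np.sin(phi)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    offset, b, c = coef
    amplitude = float(np.hypot(b, c))
    peak = float(np.degrees(np.arctan2(c, b)))
    return float(offset), amplitude, peak


def median_power_split(band_power_per_trial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices at the median band power.

    Trials with power <= median go to the lower set (so exact-median and
    all-equal inputs land low); returns (below_idx, above_idx).
    """
    p = np.asarray(band_power_per_trial, dtype=float)
    if p.size < 2:
        raise ParameterError("need at least 2 trials to split")
    med = np.median(p)
    below = np.flatnonzero(p <= med)
    above = np.flatnonzero(p > med)
    return below, above
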