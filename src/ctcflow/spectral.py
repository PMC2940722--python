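"""Multitaper spectra, cross-spectral phase, band power, phase binning.

Power and cross-spectra are estimated by the multitaper method: the
windowed signal is multiplied with K orthonormal Slepian (DPSS) tapers,
Fourier transformed, and the squared amplitudes (or cross products) are
averaged over tapers, trading a little bandwidth for a large variance
reduction.  The phase relation between two pools at a frequency is the
angle of the taper-averaged cross spectrum; windows are then grouped into
bins by their phase offset from the session's circular mean phase, which
is how every phase-resolved analysis downstream is organized.

Sign convention: positive phase means the second signal lags the first
(a pure delay d of y relative to x gives +360·f·d degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .errors import ParameterError, UndefinedMeanError

__all__ = [
    "SpectralEstimate",
    "PhaseBinnedTrials",
    "slepian_tapers",
    "multitaper_power",
    "multitaper_cross",
    "cross_spectrum_phase",
    "band_power_fraction",
    "circular_mean",
    "bin_by_phase",
]

DEFAULT_TIME_BANDWIDTH = 3.0
DEFAULT_N_TAPERS = 5  # 2*NW - 1
DEFAULT_FS = 1000.0  # Hz; MUA is stepped at 1 ms


@dataclass
class SpectralEstimate:
    """Taper-averaged power (and optionally cross) spectrum of one window."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray  # same length, >= 0
    cross: np.ndarray | None = None  # complex, for a pool pair
    window_length: float = 0.0  # ms
    n_tapers: int = DEFAULT_N_TAPERS
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH


@dataclass
class PhaseBinnedTrials:
    """Assignment of analysis windows to phase-offset bins.

    Offsets are wrapped to (-180, 180] degrees relative to the circular
    mean; bin 0 is centered on zero offset, bin b on ``b * 360/n_bins``
    (wrapped).  Every window lands in exactly one bin.
    """

    phase_per_window: np.ndarray  # degrees in (-180, 180]
    circular_mean_deg: float
    bin_centers: np.ndarray  # degrees, bin 0 first
    assignment: np.ndarray  # window -> bin index

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def windows_in_bin(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == b)


def slepian_tapers(n_samples: int, time_bandwidth: float = DEFAULT_TIME_BANDWIDTH, n_tapers: int = DEFAULT_N_TAPERS) -> np.ndarray:
    """Orthonormal DPSS taper set, shape (n_tapers, n_samples).

    The usable taper count is limited by the concentration rule
    ``n_tapers <= 2 * time_bandwidth - 1``.
    """
    if n_tapers < 1:
        raise ParameterError("n_tapers must be >= 1")
    if n_tapers > 2 * time_bandwidth - 1:
        raise ParameterError(
            f"n_tapers={n_tapers} infeasible for time_bandwidth={time_bandwidth} "
            f"(limit {int(2 * time_bandwidth - 1)})"
        )
    tapers = dpss(n_samples, time_bandwidth, Kmax=n_tapers)
    return np.atleast_2d(tapers)


def _taper_ffts(x: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    return rfft(tapers * x[None, :], axis=1)


def multitaper_power(
    x: np.ndarray,
    fs: float = DEFAULT_FS,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
    n_tapers: int = DEFAULT_N_TAPERS,
    tapers: np.ndarray | None = None,
) -> SpectralEstimate:
    """Multitaper power spectrum of one window.

    Returns the squared Fourier amplitude of the tapered signal averaged
    over tapers, on the rfft frequency grid (spacing fs/len(x)).
    """
    x = np.asarray(x, dtype=float)
    if tapers is None:
        tapers = slepian_tapers(len(x), time_bandwidth, n_tapers)
    if tapers.shape[1] != len(x):
        raise ParameterError("taper length does not match window length")
    X = _taper_ffts(x, tapers)
    power = (np.abs(X) ** 2).mean(axis=0)
    freqs = rfftfreq(len(x), 1.0 / fs)
    return SpectralEstimate(
        frequencies=freqs,
        power=power,
        window_length=len(x) / fs * 1e3,
        n_tapers=tapers.shape[0],
        time_bandwidth=time_bandwidth,
    )


def multitaper_cross(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = DEFAULT_FS,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
    n_tapers: int = DEFAULT_N_TAPERS,
    tapers: np.ndarray | None = None,
) -> SpectralEstimate:
    """Taper-averaged cross spectrum X(f)·conj(Y(f)) plus both powers."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y windows must have equal length")
    if tapers is None:
        tapers = slepian_tapers(len(x), time_bandwidth, n_tapers)
    X = _taper_ffts(x, tapers)
    Y = _taper_ffts(y, tapers)
    cross = (X * np.conj(Y)).mean(axis=0)
    power = (np.abs(X) ** 2).mean(axis=0)  # power of x; |cross|^2 <= Px*Py
    freqs = rfftfreq(len(x), 1.0 / fs)
    return SpectralEstimate(
        frequencies=freqs,
        power=power,
        cross=cross,
        window_length=len(x) / fs * 1e3,
        n_tapers=tapers.shape[0],
        time_bandwidth=time_bandwidth,
    )


def nearest_bin(frequencies: np.ndarray, f: float) -> int:
    if f < 0 or f > frequencies[-1]:
        raise ParameterError(f"frequency {f} Hz outside resolvable range")
    return int(np.argmin(np.abs(frequencies - f)))


def cross_spectrum_phase(
    x: np.ndarray,
    y: np.ndarray,
    f: float,
    fs: float = DEFAULT_FS,
    **kwargs,
) -> float:
    """Phase relation (degrees) between two windows at frequency ``f``.

    Angle of the taper-averaged cross spectrum at the grid bin nearest
    ``f``; positive phase means ``y`` lags ``x``.
    """
    est = multitaper_cross(x, y, fs=fs, **kwargs)
    k = nearest_bin(est.frequencies, f)
    return float(np.degrees(np.angle(est.cross[k])))


def band_power_fraction(est: SpectralEstimate, band: tuple[float, float]) -> float:
    """Fraction of total (non-DC) power inside ``band`` (Hz, inclusive)."""
    lo, hi = band
    freqs, power = est.frequencies, est.power
    if lo > hi or hi <= 0 or lo > freqs[-1]:
        raise ParameterError(f"empty band {band}")
    in_band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not in_band.any():
        raise ParameterError(f"band {band} contains no frequency bins")
    total = power[freqs > 0].sum()
    if total == 0:
        return 0.0
    return float(power[in_band].sum() / total)


def circular_mean(phases_deg: np.ndarray) -> float:
    """Circular mean (degrees): the angle of the resultant vector."""
    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.size == 0:
        raise ParameterError("empty phase list")
    z = np.exp(1j * np.radians(phases_deg)).mean()
    if np.abs(z) < 1e-9:
        raise UndefinedMeanError("resultant vector numerically zero; mean undefined")
    return float(np.degrees(np.angle(z)))


def wrap_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180] degrees."""
    a = np.asarray(angles, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped


def bin_by_phase(
    phases_deg: np.ndarray,
    mean_deg: float | None = None,
    n_bins: int = 6,
) -> PhaseBinnedTrials:
    """Group windows into equal phase-offset bins around the circular mean.

    Offsets ``phase - mean`` are wrapped to (-180, 180] and partitioned
    into ``n_bins`` bins of width 360/n_bins; bin 0 is centered on zero
    offset (the mean phase), successive bins on multiples of the width.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    phases = wrap_deg(np.asarray(phases_deg, dtype=float))
    if mean_deg is None:
        mean_deg = circular_mean(phases)
    offsets = wrap_deg(phases - mean_deg)
    width = 360.0 / n_bins
    idx = np.mod(np.round(offsets / width).astype(int), n_bins)
    centers = wrap_deg(np.arange(n_bins) * width)
    return PhaseBinnedTrials(
        phase_per_window=phases,
        circular_mean_deg=float(mean_deg),
        bin_centers=centers,
        assignment=idx,
    )
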