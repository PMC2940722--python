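"""Configured experiment runs: simulate, analyze, sweep.

Ties the pieces together the way the study is organized:

* ``run_phase_experiment`` — simulate (or accept) a session, extract the
  two selective pools' MUA, estimate the per-window band power and
  cross-spectral phase, bin windows by phase offset from the circular
  mean, and produce the phase-binned Spearman correlation curve and the
  phase-binned directional transfer entropy.  Sorting can use the
  dominant band or deliberately the non-dominant one (the cross-band
  control conditions).
* ``run_power_sweep`` — repeat sessions across NMDA/AMPA modification
  ratios and report gamma-band power fraction and TE at the mean phase,
  with bootstrap intervals over trials.
* ``run_timing_experiment`` — latency-resolved TE around stimulus onset
  per modification ratio, with the 50%-of-average rise time.

All randomness derives from the config seed; a config hash plus the seed
reproduce any result table exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .interaction import (
    PhaseCorrelationCurve,
    median_power_split,
    phase_binned_correlation,
    windowed_band_power,
)
from .mua import MuaSeries, pool_mua
from .netsim import SpikeData, run_session
from .params import (
    ArchitectureSpec,
    StimulusProtocol,
    SynapseParams,
    beta_mode,
)
from .spectral import (
    PhaseBinnedTrials,
    band_power_fraction,
    bin_by_phase,
    multitaper_power,
    nearest_bin,
    slepian_tapers,
)
from .te import (
    TEEstimate,
    TESettings,
    TETimecourse,
    quantize,
    te_by_phase_bin,
    te_timecourse,
    transfer_entropy_segments,
)

__all__ = [
    "AnalysisSettings",
    "ExperimentConfig",
    "PhaseExperimentResult",
    "run_phase_experiment",
    "run_power_sweep",
    "run_timing_experiment",
    "session_mua",
    "band_peak_frequency",
    "session_band_fractions",
]

GAMMA_BAND = (30.0, 85.0)
BETA_BAND = (12.0, 30.0)


@dataclass(frozen=True)
class AnalysisSettings:
    """Analysis-chain constants (windows, bins, bands, TE settings)."""

    spectral_window_ms: float = 1000.0
    corr_window_ms: float = 500.0
    n_phase_bins: int = 6
    gamma_band: tuple[float, float] = GAMMA_BAND
    beta_band: tuple[float, float] = BETA_BAND
    gamma_freq: float = 60.0
    beta_freq: float = 20.0
    n_sampled: int = 10
    use_band_peak: bool = True  # sort at the measured in-band peak frequency
    te: TESettings = field(default_factory=TESettings)
    lag_from_delay: bool = True  # TE prediction horizon = conduction delay


@dataclass(frozen=True)
class ExperimentConfig:
    """One simulated session and how to analyze it.

    ``mode`` selects the oscillation regime: gamma uses the default
    synapse kinetics, beta retunes GABA/AMPA decay (38 ms / 1.5 ms).
    ``scale`` picks the architecture profile; the reduced/tiny profiles
    shrink populations with conductance rescaling and exist for
    desk-scale work.
    """

    mode: str = "gamma"
    r: float | None = None  # None -> mode default (gamma 0.12, beta 0.07)
    scale: str = "reduced"
    n_trials: int = 10
    pre_stimulus_ms: float = 400.0
    stimulus_ms: float = 2100.0
    post_stimulus_ms: float = 0.0
    conduction_delay_ms: float = 4.0
    feedback_feedforward_ratio: float = 1.0 / 3.0
    # chosen so the realized mean phase lag sits near the delay-consistent
    # phase 360 f d at the gamma peak (the regime the CTC analyses assume)
    # and stimulus ignition of both pools is reliable across seeds
    w_feedforward: float = 1.4
    seed: int = 0
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def __post_init__(self) -> None:
        if self.mode not in ("gamma", "beta"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.scale not in ("full", "reduced", "tiny"):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")

    @property
    def effective_r(self) -> float:
        if self.r is not None:
            return self.r
        return 0.12 if self.mode == "gamma" else 0.07

    def architecture(self) -> ArchitectureSpec:
        factory = {
            "full": ArchitectureSpec.full,
            "reduced": ArchitectureSpec.reduced,
            "tiny": ArchitectureSpec.tiny,
        }[self.scale]
        kw = dict(
            conduction_delay=self.conduction_delay_ms,
            feedback_feedforward_ratio=self.feedback_feedforward_ratio,
            w_feedforward=self.w_feedforward,
        )
        if self.mode == "beta":
            # the slow-GABA regime needs a stronger excitatory core to
            # ignite: beta sessions run with a selective fraction of 1/4
            kw["n_selective"] = {"full": 200, "reduced": 50, "tiny": 25}[self.scale]
        return factory(**kw)

    def te_settings(self) -> TESettings:
        """Effective TE settings: the prediction horizon follows the
        conduction delay (in MUA steps) unless lag_from_delay is off."""
        s = self.analysis.te
        if not self.analysis.lag_from_delay:
            return s
        lag = max(int(round(self.conduction_delay_ms)), 1)
        return dataclasses.replace(s, lag=lag)

    def synapses(self) -> SynapseParams:
        syn = SynapseParams()
        return beta_mode(syn) if self.mode == "beta" else syn

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            pre_stimulus=self.pre_stimulus_ms,
            stimulus=self.stimulus_ms,
            post_stimulus=self.post_stimulus_ms,
            n_trials=self.n_trials,
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ExperimentConfig":
        """Build a config from a flat mapping (e.g. a key=value file).

        Keys must be ExperimentConfig field names; an unknown key raises a
        parameter error naming it.  Analysis settings keep their defaults
        (construct AnalysisSettings separately for non-default analyses).
        """
        allowed = {f for f in cls.__dataclass_fields__ if f != "analysis"}
        unknown = set(mapping) - allowed
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def simulate(self) -> SpikeData:
        return run_session(
            self.architecture(),
            self.synapses(),
            self.protocol(),
            r=self.effective_r,
            master_seed=self.seed,
        )


def session_mua(config: ExperimentConfig, spikes: SpikeData) -> tuple[list[MuaSeries], list[MuaSeries]]:
    """Z-scored MUA of the two selective pools, same sampled ids per pool
    across trials."""
    a = config.analysis
    m1 = pool_mua(
        spikes, "S1", n_sampled=a.n_sampled, seed=config.seed + 101, on_degenerate="zeros"
    )
    m2 = pool_mua(
        spikes, "S2", n_sampled=a.n_sampled, seed=config.seed + 202, on_degenerate="zeros"
    )
    return m1, m2


def _stimulus_span(config: ExperimentConfig) -> tuple[float, float]:
    return (config.pre_stimulus_ms, config.pre_stimulus_ms + config.stimulus_ms)


def _mean_stimulus_spectrum(
    mua: list[MuaSeries], t0: float, t1: float, window_ms: float
):
    """Average multitaper spectrum over non-overlapping stimulus windows
    and trials."""
    w_steps = int(round(window_ms))
    n_windows = int((t1 - t0) // window_ms)
    if n_windows < 1:
        raise DataError("stimulus span shorter than one spectral window")
    tapers = slepian_tapers(w_steps)
    acc = None
    count = 0
    for series in mua:
        for w in range(n_windows):
            x = series.slice_ms(t0 + w * window_ms, t0 + (w + 1) * window_ms)[:w_steps]
            if len(x) < w_steps:
                continue
            est = multitaper_power(x, tapers=tapers)
            acc = est.power if acc is None else acc + est.power
            count += 1
    if count == 0:
        raise DataError("no complete spectral windows")
    est.power = acc / count
    return est


def band_peak_frequency(est, band: tuple[float, float]) -> float:
    """Frequency of the largest power inside ``band``."""
    f, p = est.frequencies, est.power
    m = (f >= band[0]) & (f <= band[1])
    if not m.any():
        raise ParameterError(f"band {band} outside the frequency grid")
    return float(f[m][np.argmax(p[m])])


def session_band_fractions(
    config: ExperimentConfig, mua: list[MuaSeries]
) -> dict[str, float]:
    """Gamma/beta power fractions and in-band peak frequencies of the
    session-averaged stimulus spectrum."""
    a = config.analysis
    t0, t1 = _stimulus_span(config)
    est = _mean_stimulus_spectrum(mua, t0, t1, a.spectral_window_ms)
    return {
        "gamma_fraction": band_power_fraction(est, a.gamma_band),
        "beta_fraction": band_power_fraction(est, a.beta_band),
        "gamma_peak_hz": band_peak_frequency(est, a.gamma_band),
        "beta_peak_hz": band_peak_frequency(est, a.beta_band),
    }


@dataclass
class PhaseExperimentResult:
    """Phase-resolved correlation and TE of one session."""

    config: ExperimentConfig
    sort_band: str
    sort_frequency_hz: float
    mean_phase_deg: float
    bins: PhaseBinnedTrials
    curve: PhaseCorrelationCurve
    te_per_bin: list[TEEstimate | None]
    window_stats: pd.DataFrame
    band_info: dict[str, float]
    te_overall: TEEstimate | None = None
    split_curves: dict[str, PhaseCorrelationCurve] | None = None
    symbol_pairs: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def te_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(bin_centers, te_forward, te_backward) with NaN for empty bins."""
        fwd = np.array([t.te_forward if t else np.nan for t in self.te_per_bin])
        bwd = np.array([t.te_backward if t else np.nan for t in self.te_per_bin])
        return self.bins.bin_centers.copy(), fwd, bwd

    def mean_phase_bin_te(self) -> TEEstimate | None:
        return self.te_per_bin[0]

    def to_table(self) -> pd.DataFrame:
        centers, fwd, bwd = self.te_arrays()
        return pd.DataFrame(
            {
                "bin_center_deg": centers,
                "rho": self.curve.rho,
                "n_windows": self.curve.n_windows,
                "te_forward_bits": fwd,
                "te_backward_bits": bwd,
            }
        )


def _window_symbol_pairs(
    m1: list[MuaSeries],
    m2: list[MuaSeries],
    window_stats: pd.DataFrame,
    corr_window_ms: float,
    settings: TESettings,
) -> list[tuple[np.ndarray, np.ndarray]]:
    by_trial_1 = {s.trial_index: s for s in m1}
    by_trial_2 = {s.trial_index: s for s in m2}
    pairs = []
    for row in window_stats.itertuples():
        s1 = by_trial_1[row.trial]
        s2 = by_trial_2[row.trial]
        a = quantize(s1.slice_ms(row.window_start_ms, row.window_start_ms + corr_window_ms), settings.resolution)
        b = quantize(s2.slice_ms(row.window_start_ms, row.window_start_ms + corr_window_ms), settings.resolution)
        pairs.append((a, b))
    return pairs


def run_phase_experiment(
    config: ExperimentConfig,
    spikes: SpikeData | None = None,
    mua_pair: tuple[list[MuaSeries], list[MuaSeries]] | None = None,
    sort_band: str = "auto",
    median_split: bool = False,
    te_bias_correction: bool = False,
) -> PhaseExperimentResult:
    """Phase-binned correlation and TE for one session.

    ``sort_band`` chooses the band whose phase orders the windows:
    'auto' (the mode's own band), 'gamma' or 'beta' (the cross-band
    control).  ``median_split`` additionally recomputes the correlation
    curve for trials below/above the median sort-band power;
    ``te_bias_correction`` subtracts each bin's shuffle bias so bins of
    unequal occupancy are comparable.
    Pre-simulated spikes or a ready MUA pair may be passed in; a session
    is simulated otherwise.
    """
    a = config.analysis
    if mua_pair is None:
        if spikes is None:
            spikes = config.simulate()
        m1, m2 = session_mua(config, spikes)
    else:
        m1, m2 = mua_pair
    if not m1:
        raise DataError("session contains no trials")

    band_info = session_band_fractions(config, m1)
    if sort_band == "auto":
        sort_band = "gamma" if config.mode == "gamma" else "beta"
    if sort_band not in ("gamma", "beta"):
        raise ParameterError(f"unknown sort band {sort_band!r}")
    if a.use_band_peak:
        f_sort = band_info[f"{sort_band}_peak_hz"]
    else:
        f_sort = a.gamma_freq if sort_band == "gamma" else a.beta_freq

    t0, t1 = _stimulus_span(config)
    stats = windowed_band_power(m1, m2, t0, t1, a.corr_window_ms, f_sort)
    if stats.empty:
        raise DataError("no analysis windows in the stimulus span")
    te_set = config.te_settings()
    bins = bin_by_phase(stats["phase_deg"].to_numpy(), n_bins=a.n_phase_bins)
    curve = phase_binned_correlation(stats, bins)
    pairs = _window_symbol_pairs(m1, m2, stats, a.corr_window_ms, te_set)
    te_bins = te_by_phase_bin(
        pairs,
        bins,
        te_set,
        bias_correction=te_bias_correction,
        rng=np.random.default_rng(config.seed + 9090),
    )
    fwd, n = transfer_entropy_segments(pairs, te_set)
    bwd, _ = transfer_entropy_segments([(y, x) for x, y in pairs], te_set)
    overall = TEEstimate(fwd, bwd, n, te_set)

    split = None
    if median_split:
        per_trial = stats.groupby("trial")["power_x"].mean()
        below_t, above_t = median_power_split(per_trial.to_numpy())
        trial_ids = per_trial.index.to_numpy()
        split = {}
        for name, sel in (("below", below_t), ("above", above_t)):
            chosen = set(trial_ids[sel])
            mask = stats["trial"].isin(chosen).to_numpy()
            if mask.sum() < 2:
                continue
            sub_bins = PhaseBinnedTrials(
                phase_per_window=bins.phase_per_window[mask],
                circular_mean_deg=bins.circular_mean_deg,
                bin_centers=bins.bin_centers,
                assignment=bins.assignment[mask],
            )
            split[name] = phase_binned_correlation(stats[mask].reset_index(drop=True), sub_bins)

    return PhaseExperimentResult(
        config=config,
        sort_band=sort_band,
        sort_frequency_hz=f_sort,
        mean_phase_deg=bins.circular_mean_deg,
        bins=bins,
        curve=curve,
        te_per_bin=te_bins,
        window_stats=stats,
        band_info=band_info,
        te_overall=overall,
        split_curves=split,
        symbol_pairs=pairs,
    )


def _bootstrap_te_ci(
    pairs_by_trial: dict[int, list[tuple[np.ndarray, np.ndarray]]],
    settings: TESettings,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    trials = sorted(pairs_by_trial)
    if len(trials) < 2 or n_boot < 1:
        return (np.nan, np.nan)
    vals = []
    for _ in range(n_boot):
        pick = rng.choice(trials, size=len(trials), replace=True)
        segs = [p for t in pick for p in pairs_by_trial[t]]
        try:
            te, _ = transfer_entropy_segments(segs, settings)
        except DataError:
            continue
        vals.append(te)
    if not vals:
        return (np.nan, np.nan)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def run_power_sweep(
    config: ExperimentConfig,
    r_values: list[float],
    n_boot: int = 200,
) -> pd.DataFrame:
    """Gamma power fraction and mean-phase TE as functions of r.

    One session per r (seed offset by the index); TE is taken in the
    mean-phase bin, with a bootstrap 95% interval over trials.  Columns:
    r, gamma_fraction, te_forward, te_backward, CI bounds, n_samples.
    """
    if len(r_values) < 2:
        raise ParameterError("sweep needs at least 2 r values")
    rows = []
    for i, r in enumerate(r_values):
        cfg = dataclasses.replace(config, r=r, seed=config.seed + 1000 * i)
        res = run_phase_experiment(cfg)
        a = cfg.analysis
        est = res.mean_phase_bin_te()
        idx = res.bins.windows_in_bin(0)
        stats = res.window_stats
        # bootstrap over trials within the mean-phase bin
        pairs_all = res.symbol_pairs
        by_trial: dict[int, list] = {}
        for j in idx:
            t = int(stats["trial"].iloc[j])
            by_trial.setdefault(t, []).append(pairs_all[j])
        rng = np.random.default_rng(cfg.seed + 77)
        lo, hi = _bootstrap_te_ci(by_trial, cfg.te_settings(), n_boot, rng)
        rows.append(
            {
                "r": r,
                "gamma_fraction": res.band_info["gamma_fraction"],
                "gamma_peak_hz": res.band_info["gamma_peak_hz"],
                "te_forward": est.te_forward if est else np.nan,
                "te_backward": est.te_backward if est else np.nan,
                "te_forward_lo": lo,
                "te_forward_hi": hi,
                "n_samples": est.n_samples if est else 0,
                "ci_defined": config.n_trials > 1,
            }
        )
    return pd.DataFrame(rows)


def run_timing_experiment(
    config: ExperimentConfig,
    r_values: list[float],
    window_ms: float = 20.0,
    step_ms: float = 1.0,
    n_boot: int = 100,
) -> pd.DataFrame:
    """TE rise time after stimulus onset per modification ratio.

    Each r gets its own session; full-trial MUA symbol pairs are pooled
    across trials in sliding latency windows.  Rise time = first latency
    at which TE reaches 50% of its stimulus-period average; bootstrap
    interval over trials.  Undefined rise times propagate as NaN.
    """
    if len(r_values) < 2:
        raise ParameterError("timing experiment needs at least 2 r values")
    if config.stimulus_ms <= 0:
        raise ParameterError("timing experiment needs a stimulus epoch")
    rows = []
    for i, r in enumerate(r_values):
        cfg = dataclasses.replace(config, r=r, seed=config.seed + 1000 * i)
        spikes = cfg.simulate()
        m1, m2 = session_mua(cfg, spikes)
        a = cfg.analysis
        te_set = cfg.te_settings()
        pairs = [
            (quantize(s1.values, te_set.resolution), quantize(s2.values, te_set.resolution))
            for s1, s2 in zip(m1, m2)
        ]
        onset = int(round(cfg.pre_stimulus_ms))
        stim_steps = int(round(cfg.stimulus_ms))
        stim_steps = min(stim_steps, len(pairs[0][0]) - onset)
        tc = te_timecourse(
            pairs, onset, stim_steps, int(round(window_ms)), int(round(step_ms)), te_set
        )
        rng = np.random.default_rng(cfg.seed + 55)
        boots = []
        for _ in range(n_boot):
            pick = rng.choice(len(pairs), size=len(pairs), replace=True)
            if len(set(pick.tolist())) < 2:
                continue
            sub = [pairs[p] for p in pick]
            t_b = te_timecourse(sub, onset, stim_steps, int(round(window_ms)), int(round(step_ms)), te_set)
            if t_b.rise_defined:
                boots.append(t_b.rise_time_ms)
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows.append(
            {
                "r": r,
                "rise_time_ms": tc.rise_time_ms if tc.rise_defined else np.nan,
                "rise_defined": tc.rise_defined,
                "rise_lo": float(lo),
                "rise_hi": float(hi),
                "average_te": tc.average_te,
            }
        )
    return pd.DataFrame(rows)
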