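"""Shared fixtures.

The expensive fixtures simulate desk-scale network sessions once per test
run and are shared across the oscillation, directionality and acceptance
tests.  Sizes (profiles, trial counts, epochs) are the package's
desk-scale study conditions; seeds are fixed so the suite is
deterministic.
"""

import pytest

from ctcflow.pipeline import (
    AnalysisSettings,
    ExperimentConfig,
    run_phase_experiment,
    run_timing_experiment,
    session_mua,
)

#: seeds used for every majority-vote network property
NETWORK_SEEDS = (1, 2, 3, 4, 5)

#: analysis settings for phase-resolved work: sort at the nominal band
#: frequency (60 / 20 Hz), as the reference analyses do
PHASE_ANALYSIS = AnalysisSettings(use_band_peak=False)


def _spectral_config(mode: str, seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        mode=mode,
        r=0.12 if mode == "gamma" else 0.07,
        scale="reduced",
        n_trials=1,
        stimulus_ms=1600.0,
        seed=seed,
        analysis=PHASE_ANALYSIS,
    )


def _phase_config(seed: int, **overrides) -> ExperimentConfig:
    base = dict(
        mode="gamma",
        r=0.07,
        scale="tiny",
        n_trials=12,
        stimulus_ms=2100.0,
        seed=seed,
        analysis=PHASE_ANALYSIS,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@pytest.fixture(scope="session")
def gamma_oscillation_sessions():
    """Reduced-scale gamma-mode sessions (r=0.12), one per seed."""
    return [_spectral_config("gamma", s).simulate() for s in NETWORK_SEEDS]


@pytest.fixture(scope="session")
def beta_oscillation_sessions():
    """Reduced-scale beta-mode sessions (slow GABA, r=0.07)."""
    return [_spectral_config("beta", s).simulate() for s in NETWORK_SEEDS]


@pytest.fixture(scope="session")
def gamma_phase_results():
    """Phase experiments on tiny gamma sessions, each analyzed twice:
    sorted by gamma phase and (cross-band control) by beta phase."""
    out = []
    for seed in NETWORK_SEEDS:
        cfg = _phase_config(seed)
        spikes = cfg.simulate()
        mua = session_mua(cfg, spikes)
        res_g = run_phase_experiment(
            cfg, mua_pair=mua, sort_band="gamma", te_bias_correction=True
        )
        res_b = run_phase_experiment(
            cfg, mua_pair=mua, sort_band="beta", te_bias_correction=True
        )
        out.append((res_g, res_b))
    return out


@pytest.fixture(scope="session")
def ratio_one_results():
    """Phase experiments with symmetric coupling (fb/ff ratio = 1)."""
    out = []
    for seed in NETWORK_SEEDS:
        cfg = _phase_config(
            seed, n_trials=6, stimulus_ms=1600.0, feedback_feedforward_ratio=1.0
        )
        out.append(run_phase_experiment(cfg))
    return out


@pytest.fixture(scope="session")
def r_sweep_results():
    """Mean-phase-bin TE at the sweep endpoints r = 0.02 and 0.12, per
    seed (the r = 0.07 midpoint comes from the shared phase sessions)."""
    out = {}
    for r in (0.02, 0.12):
        per_seed = []
        for seed in NETWORK_SEEDS:
            cfg = _phase_config(seed, r=r, n_trials=8, stimulus_ms=1600.0)
            per_seed.append(run_phase_experiment(cfg, te_bias_correction=True))
        out[r] = per_seed
    return out


@pytest.fixture(scope="session")
def rise_time_tables():
    """TE rise times at r = 0.02 vs 0.12, one table per seed."""
    tables = []
    for seed in NETWORK_SEEDS:
        cfg = ExperimentConfig(
            mode="gamma",
            scale="tiny",
            n_trials=20,
            stimulus_ms=600.0,
            seed=seed,
            analysis=PHASE_ANALYSIS,
        )
        tables.append(run_timing_experiment(cfg, [0.02, 0.12], n_boot=0))
    return tables


def majority(flags) -> bool:
    """True when more than half of the boolean votes are True."""
    flags = list(flags)
    return sum(bool(f) for f in flags) > len(flags) / 2

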