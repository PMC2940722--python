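"""Two-circuit conductance-based integrate-and-fire network simulator.

Each of the two circuits contains ``n_excitatory_per_circuit`` pyramidal
cells (a selective pool S and a non-selective rest) and an inhibitory pool;
the network is fully connected with pool-block weights, and the two
selective pools are reciprocally coupled with a conduction delay.  Membrane
potentials follow

    C_m dV/dt = -g_m (V - V_L) - I_syn,

with I_syn the sum of external-AMPA, recurrent-AMPA, NMDA (with the
Jahr–Stevens magnesium block) and GABA currents.  Channel gating uses the
standard kinetics: AMPA/GABA fractions decay exponentially and jump by +1
per presynaptic spike; NMDA uses the two-variable rise/saturation system,
which keeps its open fraction in [0, 1].

Numerics: membrane equations advance with classical fourth-order
Runge–Kutta at dt = 0.02 ms.  Linear gating is propagated by its exact
exponential between spikes, the NMDA pair by two half RK4 steps per step,
and spike delta inputs are applied as discrete jumps at step boundaries,
so the smooth part retains full integrator order.  Threshold crossings are
handled at step resolution.  Because connectivity is all-to-all with
weights that depend only on the (source pool, target pool) pair, recurrent
drive is computed from per-pool sums of gating variables: one time step
costs O(N), which is what makes desk-scale sessions practical.

The Poisson background (2.4 kHz per neuron, the superposition of 800
afferents at 3 Hz) and the 250 Hz stimulus onto S1 are generated per trial
from the trial seed by exponential inter-event sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .errors import IntegrationError, ParameterError, StructuralError
from .params import (
    EXCITATORY,
    INHIBITORY,
    ArchitectureSpec,
    NeuronClassParams,
    StimulusProtocol,
    SynapseParams,
    apply_modification_ratio,
    mg_block_factor,
)

__all__ = [
    "SpikeData",
    "GatingState",
    "update_gating",
    "total_synaptic_current",
    "integrate_trial",
    "run_session",
    "POOL_LABELS",
]

DT_MS = 0.02  # integration step, ms
POOL_LABELS = ("S1", "NS1", "I1", "S2", "NS2", "I2")

_STATUS_OK = 0
_STATUS_DIVERGED = 1
_STATUS_OVERFLOW = 2


@dataclass
class SpikeData:
    """Trial-structured spike events plus the provenance needed to rerun.

    ``events`` has columns trial, neuron_id, pool, time_ms (trial clock,
    0-based).  ``metadata`` snapshots the parameter set, the master seed
    and the per-trial seeds.
    """

    events: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return int(self.metadata.get("n_trials", self.events["trial"].nunique()))

    @property
    def trial_length(self) -> float:
        return float(self.metadata["trial_length_ms"])

    def pool_events(self, pool: str, trial: Optional[int] = None) -> pd.DataFrame:
        ev = self.events[self.events["pool"] == pool]
        if trial is not None:
            ev = ev[ev["trial"] == trial]
        return ev

    def pool_neuron_ids(self, pool: str) -> np.ndarray:
        sl = self.metadata["pool_slices"][pool]
        return np.arange(sl[0], sl[1])

    def firing_rate(self, pool: str, t_start: float = 0.0, t_stop: Optional[float] = None) -> float:
        """Mean rate (Hz) per neuron of a pool over [t_start, t_stop)."""
        if t_stop is None:
            t_stop = self.trial_length
        ev = self.pool_events(pool)
        n_sp = int(((ev["time_ms"] >= t_start) & (ev["time_ms"] < t_stop)).sum())
        n_neurons = len(self.pool_neuron_ids(pool))
        dur_s = (t_stop - t_start) / 1e3
        return n_sp / (n_neurons * max(self.n_trials, 1) * dur_s)


# ---------------------------------------------------------------------------
# Reference (pure-Python) gating and current computations.  The numba kernel
# below inlines the same arithmetic; these functions are the documented unit
# of behaviour and are what the unit tests exercise directly.
# ---------------------------------------------------------------------------


@dataclass
class GatingState:
    """Open-channel fractions of one target's presynaptic sources.

    ``s_ampa``/``x_nmda``/``s_nmda`` are per excitatory source neuron,
    ``s_gaba`` per inhibitory source; ``s_ext`` is the pooled external
    AMPA channel.
    """

    s_ampa: np.ndarray
    x_nmda: np.ndarray
    s_nmda: np.ndarray
    s_gaba: np.ndarray
    s_ext: float = 0.0

    @classmethod
    def zeros(cls, n_exc: int, n_inh: int) -> "GatingState":
        return cls(
            s_ampa=np.zeros(n_exc),
            x_nmda=np.zeros(n_exc),
            s_nmda=np.zeros(n_exc),
            s_gaba=np.zeros(n_inh),
            s_ext=0.0,
        )


def _nmda_halfstep(s: np.ndarray, x0: np.ndarray, h: float, syn: SynapseParams) -> np.ndarray:
    """One RK4 step of ds/dt = -s/tau_d + alpha x(t) (1-s), x decaying
    analytically from x0."""
    tau_d, tau_r, alpha = syn.tau_nmda_decay, syn.tau_nmda_rise, syn.nmda_alpha
    x_mid = x0 * math.exp(-0.5 * h / tau_r)
    x_end = x0 * math.exp(-h / tau_r)

    def f(s_, x_):
        return -s_ / tau_d + alpha * x_ * (1.0 - s_)

    k1 = f(s, x0)
    k2 = f(s + 0.5 * h * k1, x_mid)
    k3 = f(s + 0.5 * h * k2, x_mid)
    k4 = f(s + h * k3, x_end)
    return s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def update_gating(
    state: GatingState,
    exc_spikes: np.ndarray,
    inh_spikes: np.ndarray,
    ext_spikes: float,
    dt: float,
    syn: SynapseParams,
) -> GatingState:
    """Advance all gating variables by one step of length ``dt``.

    AMPA (recurrent and external) and GABA fractions decay with their time
    constants; the NMDA pair advances with the saturating rise/decay
    kinetics.  Presynaptic spike indicators are applied as +1 jumps at the
    end of the step.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    exc_spikes = np.asarray(exc_spikes, dtype=float)
    inh_spikes = np.asarray(inh_spikes, dtype=float)
    if exc_spikes.shape != state.s_ampa.shape or inh_spikes.shape != state.s_gaba.shape:
        raise StructuralError("spike indicator shape does not match gating state")
    s_n = _nmda_halfstep(state.s_nmda, state.x_nmda, 0.5 * dt, syn)
    s_n = _nmda_halfstep(
        s_n, state.x_nmda * math.exp(-0.5 * dt / syn.tau_nmda_rise), 0.5 * dt, syn
    )
    return GatingState(
        s_ampa=state.s_ampa * math.exp(-dt / syn.tau_ampa_decay) + exc_spikes,
        x_nmda=state.x_nmda * math.exp(-dt / syn.tau_nmda_rise) + exc_spikes,
        s_nmda=s_n,
        s_gaba=state.s_gaba * math.exp(-dt / syn.tau_gaba_decay) + inh_spikes,
        s_ext=state.s_ext * math.exp(-dt / syn.tau_ext) + float(ext_spikes),
    )


def total_synaptic_current(
    v: float,
    gating: GatingState,
    weights_exc: np.ndarray,
    weights_inh: np.ndarray,
    syn: SynapseParams,
    target: str = "excitatory",
) -> float:
    """Total synaptic current (nA, positive = hyperpolarizing outward).

    Four terms: external AMPA (unweighted pooled channel), recurrent AMPA,
    NMDA scaled by the magnesium-block factor, and GABA; excitatory terms
    use the driving force (v - v_excitatory_reversal), GABA uses
    (v - v_inhibitory_reversal).  The weighted sums run over all
    presynaptic neurons.
    """
    weights_exc = np.asarray(weights_exc, dtype=float)
    weights_inh = np.asarray(weights_inh, dtype=float)
    if weights_exc.shape != gating.s_ampa.shape:
        raise StructuralError("excitatory weight vector does not match gating")
    if weights_inh.shape != gating.s_gaba.shape:
        raise StructuralError("inhibitory weight vector does not match gating")
    if target.startswith("exc"):
        g_ext, g_rec = syn.g_ampa_ext_exc, syn.g_ampa_rec_exc
        g_nmda, g_gaba = syn.g_nmda_exc, syn.g_gaba_exc
    else:
        g_ext, g_rec = syn.g_ampa_ext_inh, syn.g_ampa_rec_inh
        g_nmda, g_gaba = syn.g_nmda_inh, syn.g_gaba_inh
    dv_e = v - syn.v_excitatory_reversal
    dv_i = v - syn.v_inhibitory_reversal
    mgb = float(mg_block_factor(v, syn.mg_concentration))
    i_pa = (
        g_ext * dv_e * gating.s_ext
        + g_rec * dv_e * float(weights_exc @ gating.s_ampa)
        + g_nmda * dv_e * mgb * float(weights_exc @ gating.s_nmda)
        + g_gaba * dv_i * float(weights_inh @ gating.s_gaba)
    )
    return i_pa / 1e3  # pA -> nA


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _run_trial_kernel(
    seed,
    ns,
    ne,
    ni,
    dt,
    n_steps,
    cm_e,
    gm_e,
    ref_e,
    cm_i,
    gm_i,
    ref_i,
    v_leak,
    v_thr,
    v_reset,
    v_rev_e,
    v_rev_i,
    g_ext_e,
    g_ext_i,
    g_rec_e,
    g_rec_i,
    g_nm_e,
    g_nm_i,
    g_gb_e,
    g_gb_i,
    tau_a,
    tau_ae,
    tau_nr,
    tau_nd,
    alpha,
    tau_g,
    mg_over,
    w_plus,
    w_minus,
    w_inh,
    w_ff,
    w_fb,
    delay_steps,
    bg_rate_ms,
    stim_rate_ms,
    stim_on,
    stim_off,
    cap,
    record_v,
):
    np.random.seed(seed)
    npc = ne + ni
    n = 2 * npc

    v = np.full(n, v_reset)
    refrac_until = np.full(n, -1.0)
    s_ext = np.zeros(n)
    s_a = np.zeros(n)
    x_n = np.zeros(n)
    s_n = np.zeros(n)
    s_g = np.zeros(n)
    # delayed copies driven by the cross-circuit conduction delay
    s_ad = np.zeros(n)
    x_nd = np.zeros(n)
    s_nd = np.zeros(n)

    # neuron -> (circuit, pool index 0=S 1=NS 2=I, is_exc)
    circuit = np.empty(n, dtype=np.int8)
    poolidx = np.empty(n, dtype=np.int8)
    is_exc = np.empty(n, dtype=np.int8)
    for i in range(n):
        c = i // npc
        loc = i - c * npc
        circuit[i] = c
        if loc < ns:
            poolidx[i] = 0
            is_exc[i] = 1
        elif loc < ne:
            poolidx[i] = 1
            is_exc[i] = 1
        else:
            poolidx[i] = 2
            is_exc[i] = 0

    # next-event times for external Poisson drives
    t_next_bg = np.empty(n)
    for i in range(n):
        if bg_rate_ms > 0.0:
            t_next_bg[i] = -math.log(np.random.random()) / bg_rate_ms
        else:
            t_next_bg[i] = 1e300
    t_next_stim = np.empty(ns)
    for k in range(ns):
        if stim_rate_ms > 0.0 and stim_off > stim_on:
            t_next_stim[k] = stim_on - math.log(np.random.random()) / stim_rate_ms
        else:
            t_next_stim[k] = 1e300

    dbuf = delay_steps + 1
    buf = np.zeros((dbuf, 2 * ns), dtype=np.float64)

    spike_ids = np.empty(cap, dtype=np.int32)
    spike_times = np.empty(cap, dtype=np.float64)
    n_spikes = 0
    scheduled = 0
    delivered = 0

    v_trace = np.empty(n_steps + 1 if record_v else 1)
    if record_v:
        v_trace[0] = v[0]

    fa_h = math.exp(-0.5 * dt / tau_a)
    fa = fa_h * fa_h
    fe_h = math.exp(-0.5 * dt / tau_ae)
    fe = fe_h * fe_h
    fg_h = math.exp(-0.5 * dt / tau_g)
    fg = fg_h * fg_h
    fx = math.exp(-dt / tau_nr)
    fx_q = math.exp(-0.25 * dt / tau_nr)  # quarter-step decay of x
    h = 0.5 * dt

    # per-stage pool sums: AMPA (S1, NS1, S2, NS2), delayed AMPA (S1, S2),
    # NMDA likewise, GABA (I1, I2)
    nm = np.zeros((3, 4))
    nmd = np.zeros((3, 2))
    wa = np.empty((2, 3, 3))
    wn = np.empty((2, 3, 3))
    wg = np.empty((2, 3))

    status = 0

    for step in range(n_steps):
        t_ms = step * dt
        pos = step % dbuf

        # deliver delayed cross-circuit spikes scheduled delay_steps ago
        for k in range(2 * ns):
            cnt = buf[pos, k]
            if cnt > 0.0:
                c = k // ns
                i = c * npc + (k - c * ns)  # S neuron index of the source
                s_ad[i] += cnt
                x_nd[i] += cnt
                delivered += int(cnt)
                buf[pos, k] = 0.0

        # external Poisson arrivals in (t-dt, t]
        for i in range(n):
            while t_next_bg[i] <= t_ms:
                s_ext[i] += 1.0
                t_next_bg[i] += -math.log(np.random.random()) / bg_rate_ms
        for k in range(ns):
            while t_next_stim[k] <= t_ms:
                if t_next_stim[k] < stim_off:
                    s_ext[k] += 1.0  # S1 neurons are indices 0..ns-1
                t_next_stim[k] += -math.log(np.random.random()) / stim_rate_ms
                if t_next_stim[k] >= stim_off:
                    t_next_stim[k] = 1e300

        # ---- NMDA integration (two half RK4 steps), pool sums at 3 stages
        for a in range(3):
            for b in range(4):
                nm[a, b] = 0.0
            nmd[a, 0] = 0.0
            nmd[a, 1] = 0.0
        for c in range(2):
            base = c * npc
            for loc in range(ne):
                i = base + loc
                p = 0 if loc < ns else 1
                col = 2 * c + p
                s0 = s_n[i]
                x0 = x_n[i]
                # first half step
                x_mid = x0 * fx_q
                x_end = x0 * fx_q * fx_q
                k1 = -s0 / tau_nd + alpha * x0 * (1.0 - s0)
                s_ = s0 + 0.5 * h * k1
                k2 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                s_ = s0 + 0.5 * h * k2
                k3 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                s_ = s0 + h * k3
                k4 = -s_ / tau_nd + alpha * x_end * (1.0 - s_)
                s_half = s0 + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                # second half step
                x0b = x_end
                x_mid = x0b * fx_q
                x_endb = x0b * fx_q * fx_q
                k1 = -s_half / tau_nd + alpha * x0b * (1.0 - s_half)
                s_ = s_half + 0.5 * h * k1
                k2 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                s_ = s_half + 0.5 * h * k2
                k3 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                s_ = s_half + h * k3
                k4 = -s_ / tau_nd + alpha * x_endb * (1.0 - s_)
                s_full = s_half + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                nm[0, col] += s0
                nm[1, col] += s_half
                nm[2, col] += s_full
                s_n[i] = s_full
                x_n[i] = x0 * fx
                # delayed copy (selective sources only carry cross input)
                if p == 0:
                    s0d = s_nd[i]
                    x0d = x_nd[i]
                    x_mid = x0d * fx_q
                    x_end = x0d * fx_q * fx_q
                    k1 = -s0d / tau_nd + alpha * x0d * (1.0 - s0d)
                    s_ = s0d + 0.5 * h * k1
                    k2 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                    s_ = s0d + 0.5 * h * k2
                    k3 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                    s_ = s0d + h * k3
                    k4 = -s_ / tau_nd + alpha * x_end * (1.0 - s_)
                    s_halfd = s0d + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                    x0b = x_end
                    x_mid = x0b * fx_q
                    x_endb = x0b * fx_q * fx_q
                    k1 = -s_halfd / tau_nd + alpha * x0b * (1.0 - s_halfd)
                    s_ = s_halfd + 0.5 * h * k1
                    k2 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                    s_ = s_halfd + 0.5 * h * k2
                    k3 = -s_ / tau_nd + alpha * x_mid * (1.0 - s_)
                    s_ = s_halfd + h * k3
                    k4 = -s_ / tau_nd + alpha * x_endb * (1.0 - s_)
                    s_fulld = s_halfd + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                    nmd[0, c] += s0d
                    nmd[1, c] += s_halfd
                    nmd[2, c] += s_fulld
                    s_nd[i] = s_fulld
                    x_nd[i] = x0d * fx

        # ---- AMPA / GABA pool sums at stage 0 (exact decay scales later)
        a_s1 = a_ns1 = a_s2 = a_ns2 = 0.0
        ad_1 = ad_2 = 0.0
        g_1 = g_2 = 0.0
        for c in range(2):
            base = c * npc
            s_sum = 0.0
            for loc in range(ns):
                s_sum += s_a[base + loc]
            ns_sum = 0.0
            for loc in range(ns, ne):
                ns_sum += s_a[base + loc]
            ad_sum = 0.0
            for loc in range(ns):
                ad_sum += s_ad[base + loc]
            gg_sum = 0.0
            for loc in range(ne, npc):
                gg_sum += s_g[base + loc]
            if c == 0:
                a_s1, a_ns1, ad_1, g_1 = s_sum, ns_sum, ad_sum, gg_sum
            else:
                a_s2, a_ns2, ad_2, g_2 = s_sum, ns_sum, ad_sum, gg_sum

        # ---- weighted drives per (circuit, target pool, stage)
        a_stage = (1.0, fa_h, fa)
        g_stage = (1.0, fg_h, fg)
        for st in range(3):
            fa_s = a_stage[st]
            fg_s = g_stage[st]
            a1s, a1n = a_s1 * fa_s, a_ns1 * fa_s
            a2s, a2n = a_s2 * fa_s, a_ns2 * fa_s
            ad1, ad2 = ad_1 * fa_s, ad_2 * fa_s
            # circuit 0 targets; cross input to S1 comes from delayed S2
            # w_minus depresses excitatory connections from/to the
            # non-selective pool; within-selective uses w_plus
            wa[0, 0, st] = w_plus * a1s + w_minus * a1n + w_fb * ad2
            wa[0, 1, st] = w_minus * (a1s + a1n)
            wa[0, 2, st] = w_inh * (a1s + a1n)
            wa[1, 0, st] = w_plus * a2s + w_minus * a2n + w_ff * ad1
            wa[1, 1, st] = w_minus * (a2s + a2n)
            wa[1, 2, st] = w_inh * (a2s + a2n)
            n1s, n1n = nm[st, 0], nm[st, 1]
            n2s, n2n = nm[st, 2], nm[st, 3]
            nd1, nd2 = nmd[st, 0], nmd[st, 1]
            wn[0, 0, st] = w_plus * n1s + w_minus * n1n + w_fb * nd2
            wn[0, 1, st] = w_minus * (n1s + n1n)
            wn[0, 2, st] = w_inh * (n1s + n1n)
            wn[1, 0, st] = w_plus * n2s + w_minus * n2n + w_ff * nd1
            wn[1, 1, st] = w_minus * (n2s + n2n)
            wn[1, 2, st] = w_inh * (n2s + n2n)
            # inhibitory-source weights are 1; w_inh applies on E->I only
            wg[0, st] = g_1 * fg_s
            wg[1, st] = g_2 * fg_s

        # ---- membrane RK4
        for i in range(n):
            if refrac_until[i] > t_ms + 1e-12:
                continue
            if is_exc[i] == 1:
                cm, gm = cm_e, gm_e
                ge, gr, gn, gg = g_ext_e, g_rec_e, g_nm_e, g_gb_e
            else:
                cm, gm = cm_i, gm_i
                ge, gr, gn, gg = g_ext_i, g_rec_i, g_nm_i, g_gb_i
            c = circuit[i]
            p = poolidx[i]
            se = s_ext[i]
            v0 = v[i]

            # stage 0
            mgb = 1.0 / (1.0 + mg_over * math.exp(-0.062 * v0))
            isyn = (
                ge * (v0 - v_rev_e) * se
                + gr * (v0 - v_rev_e) * wa[c, p, 0]
                + gn * (v0 - v_rev_e) * mgb * wn[c, p, 0]
                + gg * (v0 - v_rev_i) * wg[c, 0]
            )
            k1 = (-(gm * (v0 - v_leak)) - isyn) / cm
            # stage 1 (midpoint, twice)
            vv = v0 + 0.5 * dt * k1
            mgb = 1.0 / (1.0 + mg_over * math.exp(-0.062 * vv))
            isyn = (
                ge * (vv - v_rev_e) * se * fe_h
                + gr * (vv - v_rev_e) * wa[c, p, 1]
                + gn * (vv - v_rev_e) * mgb * wn[c, p, 1]
                + gg * (vv - v_rev_i) * wg[c, 1]
            )
            k2 = (-(gm * (vv - v_leak)) - isyn) / cm
            vv = v0 + 0.5 * dt * k2
            mgb = 1.0 / (1.0 + mg_over * math.exp(-0.062 * vv))
            isyn = (
                ge * (vv - v_rev_e) * se * fe_h
                + gr * (vv - v_rev_e) * wa[c, p, 1]
                + gn * (vv - v_rev_e) * mgb * wn[c, p, 1]
                + gg * (vv - v_rev_i) * wg[c, 1]
            )
            k3 = (-(gm * (vv - v_leak)) - isyn) / cm
            # stage 2 (full step)
            vv = v0 + dt * k3
            mgb = 1.0 / (1.0 + mg_over * math.exp(-0.062 * vv))
            isyn = (
                ge * (vv - v_rev_e) * se * fe
                + gr * (vv - v_rev_e) * wa[c, p, 2]
                + gn * (vv - v_rev_e) * mgb * wn[c, p, 2]
                + gg * (vv - v_rev_i) * wg[c, 2]
            )
            k4 = (-(gm * (vv - v_leak)) - isyn) / cm
            v_new = v0 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not (-200.0 < v_new < 100.0):
                return (
                    _STATUS_DIVERGED,
                    n_spikes,
                    spike_ids,
                    spike_times,
                    v_trace,
                    scheduled,
                    delivered,
                    step,
                )
            v[i] = v_new

        # ---- advance linear gating to the end of the step
        for i in range(n):
            s_ext[i] *= fe
            s_a[i] *= fa
            s_ad[i] *= fa
            s_g[i] *= fg

        # ---- threshold crossings, resets, jumps, delay scheduling
        t_spk = t_ms + dt
        for i in range(n):
            if refrac_until[i] > t_ms + 1e-12:
                continue
            if v[i] >= v_thr:
                v[i] = v_reset
                if is_exc[i] == 1:
                    refrac_until[i] = t_spk + ref_e
                    s_a[i] += 1.0
                    x_n[i] += 1.0
                else:
                    refrac_until[i] = t_spk + ref_i
                    s_g[i] += 1.0
                if n_spikes >= cap:
                    return (
                        _STATUS_OVERFLOW,
                        n_spikes,
                        spike_ids,
                        spike_times,
                        v_trace,
                        scheduled,
                        delivered,
                        step,
                    )
                spike_ids[n_spikes] = i
                spike_times[n_spikes] = t_spk
                n_spikes += 1
                c = circuit[i]
                loc = i - c * npc
                if loc < ns:  # selective neuron: schedule delayed delivery
                    buf[pos, c * ns + loc] += 1.0
                    scheduled += 1

        if record_v:
            v_trace[step + 1] = v[0]

    return (status, n_spikes, spike_ids, spike_times, v_trace, scheduled, delivered, n_steps)


def _pool_label_array(arch: ArchitectureSpec, ids: np.ndarray) -> np.ndarray:
    npc = arch.n_per_circuit
    ne = arch.n_excitatory_per_circuit
    ns = arch.n_selective
    loc = ids % npc
    c = ids // npc
    lab = np.where(loc < ns, 0, np.where(loc < ne, 1, 2)) + 3 * c
    return np.array(POOL_LABELS)[lab]


def integrate_trial(
    arch: ArchitectureSpec,
    syn: SynapseParams,
    protocol: StimulusProtocol,
    r: float = 0.0,
    seed: int = 0,
    exc: NeuronClassParams = EXCITATORY,
    inh: NeuronClassParams = INHIBITORY,
    record_v: bool = False,
    trial_index: int = 0,
):
    """Integrate one trial; returns ``(SpikeData, v_trace)``.

    ``r`` is the NMDA/AMPA modification ratio applied to the recurrent
    conductances before the run; ``record_v`` additionally returns the
    membrane-potential trace of neuron 0 at every step (used for the
    leak-limit validation).  Poisson drives are regenerated from ``seed``.
    """
    syn_r = apply_modification_ratio(syn, r)
    sc = arch.recurrent_scale
    n_steps = int(round(protocol.trial_length / DT_MS))
    cap = max(10_000, int(arch.n_total * protocol.trial_length * 0.35))
    stim_on, stim_off = protocol.stimulus_window

    out = _run_trial_kernel(
        np.uint32(seed),
        arch.n_selective,
        arch.n_excitatory_per_circuit,
        arch.n_inhibitory_per_circuit,
        DT_MS,
        n_steps,
        exc.membrane_capacitance * 1e3,  # nF -> pF so pA/pF = mV/ms
        exc.leak_conductance,
        exc.refractory_period,
        inh.membrane_capacitance * 1e3,
        inh.leak_conductance,
        inh.refractory_period,
        exc.resting_potential,
        exc.threshold_potential,
        exc.reset_potential,
        syn_r.v_excitatory_reversal,
        syn_r.v_inhibitory_reversal,
        syn_r.g_ampa_ext_exc,
        syn_r.g_ampa_ext_inh,
        syn_r.g_ampa_rec_exc * sc,
        syn_r.g_ampa_rec_inh * sc,
        syn_r.g_nmda_exc * sc,
        syn_r.g_nmda_inh * sc,
        syn_r.g_gaba_exc * sc,
        syn_r.g_gaba_inh * sc,
        syn_r.tau_ampa_decay,
        syn_r.tau_ext,
        syn_r.tau_nmda_rise,
        syn_r.tau_nmda_decay,
        syn_r.nmda_alpha,
        syn_r.tau_gaba_decay,
        syn_r.mg_concentration / 3.57,
        arch.w_plus,
        arch.w_minus,
        arch.w_inhib,
        arch.w_feedforward,
        arch.w_feedback,
        int(round(arch.conduction_delay / DT_MS)),
        protocol.background_rate_total / 1e3,
        protocol.input_rate / 1e3,
        stim_on,
        stim_off,
        cap,
        record_v,
    )
    status, n_spikes, ids, times, v_trace, scheduled, delivered, last_step = out
    if status == _STATUS_DIVERGED:
        raise IntegrationError(
            f"membrane potential diverged at step {last_step} (t={last_step * DT_MS:.2f} ms)"
        )
    if status == _STATUS_OVERFLOW:
        raise IntegrationError(f"spike buffer overflow at step {last_step}")
    ids = ids[:n_spikes].copy()
    times = times[:n_spikes].copy()
    events = pd.DataFrame(
        {
            "trial": np.full(n_spikes, trial_index, dtype=np.int32),
            "neuron_id": ids,
            "pool": _pool_label_array(arch, ids) if n_spikes else np.array([], dtype=object),
            "time_ms": times,
        }
    )
    sl = {k: (s.start, s.stop) for k, s in arch.pool_slices().items()}
    meta = {
        "n_trials": 1,
        "trial_length_ms": protocol.trial_length,
        "pool_slices": sl,
        "trial_seeds": [int(np.uint32(seed))],
        "delay_scheduled": int(scheduled),
        "delay_delivered_plus_inflight": int(delivered),
        "r": r,
    }
    return SpikeData(events=events, metadata=meta), (v_trace if record_v else None)


def run_session(
    arch: ArchitectureSpec,
    syn: SynapseParams,
    protocol: StimulusProtocol,
    r: float = 0.0,
    master_seed: int = 0,
    exc: NeuronClassParams = EXCITATORY,
    inh: NeuronClassParams = INHIBITORY,
) -> SpikeData:
    """Run ``protocol.n_trials`` independent trials.

    Per-trial seeds are spawned deterministically from ``master_seed``
    (recorded in the metadata), so the same master seed reproduces the
    session bit for bit.
    """
    seeds = np.random.SeedSequence(master_seed).generate_state(max(protocol.n_trials, 1))
    frames = []
    trial_seeds = []
    sched = deliv = 0
    for t in range(protocol.n_trials):
        s = int(seeds[t]) % (2**31)
        trial_seeds.append(s)
        sd, _ = integrate_trial(
            arch, syn, protocol, r=r, seed=s, exc=exc, inh=inh, trial_index=t
        )
        sched += sd.metadata["delay_scheduled"]
        deliv += sd.metadata["delay_delivered_plus_inflight"]
        frames.append(sd.events)
    events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trial", "neuron_id", "pool", "time_ms"])
    )
    sl = {k: (s.start, s.stop) for k, s in arch.pool_slices().items()}
    meta = {
        "n_trials": protocol.n_trials,
        "trial_length_ms": protocol.trial_length,
        "pool_slices": sl,
        "master_seed": int(master_seed),
        "trial_seeds": trial_seeds,
        "delay_scheduled": sched,
        "delay_delivered_plus_inflight": deliv,
        "r": r,
        "params": {
            "arch": arch.__dict__ if not hasattr(arch, "__dataclass_fields__") else {
                k: getattr(arch, k) for k in arch.__dataclass_fields__
            },
            "syn": {k: getattr(syn, k) for k in syn.__dataclass_fields__},
            "protocol": {k: getattr(protocol, k) for k in protocol.__dataclass_fields__},
            "exc": {k: getattr(exc, k) for k in exc.__dataclass_fields__},
            "inh": {k: getattr(inh, k) for k in inh.__dataclass_fields__},
        },
    }
    return SpikeData(events=events, metadata=meta)
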