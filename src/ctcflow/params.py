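"""Network parameters: neuron classes, synapses, architecture, protocol.

The defaults reproduce the two-circuit conductance-based integrate-and-fire
network of the Brunel–Wang family used to study communication through
coherence: each circuit holds 800 excitatory and 200 inhibitory cells, a
selective pool S inside the excitatory population receives the stimulus,
and the two selective pools are reciprocally coupled with a conduction
delay.  Gamma-band oscillations arise from the pyramidal–interneuron loop;
their strength is controlled by the NMDA/AMPA *modification ratio* ``r``
(recurrent NMDA scaled by ``1 - r``, recurrent AMPA by ``1 + 10 r``), and
beta-band oscillations are obtained by slowing GABA decay to 38 ms (with
AMPA decay at 1.5 ms).

Units follow the field's conventions: capacitance nF, conductance nS,
potential mV, time ms, rates Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "NeuronClassParams",
    "SynapseParams",
    "ArchitectureSpec",
    "StimulusProtocol",
    "EXCITATORY",
    "INHIBITORY",
    "DEFAULT_SYNAPSES",
    "apply_modification_ratio",
    "mg_block_factor",
    "beta_mode",
]


@dataclass(frozen=True)
class NeuronClassParams:
    """Passive membrane parameters of one neuron class.

    The membrane obeys ``C_m dV/dt = -g_m (V - V_L) - I_syn``; on reaching
    the threshold the cell spikes, resets, and stays shunted for the
    refractory period.
    """

    membrane_capacitance: float  # nF
    leak_conductance: float  # nS
    resting_potential: float  # mV
    threshold_potential: float  # mV
    reset_potential: float  # mV
    refractory_period: float  # ms

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0:
            raise ParameterError("membrane_capacitance must be > 0")
        if self.leak_conductance <= 0:
            raise ParameterError("leak_conductance must be > 0")
        if self.refractory_period <= 0:
            raise ParameterError("refractory_period must be > 0")
        if not self.resting_potential < self.threshold_potential:
            raise ParameterError("resting_potential must lie below threshold")
        if not self.reset_potential < self.threshold_potential:
            raise ParameterError("reset_potential must lie below threshold")

    @property
    def membrane_tau(self) -> float:
        """Membrane time constant C_m/g_m in ms."""
        return 1e3 * self.membrane_capacitance / self.leak_conductance


#: Pyramidal-cell defaults (C_m 0.5 nF, g_m 25 nS, refractory 2 ms).
EXCITATORY = NeuronClassParams(0.5, 25.0, -70.0, -50.0, -55.0, 2.0)
#: Interneuron defaults (C_m 0.2 nF, g_m 20 nS, refractory 1 ms).
INHIBITORY = NeuronClassParams(0.2, 20.0, -70.0, -50.0, -55.0, 1.0)


@dataclass(frozen=True)
class SynapseParams:
    """Conductances and kinetics of the AMPA/NMDA/GABA receptor channels.

    Each maximal conductance carries one value for excitatory targets and
    one for inhibitory targets.  AMPA and GABA gating decays exponentially
    and jumps by +1 per presynaptic spike; NMDA uses the two-variable
    rise/saturation kinetics with rate ``nmda_alpha`` and a voltage
    dependence through the magnesium block.
    """

    g_ampa_ext_exc: float = 2.08  # nS, external AMPA onto excitatory cells
    g_ampa_ext_inh: float = 1.62
    g_ampa_rec_exc: float = 0.104  # nS, recurrent AMPA
    g_ampa_rec_inh: float = 0.081
    g_nmda_exc: float = 0.327
    g_nmda_inh: float = 0.258
    g_gaba_exc: float = 1.287
    g_gaba_inh: float = 1.002
    v_excitatory_reversal: float = 0.0  # mV
    v_inhibitory_reversal: float = -70.0  # mV
    tau_ampa_decay: float = 2.0  # ms, recurrent AMPA
    tau_ampa_ext_decay: float | None = None  # ms, external AMPA (None -> same)
    tau_nmda_rise: float = 2.0  # ms
    tau_nmda_decay: float = 100.0  # ms
    tau_gaba_decay: float = 10.0  # ms
    nmda_alpha: float = 0.5  # 1/ms
    mg_concentration: float = 1.0  # mM

    def __post_init__(self) -> None:
        for name in (
            "g_ampa_ext_exc",
            "g_ampa_ext_inh",
            "g_ampa_rec_exc",
            "g_ampa_rec_inh",
            "g_nmda_exc",
            "g_nmda_inh",
            "g_gaba_exc",
            "g_gaba_inh",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in (
            "tau_ampa_decay",
            "tau_nmda_rise",
            "tau_nmda_decay",
            "tau_gaba_decay",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.mg_concentration < 0:
            raise ParameterError("mg_concentration must be >= 0")
        if not self.tau_nmda_decay > self.tau_ampa_decay:
            raise ParameterError("tau_nmda_decay must exceed tau_ampa_decay")
        if self.tau_ampa_ext_decay is not None and self.tau_ampa_ext_decay <= 0:
            raise ParameterError("tau_ampa_ext_decay must be > 0")

    @property
    def tau_ext(self) -> float:
        """Decay time of the external AMPA channel (ms)."""
        return (
            self.tau_ampa_ext_decay
            if self.tau_ampa_ext_decay is not None
            else self.tau_ampa_decay
        )


DEFAULT_SYNAPSES = SynapseParams()


def beta_mode(syn: SynapseParams) -> SynapseParams:
    """Return synapse parameters retuned for beta-band oscillation.

    Slowing GABA decay to 38 ms lengthens each inhibition cycle of the
    pyramidal–interneuron loop and drops the population frequency to
    ~20 Hz; recurrent AMPA decay is shortened to 1.5 ms.  The external
    AMPA channel keeps its 2 ms decay: the retuning targets the loop
    kinetics, and shortening the background synapse would cut the
    external charge that sustains the spontaneous state.
    """
    return replace(syn, tau_gaba_decay=38.0, tau_ampa_decay=1.5, tau_ampa_ext_decay=2.0)


def apply_modification_ratio(syn: SynapseParams, r: float) -> SynapseParams:
    """Trade recurrent NMDA for AMPA conductance at fixed spontaneous drive.

    ``g_nmda -> g_nmda * (1 - r)`` and ``g_ampa_rec -> g_ampa_rec *
    (1 + 10 r)`` for both excitatory and inhibitory targets; the factor 10
    compensates the ~10:1 NMDA:AMPA charge-entry ratio near threshold so
    the spontaneous state is unchanged while fast excitation (hence gamma)
    grows with ``r``.  External AMPA and GABA are untouched.
    """
    if r < 0:
        raise ParameterError(f"modification ratio must be >= 0, got {r}")
    return replace(
        syn,
        g_nmda_exc=syn.g_nmda_exc * (1.0 - r),
        g_nmda_inh=syn.g_nmda_inh * (1.0 - r),
        g_ampa_rec_exc=syn.g_ampa_rec_exc * (1.0 + 10.0 * r),
        g_ampa_rec_inh=syn.g_ampa_rec_inh * (1.0 + 10.0 * r),
    )


def mg_block_factor(v, mg: float = 1.0):
    """Voltage-dependent magnesium unblock of the NMDA channel.

    Jahr–Stevens form ``1 / (1 + (mg / 3.57) exp(-0.062 v))`` with ``v`` in
    mV and ``mg`` in mM; monotone increasing in ``v`` and equal to 1 when
    the magnesium concentration is zero.
    """
    if mg < 0:
        raise ParameterError("mg concentration must be >= 0")
    return 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * np.asarray(v, dtype=float)))


@dataclass(frozen=True)
class ArchitectureSpec:
    """Sizes, weights and coupling of the two-circuit network.

    The network is fully connected.  Within each circuit the selective
    pool S (``n_selective`` cells) has potentiated recurrent weight
    ``w_plus``; excitatory connections from/to the non-selective pool use
    the depressed weight ``w_minus``; every connection with an inhibitory
    endpoint uses ``w_inhib``.  Across circuits only S and S' are coupled:
    forward weight ``w_feedforward``, feedback weight ``w_feedforward *
    feedback_feedforward_ratio``, both with a conduction delay.

    ``recurrent_scale`` multiplies all recurrent conductances; the reduced
    profiles set it to the population shrink factor so the mean synaptic
    drive per cell is preserved at desk scale.
    """

    n_excitatory_per_circuit: int = 800
    n_inhibitory_per_circuit: int = 200
    n_selective: int = 80
    w_plus: float = 1.8
    w_minus: float = 0.6
    w_inhib: float = 1.5
    w_feedforward: float = 1.0
    feedback_feedforward_ratio: float = 1.0 / 3.0
    conduction_delay: float = 4.0  # ms
    recurrent_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.n_selective <= self.n_excitatory_per_circuit:
            raise ParameterError("need 0 < n_selective <= n_excitatory_per_circuit")
        if self.n_inhibitory_per_circuit <= 0:
            raise ParameterError("n_inhibitory_per_circuit must be > 0")
        if not (self.w_plus > 1.0 >= self.w_minus):
            raise ParameterError("weights must satisfy w_plus > 1 >= w_minus")
        if self.feedback_feedforward_ratio < 0 or self.w_feedforward < 0:
            raise ParameterError("coupling weights must be >= 0")
        if self.conduction_delay < 0:
            raise ParameterError("conduction_delay must be >= 0")
        if self.recurrent_scale <= 0:
            raise ParameterError("recurrent_scale must be > 0")

    @property
    def w_feedback(self) -> float:
        return self.w_feedforward * self.feedback_feedforward_ratio

    @property
    def n_per_circuit(self) -> int:
        return self.n_excitatory_per_circuit + self.n_inhibitory_per_circuit

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_circuit

    @classmethod
    def full(cls, **overrides) -> "ArchitectureSpec":
        """The reference architecture: 800 E + 200 I per circuit."""
        return cls(**overrides)

    @classmethod
    def reduced(cls, **overrides) -> "ArchitectureSpec":
        """Desk-scale profile: 200 E + 50 I per circuit.

        Recurrent conductances are scaled by 4 (the shrink factor) to keep
        the mean drive per neuron; an approximation of the full network,
        not a replica.
        """
        kw = dict(
            n_excitatory_per_circuit=200,
            n_inhibitory_per_circuit=50,
            n_selective=20,
            recurrent_scale=4.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def tiny(cls, **overrides) -> "ArchitectureSpec":
        """Smallest profile that still sustains the population rhythm
        (100 E + 25 I per circuit); used for fast property checks."""
        kw = dict(
            n_excitatory_per_circuit=100,
            n_inhibitory_per_circuit=25,
            n_selective=10,
            recurrent_scale=8.0,
        )
        kw.update(overrides)
        return cls(**kw)

    def pool_slices(self) -> dict[str, slice]:
        """Global index ranges of the six pools (S1/NS1/I1/S2/NS2/I2)."""
        ne, ni, ns = (
            self.n_excitatory_per_circuit,
            self.n_inhibitory_per_circuit,
            self.n_selective,
        )
        npc = ne + ni
        out: dict[str, slice] = {}
        for c, suffix in enumerate(("1", "2")):
            base = c * npc
            out["S" + suffix] = slice(base, base + ns)
            out["NS" + suffix] = slice(base + ns, base + ne)
            out["I" + suffix] = slice(base + ne, base + npc)
        return out


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial structure and external drive.

    Each trial: ``pre_stimulus`` ms of spontaneous activity, then the
    stimulus (a Poisson spike train at ``input_rate`` onto every S1 cell),
    then ``post_stimulus`` ms.  Every neuron additionally receives
    background drive at ``background_rate_total`` (the superposition of
    800 external afferents at 3 Hz).
    """

    pre_stimulus: float = 400.0  # ms
    stimulus: float = 5500.0  # ms
    post_stimulus: float = 100.0  # ms
    input_rate: float = 250.0  # Hz onto each S1 neuron
    background_rate_total: float = 2400.0  # Hz onto every neuron
    n_trials: int = 100

    def __post_init__(self) -> None:
        if min(self.pre_stimulus, self.stimulus, self.post_stimulus) < 0:
            raise ParameterError("durations must be >= 0")
        if self.input_rate < 0 or self.background_rate_total < 0:
            raise ParameterError("rates must be >= 0")
        if self.n_trials < 0:
            raise ParameterError("n_trials must be >= 0")

    @property
    def trial_length(self) -> float:
        return self.pre_stimulus + self.stimulus + self.post_stimulus

    @property
    def stimulus_window(self) -> tuple[float, float]:
        return (self.pre_stimulus, self.pre_stimulus + self.stimulus)
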