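"""Network simulator: gating kinetics, currents, integration, sessions."""

import numpy as np
import pytest

from ctcflow.errors import ParameterError, StructuralError
from ctcflow.mua import bin_spikes, znormalize
from ctcflow.netsim import (
    GatingState,
    SpikeData,
    integrate_trial,
    run_session,
    total_synaptic_current,
    update_gating,
)
from ctcflow.params import (
    EXCITATORY,
    INHIBITORY,
    ArchitectureSpec,
    StimulusProtocol,
    SynapseParams,
)

SYN = SynapseParams()


def _quiet_protocol(length_ms=20.0):
    return StimulusProtocol(
        pre_stimulus=length_ms,
        stimulus=0.0,
        post_stimulus=0.0,
        input_rate=0.0,
        background_rate_total=0.0,
        n_trials=1,
    )


class TestGating:
    def test_ampa_exponential_decay(self):
        state = GatingState.zeros(1, 1)
        state.s_ampa[0] = 1.0
        out = update_gating(state, np.zeros(1), np.zeros(1), 0.0, 2.0, SYN)
        assert out.s_ampa[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_zero_is_fixed_point(self):
        state = GatingState.zeros(3, 2)
        out = update_gating(state, np.zeros(3), np.zeros(2), 0.0, 0.5, SYN)
        for arr in (out.s_ampa, out.x_nmda, out.s_nmda, out.s_gaba):
            assert np.all(arr == 0)
        assert out.s_ext == 0

    def test_spikes_jump_by_one(self):
        state = GatingState.zeros(2, 2)
        out = update_gating(state, np.array([1, 0]), np.array([0, 1]), 2.0, 0.02, SYN)
        assert out.s_ampa[0] == pytest.approx(1.0)
        assert out.s_gaba[1] == pytest.approx(1.0)
        assert out.s_ext == pytest.approx(2.0)

    def test_nmda_saturates_below_one(self):
        """Sustained high-rate drive pushes the NMDA fraction toward but
        never beyond 1."""
        state = GatingState.zeros(1, 1)
        spikes = np.ones(1)
        for _ in range(5000):
            state = update_gating(state, spikes, np.zeros(1), 0.0, 0.5, SYN)
        assert 0.9 < state.s_nmda[0] <= 1.0

    def test_shape_mismatch_rejected(self):
        state = GatingState.zeros(2, 2)
        with pytest.raises(StructuralError):
            update_gating(state, np.zeros(3), np.zeros(2), 0.0, 0.02, SYN)


class TestSynapticCurrent:
    def test_zero_gating_zero_current(self):
        state = GatingState.zeros(4, 2)
        i = total_synaptic_current(-60.0, state, np.ones(4), np.ones(2), SYN)
        assert i == 0.0

    def test_excitatory_terms_vanish_at_reversal(self):
        state = GatingState.zeros(2, 1)
        state.s_ampa[:] = 0.7
        state.s_nmda[:] = 0.4
        state.s_ext = 1.3
        i = total_synaptic_current(SYN.v_excitatory_reversal, state, np.ones(2), np.ones(1), SYN)
        # only GABA could remain, and it is zero here
        assert i == pytest.approx(0.0)

    def test_single_gaba_channel_hand_value(self):
        """1.287 nS x (−50 − (−70)) mV = 25.74 pA = 0.02574 nA."""
        state = GatingState.zeros(1, 1)
        state.s_gaba[0] = 1.0
        i = total_synaptic_current(-50.0, state, np.zeros(1), np.ones(1), SYN, "excitatory")
        assert i == pytest.approx(0.02574, abs=1e-9)

    def test_weight_dimension_checked(self):
        state = GatingState.zeros(2, 2)
        with pytest.raises(StructuralError):
            total_synaptic_current(-60.0, state, np.ones(3), np.ones(2), SYN)


class TestIntegration:
    def test_leak_only_matches_analytic_exponential(self):
        """With all drives silent the RK4 trajectory follows
        V(t) = V_L + (V0 - V_L) exp(-t/tau) to better than 1e-6 mV."""
        arch = ArchitectureSpec.tiny()
        _, v = integrate_trial(arch, SYN, _quiet_protocol(20.0), seed=1, record_v=True)
        t = np.arange(len(v)) * 0.02
        v0, v_leak = EXCITATORY.reset_potential, EXCITATORY.resting_potential
        analytic = v_leak + (v0 - v_leak) * np.exp(-t / EXCITATORY.membrane_tau)
        assert np.max(np.abs(v - analytic)) < 1e-6
        assert v[-1] == pytest.approx(-64.4818, abs=1e-3)

    def test_no_input_no_spikes(self):
        arch = ArchitectureSpec.tiny()
        sd, _ = integrate_trial(arch, SYN, _quiet_protocol(100.0), seed=2)
        assert len(sd.events) == 0

    def test_spike_times_within_trial(self):
        arch = ArchitectureSpec.tiny()
        proto = StimulusProtocol(pre_stimulus=100.0, stimulus=300.0, post_stimulus=50.0, n_trials=1)
        sd, _ = integrate_trial(arch, SYN, proto, r=0.07, seed=3)
        assert len(sd.events) > 0
        t = sd.events["time_ms"].to_numpy()
        assert t.min() >= 0.0 and t.max() <= proto.trial_length

    def test_refractory_guarantee(self):
        """Inter-spike intervals respect each class's refractory period."""
        arch = ArchitectureSpec.tiny()
        proto = StimulusProtocol(pre_stimulus=100.0, stimulus=500.0, post_stimulus=0.0, n_trials=1)
        sd, _ = integrate_trial(arch, SYN, proto, r=0.12, seed=4)
        ev = sd.events
        for pool, refrac in (("S1", 2.0), ("I1", 1.0), ("S2", 2.0), ("I2", 1.0)):
            sub = ev[ev["pool"] == pool]
            for _, grp in sub.groupby("neuron_id"):
                isi = np.diff(np.sort(grp["time_ms"].to_numpy()))
                if isi.size:
                    assert isi.min() >= refrac - 1e-9

    def test_delay_bookkeeping_conserved(self):
        """Every scheduled cross-circuit spike is delivered exactly once
        (up to those still in flight at trial end)."""
        arch = ArchitectureSpec.tiny()
        proto = StimulusProtocol(pre_stimulus=100.0, stimulus=400.0, post_stimulus=0.0, n_trials=1)
        sd, _ = integrate_trial(arch, SYN, proto, r=0.07, seed=5)
        sched = sd.metadata["delay_scheduled"]
        deliv = sd.metadata["delay_delivered_plus_inflight"]
        n_sel_spikes = len(sd.events[sd.events["pool"].isin(["S1", "S2"])])
        assert sched == n_sel_spikes
        in_flight_window = arch.conduction_delay + 0.1
        late = sd.events[
            sd.events["pool"].isin(["S1", "S2"])
            & (sd.events["time_ms"] > proto.trial_length - in_flight_window)
        ]
        assert 0 <= sched - deliv <= len(late) + 1

    def test_spontaneous_rates_low_without_stimulus(self):
        """Zero stimulus leaves the selective pools in the spontaneous
        regime (< 10 Hz)."""
        arch = ArchitectureSpec.reduced()
        proto = StimulusProtocol(
            pre_stimulus=400.0, stimulus=600.0, post_stimulus=0.0, input_rate=0.0, n_trials=1
        )
        sd, _ = integrate_trial(arch, SYN, proto, seed=6)
        assert sd.firing_rate("S1") < 10.0
        assert sd.firing_rate("S2") < 10.0


class TestSession:
    def test_trial_count_and_indices(self):
        arch = ArchitectureSpec.tiny()
        proto = StimulusProtocol(pre_stimulus=50.0, stimulus=150.0, post_stimulus=0.0, n_trials=3)
        sd = run_session(arch, SYN, proto, r=0.07, master_seed=1)
        assert sd.n_trials == 3
        assert set(sd.events["trial"].unique()) <= {0, 1, 2}
        assert len(sd.metadata["trial_seeds"]) == 3

    def test_bitwise_reproducibility(self):
        arch = ArchitectureSpec.tiny()
        proto = StimulusProtocol(pre_stimulus=50.0, stimulus=200.0, post_stimulus=0.0, n_trials=2)
        a = run_session(arch, SYN, proto, r=0.07, master_seed=42)
        b = run_session(arch, SYN, proto, r=0.07, master_seed=42)
        assert a.events.equals(b.events)

    def test_different_seeds_differ(self):
        arch = ArchitectureSpec.tiny()
        proto = StimulusProtocol(pre_stimulus=50.0, stimulus=200.0, post_stimulus=0.0, n_trials=1)
        a = run_session(arch, SYN, proto, r=0.07, master_seed=1)
        b = run_session(arch, SYN, proto, r=0.07, master_seed=2)
        assert not a.events.equals(b.events)


class TestOscillationRegimes:
    """Gamma appears with the default kinetics at high r; slowing GABA
    decay moves the rhythm into the beta range (majority over seeds)."""

    @staticmethod
    def _dominant_peak(sd: SpikeData, pool: str, t0: float, t1: float):
        from ctcflow.spectral import multitaper_power

        ev = sd.pool_events(pool)
        times = ev["time_ms"].to_numpy()
        times = times[(times >= t0) & (times < t1)]
        if len(times) < 30:
            return None
        counts = bin_spikes(times - t0, t1 - t0)
        if counts.std() == 0:
            return None
        z = znormalize(counts)
        n = (len(z) // 1000) * 1000
        if n == 0:
            return None
        acc = None
        for w in range(n // 1000):
            est = multitaper_power(z[w * 1000 : (w + 1) * 1000])
            acc = est.power if acc is None else acc + est.power
        f = est.frequencies
        m = f >= 5.0
        return float(f[m][np.argmax(acc[m])])

    def test_gamma_mode_peak_in_gamma_band(self, gamma_oscillation_sessions):
        votes = 0
        for sd in gamma_oscillation_sessions:
            peak = self._dominant_peak(sd, "S1", 400.0, sd.trial_length)
            if peak is not None and 30.0 <= peak <= 85.0:
                votes += 1
        assert votes > len(gamma_oscillation_sessions) / 2

    def test_beta_mode_peak_below_30(self, beta_oscillation_sessions):
        votes = 0
        for sd in beta_oscillation_sessions:
            peak = self._dominant_peak(sd, "S1", 400.0, sd.trial_length)
            if peak is not None and peak < 30.0:
                votes += 1
        assert votes > len(beta_oscillation_sessions) / 2
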