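# Methods

## The model

`ctcflow` simulates two reciprocally coupled cortical circuits and asks how
much directed information flows between them as a function of their
oscillatory phase relation — the communication-through-coherence (CTC)
question.  Each circuit is a fully connected network of conductance-based
leaky integrate-and-fire neurons (800 excitatory, 200 inhibitory at full
scale) in the Brunel–Wang tradition:

    C_m dV/dt = -g_m (V - V_L) - I_syn,

with threshold/reset/refractory spiking and synaptic currents through four
receptor channels: external AMPA (Poisson background of 2.4 kHz per neuron,
the superposition of 800 afferents at 3 Hz), recurrent AMPA, NMDA with the
Jahr–Stevens magnesium block 1/(1 + [Mg]/3.57 · exp(−0.062 V)), and GABA-A.
AMPA/GABA gating decays exponentially (2 ms / 10 ms) and jumps by +1 per
presynaptic spike; NMDA uses the two-variable rise (2 ms) / saturating decay
(100 ms, α = 0.5 /ms) kinetics that keeps its open fraction in [0, 1].

Within each circuit a selective pool S (potentiated recurrent weight
w⁺ = 1.8) receives the stimulus; excitatory connections from/to the
non-selective rest are depressed (w⁻ = 0.6); pyramidal→interneuron
connections carry w_I = 1.5, and inhibitory-source weights are 1.  We tested
the alternative reading in which w_I also scales I→E/I→I connections, and
the reading in which w⁻ depresses only inputs to S: both destabilize the
stimulated state (the first silences the network, the second makes stimulus
ignition a coin flip per trial), so the weight matrix above is the one the
package uses.

The two selective pools are connected bidirectionally with a conduction
delay of 4 ms.  The feedback weight is the feedforward weight times the
feedback/feedforward ratio (default 1/3).  A trial is 400 ms of spontaneous
activity, 5500 ms of stimulus (an extra 250 Hz Poisson train into every S1
cell), and 100 ms post-stimulus; a session is 100 such trials.  Desk-scale
work shortens the stimulus epoch and the trial count; the protocol object
makes all of this explicit.

### Oscillation control

Gamma rhythms arise from the pyramidal–interneuron loop.  The *modification
ratio* r trades slow for fast excitation at a fixed spontaneous state:
recurrent NMDA is scaled by (1 − r) and recurrent AMPA by (1 + 10r) — the
factor 10 matches the ~10:1 NMDA:AMPA charge-entry ratio near threshold.
Raising r from 0 to 0.12 moves the network from weakly rhythmic to strongly
gamma-oscillatory.  Beta rhythms come from the same network with the GABA
decay slowed to 38 ms and the *recurrent* AMPA decay shortened to 1.5 ms.
We keep the external AMPA channel at 2 ms in beta mode: the retune targets
the loop kinetics, and shortening the background synapse would cut the
external charge that sustains the spontaneous state (the network falls
silent if it is applied there).  Beta-mode sessions also run with a larger
selective pool (fraction 1/4 instead of 1/10 of the excitatory population)
because the slow-inhibition regime cannot ignite from the 250 Hz stimulus
with the small pool; this operating point is the package's choice, not a
literature value.

### The feedforward weight

The absolute inter-circuit weight w_ff is a free parameter of this model
family.  It sets both the strength of transmission and the equilibrium
phase lag between the pools: too weak and the second pool never ignites,
too strong and the pair locks rigidly.  The default w_ff = 1.4 was chosen
once so that the realized mean phase lag at the gamma peak frequency
(~110°) sits close to the delay-consistent phase 360·f·(4 ms), which is the
regime the CTC analyses presuppose (a 4 ms delay at 60 Hz is ~86°).

### Numerics

Membrane equations advance with classical RK4 at dt = 0.02 ms.  Pool-block
connectivity lets recurrent drive be computed from per-pool sums of gating
variables, making a step O(N).  Linear gating propagates by its exact
exponential; the NMDA pair advances by two half RK4 steps; spike deltas are
applied at step boundaries, and threshold crossings are resolved at step
resolution (the induced jitter is far below a refractory period).  In the
leak-only limit the trajectory matches the analytic exponential to <1e-6 mV.
Cross-circuit spikes travel through a ring buffer and are delivered exactly
one conduction delay after emission; the scheduled and delivered counts are
carried in the session metadata so the bookkeeping is testable.  Poisson
drives are generated by exponential inter-arrival sampling from the
per-trial seed; sessions are bit-reproducible given the master seed.

Reduced profiles (200E+50I and 100E+25I per circuit) scale all recurrent
conductances by the population shrink factor to preserve mean drive.  They
are approximations for desk-scale work: the rescaling makes individual
synapses stronger, so the scaled networks are *more* coherent than the full
network, with consequences discussed below.

## The analysis chain

* **MUA** — 10 neurons are sampled per selective pool (the same ids across
  a session's trials), their spikes counted in 5 ms windows stepped by 1 ms,
  and each trial's series z-scored (population SD) over the whole trial.
  Normalization removes rate scaling so the measures respond to temporal
  structure.  Binning is half-open [t, t+5) anchored at 0.
* **Spectra and phase** — multitaper estimation with 5 Slepian tapers
  (time-bandwidth 3): 1000 ms windows for power fractions and spectral
  peaks, 500 ms windows for the per-window phase/power analysis.  The phase
  relation is the angle of the taper-averaged cross spectrum at the bin
  nearest the target frequency (positive = pool 2 lags pool 1); per-window
  phases are wrapped relative to their circular mean and sorted into six
  60° bins, bin 0 centered on the mean.  Phase-resolved analyses sort at
  the nominal band frequency (60 Hz gamma / 20 Hz beta) by default; the
  measured in-band peak can be used instead via a flag.
* **Correlation** — the Spearman rank correlation (average ranks on ties)
  of the two pools' per-window band power is computed within each phase
  bin, pooling windows across trials, and a cosine
  offset + A·cos(φ − φ₀) is least-squares fitted to the curve.  The
  median-power split recomputes the curve for trials below/above the
  median band power (ties to the lower set).
* **Transfer entropy** — the z-scored MUA is coarse-grained into 4 equal
  amplitude bins on [−3, 3] (outliers clipped) and the plug-in TE is
  computed from joint histograms with source/target embeddings k = l = 1.
  The prediction horizon (lag) follows the conduction delay — 4 MUA steps
  by default: with a 1-step horizon the estimator cannot see across the
  4 ms axonal delay and direction detection fails, while at lag = delay the
  forward estimate on gamma sessions is both directionally correct and of
  the expected magnitude.  Embedding vectors never bridge window
  boundaries; phase-binned estimates pool symbol tuples across a bin's
  windows.  No bias correction is applied by default; a shuffle-based
  correction (re-pairing source windows with permuted target windows) is
  available and is used wherever bins of very different occupancy are
  compared, since the plug-in bias scales inversely with the sample count
  and would otherwise inflate sparse bins.
* **Timecourse** — TE as a function of latency after stimulus onset, from
  20 ms windows stepped by 1 ms pooled across trials; the rise time is the
  first latency at which the curve reaches 50% of its stimulus-period
  average, undefined if the level is never crossed.  The timecourse is
  shuffle-corrected by default: a latency window holds only a few hundred
  samples, and the uncorrected plug-in bias alone can cross the half-average
  level for weak-coupling conditions.

## The surrogate generators

The surrogate module generates data with exactly the statistical structure
the analyses assume, so every stage is testable without the simulator:

* **Markov pairs** — x i.i.d. uniform bits, y_{t+1} = x_t flipped with
  probability p: forward TE is 1 − H₂(p) bits in closed form, backward 0.
  This is the analytic oracle for the estimator.
* **Oscillatory pools** — two Poisson count series (1 ms resolution) with
  sinusoidal rate modulation, a controllable inter-pool lag plus per-window
  Gaussian phase jitter, and optional one-way delayed coupling that can be
  gated on the instantaneous phase offset.  Defaults: 60 Hz, modulation
  depth 0.6, 200 Hz base rate (ten sampled neurons at ~20 Hz), 4 ms
  coupling delay — chosen to mirror the simulator's stimulus-period MUA.
  The realized per-window offsets and gate states ride along as ground
  truth.
* **Independent noise** — Gaussian series for null calibration of TE,
  rank correlation and cosine amplitude.

Surrogates emulate the statistics the analysis consumes, not conductance
dynamics; passing surrogate-based tests validates the analysis chain, not
the network model.

## What the desk-scale network does and does not reproduce

On the reduced profiles the package reproduces, robustly across seeds: the
gamma spectral peak inside 30–85 Hz with its power fraction growing with r,
the beta peak below 30 Hz under the slow-GABA retune, the delay-controlled
phase lag, forward-dominant transfer entropy at feedback/feedforward = 1/3,
and the shrinking of that asymmetry as the ratio approaches 1.

Two results reproduce only partially.  The first is the phase-binned TE
curve.  The
desk-scale curve does fall to near zero for offsets of ±120–180°, but its
maximum sits in the bins adjacent to the mean (±60°) rather than in the
mean-phase bin itself, where a shallow dip appears.  The mechanism is a
small-scale artifact: conductance rescaling makes the reduced rhythm nearly
clock-like, and in perfectly locked windows the target's own past already
predicts its future, so conditioning discounts the source's contribution —
transfer entropy is maximal at moderate, not zero, desynchronization.  In
the full-size network the rhythm carries enough cycle-by-cycle noise that
mean-phase windows are not self-predictable and the maximum falls at the
mean.  We verified that the dip is not an occupancy-bias artifact (it
survives shuffle correction) and not an estimator-setting artifact (it
persists across lags 2–6, resolutions 2–6 and embeddings up to k = l = 2).

The second is the ordering of TE rise times across oscillation strengths.
At desk scale the post-onset TE rise is dominated by the attractor-ignition
latency of the receiving pool (~100–240 ms) whose seed-to-seed variance
(±50 ms) is far larger than the ~10 ms speed-up that stronger gamma confers
at full scale, so the ordering of rise times between r = 0.02 and r = 0.12
is not resolved by the reduced profiles at any trial count we tested.  The
rise-time machinery itself is exercised and validated on synthetic
timecourses with known switch points.

## Parameter summary

| Parameter | Default | Units | Note |
|---|---|---|---|
| C_m (E/I) | 0.5 / 0.2 | nF | membrane capacitance |
| g_m (E/I) | 25 / 20 | nS | leak conductance |
| V_L, V_thr, V_reset | −70, −50, −55 | mV | |
| refractory (E/I) | 2 / 1 | ms | |
| g_AMPA,ext (E/I targets) | 2.08 / 1.62 | nS | |
| g_AMPA,rec (E/I) | 0.104 / 0.081 | nS | scaled by (1+10r) |
| g_NMDA (E/I) | 0.327 / 0.258 | nS | scaled by (1−r) |
| g_GABA (E/I) | 1.287 / 1.002 | nS | |
| τ_AMPA, τ_NMDA,rise, τ_NMDA,decay, τ_GABA | 2, 2, 100, 10 | ms | beta: τ_GABA 38, τ_AMPA,rec 1.5 |
| w⁺, w⁻, w_I | 1.8, 0.6, 1.5 | – | |
| w_ff (free), fb/ff ratio | 1.4, 1/3 | – | w_ff chosen for phase alignment |
| conduction delay | 4 | ms | also the TE prediction horizon |
| stimulus, background | 250, 2400 | Hz | Poisson |
| selective fraction | 1/10 (gamma), 1/4 (beta) | – | see above |
| MUA bin/step, sample | 5 / 1 ms, 10 cells | | |
| spectral windows | 1000 / 500 | ms | power / phase-resolved |
| TE | k=l=1, 4 bins on [−3,3], lag 4 | | log base 2 |
| phase bins | 6 × 60° | | bin 0 at the circular mean |

## Problem sizes used in tests and the acceptance script

Deterministic checks run at full precision in seconds.  The stochastic
network properties run on the reduced (200E+50I) and tiny (100E+25I)
profiles with 1–24 trials of 2–3 s and five seeds per property — the sizes
are the package's desk-scale study conditions, chosen so a complete
verification runs on one core in well under half an hour.  Absolute TE
values depend on estimator settings (resolution, embeddings, horizon), so
quantities reported by the acceptance script carry those settings; the
full-scale session (100 × 6 s trials, 1000 neurons per circuit) is
available through `scale="full"` for anyone wanting the reference numbers
at their original size.

## Known limitations

* The reduced profiles' conductance rescaling raises coherence; see above.
* No sub-step threshold interpolation (dt = 0.02 ms makes the jitter
  negligible against 1–2 ms refractory periods).
* The naive-histogram TE estimator is biased upward at small sample counts;
  the shuffle correction removes the occupancy-dependent part but inflates
  variance slightly.
* Only the histogram estimator is provided (no kernel or nearest-neighbor
  TE), and no conditional/multivariate TE.
* The beta regime requires the larger selective pool and r = 0.07; beta at
  r = 0 does not oscillate coherently in this implementation.
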