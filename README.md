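# ctcflow

Communication through coherence in a two-circuit spiking network:
simulation and directed information-flow analysis.

## The problem

When two groups of cortical neurons oscillate — in the gamma band
(30–85 Hz) or the beta band (~20 Hz) — does the *phase relation* between
their rhythms control how much information one group transmits to the
other?  This is the communication-through-coherence (CTC) hypothesis:
inputs arriving at a favorable phase of the receiver's excitability cycle
are transmitted effectively, inputs at an unfavorable phase are not, so
synchronization can functionally connect and disconnect areas without
changing anatomy.

`ctcflow` is for computational neuroscientists who want to study this
question in a controlled, fully reproducible setting.  It provides:

* a two-circuit network of conductance-based leaky integrate-and-fire
  neurons (AMPA/NMDA/GABA synapses, Poisson background, stimulus drive,
  4 ms inter-circuit conduction delay) whose rhythm band and strength are
  controlled by two documented parameters;
* the analysis chain used on such data: multi-unit activity (MUA)
  extraction, multitaper power and cross-spectral phase, phase-binned
  Spearman correlation of band power with a cosine fit, and directional
  **transfer entropy** (TE) — a model-free measure that, unlike
  correlation, distinguishes driving from responding populations:

      TE(X→Y) = Σ p(y_{t+ℓ}, y_t, x_t) · log₂ [ p(y_{t+ℓ}|y_t, x_t) / p(y_{t+ℓ}|y_t) ]

  estimated by coarse-grained histograms on the z-scored MUA;
* surrogate generators with known ground truth (closed-form-TE Markov
  pairs, phase-lagged oscillatory Poisson pools with optional phase-gated
  one-way coupling) so every analysis stage is testable without the
  simulator.

## Worked example

```python
from ctcflow import ExperimentConfig, run_phase_experiment

cfg = ExperimentConfig(mode="gamma", r=0.07, scale="tiny",
                       n_trials=16, stimulus_ms=2100.0, seed=1)
res = run_phase_experiment(cfg, te_bias_correction=True)

print(f"mean phase lag : {res.mean_phase_deg:.0f} deg at {res.sort_frequency_hz:.0f} Hz")
print(f"TE forward     : {res.te_overall.te_forward:.3f} bits")
print(f"TE backward    : {res.te_overall.te_backward:.3f} bits")
print(res.to_table().round(3))
```

Output (seed 1):

```
mean phase lag : 152 deg at 77 Hz
TE forward     : 0.204 bits
TE backward    : 0.046 bits
   bin_center_deg    rho  n_windows  te_forward_bits  te_backward_bits
0            -0.0  0.639         52            0.172             0.019
1            60.0  0.829          6            0.093             0.057
2           120.0  1.000          2            0.003            -0.000
3           180.0    NaN          0              NaN               NaN
4          -120.0    NaN          1            0.011             0.001
5           -60.0  0.500          3            0.150             0.022
```

Reading it: the second pool lags the first by ~152° at the session's
77 Hz gamma peak — the 4 ms conduction delay plus the synaptic lag of the
receiving loop.  Forward TE (pool 1 → 2) is more than four times backward
TE: the estimator correctly identifies the stimulated pool as the driver.
The phase-binned columns show TE and rank correlation highest for windows
near the mean phase relation and collapsing toward zero for strongly
offset windows, while `n_windows` shows how the phase distribution
concentrates around its mean, as in recordings (bins holding only a
window or two — rho of exactly 1.0, NaN — are too sparse to interpret).

Switching `mode="beta"` retunes the synaptic kinetics (GABA decay 38 ms,
recurrent AMPA 1.5 ms) so the same network oscillates near 25 Hz, and the
same analyses apply with beta-band sorting.  `run_power_sweep` and
`run_timing_experiment` reproduce the oscillation-strength analyses: TE
at the mean phase grows with the NMDA/AMPA modification ratio r, and the
post-stimulus TE rise is faster when gamma power is high.

A command-line interface wraps the same functions:

```bash
ctcflow simulate --mode gamma --scale tiny --n-trials 4 --seed 1 --out results/
ctcflow analyze  --mode gamma --scale tiny --n-trials 8 --seed 1 --out results/
ctcflow report   --results results/
```

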