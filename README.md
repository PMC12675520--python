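# macroir

Bayesian inference for macroscopic ion-channel currents that treats every
data point as what it physically is: a **time average over a finite
window**. The package targets kinetic modelling of ligand-gated channels
recorded in macropatches — many channels summing into one noisy current —
where classical instantaneous-emission filters break down as soon as the
averaging windows exceed the gating timescales.

It provides, end to end:

* **Kinetic schemes** — a first-principles homotrimeric receptor model in
  which each subunit binds agonist and rotates, with asymmetric allosteric
  coupling between each binding pocket and its two framing subunits
  (64 micro-states, lumped exactly onto 24 cyclic-symmetry classes), plus
  declarative TOML-configured schemes of any topology.
* **The interval-averaged recursive likelihood** — per measurement window
  the engine propagates the joint Gaussian moments of the channel-state
  counts *x* and the running integral A = ∫ g·x dt, scores the observed
  window average, and conditions the boundary state on it. A non-recursive
  midpoint control is included for comparison.
* **Inference** — affine-invariant parallel-tempering ensemble MCMC over a
  β-ladder including the prior rung, thermodynamic-integration
  log-evidence with an honest standard error, split-R̂ / ESS / posterior
  concentration factor diagnostics, and label-switching relabeling for the
  coupling-factor degeneracy of the symmetric trimer.
* **A stochastic macropatch simulator** — exact event-driven channels,
  deterministic inactivation envelope, white and 1/f noise — generating
  protocol-shaped synthetic datasets with known ground truth.
* **Posterior analyses** — occupancy trajectories, conductance fractions
  by rotational class, gating/white/pink variance partitioning, posterior
  predictive traces, and allosteric-regime classification (catalytic /
  regular / inhibitory) with barrier shifts ΔΔG‡ = −ln(factor) in kT.

## The model in brief

A kinetic scheme is a continuous-time Markov chain with generator Q(c)
(rows sum to zero; binding edges proportional to agonist concentration c).
The recorded current is

    y(t) = i0 + e^(−k_inact·t) · Σ_channels g(state) + ε(t) + ν(t)

with unitary conductances g(n rotated) = γ·Rγ^(3−n) (and γ·ρ_leak for the
fully resting state), white noise of power ε² (window variance ε²/Δ) and a
pink-noise floor ν². The likelihood of a window average is Gaussian with
mean i0 + E[A/Δ] and variance Var[A/Δ] + ε²/Δ + ν²; the recursion carries
the boundary-conditioned state moments from window to window. Evidence is
log Z = ∫₀¹ E_β[log L] dβ over the tempered ladder. See
`docs/methods.md` for the full treatment.

## Worked example

Simulate a 50-channel patch with a two-state scheme, segment the trace,
and fit it back:

```python
import numpy as np
from macroir import (Epoch, IntervalCurrentModel, ObservationParams,
                     PriorParam, PriorSpec, Protocol, scheme_from_config,
                     segment_trace, simulate_ensemble_trace)
from macroir.segmentation import SegmentationPlan

scheme = scheme_from_config("""
[scheme]
states = ["C", "O"]
classes = [0, 3]
[scheme.params]
k_on = 0.05    # uM^-1 s^-1
k_off = 200.0  # s^-1
[[scheme.edge]]
from = "C"
to = "O"
rate = "k_on"
conc = true
[[scheme.edge]]
from = "O"
to = "C"
rate = "k_off"
""")

protocol = Protocol(
    epochs=(Epoch(0.0, 0.02, 0.0),          # 20 ms baseline
            Epoch(0.02, 0.002, 1000.0),     # 2 ms pulse at 1 mM
            Epoch(0.022, 0.05, 0.0)),       # 50 ms decay
    sampling_rate=10_000.0,
)
truth = ObservationParams(gamma=1.0, i0=0.0, N_ch=50, eps2=5e-5, nu2=0.0)
t, y = simulate_ensemble_trace(scheme, truth, protocol, seed=21)
trace = segment_trace(t, y, protocol, SegmentationPlan(
    coarse_width=5e-3, n_fine=2, fine_width=5e-4, pre_onset=5e-4, per_decade=4))
print(f"{len(trace)} intervals from {len(t)} raw samples")

prior = PriorSpec([
    PriorParam("k_on", loc=0.05, scale=0.5, transform="log"),
    PriorParam("k_off", loc=200.0, scale=0.5, transform="log"),
])
model = IntervalCurrentModel(trace, scheme, prior, truth, method="macroir")
res = model.fit(n_rungs=5, n_walkers=8, n_steps=250, n_burn=100, seed=4)
print(res.summary().round(3).to_string())
ev = res.log_evidence
print(f"log evidence = {ev.log_evidence:.2f} +- {ev.std_error:.2f}")
```

Output:

```
42 intervals from 720 raw samples
            median     mean      sd      q05      q95   rhat      ess    pcf
parameter
k_on         0.059    0.062   0.020    0.036    0.101  1.046  179.029  1.590
k_off      249.648  257.670  69.645  156.342  379.868  1.028  345.151  1.853
log evidence = -41.45 +- 0.06
```

The 90% equal-tailed intervals cover the generating values (k_on = 0.05
µM⁻¹s⁻¹, k_off = 200 s⁻¹); `pcf` > 1 says the 42 windows genuinely
constrained both rates beyond the prior, and the log-evidence (with its
standard error) is what model comparison runs on — fit two schemes to the
same trace and difference the evidences.

The same machinery drives the command line:
`macroir simulate | segment | loglik | fit | evidence | ppc | report`
(see `macroir --help`).

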