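# Methods

This note documents the models, algorithms, and numerical choices in
`macroir`, and what the synthetic-data studies do and do not establish.

## Kinetic model of the trimeric receptor

Each of the three subunits of a homotrimeric ligand-gated receptor carries
two binary coordinates: occupancy of the agonist pocket it heads, and a
rotated/unrotated conformation. A micro-state is the 6-bit word of these
flags, giving 64 states; because the three subunits are arranged on a ring,
states related by a cyclic shift are physically identical and the chain
lumps exactly (strong lumpability) onto the 24 cyclic-equivalence classes.
`enumerate_trimer_states` counts the classes by direct canonicalization
(cross-checked by Burnside's lemma: (4³ + 2·4)/3 = 24), and
`lump_by_symmetry` performs the aggregation after verifying invariance of
the generator under the cyclic permutation.

Geometry convention: pocket *i* sits between subunit *i* (its **A-side**)
and subunit *i+1 mod 3* (its **B-side**). Allosteric coupling factors are
dimensionless multipliers named for the direction of influence:

| factor | acts on | meaning |
|---|---|---|
| `RB`, `BR` | equilibrium | pocket↔A-side / pocket↔B-side equilibrium shift |
| `RB_bon`, `BR_bon` | binding on-rate | binding acceleration when the framing subunit is rotated |
| `RB_ron`, `BR_ron` | rotation on-rate | rotation acceleration when the flanking pocket is bound |

Binding at pocket *i* proceeds at `b_on·c` multiplied by `RB_bon` if
subunit *i* is rotated and `BR_bon` if subunit *i+1* is; rotation of
subunit *j* proceeds at `r_on` multiplied by `RB_ron` if pocket *j* is
bound and `BR_ron` if pocket *j−1* is. Contributions from the two flanking
sites multiply, because independent free-energy contributions add. Off-rate
factors are *derived* as on-factor/equilibrium-factor (e.g.
`RB_boff = RB_bon/RB`), which forces every cycle of the state graph to
satisfy microscopic reversibility identically — the test suite verifies the
Kolmogorov criterion on a full cycle basis. Setting the `BR` family equal
to the `RB` family yields the symmetric variant of the scheme.

Units are fixed throughout: concentration in µM, time in s, current in pA;
`b_on` is in µM⁻¹s⁻¹.

**Conductance ladder.** A state with *n* rotated subunits passes unitary
current `g(3) = γ`, `g(2) = γ·Rγ`, `g(1) = γ·Rγ²`, and `g(0) = γ·ρ_leak`.
The geometric interpolation in a single factor `Rγ` is a modelling choice:
it is the most parsimonious one-parameter link between the fully rotated
conductance and the partially rotated states, with a separate leak ratio
for the fully resting channel. Other monotone mappings are conceivable; the
mapping is isolated in `conductance_vector` and easy to replace.

Arbitrary schemes (chains, branched topologies, …) are declared as TOML
text: states, per-state conductance classes, named parameters, and edges
with rate expressions and an optional `conc = true` tag marking
concentration-proportional (binding) edges.

## Observation model

The recorded current is
`y(t) = i0 + e^(−k_inact·t) · Σ_channels g(state) + white + pink`.

* **Inactivation** is a deterministic exponential envelope with rate
  `k_inact`, not an absorbing Markov state: it enters the observation layer
  as a scalar scaling of the conducting population, which is the simplest
  mechanism consistent with a single rate parameter.
* **White noise** has power `ε²` (pA²·s): a window of width Δ averages it
  to variance `ε²/Δ`, and a raw sample at rate f_s carries variance
  `ε²·f_s`.
* **Pink (1/f) noise** has power `ν²` (pA²) and contributes a
  width-independent variance floor `ν²` per window. This parameterization
  makes a two-tier baseline design (many long windows plus a few very
  short ones) identify `ε²` and `ν²` exactly: short windows are dominated
  by `ε²/Δ`, long windows by `ν²`.

## Trace segmentation

Raw traces are reduced to contiguous intervals at four resolutions
(defaults in parentheses): coarse baseline windows (13.7 ms) and a small
set of fine baseline windows (10 × 0.02 ms) placed immediately before the
retained raw region — they estimate fast noise adjacent to the pulse; raw
unit-sample intervals through each pulse and a short pre-onset margin
(0.24 ms); and log-spaced decay bins (10 per time decade) after the pulse.
The baseline remainder that does not fill a whole coarse window is trimmed
from the start of the trace, keeping window widths homogeneous per tier;
the retained intervals form an exact partition of the covered span and
averaging is mean-preserving (both are tested). Steady-state points are
read from long monitor pulses as the mean over the final half of the
pulse.

## The interval-averaged recursive likelihood

Every measured point is a time average over a finite window, which
correlates successive samples and invalidates instantaneous-emission
filters when windows are long. The engine therefore propagates, per
interval, the *joint* Gaussian moments of the end-of-interval channel-state
counts `x` and the running integral `A = ∫ g·x dt`:

1. Split the interval of width Δ into `n_sub` substeps with
   `max|Q_ii|·(Δ/n_sub) ≤ q*` (default `q* = 0.05`, minimum 2 substeps) and
   compute the exact one-substep transition matrix `P = exp(Qδ)`.
2. Per substep, accumulate `A += δ·g·x` at the left endpoint, then advance
   the chain: the mean, covariance, and the cross-covariance of `(x, A)`
   update exactly for the discretized chain (the jump noise of counts is
   `diag(P^T μ) − P^T diag(μ) P`).
3. Score the observation `y ~ N(i0 + A/Δ, Var(A/Δ) + ε²/Δ + ν²)` and
   condition the end-state moments on `y` by joint-Gaussian conditioning
   through the cross term.
4. Project: negative means are clipped and rescaled to the conserved
   (inactivation-scaled) channel total; the covariance is symmetrized with
   negative eigenvalues floored at zero.

The propagated moments are exact for the discretized chain — the test
suite verifies machine-precision agreement with exhaustive path
enumeration — and converge to the continuous-time moments as `n_sub`
grows; the left-endpoint accumulation leaves an O(δ) bias in the
state/average cross-covariance, which is why accuracy-critical tests pin a
finer `q*`. The Gaussian moment closure is the second approximation; it is
excellent whenever instrument noise is comparable to or larger than the
per-interval gating spread, and the suite quantifies it against an exact
count-based hidden-Markov filter (agreement within 0.05 log-units over a
20-interval trace for a single channel).

The initial state of a trace is stationary at the first interval's
concentration with multinomial covariance `N_ch(diag π − ππᵀ)`: recordings
are assumed to start long after the previous stimulation.

The filter conditions on the end state of each window (a one-sided,
filtering recursion); a two-sided smoothing construction that also
conditions the start state on the current observation is not implemented.

**The non-recursive control** (`macroinr_loglik`) evolves mean occupancies
deterministically, scores each interval with an instantaneous Gaussian at
the interval midpoint (multinomial gating variance plus instrument noise),
and never conditions on the data. It coincides with the recursive
likelihood only when the chain is frozen and state-uncertainty-free, and
deviates by many log-units when windows span relaxation times.

**Batching.** All heavy routines accept length-K parameter arrays and
evaluate K likelihoods in one vectorised pass (the per-substep updates act
on (K,S,S) stacks). Within a batch the substep count of an interval is the
worst case over members, so a batch member can differ from a standalone
evaluation at discretization level only. Per-substep propagators are
computed by batched eigendecomposition with a `scipy.linalg.expm` fallback.

## Inference

**Priors** are independent truncated normals on a per-parameter sampling
scale: log for rates, coupling factors, conductances and noise powers;
identity for baseline current. Defaults are weakly informative (log-scale
sd 0.2–0.5 around order-of-magnitude guesses); they are stand-ins, not a
calibrated elicitation. `N_ch` may be sampled as a continuous parameter
≥ 1.

**Sampler.** Affine-invariant stretch moves (scale a = 2, complementary
half-ensemble partners, acceptance `min(1, z^(d−1) e^Δ)`) run on every rung
of an inverse-temperature ladder — β = 0 plus a geometric grid from 0.01
to 1 (default 8 rungs; 16 for evidence work) — with adjacent-rung walker
swaps every sweep, alternating pair parity. The β = 0 rung samples the
prior exactly, which anchors the thermodynamic integral. Runs are
deterministic given the seed; an HDF5 checkpoint stores walker state, RNG
state and kept history so that interrupting and resuming reproduces the
uninterrupted run bit-exactly.

**Evidence.** `log Z = ∫₀¹ E_β[log L] dβ` by trapezoid quadrature over the
ladder. The standard error is the variance of the per-sweep
quadrature-weighted series `Σ_r w_r · mean_walkers(log L)` inflated by its
integrated autocorrelation time (Geyer initial-positive-sequence
truncation). Rung means are *not* independent — swaps carry walkers across
rungs — so per-rung error propagation underestimates the spread; the
per-sweep combined series captures both the cross-rung covariance and the
serial correlation. Seed calibration on a conjugate Gaussian model (known
log Z) shows the estimator is slightly conservative and the 16-rung
trapezoid bias (~0.005–0.01) lies well inside one SE.

**Diagnostics.** Split-R̂ and autocorrelation ESS are computed with arviz,
treating walkers as chains. The posterior concentration factor (PCF) is
the ratio of the prior to posterior 90% equal-tailed widths on the
sampling scale — 1 means the data taught nothing, ≥10 strong constraint.
Label-switching across the A/B coupling degeneracy is resolved by
`relabel_symmetry`: any draw with `RB < BR` has the three coupling pairs
swapped so the stronger equilibrium coupling always carries the A-side
label (ties untouched; an involution on the swap set).

## Simulator and synthetic studies

The simulator evolves `N_ch` independent channels by exact event-driven
(Gillespie) simulation across piecewise-constant concentration epochs and
renders per-sample currents with the observation model above; pink noise
is synthesised spectrally (1/√f amplitudes, random phases, variance scaled
to ν²) for exact PSD control. Default protocol designs mirror a brief-pulse
concentration series (0.1, 0.2, 0.5, 1, 2, 10 mM at 0.2 ms) plus 10 ms
monitor pulses at 1 mM, with baselines shrunk to 0.1 s so that a full
dataset is desk-sized. Every trace draws an independent child seed from the
dataset seed; regeneration is bit-identical.

What the simulator does **not** emulate: the recording amplifier's Bessel
filter (currents are ideal step-response sums), solution-exchange kinetics
(concentration steps are instantaneous), channel run-down or modal gating,
and series-resistance artefacts. Passing tests on synthetic data therefore
establish internal consistency of the inference machinery — not that real
recordings satisfy the model.

**Desk-scale study sizes.** The recovery study fits a 3-state chain
(C⇌F⇌O, binding edge concentration-proportional) to 10 replicate synthetic
datasets, N_ch = 100, one 5 ms pulse at 1 mM per trace (10 ms baseline,
20 ms decay, 10 kHz), segmented to ~69 intervals; the sampler uses 6 rungs,
12 walkers, 250 sweeps (half burn-in). True parameters scatter log-normally
(sd 0.15) around the scheme's nominal rates, inside the fitting prior
(sd 0.3). The 2-state mis-specification is fitted identically. The
Monte-Carlo oracle checks use 2×10⁴ exact-event paths; the calibration
check uses 10⁴ model-generated intervals. These sizes are the package's
default verification scale and complete on a single CPU in minutes.

## Known limitations

* Gaussian moment closure misrepresents strongly non-Gaussian count
  distributions (very few channels, near-deterministic gating, extreme
  open probabilities) — exactly the regime the count-filter comparison
  bounds.
* The pink-noise likelihood term treats window averages as independent
  with a flat ν² floor; true 1/f noise is long-range correlated across
  windows.
* The left-endpoint integral accumulation biases the cross-covariance at
  O(δ); halve `target_qdelta` to halve it.
* Trapezoid thermodynamic integration carries an O(R⁻²) ladder bias;
  comparisons between models on the same ladder largely cancel it.
* The evidence SE reflects sampler noise, not the quadrature bias.
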