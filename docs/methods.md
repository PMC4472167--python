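# Methods

## Model

A pair of expression profiles for one gene, measured at two sites over
time courses of unequal length (T₁ ≥ T₂, the grapevine geometry being
19/17 weeks), is modelled as two emission sequences of one latent
first-order Markov chain S₁..S_T over N discrete states. States represent
quantitative expression levels; emissions are univariate Gaussians
b(x | μ_j, σ²_j). The long profile observes every state position; the
short profile observes all positions except a set of gap positions
G ⊂ {2, …, T} with |G| = T − T₂, identical for every gene. The mapping
τ₂ from short-profile time indices to state positions is the strictly
increasing complement of G; position 1 is never a gap because the
experimental design aligns the first measurements. Two facts drive the
estimation strategy:

* a single pair rarely identifies the gaps, but because all profiles are
  scaled to [0, 1] the state space and emissions can be treated as common
  to all genes, so the gap positions are estimated by pooling all pairs;
* genes driven by site-specific factors (temperature and the like) do not
  share a latent trajectory across sites and would bias a joint MLE, so
  the parameter estimate should not lean on the pairing.

## Estimation

**Two-step (default).** Step 1 fits one standard Gaussian HMM to *all*
individual profiles from both sites by pooled Baum-Welch — the pairing and
the gaps drop out entirely, which is what makes the estimate robust to
non-alignable pairs. Step 2 evaluates the alignment log-likelihood at the
fitted λ̂ for every admissible gap set (C(T−1, |G|) candidates, 153 in the
two-gap grapevine case) and takes the argmax; the full surface is kept for
heat-map rendering and for the peak-sharpness diagnostic (max − median).
Ties in the argmax are broken toward the lexicographically smallest gap
set and reported explicitly.

**Full MLE at fixed gaps.** EM on the alignment model itself: the E-step
is forward–backward over the T state positions with composite emission
weights (the product of one or two Gaussian densities, depending on
whether the position is doubly observed); the M-step weights both
observations mapped to a position by that position's posterior. This
estimate is exposed for comparison: when a fraction of pairs is not
alignable, very different values are forced onto common positions and the
fitted variances inflate relative to the pooled fit — the comparison is a
useful contamination diagnostic, and the reason the two-step estimate is
the default.

The model is a special case of a hidden semi-Markov model, but no HSMM
machinery is needed: at fixed gaps everything reduces to a standard HMM
with per-position composite emissions.

## Diagnostics and classification

For pair k, the joint Viterbi path Ŝ (length T) is compared with the two
individually decoded paths at their mapped positions:

H(k) = Σₜ I{Ŝ(τ₁,ₜ) ≠ Ŝw(t)} + Σₜ I{Ŝ(τ₂,ₜ) ≠ Ŝc(t)},  0 ≤ H ≤ T₁+T₂.

Pairs that genuinely share a trajectory decode consistently (H small);
the per-pair log-likelihood is reported alongside but the classifier uses
H only, because the log-likelihood also absorbs unrelated aspects of fit
(distance of values from state means). The label rule is inclusive:
"developmental" iff H ≤ threshold, default 10. ROC curves use −H as the
score, sweeping thresholds over observed values; tied scores contribute ½,
so the trapezoidal AUC equals P(H₊ < H₋) + ½P(H₊ = H₋).

## Preprocessing

Replicate columns are averaged within each time point (missing replicates
are averaged over the remainder, with a warning; a fully missing time
point is an error — the weekly design is complete). The fold-change
filter keeps a gene when max/min ≥ 2 on the unlogged intensity scale at
*either* site, computed after replicate averaging; the rule's scale and
site-combination are genuinely open choices, so they are recorded in the
drop log and the threshold is configurable. Retained profiles are then
linearly mapped to attain 0 and 1 exactly, per profile per site.
Upstream significance screening (e.g. a moderated-t differential
expression test) is deliberately out of scope; the pipeline accepts
pre-filtered matrices.

## Synthetic data

The generator produces exactly what the model assumes, plus controlled
violations:

* **alignable pair** — one latent path per gene drawn from (a, A); the
  long profile emitted at all T positions, the short at the non-gap
  positions, independent Gaussian noise;
* **independent_states contamination** — the two profiles come from two
  independently drawn paths (the default notion of "not suitable for
  alignment");
* **different_gaps contamination** — a shared path but the short profile
  mapped through a discordant gap set.

Defaults (all configurable): N = 5 states, means evenly spaced on [0, 1],
common variance 0.01, uniform initial distribution, transition matrix
with 0.6 on the diagonal and the remainder spread evenly off it, true
gaps (2, 11), T₁/T₂ = 19/17. These mirror the fitted regime of the
motivating data — evenly spaced means across the scaled range with strong
state persistence — and give profiles whose latent level changes a
handful of times per series. Generated values are treated as already
scaled and are not re-mapped to [0, 1]. Contaminated pairs are the last
⌊K·f⌋ of the K generated (order carries no information for any consumer).

What the generator does **not** emulate: replicate-level noise and
missingness, probe-level artefacts, the empirical point masses of scaled
values at exactly 0 and 1, correlation between genes, and non-Gaussian or
autoregressive emission structure. Passing tests therefore demonstrate
correctness of the machinery and robustness under the model's own
assumptions, not performance guarantees on any particular real dataset.

## Numerical choices

* Forward/backward passes run in scaled linear space with a per-position
  shift of the emission log-densities (the per-state maximum is factored
  out before exponentiation), so the smallest representable emission
  density is never a limit and per-sequence log-likelihoods are exact in
  log space. This is numerically equivalent to log-sum-exp recursions and
  considerably faster as dense matrix products.
* Viterbi runs in log space; ties at every argmax resolve to the smallest
  state index, making decoding deterministic.
* EM initialisation is deterministic: means evenly spaced over the
  observed data range, the pooled sample variance for every state, uniform
  initial distribution, uniform transitions with a +0.1 diagonal boost
  (renormalised). Optional seeded multi-start jitters the means (sd 5 % of
  the data range) and keeps the best final log-likelihood. Convergence:
  relative log-likelihood change < 1e−6, max 500 iterations;
  non-convergence is a warning, not an error. Monotonicity of the
  log-likelihood is asserted in tests with 1e−8 slack.
* Variances are clamped to the floor (default 0.001) after every M-step;
  a starved state (zero expected occupancy) keeps its previous parameters
  for that iteration.
* The gap search enumerates gap sets exhaustively with a configurable cap
  (default 10⁵ candidates) and refuses above it; exact floating-point ties
  on the surface maximum are collected and broken lexicographically.
* Seeds: dataset generation is bit-reproducible from one integer seed;
  the robustness sweep spawns one child seed per (fraction, replicate)
  cell from the base seed via `numpy.random.SeedSequence`, so cells are
  independent and the whole table is reproducible.

## Problem sizes used in the shipped experiments

The robustness experiment runs K = 1000 pairs per cell, contamination
fractions 0–90 % in steps of 10, and 5 replicates per fraction; pooled
Baum-Welch at this size converges in ~50 iterations and the 153-point gap
grid evaluates in a couple of seconds, so the full sweep completes in a
few minutes on one core. Parameter-recovery checks use 500–1000 profiles;
enumeration oracles are restricted to N^T ≤ 10⁵.

## Known limitations

* The gap positions are global; per-gene alignment variation is outside
  the model by design.
* Exact replication of a historical parameter estimate is not guaranteed:
  EM initialisation and stopping rules affect the local optimum reached,
  and the original analysis's choices are not fully specified. The gap
  argmax is far less sensitive to this than λ̂ itself (different N give
  the same argmax on well-determined data).
* Emissions are Gaussian and conditionally independent given the states;
  replicate structure, autoregression and higher-order chains are not
  modelled.
* The two-gap grid is exact and cheap; for many gaps the combinatorial
  enumeration grows as C(T−1, G) and the cap will refuse pathological
  cases rather than approximate them.
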