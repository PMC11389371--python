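# Methods

This note documents the models, estimators, and numerical choices behind
`mbinterp`, and what the synthetic cohort does and does not emulate.

## Data model and preprocessing

The unit of analysis is one individual's time series of compositions: a
matrix of relative abundances with strictly increasing time stamps in days
(stored relative to the first sample). Raw tables may hold counts or
proportions; every sample is renormalized on load, and duplicate time
stamps or all-zero samples are rejected. Preprocessing keeps the k taxa
(default 30) with the highest mean relative abundance across the
individual's samples and pools everything else into a final `others`
column, which is present even when empty so that all downstream methods
see a fixed taxon set. Ties at the k-th rank break lexicographically, and
an existing `others` column never competes for a slot, which makes the
operation idempotent. `others` participates in all per-taxon analyses as a
regular column; callers who want it excluded can drop it from the
bimodality tables by label.

## Interpolators

All methods output a composition on the simplex; methods whose raw output
is not compositional (per-taxon means, splines, the dynamic models) are
clipped at zero and renormalized. Only clipping-then-closure is applied —
no smoothing of negative predictions.

* **mean / median / last** — per-taxon statistics over *all* samples (the
  natural reading of "all available samples"; using only past samples
  would make the estimator extrapolative). `last` requires a strictly
  preceding sample and fails otherwise rather than extrapolating backwards.
* **weighted average** — the convex combination of the nearest bracketing
  samples with weights inversely proportional to the time distances. Being
  convex it needs no renormalization; it equals per-taxon linear
  interpolation, which the tests exploit as an oracle.
* **KNN (default K=5)** — the K samples nearest in time on either side,
  combined with Epanechnikov weights ¾(1−u²) where u is the distance
  normalized by the largest selected distance. Two consequences are worth
  knowing: the farthest selected neighbor always gets exactly zero weight
  (u=1), so K=1 degenerates to the nearest sample; and if all selected
  distances are equal every weight is zero, in which case the
  implementation falls back to a uniform average — the kernel's limit as
  the spread of distances vanishes. Distance ties for the K-th slot are
  resolved toward the earlier sample, keeping the method deterministic.
* **cubic spline** — a not-a-knot cubic per taxon, clipped at zero, then
  closed. With exactly 2 or 3 samples the unique linear/quadratic
  interpolant is used instead. If every taxon clips to zero the method
  reports a degenerate-spline error instead of fabricating a composition.
* **dynamic Bayesian network** — a bipartite linear-Gaussian model: each
  taxon at the next sample is a linear function of all taxa at the
  previous sample plus the inter-sample gap Δt. Training pairs are all
  consecutive pairs among the *remaining* samples, so after a leave-one-out
  deletion the flanking samples form a pair with their true, larger Δt —
  consistent with the explicit Δt regressor. The dense configuration fits
  each child by ridge regression (default ridge 1e-6, intercept
  unpenalized; ridge 0 gives the minimum-norm least-squares fit); the
  sparse configuration selects up to `max_parents` (default 3) parents per
  child by greedy forward BIC. This is a from-scratch linear-Gaussian
  implementation, not a wrapper around any external Bayesian-network
  package. One identifiability caveat: on closed compositions the
  abundance columns sum to the intercept column, so the dense map is only
  identified up to a per-row constant shift; predictions are unaffected.

## Generalized Lotka-Volterra estimation

The continuous gLV equations are discretized per consecutive sample pair as
Δln xᵢ/Δt = βᵢ + Σⱼ αᵢⱼ xⱼ, giving the regression F = (A B)Y where each F
column holds the per-interval log-abundance rates (divided by the pair's
Δt, since sampling is irregular) and each Y column the abundances at the
interval start plus a constant 1. Zeros are replaced by a pseudocount
ε = 1e-6 before the log, preserving the pair count with bounded influence
on F.

Three estimators solve the system row by row:

* **least squares** (`glv_mse`) — `lstsq`, returning the minimum-norm
  solution when underdetermined;
* **ridge / MLRR** (`mlrr`) — (YYᵀ+λI)⁻¹ normal equations via the SVD;
  when λ is not supplied it is chosen by leave-one-pair-out
  cross-validation over a log grid (1e-6…1e2), computed in closed form
  from the hat-matrix diagonal. λ=0 reproduces the least-squares fit;
* **LIMITS** (`limits`) — per taxon, forward stepwise selection starting
  from the self-interaction term: each bootstrap repetition splits the
  pairs 50/50 into train/test halves and greedily adds the covariate that
  most reduces test-half error, stopping when the relative improvement
  falls below 1e-3; final coefficients are the entrywise median over
  repetitions (default 100), zeros included. Candidate regressions at each
  step are scored by one batched normal-equations solve.

Prediction is a single forward Euler step from the nearest preceding
available sample — ln x(t+Δt) = ln x(t) + Δt(β + A x(t)) — exponentiated
and closed. Multi-step integration is deliberately not used: one step from
the previous sample mirrors the DBN's prediction protocol and avoids
compounding discretization error over long gaps. Log-rates are clamped at
±50 (with a warning) so an explosive fitted system cannot overflow the
exponent. The model operates on relative abundances as the data provide
them, with the known compositional caveat; an absolute-abundance mode of
the simulator exists purely so the estimators can be validated
analytically (noise-free recovery to 1e-6 is part of the test suite).

## Evaluation framework

Leave-one-out omits each interior sample in turn (the first and last time
points are never targets, so every prediction is an interpolation),
refits any trainable method on the remaining samples, and scores the
Bray-Curtis similarity and per-taxon relative errors |real−pred|/real
(NaN where the truth is zero; excluded from aggregates). Method failures
at a target produce flagged records rather than silent drops.

The Monte-Carlo subsampling experiment always retains the two endpoint
samples, draws the remaining samples uniformly without replacement down to
the requested size, and scores one randomly chosen retained interior
target — so subsampling at full size reproduces leave-one-out scores
exactly, a property the tests check. Stratified summaries hold either the
sample size or the preceding-gap stratum fixed while binning the other.

Correlation analyses use Pearson for accuracy-accuracy and
diversity-accuracy relationships and Spearman for the stability analyses;
p-values use the standard t-approximation with no multiple-testing
correction. "Adjacent" accuracy for a record is the mean of the records
immediately before and after it in time (one-sided at the boundaries);
random-pairing correlations (same individual / same dataset / other
dataset) are seeded and can be averaged over several draws.

## Stability and bimodality

Community stability at a time point is the mean of three Bray-Curtis
similarities: the two preceding samples, the two succeeding samples, and
the nearest preceding-succeeding pair (the third pair uses the nearest
neighbors; the sentence defining the metric admits either reading).
Taxon stability uses the bimodality coefficient
β = (γ²+1)/(κ + 3(n−1)²/((n−2)(n−3))) with moment-estimator skewness γ and
*excess* kurtosis κ — with excess kurtosis the coefficient hits the
standard benchmarks (uniform 5/9, normal 1/3, two-point mass 1), which the
tests verify at n=1e5. β > 0.7 classifies a taxon as non-stable
(conditionally rare or strongly fluctuating); the reversed orientation is
available behind a flag for comparability with sources using the opposite
convention.

## The accuracy predictor

A linear mixed model with a per-individual random intercept predicts
logit(BC) from the gaps to the neighboring samples and the (logit)
leave-one-out accuracies observed at those neighbors, all from the same
method's records. Accuracies are clipped to [1e-3, 1−1e-3] before the
logit; records missing a neighbor are dropped. Estimation is REML via
`statsmodels.MixedLM` with its default BFGS optimization; a singular fit
falls back to OLS with zero random-intercept variance, flagged by a
warning. Wald z = coef/SE with two-sided normal p-values. Out-of-sample
evaluation is grouped by individual (fit on most individuals, predict the
held-out ones with fixed effects only) to avoid leakage through the random
intercepts; performance is reported as MAE on the Bray-Curtis scale plus
the Spearman correlation between predicted and observed accuracy. The
per-individual sample count is constant within an individual and therefore
absorbed by the random intercept; it is excluded from the default
covariate set and available as an option.

## Synthetic cohort

The generator produces per-individual compositions from a Gompertz-form
Lotka-Volterra model on log-abundances: each taxon reverts at rate
0.35/day toward a (possibly time-varying) attractor composition, with weak
random pairwise interactions (sd 0.05) and Gaussian log-noise scaling with
√Δt. Key structural features:

* **regimes** — adults fluctuate around a fixed attractor drawn from a
  moderately even log-normal (σ=1.0); infants hand off logistically from
  an "early" to a "late" attractor drawn from a more dominated log-normal
  (σ=1.8) and carry 2.2× the process noise, producing the directed
  turnover and the lower, more variable accuracy seen in infant series.
* **long-horizon drift** — the attractor itself performs a slow random
  walk (0.10 log units per √day). Pure mean reversion decorrelates within
  days, which would make interpolation accuracy independent of the
  sampling gap beyond a few days; the drift term gives community
  similarity the multi-week decay over which gap effects are measurable.
* **heterogeneous, autocorrelated noise** — each individual's noise level
  is drawn log-normally (sd 0.3) and modulated in time by an AR(1) process
  (ρ=0.9, stationary sd 0.35), so stability varies across individuals and
  drifts within them — the structure the stability correlations and the
  accuracy predictor rely on.
* **conditional taxa** — 4 taxa per individual switch presence through a
  two-state Markov process (on→off 0.12/day, off→on 0.08/day, off factor
  1e-3), yielding the bimodal abundance distributions (high β) of
  conditionally rare taxa.

Defaults (20 individuals, 10 per regime; 31 taxa including an `others`
stand-in; 45-60 samples at mean 1.5-day gamma-distributed intervals) were
chosen to emulate the density of published dense adult and infant 16S
series and to put neighbor-based interpolation accuracy in the
0.85-0.93 (adult) and 0.75-0.86 (infant) bands reported for such data.
What the generator does **not** emulate: sequencing noise and library-size
variation, true zero-inflation from detection limits, taxonomic
correlation structure (phylogeny), diet/antibiotic perturbations, or
disease states. Passing tests therefore demonstrate correctness of the
machinery and reproduction of the qualitative regime/stability/gap
effects under an idealized community model — not performance guarantees
on any particular real data set.

## Problem sizes and numerical choices

The integration checks and the reproduction script run the full 12-method
leave-one-out comparison on the default cohort (~1000 targets per method).
At this scale LIMITS runs with 10 bootstrap repetitions and a 5-term
support cap per taxon (its estimator-level defaults remain 100 and
unlimited); MLRR cross-validates λ per fold via the SVD shortcut. The
noise-free estimator-recovery fixtures use an oscillatory 5-taxa system
(strong antisymmetric interaction component) because trajectories that
settle into equilibrium leave the regression design too ill-conditioned
for 1e-6-level recovery; fixture seeds are chosen so trajectories stay
well above the log pseudocount. Simplex sums are enforced to 1e-9;
simulation aborts with a diagnostic if any log-abundance exceeds ±500.
All randomness flows from explicit seeds; reruns of the pipeline with the
same configuration are byte-identical, which the tests assert.
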