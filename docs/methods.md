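# Methods

## Model and estimation target

The observation model is `MR(k) = τᵀ(k)γ + w(k)` with
`τ(k) = (1, S(k), …, Sⁿ(k))` and `w` i.i.d. Gaussian with variance σ².
The likelihood of the sample, profiled over σ² (whose maximum-likelihood
value is the residual mean square), is a strictly decreasing function of
the mean squared residual λ(γ); `log_likelihood_profile` returns
`−(kmax/2)(ln 2π + 1) − (kmax/2)·ln λ`.  The additive constant is fixed to
that value so the function is fully defined; only differences matter for
estimation, and a perfect fit (λ = 0) reports `+inf` rather than raising.
Minimizing λ is therefore exact maximum likelihood, and because λ is a
convex quadratic in γ the minimizer has the closed form solved by
`ols_fit` (QR-backed `lstsq` on the Vandermonde design, with an explicit
rank check).  The evolutionary searches exist as general-purpose
minimizers of the same objective; the closed form is kept as the oracle
that every search result is compared against in the tests.

Datasets are regression samples: records are indexed k = 1..kmax for
bookkeeping, but the estimators are permutation-invariant and never use
the time column or sampling period Δ (kept as metadata, default 0.5 min).
The physical range check S ∈ (0, 1] is enforced at the CSV boundary
(`read_dataset`); the in-memory container only requires finite values, so
algebraic toy datasets (e.g. S = 0 or S = 2) remain constructible in tests.

## Search algorithms

Both estimators run exactly `generations` sweeps (no early stopping) over
a population of `P ≥ 4` coefficient vectors, initialized uniformly on
`[init_low, init_high)` and unbounded afterwards.  Within a sweep, mutation
partners are drawn from the frozen parent generation while survivors
accumulate separately; partner triples are drawn without replacement
excluding the target index.  Crossover is binomial with one forced mutant
element (the forced position is uniform on the Q coefficient positions).
Selection is strictly greedy: a trial replaces its parent only on a strict
fitness improvement, so ties keep the parent and the best-so-far fitness
trajectory is non-increasing by construction.  Best-individual ties are
broken by the lowest population index.  All randomness flows from a single
`numpy.random.Generator` seeded from the configuration, giving bitwise
reproducibility.

Classic defaults are P = 30, gmax = 20, F = 0.5, CR = 0.9 — standard
DE/rand/1/bin practice.  Initialization on [0, 1) is the documented
convention even though realistic drying coefficients lie well outside it;
recovery tests therefore widen the initialization box (typically
[−15, 15]) and the search budget (P = 50, gmax = 500), which reaches the
least-squares optimum to ~1e−18 on noise-free cubics in about a second.

### Improved schedules

The improved estimator sorts each partner triple by fitness (stable sort,
ties by ascending index, fitness cached once per sweep against the frozen
parents) and mutates from the best partner along the suboptimal-minus-worst
direction.  Its scaling factor decays exponentially,
`F(g+1) = f1·exp(−f2·(g+1)/gmax^f3)`, and its crossover rate oscillates,
`CR(g+1) = (1 + sin(g+1))/c1 + c2` — sine of the bare integer generation
index in radians — recomputed at generation 1 and every even generation
and held through each following odd generation.  The constraint
`2/c1 + c2 ≤ 1` keeps CR a probability.

The five constants are genuinely free parameters of the method, and the
defaults here — f1 = 0.9, f2 = 0.8, f3 = 1, c1 = 2.2, c2 = 0.09 — were
calibrated on synthetic noisy cubic data so that the improved estimator
does what it is designed to do: at the small budget (P = 30, gmax = 20) its
median final fitness over 20 paired seeds beats the classic estimator's on
every generator seed tried, while F still decays smoothly (0.87 → 0.40
over 20 generations) and CR sweeps most of (0, 1].  A steeper decay
(f2 = 2) or a narrow CR band (c1 = 4, c2 = 0.3) was measurably worse than
the classic algorithm at that budget — mainly because with only Q = n+1 ≤ 4
coefficients a small CR rarely transfers enough mutant elements per trial.

## Metrics and order selection

R² is `1 − RSS/TSS` about the observed mean; a zero-variance observed
series raises `DegenerateDataError` rather than returning ±∞.  Adjusted
R² is `1 − (1−R²)(kmax−1)/(kmax−(n+1))`, requiring `kmax > n+1`.  RMSE is
`sqrt(λ)`, so `rmse² = mlf` holds identically for model-based predictions.
Validation (`evaluate_model`, CLI `validate`) scores a fixed model on a
second dataset using that dataset's own mean and count, and keeps the
model's order in the adjustment even though nothing is re-estimated.
`select_order` fits each candidate order and keeps the largest adjusted
R²; differences below 1e−12 count as ties and ties keep the smaller order
(parsimony), which makes the tie-break meaningful when several orders
interpolate exactly and differ only at floating-point level.  Its default
search budget (P = 50, gmax = 300, init [−15, 15]) is deliberately
generous so order ranking reflects the model class, not unconverged
searches.

## Imaging pipeline

Grayscale uses fixed ITU-R 601 luma weights (0.299/0.587/0.114) so masks
are bit-reproducible.  Thresholding defaults to Otsu with a strict `>`
comparison, bright-object-on-dark polarity and an `invert` option; a
constant frame yields a warning and an empty (or full) mask.  Hole filling
treats the background as 4-connected, particle filtering labels foreground
8-connected — stated explicitly because the two differ at diagonal
contacts.  `filter_particles` removes components below `min_area`
(default 50 px) and by default keeps only the largest component, area ties
going to the component first encountered in raster scan order.  Both
cleaning steps are idempotent.  Shrinkage is always reported relative to
the first frame of a series, so S(1) = 1 whenever frame 1 segments
non-empty; an empty mask is recorded as S = 0 with a warning rather than
aborting a series.  An optional rectangular region-of-interest crop exists
for real photographs but is off by default.

## Synthetic data

The generator reproduces the statistical structure the model assumes, not
drying physics.  Shrinkage follows
`S(k) = 1 − (1 − s_min)(k/kmax)^β` (strictly decreasing, ending exactly at
`s_min`); moisture ratios are the ground-truth polynomial plus unclipped
Gaussian noise, so MR may slightly leave [0, 1] — clipping would break the
Gaussian assumption the likelihood is derived from.  Defaults: the cubic
γ = (−4.0180, 12.5609, −11.1670, 3.5632), kmax = 100, s_min = 0.55
(below S ≈ 0.52 that cubic turns negative, so the truth is used only where
it is physically sensible), β = 1, σ = 0.02 (the residual scale of good
experimental fits).  Image stacks draw a bright disk of radius
`r0·√S(k)` on a dark background — commanded area ratio exactly S(k) —
decorated with sub-threshold-size specks outside the slice and small
holes inside it, plus σ = 5 pixel noise (strong enough to be visible,
far too weak to flip a pixel across the foreground/background contrast).
The truth sidecar (coefficients and realized noise) is written to a
separate file from the data CSV so estimation code cannot read it by
accident.  CSVs are written at 9 significant digits and round-trip within
1e−9.

What passing tests on these fixtures do **not** show: robustness to
illumination gradients, shadows, specular highlights, non-disk slice
geometry, camera motion, or model misspecification (real MR–S
relationships need not be polynomial).  The fixtures establish
correctness of the estimation and measurement machinery, not field
performance.

## Problem sizes and numerical choices

Test and acceptance workloads use kmax = 60–100 samples, populations of
30–50 and budgets of 20–500 generations — the scale at which the
convergence, recovery and dominance properties are sharply measurable
while a full run of everything stays under a minute.  The recovery
tolerance (coefficients within 1e−2 of the least-squares optimum) and the
99% chi-square band on the fitted RMSE follow from the σ = 0.02, kmax = 100
study conditions.  Rasterization tolerance for disk-area measurements is
2% for radii ≥ 30 px, dominated by boundary pixelization.

## Known limitations

* The polynomial-in-shrinkage family is the only model class; no
  mechanistic drying models (Page, Lewis, …) and no standard errors or
  confidence intervals for γ.
* Order selection uses adjusted R² only (no AIC/BIC or cross-validation).
* The improved estimator implements exactly one schedule family; no
  self-adaptive per-individual F/CR memories.
* With initialization on the default [0, 1) box and the small default
  budget, neither search converges for realistic coefficient magnitudes;
  widen the box and budget as the examples do.
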