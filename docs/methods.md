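# Methods

This note documents the models, the estimation and search procedures, the
numerical choices, and the design decisions behind the package, together
with what the simulation studies do and do not demonstrate.

## Model and likelihoods

All inference assumes a constant-rate birth–death process: each lineage
independently speciates at rate λ and goes extinct at rate μ.  Observed data
are reconstructed trees — ultrametric, strictly bifurcating crown
phylogenies of extant taxa, with ages measured backward from the present.
The package works with three nested likelihood families:

* **Branch-product form.**  The density of a reconstructed tree is a product
  over its 2m branches (m = n−1 internal nodes) of
  `e^{-r(t_r - t_t)} · [g(t_t)/g(t_r)]²` with `g(x) = λ − μ e^{-r x}` and
  `r = λ − μ`, times λ^m.  Because the product runs over branches rather
  than over non-crown speciation events, it is defined for every n ≥ 2,
  including cherries.  For μ > λ every `g` factor is negative, so the
  squared ratio is computed from |g| in log space.
* **Oriented branching-times form.**  The conventional
  `[p₁(t₁)/(1−p₀(t₁))]² ∏_{i=2}^{n-1} λ p₁(t_i)` over the n−1 branching
  times.  Its product term is empty at n = 2: `bd_loglik_oriented` raises
  `NotDefinedForCherryError` rather than returning a silent zero, because
  this undefinedness is precisely what censors cherries from practical
  datasets.  The test suite verifies that the two forms differ by a
  parameter-free constant on every tree, so they share their maximizer.
* **Special cases.**  μ = 0 reduces to Nee's Yule likelihood
  `(n−1)! λ^{n−2} e^{-λ s}`; λ = μ has its own one-parameter critical form
  with `g(x) → (1 + λx)⁻¹`-type kernels.  The general code dispatches to the
  critical branch when |λ−μ| < 10⁻⁹·λ to avoid catastrophic cancellation in
  `e^{-rt}` differences.

**Conditioning.**  Three variants are exposed everywhere: unconditioned;
conditioned on crown survival (divide by `[1−P₀(t)]²` and drop one factor of
λ for the crown event); and conditioned on the clade having more than two
tips (divide instead by `P(n>2|t) = [1−P₀(t)]² − P₁(t)²`).  The divisor uses
the observed crown age.  The n>2 variant is the estimator matched to
datasets from which cherries were censored; using the survival variant on
such data inflates rates in young clades (the structural bias the
`table1` study quantifies).

A note on P₁: the standard single-lineage kernel
`P₁(t) = r² e^{-rt} / (λ − μ e^{-rt})²` is used throughout.  A variant with
denominator `(λ + r e^{-rt})²` circulates in print but fails the basic
sanity check P₁(0) = 1 and makes the tip-count distribution sum to less
than one; it is treated here as a typographical error.  (The package's
reproduction of the structural-bias table, which matches at every clade
age, is consistent with the standard kernel.)

**Cherry non-identifiability.**  On a two-taxon tree the survival-conditioned
likelihood is `[P₁(t)/(1−P₀(t))]²`, a function of the single number
P₁/(1−P₀): its level sets in the (λ, μ) plane are one-dimensional curves,
the supremum is approached only as (λ, μ) → (0, 0), and no interior maximum
exists.  The package demonstrates this numerically (grid contouring plus
level-set bisection in the tests) and `fit_bd` refuses cherries with
`NonIdentifiableError` rather than returning an arbitrary ridge point.

## Estimation

`fit_bd` maximizes the branch-product likelihood over (log τ, ε) with
τ = λ+μ ∈ [10⁻⁶, 10³] and ε = μ/λ ∈ [10⁻⁹, 1−10⁻⁶], then back-transforms.
The composite parameterization decorrelates the parameters and matches the
generating design of the simulation studies (ε uniform on [0,1]).  The ε
upper bound just below 1 mirrors that design; it clips fits that would
prefer μ̂ > λ̂ — a declared limitation, not silently absorbed (experiments
with ε ≤ 3 produced badly inflated extinction estimates on this design and
were rejected).

The optimizer is a compact bounded Nelder–Mead (the objective is cheap and
2-d; the simplex loop is inlined for speed) run from 5 Latin-hypercube
starting points whose log-turnover range is centred on the crude Yule rate
scale (n−2)/s; the best restart wins, with ties broken toward smaller τ̂.
Convergence tolerances are 10⁻⁸ on the log-likelihood and 10⁻⁶ on the
simplex; fits were spot-verified against dense (λ, μ) grid argmaxes (the
test suite retains this oracle check).  Boundary optima — ε̂ pinned at its
lower bound (pure-birth-like fits) or just below 1 (μ̂ ≈ λ̂) — are common
for small trees and are genuine constrained maxima of the conditioned
likelihood.

`hessian_check` computes a central finite-difference Hessian of the negative
log-likelihood in (τ, ε) at the optimum (relative step 10⁻⁴ per coordinate),
inverts it, and flags the fit valid only when both implied variances are
positive; an optimum within one step of the search bounds is flagged invalid
rather than extrapolated.  In the birth–death study this check plays the
role of an optimizer-sanity filter.  Because in this implementation interior
optima essentially always pass it while boundary optima fail it by
construction, the study excludes only fits that are *interior and invalid*
and retains boundary-constrained optima; dropping all boundary fits (about
60% of small-tree fits) was tested and systematically distorted the
derived-parameter regressions.  The retained fraction (~0.8 of design
points) is comparable to the full-scale study's reported retention (~0.7).

`fit_yule` uses the closed form (n−2)/s for the unconditioned/survival
cases and a bounded 1-d maximization of the n>2-conditioned likelihood
otherwise.  The conditioned objective is monotone decreasing for n = 3
(the conditioning term −log(1−e^{-2λt}) dominates), so three-tip trees
legitimately estimate λ̂ ≈ 0 under conditioning; the robust regressions
downweight these.

## Bias corrections

Closed-form multiplicative corrections, applied to the MLEs:

| parameter | correction |
|---|---|
| speciation | λ̂ · (n−1)/(n−2) |
| extinction | μ̂ · (n/(n−1) + ε̂) |
| turnover | λ̂_corr + μ̂_corr |
| net diversification | (λ̂ − μ̂) · (n/(n−1) + ε̂) |

The speciation factor is the exact inverse of the Yule conditional
expectation E(λ̂|n) = λ(n−2)/(n−1); the bias −λ/(n−1) and the fixed-duration
variance λ²/(2(e^{λt}−1)) (scaling with c² under a correction factor c) are
exposed by `yule_expected_estimate` and `kendall_variance`.  Net
diversification deliberately corrects the *uncorrected* difference λ̂ − μ̂:
its systematic error is dominated by the same extinction-fraction coupling
that biases μ̂, so the factor matches the extinction correction rather than
λ̂_corr − μ̂_corr.

`expectation_recalibrate` fits a robust line of corrected estimates on
generating values and inverts it, `θ' = (θ_corr − a)/b`; this removes the
small approximately-linear residual bias that remains after the closed-form
corrections in simulation.

All robust regressions use Huber M-estimation via statsmodels RLM: tuning
constant 1.345 (95% Gaussian efficiency), MAD scale, IRLS to tolerance 10⁻⁸
with at most 50 iterations.  Single-tree rate estimates are extremely
heavy-tailed and ordinary least squares is dominated by a handful of small
trees.

## Symbolic-regression search

The search space is the set of multiplicative corrections θ̂·c(·) with c a
dimensionless composition of: n, the primitive ratios f₁ = (n−1)/(n−2) and
f₂ = n/(n−1), ε̂ (for extinction and net-diversification targets), and the
constants {0.5, 1, 2}, combined by +, −, ×, ÷.  c applies at most one
operation over the tokens — the space of primitive tokens and their pairwise
combinations.  This spans every closed-form correction of interest
(f₂ + ε̂, 2(n−2)/(n−1) = 2/f₁, products/ratios of f₁ and f₂, bare
constants); unrestricted two-operator composition was tested and rejected
because it admits arbitrarily fine interpolating expressions that win by
overfitting noise rather than by structure.

**Depth** counts each token as 1 — except ε̂, which counts 2 because it is
itself the composite μ̂/λ̂ — and each operator adds one level; a bare θ̂ has
depth 1.  This yields depth 2 for λ̂·f₁ and 2μ̂, 3 for μ̂·2(n−2)/(n−1), and
4 for μ̂·(f₂+ε̂).

Enumeration is exhaustive up to `max_depth = 4` (a hard guard: the space
grows combinatorially) followed by fingerprint deduplication: candidates
agreeing to ~10⁻¹⁰ relative on 64 random probe points collapse to the
representative with the smallest (depth, canonical string).  Candidates
producing non-finite values are disqualified outright.

**Scoring.**  Each candidate's output is robust-regressed on the generating
values; the raw score is the squared deviation of the fitted line from the
1:1 relationship, `(slope − 1)² + intercept²`.  The mean per-point Huber
loss of the 1:1 residuals is also recorded for audit but is not used for
ranking: on single-tree estimates it is dominated by estimator noise common
to all candidates and separates them only in the fourth decimal, whereas the
line-deviation score separates structurally correct corrections from the
uncorrected estimator by two orders of magnitude.  Rankings penalize
complexity with Ω = α·depth over a dense grid (5,000 points) of α values;
whenever the top expression changes, the previous one's optimality interval
is recorded with Ω at its endpoints.  Ties break toward smaller depth, then
lexicographic canonical form.

## Simulator and study designs

The simulator is event-driven on the whole-tree scale: with k lineages
alive, the next event arrives at rate k(λ+μ) and is a speciation with
probability λ/(λ+μ).  Crown simulations start from two lineages and run for
a fixed clade age; extinct subtrees are pruned and degree-2 nodes suppressed
to produce the reconstructed tree.  Crown survival means each root daughter
retains at least one extant descendant (this preserves the crown age that
the conditioning formulas consume).  Tip-count distributions are validated
against the closed-form kernels (Yule crown, critical single-lineage) to
three Monte-Carlo standard errors.

Default study conditions (reduced scale relative to the original 10⁵–5·10⁵
tree experiments; summary statistics stabilize well below full scale):

* **Structural-bias table** (`run_table1`): 5,000 trees per clade age at
  λ = 0.1, μ = 0.05, ages {5,…,30}; one tree per replicate, cherries
  censored; each retained tree fitted with both the survival-conditioned and
  the n>2-conditioned likelihood.  Cells report across-tree means (medians
  are also emitted; the mean is the statistic that reproduces the published
  full-scale table).
* **Yule validation** (`run_yule_validation`): 30,000 Latin-hypercube points
  with age ~ U[0,5] and λ ~ U[0,0.5]; one tree per point, non-(n>2) points
  discarded without resampling (retention ≈ 56%, matching the design-averaged
  1 − e^{-2λt}); per-tree estimate = the n>2-conditioned Yule MLE (the
  unconditioned closed form is kept as a comparison column).
* **Birth–death study** (`run_bd_study`): 30,000 Latin-hypercube points with
  age ~ U[0,10], λ ~ U[0,1], ε ~ U[0,1], μ = λ·ε.  Each point is simulated
  *conditional on crown survival* (redrawn until the crown survives, capped
  at 100 tries) and cherries are then censored without resampling.  The
  discard-everything protocol was tested and rejected: it cannot reproduce
  the full-scale study's retained-fit count and produces large spurious
  intercepts in the derived-parameter regressions, because low-rate design
  points then contribute only their rare, extreme realizations.
  Fits use the n>2-conditioned likelihood in (τ, ε); the validity filter is
  described above.  Huber regressions of corrected λ, μ, turnover and net
  diversification (direct, from-corrected, and expectation-recalibrated) on
  their generating values form the slope table; the symbolic-regression
  rankings for λ (α ∈ [0, 10⁻³]) and μ (α ∈ [0, 10⁻¹]) run on the same
  estimates.

All studies derive per-replicate seeds deterministically from
(master seed, row id), so reruns are byte-identical.

## What the studies do and do not show

The generator emulates clean, completely sampled, correctly dated
ultrametric trees under exactly the model being fitted.  Passing studies
therefore demonstrate the internal consistency of the estimators,
conditionings and corrections — not robustness to incomplete taxon sampling,
rate heterogeneity across lineages or time, fossil/sampled-ancestor tips, or
tree-estimation error, all of which are out of scope.

At reduced scale the slope and interval *structure* of the
symbolic-regression results reproduces stably, but the identity of the
single best expression at α = 0 sits within Monte-Carlo noise of close
algebraic relatives (e.g. f₁ vs f₂ for λ, whose raw scores differ by ~10⁻⁴;
ε̂-coupled variants for μ): the α = 0 winner can differ from the full-scale
result at a given seed.  The extinction estimator composition is also
sensitive to unstated implementation details of the original optimizer
(bounds and boundary handling), which shifts which ε̂-dependent correction
scores best.

## Known limitations

* ε̂ is bounded below 1: trees whose likelihood prefers μ̂ > λ̂ are clipped
  to the near-critical boundary.
* The n>2-conditioned Yule MLE is degenerate (0) at n = 3; downstream
  regressions rely on Huber downweighting rather than excluding such trees.
* The Hessian validity check uses fixed relative steps; near-boundary
  curvature estimates are numerically delicate and intentionally
  conservative only for interior optima.
* `max_depth` > 4 in the symbolic search is refused rather than supported.
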