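# Methods

## Population model and simulated conditions

Each simulation condition fixes a common-factor model for p = m·k ordinal
items: Σ = ΛΦΛᵀ + diag(Ψ), where Λ is the p × m loading matrix, Φ the
compound-symmetric factor correlation matrix (off-diagonals all equal to
ρ ∈ {0, 0.3, 0.6}), and Ψ_i = 1 − (ΛΦΛᵀ)_ii the unique variances. Primary
loadings are uniform in a level-dependent range (low 0.35–0.50, medium
0.50–0.65, high 0.65–0.80). When m > 1 every item receives exactly one
cross-loading (low 0–0.10, medium 0.10–0.20, high 0.20–0.30) on the
cyclically next factor — factor f's items cross-load on factor
(f mod m) + 1. Placing cross-loadings on *all* non-primary factors at
these ranges would drive communalities above 1 for every
high-loading/high-cross four-factor condition (e.g. λ = (0.725, 0.25,
0.25, 0.25) under ρ = 0.6 gives λᵀΦλ ≈ 1.53), so single placement is used;
draws that still yield some Ψ_i ≤ 0 are redrawn up to 100 times before the
condition is declared infeasible ("n/a").

Sample sizes are 300, 600 or 1000; indicators per factor 5 or 10; factors
1, 2 or 4 (single-factor conditions force ρ = 0 and ignore the
cross-loading level). The full factorial crossing has
3 × 2 × 3 × 3 × 3 × 3 × 4 × 2 = 3,888 cells.

## Continuous data and discretisation

Normal data are drawn N(0, Σ) through a Cholesky factor. Non-normal data
target marginal skewness 2 and **excess** kurtosis 7 (the standard
convention of the non-normality literature these values come from) with
covariance Σ, via the independent-generator construction: X = V Aᵀ with
A = chol(Σ) and independent components V whose third/fourth cumulants are
solved from the triangular systems (A∘³)γ₁ = s·1 and (A∘⁴)γ₂ = k·1
(cumulants of independent sums add through powered mixing weights); each
component is a Fleishman cubic polynomial of a standard normal. When the
component system leaves the Fleishman-attainable region — common for
strongly structured Σ, where late Cholesky columns demand extreme
component kurtosis — the generator falls back to the Vale–Maurelli
construction (a common marginal Fleishman transform of a normal vector
whose intermediate correlations solve the induced cubic per pair). Both
routes satisfy the same moment-level contract: population covariance Σ and
the target marginal moments; the two are exchangeable for everything
downstream, which only sees the ordinal codes.

Discretisation assigns category c when τ_{c−1} < x ≤ τ_c with fixed
cutpoint sets on the latent standard-normal scale: 4 categories symmetric
(−0.67, 0, 0.67) or skewed (0, 0.43, 0.97); 5 categories symmetric
(−0.84, −0.25, 0.25, 0.84) or skewed (0.08, 0.25, 0.62, 1.11). Thresholds
are applied to the raw continuous scores for both the normal and
non-normal generators, so "skewed" always refers to the cutpoints, not
the underlying distribution. The generator is a pure function of
(condition, seed).

## Polychoric estimation

Two-step ML. Step 1: per-column thresholds τ_c = Φ⁻¹(cumulative
proportion); empty categories are collapsed into the adjacent lower
category. Step 2: per pair, the contingency-table log-likelihood
Σ n_ij log π_ij(ρ) — π_ij a bivariate-normal rectangle probability
between consecutive thresholds — is maximised by bounded Brent search
(tolerance 1e-6) over |ρ| ≤ 0.999. Rectangle probabilities use Genz's
BVND quadrature (6/12/20-node Gauss–Legendre rules with a near-singular
expansion for |ρ| ≥ 0.925), implemented as numba kernels because the
permutation reference of PA re-estimates the full matrix dozens of times
per replication; the kernels agree with `scipy`'s bivariate normal CDF to
machine precision (tested). Estimates within 1e-3 of the bound are
reported at the cap and flagged `boundary`; a non-finite likelihood falls
back to the Pearson correlation of the codes, flagged `fallback`. If the
assembled matrix is not positive definite it is repaired by clipping
eigenvalues at 1e-4 and rescaling to unit diagonal (`repaired = True`);
the deterministic clip is preferred to nearest-PD projection for speed
and reproducibility.

## Parallel analysis

Principal-component eigenvalues of the polychoric matrix itself (no
reduction) are compared position by position against reference spectra
from `n_iter = 20` datasets formed by independently permuting each ordinal
column — the reference thus shares the exact category margins and the full
polychoric pipeline. The number of factors is the largest m such that the
observed eigenvalue exceeds the reference statistic at *every* position
≤ m (sequential stop). The reference statistic is the positionwise mean by
default; the 95th percentile is selectable. Both the rule and `n_iter` are
exposed because different implementations of the method disagree on them.

## Exploratory graph analysis

The polychoric matrix S enters a graphical lasso with the L1 penalty on
off-diagonal precision entries, solved by Friedman block coordinate
descent (numba, warm-started) along 100 log-spaced penalties from
λ_max = max|S_offdiag| down to 0.1·λ_max. This solver is exact on the
two-variable closed form and agrees with `sklearn.covariance.graphical_lasso`
(which serves as the independent cross-check in the tests, not as the
implementation — it is ~60× slower per path at p = 40). The penalty is
chosen by EBIC = −2ℓ(K) + E log n + 4γE log p with
ℓ(K) = (n/2)(log det K − tr(SK)), E the nonzero upper-triangle edge count,
γ = 0.5, and n the number of ordinal rows. Edge weights are partial
correlations W_ij = −K_ij/√(K_ii K_jj); walktrap (4 steps,
modularity-selected cut) on |W| yields communities, equated with factors.

Two pipeline guards:

- **Unidimensionality check (default "louvain").** Sparse-network
  community detection over-splits genuinely one-factor data, so EGA first
  applies Louvain community detection to the absolute zero-order
  polychoric correlations; one community ⇒ one factor, otherwise the
  network pipeline decides. The alternative "expand" check augments the
  items with a simulated one-factor 4-item block (population loadings
  0.70, the data's n and threshold set) and declares unidimensionality
  when all original items share one community of the augmented network.
  The two differ materially: the zero-order check also absorbs
  multi-factor structures whose between-block correlations approach the
  within-block ones (high cross-loadings plus ρ = 0.6), which the
  partial-correlation network would still separate — this is what makes
  strongly overlapping two-factor data come out unidimensional, and it is
  the behavior the accuracy benchmarks encode. Louvain runs
  deterministically on the vertex order.
- **γ step-down.** For weak loadings at n = 300 the EBIC at γ = 0.5
  prefers the empty network outright; every isolated item would then count
  as its own community and EGA would overfactor wildly. When the selected
  network leaves isolated nodes, γ is lowered by 0.25 (to a floor of 0)
  and the selection — not the path fit, which is γ-free — is repeated. An
  empty network surviving at γ = 0 (e.g. truly independent items) still
  yields p singleton communities, counted as overfactoring.

## Evaluation driver

Replications derive their seeds from (master seed, condition id, rep) via
`numpy` SeedSequence spawn keys, so any cell reproduces in isolation and
the whole run is a pure function of (grid, reps, master seed). Estimates
are scored correct / underfactoring / overfactoring against the generating
m; failed estimates are recorded as missing and counted as incorrect
(neither under nor over). Aggregations report percentages per method and
per cell, plus a wide pivot (distribution × m × ρ × loading levels against
method × k × N) averaged over the category factor, which has no column of
its own in the study's summary table. The logistic comparison fits a
binomial GLM of correctness on dummy-coded design factors, a method main
effect and method × factor interactions; constant factors are dropped with
a notice, aliased designs raise with the offending terms named, and a
ridge (L2) option stabilises separated data (cells at 0%/100% are common).

## Problem sizes and defaults used in the checks

The bundled checks run desk-scale versions of the study: benchmark cells
use 25 replications per category variant (10 for the four-factor,
p = 40, N = 1000 cell) and the aggregate-ordering check uses one
n = 300, k = 5 condition per m × ρ × primary-loading stratum at 20
replications. At these sizes the whole suite runs in a few minutes on one
CPU while every reported rate is still a multiple of 2–5%. PA uses
n_iter = 20 and the mean rule; EGA uses nlambda = 100,
lambda_min_ratio = 0.1, γ = 0.5 with 0.25 step-down, walktrap steps = 4.

## Known limitations

- The simulator draws one cross-loading per item on a deterministic
  (cyclic) target factor; bifactor, hierarchical, or denser cross-loading
  patterns are out of scope. Real scales also violate the equal-ρ
  (compound symmetry) assumption.
- Under this population design the four-factor high-cross-loading cells
  remain cleanly separable in the partial-correlation network
  (within-block partial correlations ≈ 0.16 vs between ≈ 0.05 at the
  population matrix), so EGA recovers them essentially always; pipelines
  built on denser cross-loading placements report failure there instead.
- Polychoric estimation assumes underlying bivariate normality per pair;
  the non-normal conditions deliberately violate it, which is part of
  what the simulation measures, but no robustness correction is applied.
- The permutation reference for PA is one of several reference schemes in
  use; simulated-normal references can give different cutoffs at small n.
- Missing-data mechanisms, item-specific thresholds, and more than five
  categories are not supported.
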