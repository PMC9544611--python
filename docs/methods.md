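# Methods

## The measure

A Q matrix holds membership coefficients q_ki for I individuals (rows) in
K clusters (columns); rows are probability vectors. The package measures
variability *across rows* by the classical heterozygosity-based
differentiation statistic applied under an analogy in which each
individual plays the role of a subpopulation and its membership vector the
role of an allele-frequency vector:

- H_S = 1 − (1/I) Σ_i Σ_k q_ki² — the mean "within-individual"
  heterozygosity; low when individual vectors sit near simplex vertices.
- H_T = 1 − Σ_k (mean_i q_ki)² — the heterozygosity of the pooled mean
  vector.
- F_ST = (H_T − H_S)/H_T, defined only when H_T > 0.

F_ST is 0 exactly when all rows are identical, but its upper limit given
the data's I and M (the largest column mean) is usually well below 1, so
raw F_ST values are incomparable across matrices of different shape or
mean composition. The reported measure is F_ST/F_STmax, where F_STmax is
the maximum of F_ST over all Q matrices with the same I and M and an
unbounded number of columns.

### The bound and its two implementations

Writing σ₁ = I·M, the maximum is attained by explicit configurations:

- non-integer σ₁ ∈ (1, I): ⌊σ₁⌋ individuals fully in the dominant
  cluster, one individual split ({σ₁}, 1−{σ₁}) between the dominant
  cluster and a private one, all remaining individuals fully in mutually
  distinct private clusters. Evaluating F_ST on this configuration gives
  the closed form (D − 2I·f(1−f))/D with f = {σ₁} and
  D = I(I−1) − σ₁² + σ₁ + f(1−f).
- 0 < σ₁ ≤ 1 (only possible when K > I): every individual occupies its
  own J = ⌈1/σ₁⌉ private clusters, J−1 of them with coefficient exactly
  σ₁ and one with 1−(J−1)σ₁; many clusters then tie at mean M. The
  closed form is S(I−1)/(I−S) with S = 1 − σ₁(J−1)(2−Jσ₁).
- integer σ₁ ∈ {1, …, I−1}: the f → 0 limit of the first case; the bound
  is exactly 1.

Both routes are implemented (`fst_max_closed`, `fst_max_constructive`)
and the test suite requires them to agree to 1e−12 on a dense (I, M)
grid; the constructive configuration is the authoritative oracle, since
its value is produced by the same public H_S/H_T code every caller uses.

### Numerical choices

- Integer-σ₁ detection uses |σ₁ − round(σ₁)| ≤ 1e−9. Both adjacent
  branches converge to 1 at integer σ₁, so classification at the
  tolerance boundary is harmless.
- M within 1e−12 of 1 raises a "monomorphic" error: the bound's true
  value tends to 0 there, the matrix is (to double precision)
  monomorphic, and both F_ST and the bound are dominated by catastrophic
  cancellation. For M between ~1−1e−6 and 1−1e−12 values are returned
  but carry absolute noise up to ~1e−10; the closed form is clipped into
  [0, 1].
- A matrix whose rows are bit-identical gets F_ST = 0 exactly (the
  algebraic characterization is enforced, not left to float
  accumulation), so ratio = 0 iff all rows are identical.
- Monomorphic input (H_T = 0) raises a typed error everywhere rather
  than returning 0 or NaN; the CLI maps it to exit code 3 (or reports
  NaN under `--allow-degenerate`). A silent 0 would corrupt group
  comparisons.
- Ties among column means for M are broken toward the lowest column
  index; the statistic is provably identical under any tie choice.
- Row validation accepts raw row sums within 1e−3 of 1 (structure-style
  output prints 3–6 decimals) and then renormalizes by a single division
  pass; rows whose float sum is already exactly 1 are untouched, making
  renormalization idempotent to one ulp.

## Bootstrap comparison of groups

For each group's Q matrix, B replicates (default 1000) are formed by
drawing I rows with replacement and recomputing the ratio. Two groups are
compared by a two-sided Wilcoxon rank-sum (Mann–Whitney) test on the two
sets of B bootstrap ratios, using the normal approximation with tie
correction; three or more groups get one Kruskal–Wallis omnibus test plus
all pairwise rank-sum tests. Pairwise p-values are unadjusted by default,
with Bonferroni and Benjamini–Hochberg available by flag.

Degenerate replicates — a resample that happens to be monomorphic, which
requires some individual to be fully assigned to a single cluster and its
copies to fill the entire resample — are assigned ratio 0, counted, and
reported via a warning, keeping the distribution at exactly B values.

Reproducibility: every bootstrap is deterministic given its seed. The CLI
derives each group's stream from the master seed plus a content digest of
the group's matrix, so adding or reordering groups does not perturb the
other groups' draws, and the same matrix passed twice produces identical
distributions (a pure-tie comparison).

Caveat, by design: the rank test treats the B bootstrap ratios as
independent observations. Its null hypothesis is that the two bootstrap
distributions coincide — which holds when the two groups' *observed*
matrices have the same empirical distribution of rows, not when two
different samples merely come from the same population. See the
calibration experiment below; the package implements the published test
as specified rather than a repaired variant.

## Dirichlet generative model

Rows are simulated i.i.d. from Dir(α·λ) with Σλ_k = 1: λ sets the
parametric mean of each cluster's membership and α the concentration,
with Var(q_k) = λ_k(1−λ_k)/(α+1). Sampling uses normalized independent
gamma variates; with tiny shape parameters (α·λ_k ≪ 1) a whole row can
underflow to zero, in which case it is redrawn. `alpha_from_variance`
inverts the variance law to pick α for a target variance.

Under this model the expected ratio obeys, to first order,
E[F_ST/F_STmax] ≈ 1/(α+1), independent of λ and of K. Three experiments
probe the model:

1. **Variance sweep** (`run_variance_sweep`): λ = (2/3, 1/3), I = 50,
   K = 2, and the 45-level variance grid {0.001} ∪ {0.005, …, 0.220}
   spanning (0, 2/9). The zero-intercept OLS slope of ratio on variance
   is ≈ 1/(λ₁λ₂) = 4.5 with R² (about the zero-intercept model) ≈ 99%.
   The acceptance script runs 100 replicates per level (4,500 matrices,
   seconds of runtime); the test suite asserts slope ∈ [4.3, 4.7] and
   R² ≥ 0.98 at the same size.
2. **Expectation law** (`expectation_check`): Monte-Carlo mean ratio vs
   1/(α+1) with a standard error. The law is accurate to well under one
   percent across moderate α and any K tested, but it is an
   approximation: at the extreme α = 1/99 (parametric variance 0.22,
   rows nearly at simplex vertices) the true mean is ≈ 0.996 at I = 50,
   not 0.990 — a bias of ~0.006 (and ~−0.0001 at K = 5, α = 99),
   independently verified with a second Dirichlet sampler and the
   constructive bound. Tests asserting agreement within 3 Monte-Carlo
   SEs at 500 replicates therefore fail at those extremes; this is a
   documented limitation of the approximation, not of the estimator.
3. **Calibration** (`calibration_experiment`): repeated
   simulate → bootstrap → rank-test runs. Under the shared-matrix null
   (one simulated matrix bootstrapped twice with independent streams —
   the test's exact null) p-values are uniform on (0, 1); a KS check at
   level 0.01 passes at 500 repetitions, B = 200. Under the
   population-level null (two independent matrices from the same spec,
   `null_design="independent"`) the test rejects nearly always — the
   quantitative face of the caveat above. Power: α = 21901/99 vs
   α = 1/99 (the extreme concentrations of the variance grid) is
   rejected at the 0.05 level in ≥ 99% of repetitions.

### What the simulator does and does not emulate

The Dirichlet model produces exchangeable individuals with a common mean
vector — adequate for studying the measure's response to variability.
Real Q matrices add features it lacks: inferred (not true) coefficients
with correlated estimation error, non-exchangeable individuals
(admixture gradients, family structure), cluster-label switching across
runs, and values truncated by the inference software's printing
precision. Passing tests therefore demonstrate correctness of the
statistic and its sampling machinery, not robustness to inference
artefacts in real data.

## Experiment sizes

Defaults mirror the validation study (I = 50, K = 2, λ = (2/3, 1/3),
B = 1000, 45-level variance grid). The automated tests and the
acceptance script use 100 sweep replicates per variance level, 500
expectation-law replicates, and 500 calibration repetitions at B = 200 —
sizes chosen so the whole battery runs in well under a minute on one
core while keeping Monte-Carlo error far below every asserted margin.

## Scope and limitations

- The package begins at the Q matrix: no genotype handling, no
  structure/admixture invocation, and no cluster alignment across
  replicate runs (CLUMPP-style matching is a separate problem; plots
  stack segments in input column order).
- Full STRUCTURE output files with header blocks are not parsed; extract
  the numeric block or use `--skip-cols`.
- The K-unbounded bound is used for normalization; no finite-K
  constrained bound, and no allele-based F_ST estimators
  (Weir–Cockerham etc.).
- F_ST/F_STmax compares variability, not mean membership: groups with
  identical variability but different means are (correctly) not
  distinguished.
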