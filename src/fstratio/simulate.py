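"""Dirichlet generative model for Q matrices and validation experiments.

Membership-coefficient vectors within a population are modelled as i.i.d.
draws from Dir(alpha * lambda), where lambda (length K, summing to 1) sets
the parametric mean of each cluster's membership and the concentration
alpha sets the spread:

    Var(q_k) = lambda_k * (1 - lambda_k) / (alpha + 1).

Large alpha concentrates every row near lambda; alpha -> 0 pushes rows
toward the vertices of the simplex.  Under this model the expected
variability measure obeys, to good approximation,

    E[F_ST / F_STmax] ~= 1 / (alpha + 1),

independent of lambda and of K — the property the experiments in this
module check numerically: a variance sweep (the ratio grows linearly in
Var(q_1) with slope 1/(lambda_1*lambda_2) for K = 2), a direct test of the
expectation law, and a calibration experiment confirming that the bootstrap
rank-sum test has uniform p-values under the null.

Default experiment conditions are I = 50 individuals, K = 2 clusters,
lambda = (2/3, 1/3), and the 45-point parametric-variance grid
{0.001} U {0.005, 0.010, ..., 0.220} spanning (0, 2/9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import bootstrap_ratios, compare_groups
from .core import ratio_batch
from .qmatrix import QMatrix

__all__ = [
    "DirichletSpec",
    "simulate_q",
    "alpha_from_variance",
    "variance_grid",
    "run_variance_sweep",
    "zero_intercept_fit",
    "expectation_check",
    "calibration_experiment",
    "DEFAULT_LAMBDA",
    "DEFAULT_I",
]

DEFAULT_LAMBDA = (2.0 / 3.0, 1.0 / 3.0)
DEFAULT_I = 50


@dataclass(frozen=True)
class DirichletSpec:
    """Parameters of the generative model: rows ~ Dir(alpha * lam), I rows.

    ``lam`` must be nonnegative and sum to 1; ``alpha`` > 0.  A degenerate
    component (some lambda_k = 1) makes every row constant at lam; it is
    allowed but the resulting matrices are monomorphic.
    """

    alpha: float
    lam: tuple[float, ...] = DEFAULT_LAMBDA
    i_count: int = DEFAULT_I

    def __post_init__(self) -> None:
        lam = tuple(float(x) for x in self.lam)
        object.__setattr__(self, "lam", lam)
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.i_count < 1:
            raise ValueError("i_count must be >= 1")
        if any(x < 0 for x in lam) or abs(sum(lam) - 1.0) > 1e-9:
            raise ValueError("lam must be nonnegative and sum to 1")

    @property
    def k_count(self) -> int:
        return len(self.lam)

    def variance(self, k: int = 0) -> float:
        """Parametric Var(q_k) = lambda_k (1 - lambda_k) / (alpha + 1)."""
        lk = self.lam[k]
        return lk * (1.0 - lk) / (self.alpha + 1.0)

    @property
    def expected_ratio(self) -> float:
        """Approximate E[F_ST/F_STmax] under the model: 1/(alpha + 1)."""
        return 1.0 / (self.alpha + 1.0)


def alpha_from_variance(target_var: float, lam_k: float) -> float:
    """Concentration alpha giving Var(q_k) = target_var at mean lam_k.

    Inverts Var(q_k) = lam_k (1 - lam_k)/(alpha + 1); the target must lie
    strictly between 0 and lam_k (1 - lam_k), the variance of a Bernoulli
    with mean lam_k (the alpha -> 0 limit).
    """
    ceiling = lam_k * (1.0 - lam_k)
    if not (0.0 < target_var < ceiling):
        raise ValueError(
            f"target variance must lie in (0, {ceiling:.6g}), got {target_var}"
        )
    return ceiling / target_var - 1.0


def _sample_rows(
    rng: np.random.Generator, shape_vec: np.ndarray, n_rows: int
) -> tuple[np.ndarray, int]:
    """Draw Dirichlet rows via normalized gamma variates.

    With tiny shapes (alpha * lambda_k well below 1) a gamma draw can
    underflow to exactly 0 in double precision; a row whose entries all
    underflow has no direction on the simplex and is redrawn.  Returns the
    rows and the number of redraws.
    """
    g = rng.gamma(shape_vec, size=(n_rows, shape_vec.size))
    sums = g.sum(axis=1)
    n_resampled = 0
    while True:
        bad = np.flatnonzero(sums == 0.0)
        if bad.size == 0:
            break
        n_resampled += bad.size
        g[bad] = rng.gamma(shape_vec, size=(bad.size, shape_vec.size))
        sums[bad] = g[bad].sum(axis=1)
    return g / sums[:, None], n_resampled


def simulate_q(
    spec: DirichletSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> QMatrix:
    """Simulate one Q matrix: I i.i.d. Dir(alpha * lam) rows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if 1.0 in spec.lam:
        # degenerate spec: rows are constant at lam
        rows = np.tile(np.asarray(spec.lam), (spec.i_count, 1))
        return QMatrix(rows)
    shape_vec = spec.alpha * np.asarray(spec.lam)
    rows, _ = _sample_rows(rng, shape_vec, spec.i_count)
    return QMatrix(rows)


def _simulate_ratios(
    spec: DirichletSpec, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Ratios of ``reps`` independently simulated matrices (vectorized)."""
    shape_vec = spec.alpha * np.asarray(spec.lam)
    rows, _ = _sample_rows(rng, shape_vec, reps * spec.i_count)
    qs = rows.reshape(reps, spec.i_count, spec.k_count)
    # at extreme alpha a simulated matrix can be monomorphic; score it 0
    return ratio_batch(qs, degenerate="zero")


def variance_grid() -> np.ndarray:
    """The 45-point parametric-variance grid {0.001} U {0.005, ..., 0.220}."""
    return np.concatenate([[0.001], np.arange(1, 45) * 0.005])


def run_variance_sweep(
    lam: tuple[float, float] = DEFAULT_LAMBDA,
    variances: np.ndarray | None = None,
    reps: int = 500,
    i_count: int = DEFAULT_I,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Simulate the ratio across a grid of parametric variances (K = 2).

    For each variance, alpha is solved from the variance law and ``reps``
    Q matrices are simulated; the ratio is computed for each.  Returns a
    tidy table with columns ``variance``, ``alpha``, ``replicate``,
    ``ratio`` — one row per simulated matrix.
    """
    if len(lam) != 2:
        raise ValueError("the variance sweep is defined for K = 2")
    if variances is None:
        variances = variance_grid()
    rng = np.random.default_rng(seed)
    frames = []
    for var in np.asarray(variances, dtype=float):
        alpha = alpha_from_variance(var, lam[0])
        spec = DirichletSpec(alpha=alpha, lam=lam, i_count=i_count)
        ratios = _simulate_ratios(spec, reps, rng)
        frames.append(
            pd.DataFrame(
                {
                    "variance": var,
                    "alpha": alpha,
                    "replicate": np.arange(reps),
                    "ratio": ratios,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of y on x with the intercept fixed at 0.

    Returns ``(slope, r_squared)`` where R^2 is computed against the
    zero-intercept model: 1 - RSS / sum(y^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = float(x @ y / (x @ x))
    rss = float(np.sum((y - slope * x) ** 2))
    tss = float(np.sum(y * y))
    return slope, 1.0 - rss / tss


def expectation_check(
    spec: DirichletSpec,
    reps: int = 500,
    seed: int | np.random.SeedSequence | None = None,
) -> dict[str, float]:
    """Monte-Carlo test of E[ratio] ~= 1/(alpha + 1).

    Simulates ``reps`` matrices from ``spec`` and returns the empirical mean
    ratio, its standard error, and the analytic prediction.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    ratios = _simulate_ratios(spec, reps, rng)
    return {
        "mean_ratio": float(ratios.mean()),
        "se": float(ratios.std(ddof=1) / np.sqrt(reps)),
        "predicted": spec.expected_ratio,
        "reps": reps,
    }


def calibration_experiment(
    spec: DirichletSpec,
    n_tests: int = 500,
    b_count: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    spec_b: DirichletSpec | None = None,
    null_design: str = "shared",
) -> np.ndarray:
    """p-values of the bootstrap rank-sum test on repeated simulated pairs.

    Each repetition builds two groups, bootstraps each with ``b_count``
    replicates, and records the two-sided rank-sum p-value.

    The rank-sum test's null hypothesis is that the two bootstrap
    distributions come from the same distribution, which holds exactly when
    both groups share one observed Q matrix.  ``null_design="shared"``
    (default) therefore simulates a single matrix from ``spec`` per
    repetition and bootstraps it twice with independent streams; the
    returned p-values are approximately Uniform(0, 1).

    ``null_design="independent"`` simulates two independent matrices from
    ``spec``.  That is a *population-level* null (equal generating
    variability, different realized samples), under which the test is
    strongly anticonservative: bootstrap spread within a matrix is
    comparable to the sampling spread between matrices, and with hundreds
    of bootstrap values per group the rank test resolves the between-matrix
    difference almost surely.  Exposed for studying exactly that behaviour.

    Passing ``spec_b`` simulates the second group from a different model
    (an alternative hypothesis, always two independent matrices); the
    rejection rate of the returned p-values then estimates power.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if null_design not in {"shared", "independent"}:
        raise ValueError(f"unknown null_design {null_design!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pvals = np.empty(n_tests)
    for t, child in enumerate(ss.spawn(n_tests)):
        rng = np.random.default_rng(child)
        qa = simulate_q(spec, rng)
        if spec_b is not None:
            qb = simulate_q(spec_b, rng)
        elif null_design == "independent":
            qb = simulate_q(spec, rng)
        else:
            qb = qa
        da = bootstrap_ratios(qa, b_count, rng, group="a")
        db = bootstrap_ratios(qb, b_count, rng, group="b")
        pvals[t] = compare_groups([da, db])[0].p_value
    return pvals
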