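"""Bootstrap distributions of F_ST/F_STmax and rank-based group comparison.

Variability of two or more groups is compared by resampling individuals
(rows) of each group's Q matrix with replacement, recomputing the ratio on
every replicate matrix, and testing the resulting bootstrap distributions
against each other: a two-sided Wilcoxon rank-sum (Mann-Whitney) test for a
pair of groups, a Kruskal-Wallis omnibus test plus all pairwise rank-sum
tests for three or more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ratio_batch
from .qmatrix import QMatrix

__all__ = [
    "BootstrapDistribution",
    "ComparisonResult",
    "bootstrap_ratios",
    "compare_groups",
    "comparisons_to_frame",
    "DEFAULT_B",
]

#: Default number of bootstrap replicates per group.
DEFAULT_B = 1000


@dataclass(frozen=True)
class BootstrapDistribution:
    """B values of F_ST/F_STmax from row-resampled replicates of one matrix.

    ``n_degenerate`` counts replicates whose resample was monomorphic
    (H_T = 0, every resampled row fully in one cluster); such replicates are
    assigned ratio 0 rather than dropped, so the distribution always has
    exactly B values.
    """

    group: str
    ratios: np.ndarray
    b_count: int
    seed: int | None
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=np.float64)
        object.__setattr__(self, "ratios", r)
        if r.shape != (self.b_count,):
            raise ValueError(f"expected {self.b_count} ratios, got shape {r.shape}")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("bootstrap ratios must lie in [0, 1]")


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test on bootstrap distributions."""

    test: str  # "rank-sum" or "kruskal-wallis"
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    adjusted_p: float | None = None


def bootstrap_ratios(
    q: QMatrix,
    b_count: int = DEFAULT_B,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    group: str | None = None,
) -> BootstrapDistribution:
    """Bootstrap the ratio by resampling rows of ``q`` with replacement.

    Each of the ``b_count`` replicates draws I rows (with replacement) from
    ``q``, keeping the original I, and computes F_ST/F_STmax on the
    replicate.  Deterministic given ``seed``.

    Raises if the source matrix itself is monomorphic (every replicate would
    be undefined).  A replicate that happens to be monomorphic — possible
    when some individual is fully assigned to one cluster and its copies
    fill the whole resample — is scored as ratio 0 and counted in
    ``n_degenerate``.
    """
    if b_count < 1:
        raise ValueError("b_count must be >= 1")
    # validates the source: monomorphic q raises here
    ratio_batch(q.values[None, :, :], degenerate="error")

    if isinstance(seed, np.random.Generator):
        rng, seed_repr = seed, None
    else:
        rng = np.random.default_rng(seed)
        seed_repr = seed if isinstance(seed, int) else None
    i_count = q.n_individuals
    idx = rng.integers(0, i_count, size=(b_count, i_count))
    replicates = q.values[idx]  # (B, I, K)
    ratios = ratio_batch(replicates, degenerate="nan")
    n_degenerate = int(np.isnan(ratios).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} of {b_count} bootstrap replicates were "
            "monomorphic and scored as ratio 0",
            stacklevel=2,
        )
        ratios = np.nan_to_num(ratios, nan=0.0)
    return BootstrapDistribution(
        group=group or q.group or "group",
        ratios=ratios,
        b_count=b_count,
        seed=seed_repr,
        n_degenerate=n_degenerate,
    )


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with normal approximation and tie correction."""
    if np.ptp(np.concatenate([x, y])) == 0.0:
        # every pooled value identical: no location difference detectable
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    dists: Sequence[BootstrapDistribution],
    adjust: str = "none",
) -> list[ComparisonResult]:
    """Rank-based tests on two or more bootstrap distributions.

    Exactly two groups yield a single two-sided rank-sum result.  Three or
    more yield one Kruskal-Wallis omnibus result across all groups followed
    by every pairwise rank-sum result.  ``adjust`` applies Bonferroni
    (``"bonferroni"``) or Benjamini-Hochberg (``"bh"``) correction to the
    pairwise p-values only; the default is no adjustment.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 bootstrap distributions to compare")
    if any(d.b_count < 2 for d in dists):
        raise ValueError("each distribution needs at least 2 values")
    if adjust not in {"none", "bonferroni", "bh"}:
        raise ValueError(f"unknown adjustment {adjust!r}")

    results: list[ComparisonResult] = []
    if len(dists) >= 3:
        samples = [d.ratios for d in dists]
        if np.ptp(np.concatenate(samples)) == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*samples)
        results.append(
            ComparisonResult(
                test="kruskal-wallis",
                statistic=float(stat),
                p_value=float(p),
                groups=tuple(d.group for d in dists),
            )
        )

    pairwise: list[ComparisonResult] = []
    for a, b in combinations(dists, 2):
        stat, p = _rank_sum(a.ratios, b.ratios)
        pairwise.append(
            ComparisonResult(
                test="rank-sum", statistic=stat, p_value=p,
                groups=(a.group, b.group),
            )
        )
    if adjust != "none" and pairwise:
        raw = np.array([r.p_value for r in pairwise])
        if adjust == "bonferroni":
            adj = np.minimum(1.0, raw * len(raw))
        else:
            adj = stats.false_discovery_control(raw, method="bh")
        pairwise = [
            ComparisonResult(
                test=r.test, statistic=r.statistic, p_value=r.p_value,
                groups=r.groups, adjusted_p=float(a),
            )
            for r, a in zip(pairwise, adj)
        ]
    return results + pairwise


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of test results: one row per comparison."""
    return pd.DataFrame(
        {
            "test": [r.test for r in results],
            "groups": [" vs ".join(r.groups) for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    )
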