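"""Heterozygosity-based F_ST on Q matrices and its constrained maximum.

The analogy: treat each individual (row of the Q matrix) as a
"subpopulation" and its membership-coefficient vector as an "allele
frequency" vector.  Then

    H_S = 1 - (1/I) * sum_i sum_k q_ki^2        (mean within-row heterozygosity)
    H_T = 1 - sum_k (mean_i q_ki)^2             (heterozygosity of the pooled rows)
    F_ST = (H_T - H_S) / H_T

F_ST measures variability of the rows, but its attainable maximum given I
and M (the mean membership of the highest-mean cluster, the analogue of the
frequency of the most frequent allele) is usually below 1.  Normalizing by
that constrained maximum, F_ST / F_STmax, yields a variability measure in
[0, 1] comparable across Q matrices of different I and K.

The maximum is available two ways, which must agree:

* :func:`fst_max_closed` — closed form in I and sigma1 = I*M, with three
  branches selected by whether sigma1 is an integer, below 1, or a
  non-integer in (1, I);
* :func:`fst_max_constructive` — builds the explicit maximizing Q matrix
  (the cluster of greatest membership is the only one shared; at most one
  individual mixes two clusters) and evaluates F_ST on it.

The constructive route is the authoritative oracle: the closed form is
validated against it on a grid before use (see the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .qmatrix import QMatrix

__all__ = [
    "FstResult",
    "MonomorphicError",
    "het_within",
    "het_total",
    "fst",
    "most_frequent_mean",
    "fst_max_closed",
    "fst_max_constructive",
    "fst_ratio",
    "ratio_batch",
    "INTEGER_SIGMA_TOL",
]

#: |sigma1 - round(sigma1)| below this counts as integer sigma1 (F_STmax = 1).
#: Both adjacent branches converge to 1 at integers, so misclassification at
#: the boundary is numerically harmless.
INTEGER_SIGMA_TOL = 1e-9


class MonomorphicError(ValueError):
    """H_T = 0: every individual is fully assigned to the same single
    cluster, so F_ST (0/0) and the ratio are undefined."""


@dataclass(frozen=True)
class FstResult:
    """Statistics of one Q matrix.

    Attributes
    ----------
    hs, ht : within-row and pooled heterozygosity, 0 <= hs <= ht <= 1.
    fst : (ht - hs) / ht.
    m : mean membership of the highest-mean cluster, in [1/K, 1].
    sigma1 : I * m.
    fst_max : maximum F_ST attainable with this I and m (K unbounded).
    ratio : fst / fst_max, in [0, 1]; the variability measure.
    i_count, k_count : matrix dimensions I and K.
    """

    hs: float
    ht: float
    fst: float
    m: float
    sigma1: float
    fst_max: float
    ratio: float
    i_count: int
    k_count: int


def _values(q: QMatrix | np.ndarray) -> np.ndarray:
    return q.values if isinstance(q, QMatrix) else np.asarray(q, dtype=np.float64)


def het_within(q: QMatrix | np.ndarray) -> float:
    """Mean within-individual heterozygosity H_S = 1 - (1/I) sum_i sum_k q_ki^2."""
    v = _values(q)
    return float(1.0 - np.mean(np.sum(v * v, axis=1)))


def het_total(q: QMatrix | np.ndarray) -> float:
    """Pooled heterozygosity H_T = 1 - sum_k (column mean)^2."""
    v = _values(q)
    means = v.mean(axis=0)
    return float(1.0 - np.sum(means * means))


def fst(q: QMatrix | np.ndarray) -> float:
    """F_ST = (H_T - H_S)/H_T of the rows of ``q``.

    Raises :class:`MonomorphicError` when H_T = 0.  Exactly 0 when all rows
    are identical (H_S = H_T), enforced explicitly so float accumulation
    cannot blur the ratio's zero characterization.
    """
    v = _values(q)
    ht = het_total(v)
    if ht <= 0.0:
        raise MonomorphicError(
            "H_T = 0: all ancestry lies in a single cluster; F_ST is undefined"
        )
    if np.all(v == v[0]):
        return 0.0
    val = (ht - het_within(v)) / ht
    # clip float round-off at the ends of the theoretical range
    return float(min(1.0, max(0.0, val)))


def most_frequent_mean(q: QMatrix | np.ndarray) -> tuple[float, float]:
    """Return (M, sigma1): the largest column mean and I times it.

    Ties between columns are broken toward the lowest index; the value is
    identical under any tie choice.
    """
    v = _values(q)
    means = v.mean(axis=0)
    m = float(means[int(np.argmax(means))])
    return m, m * v.shape[0]


def _check_bound_inputs(i_count: int, m: float) -> float:
    if i_count < 2:
        raise ValueError(f"bound requires at least 2 individuals, got I={i_count}")
    if not (0.0 < m <= 1.0):
        raise ValueError(f"M must lie in (0, 1], got {m}")
    sigma1 = i_count * m
    # only M indistinguishable from 1 in double precision is undefined; for
    # any M < 1 the bound exists (though it tends to 0 as M -> 1)
    if m >= 1.0 - 1e-12:
        raise MonomorphicError(
            "M = 1: the pooled population is monomorphic; the bound is undefined"
        )
    return sigma1


def fst_max_closed(i_count: int, m: float) -> float:
    """Maximum F_ST over all Q matrices with I rows and highest column mean M.

    K (the number of clusters) is unbounded.  Three branches in
    sigma1 = I*M:

    * integer sigma1 in {1, ..., I-1}: the maximum is exactly 1;
    * 0 < sigma1 < 1 (possible only when K > I): with J = ceil(1/sigma1)
      and S = 1 - sigma1*(J-1)*(2 - J*sigma1),
      F_STmax = S*(I-1) / (I - S);
    * non-integer sigma1 in (1, I): with f = frac(sigma1) and
      D = I*(I-1) - sigma1^2 + sigma1 + f*(1-f),
      F_STmax = (D - 2*I*f*(1-f)) / D.

    Raises :class:`MonomorphicError` for M = 1 and ``ValueError`` for I < 2.
    """
    sigma1 = _check_bound_inputs(i_count, m)
    return float(_fst_max_from_sigma(np.asarray(i_count), np.asarray(sigma1)))


def _fst_max_from_sigma(i_count: np.ndarray, sigma1: np.ndarray) -> np.ndarray:
    """Vectorized closed-form bound; inputs broadcast, 0 < sigma1 < I."""
    i_count = i_count.astype(np.float64)
    nearest = np.round(sigma1)
    is_integer = (
        (np.abs(sigma1 - nearest) <= INTEGER_SIGMA_TOL)
        & (nearest >= 1.0)
        & (nearest <= i_count - 1.0)  # sigma1 near I is not the F_STmax=1 case
    )
    small = sigma1 < 1.0

    out = np.ones(np.broadcast_shapes(i_count.shape, sigma1.shape))

    # 0 < sigma1 < 1: each row occupies J private clusters, J-1 of them at
    # exactly sigma1 so that multiple clusters tie at mean M.
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.ceil(1.0 / np.where(small, sigma1, 0.5))
        s = 1.0 - sigma1 * (j - 1.0) * (2.0 - j * sigma1)
        small_val = s * (i_count - 1.0) / (i_count - s)

        f = sigma1 - np.floor(sigma1)
        ff = f * (1.0 - f)
        d = i_count * (i_count - 1.0) - sigma1 * sigma1 + sigma1 + ff
        large_val = (d - 2.0 * i_count * ff) / d

    out = np.where(small, small_val, large_val)
    out = np.where(is_integer & ~small, 1.0, out)
    # the true bound lies in (0, 1]; cancellation very close to sigma1 = I
    # can push the float value a hair outside
    return np.clip(out, 0.0, 1.0)


def fst_max_constructive(i_count: int, m: float) -> tuple[float, QMatrix]:
    """Build the maximizing Q matrix for (I, M) and evaluate F_ST on it.

    For non-integer sigma1 in (1, I): floor(sigma1) rows fully in cluster 1,
    one row split (frac(sigma1), 1 - frac(sigma1)) between cluster 1 and a
    private cluster, and the remaining rows each fully in mutually distinct
    private clusters.  For 0 < sigma1 <= 1: every row uses its own J private
    clusters, J-1 entries equal to sigma1 and one equal to 1 - (J-1)*sigma1.
    Integer sigma1 in {1, ..., I-1} is the frac -> 0 case of the first
    construction and attains F_ST = 1.

    Returns ``(value, witness)``; the witness's highest column mean equals M
    exactly (up to float rounding) and its F_ST equals the closed-form bound.
    """
    sigma1 = _check_bound_inputs(i_count, m)
    eps = INTEGER_SIGMA_TOL
    if sigma1 < 1.0 - eps:
        # sigma1 < 1: K = I * J columns, all private
        j = math.ceil(1.0 / sigma1)
        k_total = i_count * j
        w = np.zeros((i_count, k_total))
        for i in range(i_count):
            w[i, i * j : i * j + j - 1] = sigma1
            w[i, i * j + j - 1] = 1.0 - (j - 1) * sigma1
    else:
        floor = min(int(math.floor(sigma1 + eps)), i_count - 1)
        frac = sigma1 - floor
        if frac <= eps:
            frac = 0.0
        n_mixed = 0 if frac == 0.0 else 1
        n_private = i_count - floor - n_mixed
        k_total = 1 + n_mixed + n_private
        w = np.zeros((i_count, k_total))
        w[:floor, 0] = 1.0
        col = 1
        if n_mixed:
            w[floor, 0] = frac
            w[floor, col] = 1.0 - frac
            col += 1
        for r in range(floor + n_mixed, i_count):
            w[r, col] = 1.0
            col += 1
    witness = QMatrix(w)
    return fst(witness), witness


def fst_ratio(q: QMatrix | np.ndarray) -> FstResult:
    """Compute the full statistic bundle for one Q matrix.

    The ratio F_ST / F_STmax uses the sample M of ``q`` itself as the fixed
    most-frequent-cluster mean.  Raises :class:`MonomorphicError` when the
    matrix is monomorphic (H_T = 0, which includes M = 1).
    """
    v = _values(q)
    i_count, k_count = v.shape
    if i_count < 2:
        raise ValueError("the ratio requires at least 2 individuals")
    hs = het_within(v)
    ht = het_total(v)
    if ht <= 0.0:
        raise MonomorphicError(
            "H_T = 0: all ancestry lies in a single cluster; the ratio is undefined"
        )
    if np.all(v == v[0]):
        f = 0.0
    else:
        f = min(1.0, max(0.0, (ht - hs) / ht))
    m, sigma1 = most_frequent_mean(v)
    fmax = fst_max_closed(i_count, m)
    ratio = min(1.0, max(0.0, f / fmax))
    return FstResult(
        hs=hs, ht=ht, fst=f, m=m, sigma1=sigma1, fst_max=fmax,
        ratio=ratio, i_count=i_count, k_count=k_count,
    )


def ratio_batch(qs: np.ndarray, degenerate: str = "error") -> np.ndarray:
    """F_ST / F_STmax for a stack of Q matrices, shape (n, I, K).

    Vectorized core used by the bootstrap and the simulation experiments.

    Parameters
    ----------
    qs
        Array of n Q matrices with identical dimensions; rows need not be
        renormalized here (callers pass validated or simulated matrices).
    degenerate
        Policy for monomorphic members (H_T = 0): ``"error"`` raises,
        ``"zero"`` assigns ratio 0, ``"nan"`` assigns NaN.
    """
    qs = np.asarray(qs, dtype=np.float64)
    if qs.ndim != 3:
        raise ValueError("expected shape (n, I, K)")
    n, i_count, _ = qs.shape
    hs = 1.0 - np.mean(np.sum(qs * qs, axis=2), axis=1)
    means = qs.mean(axis=1)
    ht = 1.0 - np.sum(means * means, axis=1)
    mono = ht <= 0.0
    if np.any(mono) and degenerate == "error":
        raise MonomorphicError(f"{int(mono.sum())} of {n} matrices are monomorphic")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.clip((ht - hs) / ht, 0.0, 1.0)
        identical = np.all(qs == qs[:, :1, :], axis=(1, 2))
        f[identical] = 0.0
        m = means.max(axis=1)
        sigma1 = i_count * m
        ok = m < 1.0 - 1e-12
        fmax = np.ones(n)
        fmax[ok] = _fst_max_from_sigma(np.asarray(i_count), sigma1[ok])
        ratio = np.clip(f / fmax, 0.0, 1.0)
    bad = mono | ~ok  # M within double precision of 1 counts as degenerate
    ratio[bad] = 0.0 if degenerate == "zero" else np.nan
    if degenerate == "error" and np.any(bad):
        raise MonomorphicError("matrices with M = 1 encountered")
    return ratio
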