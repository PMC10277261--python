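"""Mantel test and Mantel correlogram for distance-matrix comparison.

Divergence times form a between-species distance matrix, which makes them
directly comparable to other pairwise matrices — typically genetic
distance such as pairwise F_ST — via the Mantel permutation test: Pearson
correlation over the upper-triangle entries, with a null distribution
built by simultaneously permuting the rows and columns of the second
matrix. The correlogram repeats the test per distance class, correlating
the second matrix with the 0/1 membership indicator of each class of
divergence times.

The permutation p-value uses the plus-one rule,
p = (#{|r*| ≥ |r|} + 1)/(n_perm + 1), so it is never exactly zero. For
n ≤ 7 labels an exact test enumerating all label permutations is provided
as an oracle for the Monte-Carlo version.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DistanceMatrixPair",
    "MantelResult",
    "CorrelogramClass",
    "MantelError",
    "mantel",
    "mantel_exact",
    "correlogram",
    "sturges_breaks",
]

_EXACT_MAX_N = 7  # 7! = 5040 permutations


class MantelError(ValueError):
    """Invalid matrices or a degenerate (zero-variance) comparison."""


@dataclass
class DistanceMatrixPair:
    """Two symmetric zero-diagonal matrices over the same ordered labels."""

    x: np.ndarray
    y: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MantelError("labels must be unique")
        for name, m in (("x", self.x), ("y", self.y)):
            if m.shape != (n, n):
                raise MantelError(f"{name} shape {m.shape} != ({n}, {n})")
            if not np.allclose(m, m.T):
                raise MantelError(f"{name} is not symmetric")
            if np.any(np.diag(m) != 0):
                raise MantelError(f"{name} diagonal is not zero")
            if np.any(m < 0):
                raise MantelError(f"{name} has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_matrices(cls, x_matrix, y_matrix) -> "DistanceMatrixPair":
        """Build from two DivergenceMatrix-like objects with equal labels."""
        if list(x_matrix.labels) != list(y_matrix.labels):
            raise MantelError(
                "matrices carry different labels or orderings: "
                f"{x_matrix.labels} vs {y_matrix.labels}"
            )
        return cls(
            x=np.asarray(x_matrix.values, dtype=float),
            y=np.asarray(y_matrix.values, dtype=float),
            labels=list(x_matrix.labels),
        )


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: Optional[int] = None
    tail: str = "two-sided"


@dataclass(frozen=True)
class CorrelogramClass:
    """Mantel statistic for one divergence-time class.

    ``r``/``p_value`` are None when the class holds fewer than 3 pairs
    (too few to test).
    """

    lower_mya: float
    upper_mya: float
    r: Optional[float]
    p_value: Optional[float]
    n_pairs: int

    @property
    def testable(self) -> bool:
        return self.r is not None


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise MantelError("zero variance in a distance triangle; r undefined")
    return float(a @ b) / denom


def _observed(pair: DistanceMatrixPair) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = _triu_indices(pair.n)
    xv = pair.x[iu, ju]
    yv = pair.y[iu, ju]
    return _pearson(xv, yv), xv, iu, ju


def _exceeds(r_perm: np.ndarray, r_obs: float, tail: str) -> np.ndarray:
    if tail == "two-sided":
        return np.abs(r_perm) >= abs(r_obs) - 1e-12
    if tail == "greater":
        return r_perm >= r_obs - 1e-12
    if tail == "less":
        return r_perm <= r_obs + 1e-12
    raise MantelError(f"unknown tail {tail!r}")


def mantel(
    pair: DistanceMatrixPair,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "two-sided",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation over the n(n−1)/2 upper-triangle entries;
    the null permutes rows and columns of the second matrix
    simultaneously. Deterministic for a given seed.
    """
    if pair.n < 4:
        raise MantelError("Mantel test needs at least 4 labels")
    if n_perm < 1:
        raise MantelError("n_perm must be at least 1")
    r_obs, xv, iu, ju = _observed(pair)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(pair.n) for _ in range(n_perm)])
    # Gather each permuted upper triangle in one vectorized indexing pass.
    rows = perms[:, iu]
    cols = perms[:, ju]
    yp = pair.y[rows, cols]  # (n_perm, n_pairs)

    xc = xv - xv.mean()
    xnorm = math.sqrt(float(xc @ xc))
    yc = yp - yp.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (yc @ xc) / (ynorm * xnorm)
    r_perm = np.nan_to_num(r_perm, nan=0.0)

    hits = int(_exceeds(r_perm, r_obs, tail).sum())
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm, seed=seed, tail=tail)


def mantel_exact(pair: DistanceMatrixPair, tail: str = "two-sided") -> MantelResult:
    """Exact Mantel test by full enumeration of label permutations (n ≤ 7).

    p is the fraction of all n! permutations (the identity included) whose
    statistic is at least as extreme as the observed one.
    """
    if pair.n > _EXACT_MAX_N:
        raise MantelError(
            f"exact enumeration supports at most {_EXACT_MAX_N} labels "
            f"(got {pair.n}); use mantel() instead"
        )
    if pair.n < 4:
        raise MantelError("Mantel test needs at least 4 labels")
    r_obs, xv, iu, ju = _observed(pair)
    perms = np.array(list(itertools.permutations(range(pair.n))))
    yp = pair.y[perms[:, iu], perms[:, ju]]
    xc = xv - xv.mean()
    xnorm = math.sqrt(float(xc @ xc))
    yc = yp - yp.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (yc @ xc) / (ynorm * xnorm)
    r_perm = np.nan_to_num(r_perm, nan=0.0)
    hits = int(_exceeds(r_perm, r_obs, tail).sum())
    p = hits / len(perms)
    return MantelResult(
        r=r_obs, p_value=p, n_permutations=len(perms), seed=None, tail=tail
    )


def sturges_breaks(pair: DistanceMatrixPair) -> list[float]:
    """Equal-width class bounds over (0, max(x)] by Sturges' rule."""
    iu, ju = _triu_indices(pair.n)
    m = len(iu)
    k = max(1, int(math.ceil(math.log2(m) + 1)))
    top = float(pair.x[iu, ju].max())
    if top <= 0:
        raise MantelError("all divergence times are zero; no classes")
    return [top * i / k for i in range(k + 1)]


def correlogram(
    pair: DistanceMatrixPair,
    breaks: Optional[Sequence[float]] = None,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "two-sided",
) -> list[CorrelogramClass]:
    """Mantel correlogram: per-class Mantel tests against a 0/1 indicator.

    Classes are [lower, upper) except the last, which is closed above so
    the classes partition [0, max(x)]. Classes holding fewer than 3 pairs
    are returned untestable (r and p None). Breaks default to Sturges'
    equal-width classes.
    """
    if breaks is None:
        breaks = sturges_breaks(pair)
    breaks = [float(b) for b in breaks]
    if len(breaks) < 2 or any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise MantelError(f"breaks must be strictly increasing, got {breaks}")

    iu, ju = _triu_indices(pair.n)
    xv = pair.x[iu, ju]
    out: list[CorrelogramClass] = []
    for ci, (lo, hi) in enumerate(zip(breaks, breaks[1:])):
        last = ci == len(breaks) - 2
        in_class = (xv >= lo) & ((xv <= hi) if last else (xv < hi))
        n_pairs = int(in_class.sum())
        if n_pairs < 3:
            out.append(CorrelogramClass(lo, hi, None, None, n_pairs))
            continue
        indicator = np.zeros_like(pair.x)
        indicator[iu, ju] = indicator[ju, iu] = in_class.astype(float)
        ind_pair = DistanceMatrixPair(
            x=indicator, y=pair.y, labels=list(pair.labels)
        )
        res = mantel(ind_pair, n_perm=n_perm, seed=seed + ci, tail=tail)
        out.append(CorrelogramClass(lo, hi, res.r, res.p_value, n_pairs))
    return out
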