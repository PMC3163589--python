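"""Standardized Mantel statistic and its permutation test.

The Mantel statistic r_M is the Pearson product-moment correlation
between the upper-triangle entries of two distance matrices defined over
the same ids.  Its permutation null is built by relabelling one matrix —
permuting its rows and columns simultaneously — and recomputing the
statistic; with an optional ``pair_mask`` the statistic is evaluated on
a fixed subset of matrix *positions*, which do not move under the
permutation (labels move, positions do not).  That positional convention
is what makes a per-distance-class Mantel test well defined and is what
renders a class with no geographic variation "untestable".

p-values use the add-one (include-the-observed) convention,
p = (1 + #{permuted r at least as extreme}) / (1 + n_permutations),
so p is never 0 and is bounded below by 1/(n_permutations + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations
from typing import Iterable, Literal, Sequence

import numpy as np

from .distmat import DistanceMatrix, require_same_ids
from .exceptions import UntestableError, ValidationError

__all__ = [
    "MantelResult",
    "mantel_statistic",
    "mantel_test",
    "mantel_exact",
]

Tail = Literal["greater", "less", "two-sided"]

_EXACT_MAX_IDS = 8


@dataclass(frozen=True)
class MantelResult:
    """Outcome of a Mantel permutation test.

    ``r_m`` and ``p_value`` are ``None`` when ``testable`` is False
    (a masked vector had no variation).
    """

    r_m: float | None
    p_value: float | None
    n_permutations: int
    tail: Tail
    n_pairs_used: int
    seed: int | str | None
    testable: bool = True

    def __post_init__(self) -> None:
        if self.testable:
            if self.r_m is None or self.p_value is None:
                raise ValidationError("testable result requires r_m and p_value")
            if abs(self.r_m) > 1 + 1e-12:
                raise ValidationError(f"|r_M| > 1: {self.r_m}")
            lower = 1.0 / (self.n_permutations + 1)
            if not (lower - 1e-12 <= self.p_value <= 1.0 + 1e-12):
                raise ValidationError(f"p-value {self.p_value} outside [{lower}, 1]")

    @property
    def significant_at(self):  # convenience: result.significant_at(0.05)
        def check(alpha: float) -> bool:
            return self.testable and self.p_value < alpha

        return check

    def to_dict(self) -> dict:
        return {
            "r_m": self.r_m,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "tail": self.tail,
            "n_pairs_used": self.n_pairs_used,
            "seed": self.seed,
            "testable": self.testable,
        }


def _mask_index_arrays(
    n: int, pair_mask: Iterable[tuple[int, int]] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) arrays, optionally restricted to a mask."""
    if pair_mask is None:
        return np.triu_indices(n, k=1)
    pairs = sorted({(min(i, j), max(i, j)) for i, j in pair_mask})
    if len(pairs) < 3:
        raise ValidationError("pair_mask must select at least 3 pairs")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    if np.any(ii == jj) or np.any(jj >= n) or np.any(ii < 0):
        raise ValidationError("pair_mask contains invalid positions")
    return ii, jj


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UntestableError("untestable: no variation in a masked distance vector")
    return float(xc @ yc) / (sx * sy)


def mantel_statistic(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    pair_mask: Iterable[tuple[int, int]] | None = None,
) -> float:
    """Pearson correlation of (masked) upper-triangle entries.

    Raises :class:`UntestableError` when either masked vector is constant.
    """
    require_same_ids(d_a, d_b)
    ii, jj = _mask_index_arrays(len(d_a), pair_mask)
    if pair_mask is None and len(ii) < 3:
        raise ValidationError("need at least 3 pairs (3 ids) for a Mantel statistic")
    return _pearson(d_a.values[ii, jj], d_b.values[ii, jj])


def _tail_count(
    perm_r: np.ndarray, observed: float, tail: Tail, atol: float = 1e-12
) -> int:
    """Number of permuted statistics at least as extreme as observed."""
    if tail == "greater":
        return int(np.sum(perm_r >= observed - atol))
    if tail == "less":
        return int(np.sum(perm_r <= observed + atol))
    if tail == "two-sided":
        return int(np.sum(np.abs(perm_r) >= abs(observed) - atol))
    raise ValidationError(f"unknown tail {tail!r}")


def _permuted_statistics(
    a_vec: np.ndarray,
    b_values: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    perms: Iterable[np.ndarray],
) -> np.ndarray:
    """r for each permutation; undefined (constant-vector) r recorded as 0."""
    a_c = a_vec - a_vec.mean()
    sa = math.sqrt(float(a_c @ a_c))
    out = []
    for perm in perms:
        b_vec = b_values[perm[ii], perm[jj]]
        b_c = b_vec - b_vec.mean()
        sb = math.sqrt(float(b_c @ b_c))
        # a permuted vector can lose all variation under a mask; score 0
        out.append(float(a_c @ b_c) / (sa * sb) if sb > 0 else 0.0)
    return np.array(out)


def mantel_test(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    n_permutations: int = 1000,
    tail: Tail = "greater",
    seed: int | np.random.SeedSequence | None = None,
    pair_mask: Iterable[tuple[int, int]] | None = None,
) -> MantelResult:
    """Mantel permutation test, permuting the id order of ``d_b``.

    With a ``pair_mask``, masked positions stay fixed while the labels of
    ``d_b`` are permuted.  If the observed masked vectors have no
    variation the result is flagged ``testable=False`` with null r_M and
    p, rather than raising.
    """
    require_same_ids(d_a, d_b)
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    n = len(d_a)
    ii, jj = _mask_index_arrays(n, pair_mask)
    if pair_mask is None and n < 3:
        raise ValidationError("need at least 3 ids for a Mantel test")
    seed_record = seed if isinstance(seed, int) or seed is None else str(seed)
    try:
        observed = _pearson(d_a.values[ii, jj], d_b.values[ii, jj])
    except UntestableError:
        return MantelResult(
            r_m=None,
            p_value=None,
            n_permutations=n_permutations,
            tail=tail,
            n_pairs_used=len(ii),
            seed=seed_record,
            testable=False,
        )
    rng = np.random.default_rng(seed)
    perms = (rng.permutation(n) for _ in range(n_permutations))
    perm_r = _permuted_statistics(d_a.values[ii, jj], d_b.values, ii, jj, perms)
    p = (1 + _tail_count(perm_r, observed, tail)) / (1 + n_permutations)
    return MantelResult(
        r_m=observed,
        p_value=p,
        n_permutations=n_permutations,
        tail=tail,
        n_pairs_used=len(ii),
        seed=seed_record,
        testable=True,
    )


def mantel_exact(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    tail: Tail = "greater",
    pair_mask: Iterable[tuple[int, int]] | None = None,
) -> float:
    """Exact permutation p-value by full enumeration (≤ 8 ids).

    Enumerates every relabelling of ``d_b`` including the identity, so
    the p-value is #{r at least as extreme} / n!, which always includes
    the observed arrangement.  Raises :class:`UntestableError` on a
    constant masked vector, matching :func:`mantel_statistic`.
    """
    require_same_ids(d_a, d_b)
    n = len(d_a)
    if n > _EXACT_MAX_IDS:
        raise ValidationError(
            f"exact enumeration limited to {_EXACT_MAX_IDS} ids, got {n}"
        )
    ii, jj = _mask_index_arrays(n, pair_mask)
    observed = _pearson(d_a.values[ii, jj], d_b.values[ii, jj])
    perms = (np.array(p) for p in _all_permutations(range(n)))
    perm_r = _permuted_statistics(d_a.values[ii, jj], d_b.values, ii, jj, perms)
    return _tail_count(perm_r, observed, tail) / math.factorial(n)
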