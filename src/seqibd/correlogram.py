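"""Mantel correlogram over equal-count geographic distance classes.

The class count comes from Sturge's rule applied to the number of
pairwise comparisons, k = ceil(1 + log2 N).  The N upper-triangle pairs
are sorted by geographic distance (stable, ties broken by row then
column index) and cut into equal-count classes — ceil(N/k) pairs in each
of the first k−1 classes, the remainder in the last — so every per-class
test has the same statistical power.  Each class is then Mantel-tested
and judged against the Bonferroni-corrected level alpha/k (stored
unrounded; rounded only for display).

Two per-class statistics are available:

* ``variant="restricted"`` (default): the Mantel correlation between
  genetic and geographic distance restricted to the class's pairs.  A
  class whose geographic distances are constant (e.g. a first class made
  entirely of same-site pairs) has no variation to correlate and is
  flagged untestable, with null r_M and p.
* ``variant="membership"``: the classical indicator-matrix correlogram
  statistic — the (sign-flipped) correlation between genetic distance
  and class membership over all pairs.  Under isolation by distance this
  variant traces the canonical positive-to-negative shape across
  distance classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix, require_same_ids
from .exceptions import ValidationError
from .mantel import MantelResult, Tail, mantel_test

__all__ = [
    "DistanceClass",
    "CorrelogramResult",
    "sturges_class_count",
    "equal_count_classes",
    "mantel_correlogram",
]

Variant = Literal["restricted", "membership"]


def sturges_class_count(n_pairs: int) -> int:
    """Sturge's rule: k = ceil(1 + log2 N)."""
    if n_pairs < 1:
        raise ValidationError(f"n_pairs must be positive, got {n_pairs}")
    return max(1, math.ceil(1.0 + math.log2(n_pairs)))


@dataclass(frozen=True)
class DistanceClass:
    """One geographic distance class of a Mantel correlogram."""

    index: int  # 1-based
    lower_km: float  # observed min geographic distance among member pairs
    upper_km: float  # observed max
    midpoint_km: float
    n_pairs: int
    pairs: tuple[tuple[int, int], ...] = field(repr=False, default=())
    r_m: float | None = None
    p_value: float | None = None
    testable: bool = True
    significant: bool = False


def equal_count_classes(d_geo: DistanceMatrix, k: int) -> list[DistanceClass]:
    """Partition upper-triangle pairs into k equal-count distance classes.

    Pairs are sorted by distance ascending (stable; ties broken by
    (row, column) index); the first ceil(N/k) ranks go to class 1, the
    next ceil(N/k) to class 2, …, the final class takes the remainder.
    Bounds are the observed min/max distances within each class.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    ii, jj = d_geo.pair_index_arrays()
    dist = d_geo.values[ii, jj]
    n_pairs = len(dist)
    if k > n_pairs:
        raise ValidationError(f"k={k} exceeds number of pairs {n_pairs}")
    per_class = math.ceil(n_pairs / k)
    last = n_pairs - (k - 1) * per_class
    if last < 1:
        raise ValidationError(
            f"k={k} leaves an empty final class under ceiling-first sizing "
            f"(N={n_pairs})"
        )
    order = np.lexsort((jj, ii, dist))  # distance, then row, then column
    classes: list[DistanceClass] = []
    start = 0
    for c in range(k):
        size = per_class if c < k - 1 else last
        sel = order[start : start + size]
        start += size
        lo = float(dist[sel].min())
        hi = float(dist[sel].max())
        classes.append(
            DistanceClass(
                index=c + 1,
                lower_km=lo,
                upper_km=hi,
                midpoint_km=(lo + hi) / 2.0,
                n_pairs=size,
                pairs=tuple((int(ii[s]), int(jj[s])) for s in sel),
            )
        )
    return classes


@dataclass(frozen=True)
class CorrelogramResult:
    """Full Mantel correlogram: per-class tests plus the global decision rule."""

    classes: tuple[DistanceClass, ...]
    k: int
    alpha: float
    n_total_pairs: int
    n_permutations: int
    seed: int | None
    tail: Tail = "greater"
    variant: Variant = "restricted"

    def __post_init__(self) -> None:
        if sum(c.n_pairs for c in self.classes) != self.n_total_pairs:
            raise ValidationError("class sizes do not sum to total pair count")

    @property
    def corrected_alpha(self) -> float:
        """Bonferroni level alpha/k, unrounded."""
        return self.alpha / self.k

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.classes)

    @property
    def n_testable(self) -> int:
        return sum(c.testable for c in self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_index": [c.index for c in self.classes],
                "lower_km": [c.lower_km for c in self.classes],
                "upper_km": [c.upper_km for c in self.classes],
                "midpoint_km": [c.midpoint_km for c in self.classes],
                "n_pairs": [c.n_pairs for c in self.classes],
                "r_M": [c.r_m for c in self.classes],
                "p_value": [c.p_value for c in self.classes],
                "testable": [c.testable for c in self.classes],
                "significant": [c.significant for c in self.classes],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\n")
            fh.write(f"# alpha={self.alpha}\n")
            fh.write(f"# corrected_alpha={self.corrected_alpha!r}\n")
            fh.write(f"# n_permutations={self.n_permutations}\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write(f"# tail={self.tail}\n")
            fh.write(f"# variant={self.variant}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def plot(self, ax=None):
        """Correlogram plot: class-midpoint vs r_M, significant classes filled."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = [c.midpoint_km for c in self.classes if c.testable]
        ys = [c.r_m for c in self.classes if c.testable]
        sig = [c.significant for c in self.classes if c.testable]
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.plot(xs, ys, "-", color="black", lw=1)
        for x, y, s in zip(xs, ys, sig):
            ax.plot(x, y, "D", mfc="black" if s else "white", mec="black")
        ax.set_xlabel("distance class midpoint (km)")
        ax.set_ylabel("Mantel $r_M$")
        return ax


_FLIP: dict[str, Tail] = {"greater": "less", "less": "greater", "two-sided": "two-sided"}


def _membership_test(
    d_gen: DistanceMatrix,
    cls: DistanceClass,
    n_permutations: int,
    tail: Tail,
    seed,
) -> MantelResult:
    """Indicator-variant per-class test.

    Builds the 0/1 membership matrix for the class and correlates it with
    genetic distance over *all* pairs; the sign is flipped so that
    genetically-similar pairs concentrated in a class yield positive r_M
    (the classical correlogram orientation).
    """
    n = len(d_gen)
    ind = np.zeros((n, n))
    for i, j in cls.pairs:
        ind[i, j] = ind[j, i] = 1.0
    d_ind = DistanceMatrix(d_gen.ids, ind)
    res = mantel_test(
        d_ind, d_gen, n_permutations=n_permutations, tail=_FLIP[tail], seed=seed
    )
    if not res.testable:
        return res
    return replace(res, r_m=-res.r_m, tail=tail)


def mantel_correlogram(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    tail: Tail = "greater",
    variant: Variant = "restricted",
) -> CorrelogramResult:
    """Build and test a Mantel correlogram of genetic vs geographic distance.

    One seed drives all per-class tests through independent substreams
    (the class index is mixed into the seed sequence), so the p-value of
    class i does not depend on how many other classes exist.
    """
    require_same_ids(d_gen, d_geo)
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    n_total = d_geo.n_pairs
    k = sturges_class_count(n_total)
    skeletons = equal_count_classes(d_geo, k)
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
    corrected = alpha / k
    classes: list[DistanceClass] = []
    for cls in skeletons:
        sub = np.random.SeedSequence(seed, spawn_key=(cls.index,))
        if variant == "restricted":
            res = mantel_test(
                d_gen,
                d_geo,
                n_permutations=n_permutations,
                tail=tail,
                seed=sub,
                pair_mask=cls.pairs,
            )
        elif variant == "membership":
            res = _membership_test(d_gen, cls, n_permutations, tail, sub)
        else:
            raise ValidationError(f"unknown correlogram variant {variant!r}")
        classes.append(
            replace(
                cls,
                r_m=res.r_m,
                p_value=res.p_value,
                testable=res.testable,
                significant=bool(res.testable and res.p_value < corrected),
            )
        )
    return CorrelogramResult(
        classes=tuple(classes),
        k=k,
        alpha=alpha,
        n_total_pairs=n_total,
        n_permutations=n_permutations,
        seed=seed,
        tail=tail,
        variant=variant,
    )
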