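"""Labelled symmetric distance matrices and their TSV dialects.

A :class:`DistanceMatrix` holds an ordered tuple of ids and a square,
symmetric, hollow (zero-diagonal), nonnegative float matrix.  Genetic
matrices additionally carry ``counts`` — the per-pair number of alignment
columns that were comparable (pairwise deletion), needed for provenance.

Two on-disk dialects are supported:

* square labelled TSV — ids in the first row and first column;
* long-format TSV — one ``id1 <tab> id2 <tab> distance`` row per
  unordered pair (upper triangle only).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["DistanceMatrix"]

_SYM_ATOL = 1e-8


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        vals = np.asarray(self.values, dtype=float)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValidationError("duplicate ids in distance matrix")
        if vals.shape != (n, n):
            raise ValidationError(
                f"matrix shape {vals.shape} does not match {n} ids"
            )
        if not np.allclose(vals, vals.T, atol=_SYM_ATOL, equal_nan=False):
            raise ValidationError("matrix is not symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValidationError("matrix diagonal is not zero")
        if np.any(vals < 0):
            raise ValidationError("matrix has negative entries")
        vals = (vals + vals.T) / 2.0  # exact symmetry
        np.fill_diagonal(vals, 0.0)
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)
        if self.counts is not None:
            cnt = np.asarray(self.counts)
            if cnt.shape != (n, n):
                raise ValidationError("counts shape does not match ids")
            cnt = cnt.copy()
            cnt.flags.writeable = False
            object.__setattr__(self, "counts", cnt)

    # -- basic API ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        n = len(self.ids)
        return n * (n - 1) // 2

    def index(self, id_: str) -> int:
        try:
            return self.ids.index(id_)
        except ValueError:
            raise ValidationError(f"id {id_!r} not in matrix") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.index(p) for p in pair)
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        """Condensed vector of off-diagonal entries, row-major (i < j)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def pair_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) index arrays matching :meth:`upper_triangle` order."""
        return np.triu_indices(len(self.ids), k=1)

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.index(i) for i in ids])
        cnt = self.counts[np.ix_(idx, idx)] if self.counts is not None else None
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)], cnt)

    def same_ids(self, other: "DistanceMatrix") -> bool:
        return self.ids == other.ids

    # -- IO ----------------------------------------------------------------

    def to_square_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError("row and column ids disagree in square TSV")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))

    def to_long_tsv(self, path: str | Path) -> None:
        ii, jj = self.pair_index_arrays()
        df = pd.DataFrame(
            {
                "id1": [self.ids[i] for i in ii],
                "id2": [self.ids[j] for j in jj],
                "distance": self.values[ii, jj],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
        ids: list[str] = []
        for col in ("id1", "id2"):
            for v in df[col]:
                if v not in ids:
                    ids.append(v)
        n = len(ids)
        pos = {v: k for k, v in enumerate(ids)}
        vals = np.zeros((n, n))
        for a, b, d in zip(df["id1"], df["id2"], df["distance"]):
            vals[pos[a], pos[b]] = d
            vals[pos[b], pos[a]] = d
        return cls(tuple(ids), vals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DistanceMatrix(n={len(self.ids)})"


def require_same_ids(a: DistanceMatrix, b: DistanceMatrix) -> None:
    if a.ids != b.ids:
        raise ValidationError("distance matrices do not share ids/order")
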