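"""Aligned sequences, column filtering and uncorrected genetic distances.

The :class:`Alignment` keeps the character matrix as a fixed-width numpy
byte array plus the original column indices still in effect, so every
filtering step is a column slice that preserves provenance.

Distances are uncorrected p-distances with pairwise deletion: for each
pair of rows, only columns where *both* characters are unambiguous bases
(A/C/G/T) are compared, and the distance is mismatches over comparable
columns.  Gaps and IUPAC ambiguity codes never count as matches or
mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distmat import DistanceMatrix
from .exceptions import (
    AlignmentShapeError,
    FormatError,
    NoColumnsError,
    ValidationError,
)

__all__ = [
    "Alignment",
    "read_alignment",
    "write_alignment",
    "base_frequency_filter",
    "p_distance_matrix",
    "select_hypervariable",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _normalize_rows(rows: np.ndarray) -> np.ndarray:
    """Uppercase, '.'→'-', U→T."""
    flat = rows.tobytes().upper().replace(b".", b"-").replace(b"U", b"T")
    return np.frombuffer(flat, dtype="S1").reshape(rows.shape)


@dataclass(frozen=True)
class Alignment:
    ids: tuple[str, ...]
    rows: np.ndarray  # (n_seqs, n_cols) dtype S1, normalized
    retained_columns: np.ndarray  # original indices of current columns

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sequence ids in alignment")
        rows = np.asarray(self.rows, dtype="S1")
        if rows.ndim != 2 or rows.shape[0] != len(ids):
            raise ValidationError("alignment row/ids mismatch")
        cols = np.asarray(self.retained_columns, dtype=int)
        if cols.shape != (rows.shape[1],):
            raise ValidationError("retained_columns length != number of columns")
        if cols.size and (np.any(np.diff(cols) <= 0) or cols[0] < 0):
            raise ValidationError("retained_columns must be strictly increasing, nonnegative")
        rows = rows.copy()
        rows.flags.writeable = False
        cols = cols.copy()
        cols.flags.writeable = False
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "retained_columns", cols)

    @classmethod
    def from_strings(cls, ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        if len(ids) != len(seqs):
            raise ValidationError("ids and sequences differ in number")
        if not seqs:
            raise FormatError("empty alignment")
        length = len(seqs[0])
        for sid, s in zip(ids, seqs):
            if len(s) != length:
                raise AlignmentShapeError(
                    f"record {sid!r} has length {len(s)}, expected {length}"
                )
        rows = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
        rows = _normalize_rows(rows)
        return cls(tuple(ids), rows, np.arange(length))

    # -- views -------------------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def sequence(self, sid: str) -> str:
        try:
            i = self.ids.index(sid)
        except ValueError:
            raise ValidationError(f"unknown sequence id {sid!r}") from None
        return self.rows[i].tobytes().decode()

    def take_columns(self, which: np.ndarray) -> "Alignment":
        """New alignment keeping columns at positions ``which`` (current indexing)."""
        which = np.asarray(which, dtype=int)
        return Alignment(self.ids, self.rows[:, which], self.retained_columns[which])

    def base_code_matrix(self) -> np.ndarray:
        """Rows encoded A,C,G,T → 0..3; gaps/ambiguity → 4."""
        codes = np.full(self.rows.shape, 4, dtype=np.int8)
        for k, b in enumerate(_BASES):
            codes[self.rows == b] = k
        return codes


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned multi-FASTA (≥2 records, equal lengths)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise FormatError(f"{path}: an alignment needs at least 2 records")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Alignment.from_strings(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for sid in aln.ids:
            fh.write(f">{sid}\n")
            seq = aln.sequence(sid)
            for start in range(0, len(seq), wrap):
                fh.write(seq[start : start + wrap] + "\n")


def _column_base_counts(aln: Alignment) -> np.ndarray:
    """(4, n_cols) counts of A,C,G,T per column."""
    codes = aln.base_code_matrix()
    return np.stack([(codes == k).sum(axis=0) for k in range(4)])


def base_frequency_filter(
    aln: Alignment,
    threshold: float = 0.30,
    count_gaps: bool = False,
) -> Alignment:
    """Keep columns whose modal unambiguous base is frequent enough.

    The frequency of the modal base is taken over the column's non-gap,
    non-ambiguous characters (``count_gaps=False``, the usual
    base-frequency-filter semantics), or over all rows when
    ``count_gaps=True``.  Columns with no unambiguous base at all
    (all gap/ambiguity) are always removed.  The boundary is inclusive:
    a column at exactly ``threshold`` is retained.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    counts = _column_base_counts(aln)
    total = counts.sum(axis=0)
    denom = np.full(aln.n_columns, aln.n_sequences) if count_gaps else total
    with np.errstate(invalid="ignore", divide="ignore"):
        modal_freq = np.where(denom > 0, counts.max(axis=0) / denom, 0.0)
    keep = (total > 0) & (modal_freq >= threshold)
    if not keep.any():
        raise NoColumnsError(
            f"no columns survive base-frequency filter at threshold {threshold}"
        )
    return aln.take_columns(np.flatnonzero(keep))


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected p-distance matrix with pairwise deletion.

    Distance(i, j) = mismatches / comparable columns, where a column is
    comparable iff both rows carry an unambiguous base there.  The number
    of comparable columns per pair is returned in ``counts``.
    """
    if aln.n_sequences < 2:
        raise ValidationError("need at least 2 sequences for distances")
    if aln.n_columns < 1:
        raise NoColumnsError("alignment has no columns")
    codes = aln.base_code_matrix()
    valid = (codes < 4).astype(np.float64)
    # matches(i,j) = sum over columns of [codes_i == codes_j == base b]
    matches = np.zeros((aln.n_sequences, aln.n_sequences))
    for k in range(4):
        is_b = (codes == k).astype(np.float64)
        matches += is_b @ is_b.T
    comparable = valid @ valid.T
    off = ~np.eye(aln.n_sequences, dtype=bool)
    if np.any(comparable[off] < 1):
        ii, jj = np.nonzero((comparable < 1) & off)
        pair = (aln.ids[ii[0]], aln.ids[jj[0]])
        raise ValidationError(
            f"sequence pair {pair} shares no comparable columns"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (comparable - matches) / comparable
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 1.0)
    return DistanceMatrix(aln.ids, dist, counts=comparable.astype(int))


def column_entropies(aln: Alignment) -> np.ndarray:
    """Shannon entropy (nats) of each column over unambiguous bases only."""
    counts = _column_base_counts(aln).astype(float)
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, counts / total, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=0)


def select_hypervariable(aln: Alignment, top_fraction: float) -> Alignment:
    """Keep the most variable fraction of columns, ranked by entropy.

    A tree-free stand-in for selecting the 16S hypervariable regions when
    the alignment's region coordinates are unknown: columns are ranked by
    Shannon entropy over their unambiguous bases (gaps excluded) and the
    top ``top_fraction`` are kept, ties broken toward the lower column
    index.  Kept columns stay in positional order.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if aln.n_columns < 1:
        raise NoColumnsError("alignment has no columns")
    ent = column_entropies(aln)
    if np.all(ent <= 0.0):
        raise NoColumnsError("no variable columns: all columns are constant")
    n_keep = int(np.ceil(top_fraction * aln.n_columns))
    # stable sort by (-entropy, index): ties favour the earlier column
    order = np.lexsort((np.arange(aln.n_columns), -ent))
    chosen = np.sort(order[:n_keep])
    return aln.take_columns(chosen)
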