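"""Isolation-by-distance model: data in, fitted results out.

:class:`IsolationByDistance` pairs a genetic and a geographic distance
matrix over the same sequences; :meth:`~IsolationByDistance.fit` runs
the global Mantel permutation test and the Mantel correlogram and
returns an :class:`IBDResults` carrying the estimates, per-class table,
and a printable summary.  Constructors build the model from an alignment
plus site metadata, or straight from files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import (
    Alignment,
    base_frequency_filter,
    p_distance_matrix,
    read_alignment,
    select_hypervariable,
)
from .correlogram import CorrelogramResult, Variant, mantel_correlogram
from .distmat import DistanceMatrix
from .exceptions import ValidationError
from .geo import EARTH_RADIUS_KM, SeqSiteMap, SiteTable, build_geo_matrix
from .mantel import MantelResult, Tail, mantel_test

__all__ = ["IsolationByDistance", "IBDResults", "summarize_pairs"]


class IsolationByDistance:
    """Genetic vs geographic distance over a set of georeferenced sequences.

    Parameters
    ----------
    d_genetic : DistanceMatrix
        Uncorrected genetic distances (proportion of differing sites).
    d_geographic : DistanceMatrix
        Great-circle distances in km; must cover the same ids (it is
        reordered to the genetic matrix's id order if necessary).
    """

    def __init__(self, d_genetic: DistanceMatrix, d_geographic: DistanceMatrix):
        if set(d_genetic.ids) != set(d_geographic.ids):
            raise ValidationError("genetic and geographic matrices cover different ids")
        if d_geographic.ids != d_genetic.ids:
            d_geographic = d_geographic.reorder(d_genetic.ids)
        self.d_genetic = d_genetic
        self.d_geographic = d_geographic
        #: metadata recorded by the constructors (filter settings etc.)
        self.provenance: dict = {}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_alignment(
        cls,
        aln: Alignment,
        sites: SiteTable,
        seq_map: SeqSiteMap,
        base_freq_threshold: float = 0.30,
        hypervariable_fraction: float | None = None,
        radius_km: float = EARTH_RADIUS_KM,
    ) -> "IsolationByDistance":
        """Filter the alignment, compute both distance matrices, build the model."""
        filtered = base_frequency_filter(aln, threshold=base_freq_threshold)
        if hypervariable_fraction is not None:
            filtered = select_hypervariable(filtered, hypervariable_fraction)
        missing = sorted(set(filtered.ids) - set(seq_map.sequence_ids))
        if missing:
            raise ValidationError(f"sequences with no site mapping: {missing}")
        d_gen = p_distance_matrix(filtered)
        sub_map = SeqSiteMap(
            seq_map.frame[seq_map.frame["sequence_id"].isin(filtered.ids)]
        )
        d_geo = build_geo_matrix(sites, sub_map, radius_km=radius_km).reorder(
            d_gen.ids
        )
        model = cls(d_gen, d_geo)
        model.provenance = {
            "n_sequences": filtered.n_sequences,
            "n_columns_input": aln.n_columns,
            "n_columns_retained": filtered.n_columns,
            "base_freq_threshold": base_freq_threshold,
            "hypervariable_fraction": hypervariable_fraction,
            "radius_km": radius_km,
        }
        return model

    @classmethod
    def from_files(
        cls,
        alignment_path: str | Path,
        sites_path: str | Path,
        seq_map_path: str | Path,
        **kwargs,
    ) -> "IsolationByDistance":
        aln = read_alignment(alignment_path)
        sites = SiteTable.from_csv(sites_path)
        seq_map = SeqSiteMap.from_csv(seq_map_path)
        return cls.from_alignment(aln, sites, seq_map, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        tail: Tail = "greater",
        seed: int | None = None,
        variant: Variant = "restricted",
        include_same_site_pairs: bool = True,
    ) -> "IBDResults":
        """Run the global Mantel test and the Mantel correlogram.

        ``include_same_site_pairs=False`` drops zero-geographic-distance
        pairs from the global test (the correlogram always keeps them:
        they form the within-site class).
        """
        if seed is None:
            seed = int(np.random.default_rng().integers(2**31))
        mask = None
        if not include_same_site_pairs:
            ii, jj = self.d_geographic.pair_index_arrays()
            nz = self.d_geographic.values[ii, jj] > 0
            mask = list(zip(ii[nz], jj[nz]))
        global_result = mantel_test(
            self.d_genetic,
            self.d_geographic,
            n_permutations=n_permutations,
            tail=tail,
            seed=np.random.SeedSequence(seed, spawn_key=(0,)),
            pair_mask=mask,
        )
        corr = mantel_correlogram(
            self.d_genetic,
            self.d_geographic,
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed,
            tail=tail,
            variant=variant,
        )
        return IBDResults(
            model=self,
            global_mantel=global_result,
            correlogram=corr,
            alpha=alpha,
            seed=seed,
        )


@dataclass(frozen=True)
class IBDResults:
    """Fitted isolation-by-distance analysis."""

    model: IsolationByDistance
    global_mantel: MantelResult
    correlogram: CorrelogramResult
    alpha: float
    seed: int

    # -- tables ------------------------------------------------------------

    def pairs_table(self) -> pd.DataFrame:
        """Long-format (id1, id2, geo_km, p_distance) over all pairs."""
        dm = self.model.d_genetic
        ii, jj = dm.pair_index_arrays()
        return pd.DataFrame(
            {
                "id1": [dm.ids[i] for i in ii],
                "id2": [dm.ids[j] for j in jj],
                "geo_km": self.model.d_geographic.values[ii, jj],
                "p_distance": dm.values[ii, jj],
            }
        )

    def binned_pairs(self, **kwargs) -> pd.DataFrame:
        return summarize_pairs(self.model.d_genetic, self.model.d_geographic, **kwargs)

    def summary(self) -> str:
        """Human-readable run summary."""
        g = self.global_mantel
        lines = [
            "Isolation-by-distance analysis",
            "==============================",
            f"sequences: {len(self.model.d_genetic)}"
            f"    pairwise comparisons: {self.model.d_genetic.n_pairs}",
            f"max geographic distance: {self.model.d_geographic.values.max():.0f} km",
            "",
            "Global Mantel test",
        ]
        if g.testable:
            lines.append(
                f"  r_M = {g.r_m:.4f}    P = {g.p_value:.4g}"
                f"    ({g.n_permutations} permutations, tail={g.tail})"
            )
        else:
            lines.append("  untestable: no variation in one distance matrix")
        c = self.correlogram
        lines += [
            "",
            f"Mantel correlogram ({c.variant} variant)",
            f"  k = {c.k} equal-count distance classes (Sturge's rule)"
            f"    corrected alpha = {c.corrected_alpha:.3g}",
            f"  significant classes: {c.n_significant} of {c.k}"
            f"    ({c.k - c.n_testable} untestable)",
            "",
        ]
        with pd.option_context("display.width", 120):
            frame = c.to_frame().round(
                {"lower_km": 1, "upper_km": 1, "midpoint_km": 1, "r_M": 4}
            )
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    # -- plots -------------------------------------------------------------

    def plot_correlogram(self, ax=None):
        return self.correlogram.plot(ax=ax)

    def plot_scatter(self, ax=None):
        """Genetic vs geographic distance, point size by pair multiplicity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        binned = self.binned_pairs()
        sizes = {"1": 10, "2": 25, "3-4": 45, "5": 70, ">5": 100}
        ax.scatter(
            binned["geo_km"],
            binned["p_distance"],
            s=[sizes.get(b, 10) for b in binned["size_bin"]],
            facecolors="none",
            edgecolors="black",
        )
        ax.set_xlabel("geographic distance (km)")
        ax.set_ylabel("genetic distance (p-distance)")
        return ax


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = []
    lo = 1
    for hi in edges:
        labels.append(f"{lo}" if lo == hi else f"{lo}-{hi}")
        lo = hi + 1
    labels.append(f">{edges[-1]}")
    return labels


def summarize_pairs(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    bin_edges: Sequence[int] = (1, 2, 4, 5),
    km_decimals: int = 0,
    p_decimals: int = 4,
) -> pd.DataFrame:
    """Scatter-plot support table: identical points grouped and size-binned.

    Pairs are grouped after display rounding (km to ``km_decimals``,
    p-distance to ``p_decimals``); each distinct point gets its
    multiplicity and a size bin from the edge list (default bins
    1, 2, 3-4, 5, >5).
    """
    if d_gen.ids != d_geo.ids:
        raise ValidationError("matrices must share ids and order")
    ii, jj = d_gen.pair_index_arrays()
    df = pd.DataFrame(
        {
            "geo_km": np.round(d_geo.values[ii, jj], km_decimals),
            "p_distance": np.round(d_gen.values[ii, jj], p_decimals),
        }
    )
    grouped = (
        df.groupby(["geo_km", "p_distance"]).size().reset_index(name="count")
    )
    labels = _bin_labels(bin_edges)
    cuts = np.searchsorted(np.asarray(bin_edges), grouped["count"], side="left")
    grouped["size_bin"] = [labels[c] for c in cuts]
    return grouped.sort_values(["geo_km", "p_distance"]).reset_index(drop=True)
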