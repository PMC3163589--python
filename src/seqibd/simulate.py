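"""Synthetic georeferenced sequence datasets with tunable isolation by distance.

The generator emulates the shape of a global 16S rRNA survey: a modest
number of sites scattered uniformly over the sphere (pairwise
separations up to ~19,000 km), a few sequences per site, ~1.3 kb aligned
sequences, and small total divergence (pairwise p-distances within a few
percent).  A single knob, ``ibd_strength`` in [0, 1], moves the expected
divergence of a pair from pure pair-level noise (0, the null) to a
linear function of the pair's geographic distance (1, strong isolation
by distance).

Realization: target expected p-distances for every pair are

    t_ij = max_p_distance * [ibd_strength * geo_ij / max(geo)
                             + (1 - ibd_strength) * u_ij]  + eps_ij

with u_ij ~ U(0,1) i.i.d. per pair and eps_ij ~ N(0, noise_sd²), the sum
clipped to [0, max_p_distance].  A neighbor-joining tree is fitted to
the target matrix and sequences are evolved from a random root along it,
each branch substituting each site independently (to a uniformly chosen
different base) with probability equal to the branch length.  A
pairwise-target matrix is generally not exactly realizable by any single
set of sequences; the NJ tree is the additive matrix closest to it in
the usual agglomerative sense, and the function returns the exact
tree-implied expected p-distance matrix as ground truth, so realized
mismatch counts are binomial around the returned expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _nj

from .alignment import Alignment
from .distmat import DistanceMatrix
from .exceptions import ValidationError
from .geo import SeqSiteMap, SiteTable, build_geo_matrix

__all__ = [
    "SyntheticConfig",
    "generate_sites",
    "generate_ibd_dataset",
    "generate_null_dataset",
    "write_dataset",
]

_BASES = "ACGT"
# per-branch substitution probability must stay below the Jukes-Cantor
# saturation point 3/4 for the channel composition to be well defined
_MAX_BRANCH = 0.74


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults: ~15 global sites, 4 sequences each, 1.3 kb,
    ≤4% divergence, moderate spatial signal."""

    n_sites: int = 15
    seqs_per_site: int | Sequence[int] = 4
    seq_length: int = 1300
    ibd_strength: float = 0.5
    noise_sd: float = 0.005
    max_p_distance: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValidationError("n_sites must be >= 2")
        per_site = self.per_site_counts()
        if any(c < 1 for c in per_site):
            raise ValidationError("seqs_per_site entries must be positive")
        if sum(per_site) < 4:
            raise ValidationError("need at least 4 sequences in total")
        if self.seq_length < 1:
            raise ValidationError("seq_length must be positive")
        if not (0.0 <= self.ibd_strength <= 1.0):
            raise ValidationError("ibd_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not (0.0 < self.max_p_distance < 1.0):
            raise ValidationError("max_p_distance must be in (0, 1)")

    def per_site_counts(self) -> list[int]:
        if isinstance(self.seqs_per_site, int):
            return [self.seqs_per_site] * self.n_sites
        counts = list(self.seqs_per_site)
        if len(counts) != self.n_sites:
            raise ValidationError(
                "seqs_per_site list length must equal n_sites"
            )
        return counts


def _sample_sites(n_sites: int, rng: np.random.Generator) -> SiteTable:
    # uniform on the sphere: longitude uniform, sine of latitude uniform
    lat = np.degrees(np.arcsin(rng.uniform(-1.0, 1.0, n_sites)))
    lon = rng.uniform(-180.0, 180.0, n_sites)
    lon[lon <= -180.0] = 180.0
    width = len(str(n_sites))
    records = [
        (f"S{i + 1:0{width}d}", float(lat[i]), float(lon[i]), "synthetic site")
        for i in range(n_sites)
    ]
    return SiteTable.from_records(records)


def generate_sites(n_sites: int, seed: int | None = None) -> SiteTable:
    """Sample ``n_sites`` locations uniformly on the sphere."""
    if n_sites < 2:
        raise ValidationError("n_sites must be >= 2")
    return _sample_sites(n_sites, np.random.default_rng(seed))


def _target_matrix(
    cfg: SyntheticConfig, geo: DistanceMatrix, rng: np.random.Generator
) -> np.ndarray:
    n = len(geo)
    ii, jj = geo.pair_index_arrays()
    gmax = float(geo.values.max())
    if gmax <= 0:
        raise ValidationError("all sites coincide: no geographic variation")
    gnorm = geo.values[ii, jj] / gmax
    u = rng.uniform(0.0, 1.0, len(ii))
    eps = rng.normal(0.0, cfg.noise_sd, len(ii)) if cfg.noise_sd > 0 else 0.0
    t = cfg.max_p_distance * (
        cfg.ibd_strength * gnorm + (1.0 - cfg.ibd_strength) * u
    ) + eps
    t = np.clip(t, 0.0, cfg.max_p_distance)
    T = np.zeros((n, n))
    T[ii, jj] = t
    T[jj, ii] = t
    return T


def _fit_tree(T: np.ndarray, ids: Sequence[str]):
    tree = _nj(_SkbioDM(T, list(ids)))
    for node in tree.traverse():
        if node.length is not None:
            node.length = float(min(max(node.length, 0.0), _MAX_BRANCH))
    return tree


def _evolve(tree, ids: Sequence[str], length: int, rng: np.random.Generator):
    root_codes = rng.integers(0, 4, length)
    tip_codes: dict[str, np.ndarray] = {}

    def walk(node, seq):
        if node.length:
            hit = rng.random(length) < node.length
            n_hit = int(hit.sum())
            if n_hit:
                seq = seq.copy()
                # uniform over the three other bases
                seq[hit] = (seq[hit] + 1 + rng.integers(0, 3, n_hit)) % 4
        if node.is_tip():
            tip_codes[node.name] = seq
        else:
            for child in node.children:
                walk(child, seq)

    walk(tree, root_codes)
    lut = np.frombuffer(b"ACGT", dtype="S1")
    rows = np.stack([lut[tip_codes[i]] for i in ids])
    return Alignment(tuple(ids), rows, np.arange(length))


def _expected_p_distances(tree, ids: Sequence[str]) -> DistanceMatrix:
    """Exact expected p-distance under the per-branch substitution model.

    Each branch of probability b is a Jukes-Cantor channel whose
    mismatch eigenvalue is (1 - 4b/3); channels compose along the path,
    so E[p_ij] = 3/4 (1 - prod(1 - 4 b/3)).  Computed by summing
    -log(1 - 4b/3) along paths.
    """
    warped = tree.copy()
    for node in warped.traverse():
        if node.length is not None:
            node.length = -np.log(1.0 - (4.0 / 3.0) * min(node.length, _MAX_BRANCH))
    td = warped.tip_tip_distances(list(ids))
    expected = 0.75 * (1.0 - np.exp(-td.data))
    np.fill_diagonal(expected, 0.0)
    return DistanceMatrix(tuple(ids), expected)


def generate_ibd_dataset(
    cfg: SyntheticConfig,
) -> tuple[Alignment, SeqSiteMap, SiteTable, DistanceMatrix]:
    """Generate one synthetic dataset.

    Returns (alignment, sequence→site map, site table, ground-truth
    expected p-distance matrix).  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _sample_sites(cfg.n_sites, rng)
    per_site = cfg.per_site_counts()
    mapping: dict[str, str] = {}
    for site_id, count in zip(sites.site_ids, per_site):
        for t in range(count):
            mapping[f"{site_id}_seq{t + 1}"] = site_id
    seq_map = SeqSiteMap.from_mapping(mapping)
    geo = build_geo_matrix(sites, seq_map)
    T = _target_matrix(cfg, geo, rng)
    tree = _fit_tree(T, geo.ids)
    aln = _evolve(tree, geo.ids, cfg.seq_length, rng)
    truth = _expected_p_distances(tree, geo.ids)
    return aln, seq_map, sites, truth


def generate_null_dataset(
    cfg: SyntheticConfig,
) -> tuple[Alignment, SeqSiteMap, SiteTable, DistanceMatrix]:
    """Same as :func:`generate_ibd_dataset` with ``ibd_strength`` forced to 0."""
    return generate_ibd_dataset(replace(cfg, ibd_strength=0.0))


def write_dataset(
    out_dir: str | Path,
    aln: Alignment,
    seq_map: SeqSiteMap,
    sites: SiteTable,
    truth: DistanceMatrix | None = None,
) -> dict[str, Path]:
    """Write a generated dataset in the formats the pipeline consumes."""
    from .alignment import write_alignment

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "sites": out / "sites.csv",
        "seq_map": out / "seq_map.csv",
    }
    write_alignment(aln, paths["alignment"])
    sites.to_csv(paths["sites"])
    seq_map.to_csv(paths["seq_map"])
    if truth is not None:
        paths["truth"] = out / "true_expected_divergence.tsv"
        truth.to_square_tsv(paths["truth"])
    return paths
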