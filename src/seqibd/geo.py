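"""Geographic distance matrices from georeferenced sampling sites.

Sites live in a :class:`SiteTable` (decimal degrees, south and west
negative); sequences are tied to sites by a :class:`SeqSiteMap`.
Great-circle distances use the haversine formula on a sphere whose
default radius, 6378.388 km, is the classical international-ellipsoid
equatorial value used by the common geostatistics great-circle routines,
so distances line up with what field ecologists typically report.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .exceptions import ValidationError

__all__ = [
    "EARTH_RADIUS_KM",
    "SiteTable",
    "SeqSiteMap",
    "great_circle_distance",
    "build_geo_matrix",
    "parse_coordinate_string",
]

#: Default sphere radius in km (international ellipsoid equatorial radius).
EARTH_RADIUS_KM = 6378.388


def _check_lat(lat: float, field: str = "latitude") -> float:
    lat = float(lat)
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"{field} {lat} outside [-90, 90]")
    return lat


def _check_lon(lon: float, field: str = "longitude") -> float:
    lon = float(lon)
    if not (-180.0 < lon <= 180.0):
        raise ValidationError(f"{field} {lon} outside (-180, 180]")
    return lon


def normalize_longitude(lon: float) -> float:
    """Wrap any longitude into (-180, 180]."""
    lon = float(lon)
    wrapped = ((lon - 180.0) % -360.0) + 180.0
    if wrapped <= -180.0:
        wrapped += 360.0
    return wrapped


_COORD_RE = re.compile(
    r"^\s*([0-9.]+)\s*([NSns])[,;]?\s+([0-9.]+)\s*([EWew])\s*$"
)


def parse_coordinate_string(text: str) -> tuple[float, float]:
    """Parse ``"73.21 S 66.97 E"``-style strings into signed decimal degrees.

    South latitudes and west longitudes come out negative.
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise ValidationError(f"cannot parse coordinate string {text!r}")
    lat = float(m.group(1)) * (1 if m.group(2).upper() == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4).upper() == "E" else -1)
    return _check_lat(lat), _check_lon(lon)


@dataclass(frozen=True)
class SiteTable:
    """Georeferenced sampling locations keyed by unique site id."""

    frame: pd.DataFrame  # columns: site_id, latitude, longitude, label

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"site_id", "latitude", "longitude"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"site table missing columns {sorted(missing)}")
        if "label" not in df.columns:
            df["label"] = ""
        df["site_id"] = df["site_id"].astype(str)
        if df["site_id"].duplicated().any():
            dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
            raise ValidationError(f"duplicate site ids: {dups}")
        for _, row in df.iterrows():
            _check_lat(row["latitude"], f"latitude of site {row['site_id']}")
            _check_lon(row["longitude"], f"longitude of site {row['site_id']}")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float] | tuple[str, float, float, str]]
    ) -> "SiteTable":
        rows = []
        for rec in records:
            site_id, lat, lon, *rest = rec
            rows.append(
                {
                    "site_id": site_id,
                    "latitude": lat,
                    "longitude": lon,
                    "label": rest[0] if rest else "",
                }
            )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteTable":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        self.frame.to_csv(path, sep=sep, index=False)

    def coordinates(self, site_id: str) -> tuple[float, float]:
        sel = self.frame[self.frame["site_id"] == str(site_id)]
        if sel.empty:
            raise ValidationError(f"unknown site id {site_id!r}")
        row = sel.iloc[0]
        return float(row["latitude"]), float(row["longitude"])

    @property
    def site_ids(self) -> list[str]:
        return self.frame["site_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SeqSiteMap:
    """Mapping from sequence id to the site it was sampled at."""

    frame: pd.DataFrame  # columns: sequence_id, site_id

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = {"sequence_id", "site_id"} - set(df.columns)
        if missing:
            raise ValidationError(f"sequence map missing columns {sorted(missing)}")
        df["sequence_id"] = df["sequence_id"].astype(str)
        df["site_id"] = df["site_id"].astype(str)
        if df["sequence_id"].duplicated().any():
            dups = df.loc[df["sequence_id"].duplicated(), "sequence_id"].tolist()
            raise ValidationError(f"duplicate sequence ids: {dups}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SeqSiteMap":
        return cls(
            pd.DataFrame(
                {"sequence_id": list(mapping), "site_id": list(mapping.values())}
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeqSiteMap":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        self.frame.to_csv(path, sep=sep, index=False)

    def site_of(self, sequence_id: str) -> str:
        sel = self.frame[self.frame["sequence_id"] == str(sequence_id)]
        if sel.empty:
            raise ValidationError(f"sequence {sequence_id!r} has no site mapping")
        return str(sel.iloc[0]["site_id"])

    @property
    def sequence_ids(self) -> list[str]:
        return self.frame["sequence_id"].tolist()

    def validate_against(self, sites: SiteTable) -> None:
        known = set(sites.site_ids)
        bad = sorted(set(self.frame["site_id"]) - known)
        if bad:
            raise ValidationError(f"sequence map references unknown sites: {bad}")

    def __len__(self) -> int:
        return len(self.frame)


def great_circle_distance(
    lat1: float,
    lon1: float,
    lat2: float,
    lon2: float,
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Haversine great-circle distance in km between two points.

    Haversine is numerically stable for nearby points where the spherical
    law of cosines loses precision; the two agree beyond any printed
    precision at these scales.
    """
    if radius_km <= 0:
        raise ValidationError(f"radius_km must be positive, got {radius_km}")
    lat1 = _check_lat(lat1, "lat1")
    lat2 = _check_lat(lat2, "lat2")
    lon1 = _check_lon(lon1, "lon1")
    lon2 = _check_lon(lon2, "lon2")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2) - math.radians(lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    a = min(1.0, max(0.0, a))
    return 2.0 * radius_km * math.asin(math.sqrt(a))


def site_distance_matrix(
    sites: SiteTable, radius_km: float = EARTH_RADIUS_KM
) -> DistanceMatrix:
    """Great-circle distance matrix over the sites themselves."""
    lat = np.radians(sites.frame["latitude"].to_numpy(float))
    lon = np.radians(sites.frame["longitude"].to_numpy(float))
    dphi = lat[:, None] - lat[None, :]
    dlmb = lon[:, None] - lon[None, :]
    a = (
        np.sin(dphi / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlmb / 2) ** 2
    )
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(sites.site_ids), d)


def build_geo_matrix(
    sites: SiteTable,
    seq_map: SeqSiteMap,
    radius_km: float = EARTH_RADIUS_KM,
) -> DistanceMatrix:
    """Geographic distance matrix over *sequence* ids.

    Entry (i, j) is the great-circle distance between the sites the two
    sequences were sampled at; sequences from the same site get 0.
    """
    seq_map.validate_against(sites)
    site_dm = site_distance_matrix(sites, radius_km)
    site_pos = {s: k for k, s in enumerate(sites.site_ids)}
    seq_ids = seq_map.sequence_ids
    idx = np.array([site_pos[seq_map.site_of(s)] for s in seq_ids])
    vals = site_dm.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(seq_ids), vals)
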