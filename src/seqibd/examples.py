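"""Worked-example data: a global survey of glacier *Polaromonas* phylotypes.

Sampling sites (decimal degrees) and the GenBank 16S rRNA accessions
recorded at each, from a published global survey of glacier and
periglacial *Polaromonas* phylotypes on six continents.  One glacier
(John Evans, Nunavut) was reported with two slightly different
coordinate fixes by two studies; both are kept as distinct sites.

The sequences themselves are not bundled — fetching and re-aligning them
is an external recipe (see the README) — but the site geometry alone
supports the geographic half of the analysis, e.g. the maximum pairwise
separation of ~18,830 km between John Evans Glacier in the high Arctic
and Collins Glacier in Antarctica.
"""

from __future__ import annotations

from .geo import SeqSiteMap, SiteTable

__all__ = ["glacier_survey_sites", "glacier_survey_accessions", "glacier_survey_map"]

# site_id, latitude, longitude, label
_SITES = [
    ("A", 63.39, -149.91, "Toklat Glacier, Alaska, USA"),
    ("B", 58.435837, -134.5546, "Mendenhall Glacier, Alaska, USA"),
    ("C", 40.057276, -105.6432, "Arikaree Glacier, Colorado, USA"),
    ("D", -13.770123, -71.07002, "Cordillera Vilcanota, Peru"),
    ("E1", 79.66, -74.0, "John Evans Glacier, Nunavut, Canada"),
    ("E2", 79.63, -74.38, "John Evans Glacier, Nunavut, Canada (second fix)"),
    ("F", 47.42, 10.98, "Schneeferner Glacier, Germany"),
    ("G", 43.15, 86.87, "Glacier No. 1, Tian Shan, China"),
    ("H", 28.7210, 83.9155, "Zuntal glacial valley, Nepal"),
    ("I", 33.89, 89.15, "Puruogangri ice field, Tibet, China"),
    ("J1", -45.51, 170.14, "Fox Glacier, New Zealand"),
    ("J2", -43.48, 170.21, "Franz Josef Glacier, New Zealand"),
    ("K", -82.25, -145.0, "Kamb Ice Stream, Antarctica"),
    ("L", -73.21, 66.97, "Collins Glacier, Antarctica"),
]

# GenBank accessions per site.
_ACCESSIONS = {
    "A": [f"JF7193{n}" for n in range(24, 29)]
    + [f"JF7193{n}" for n in range(31, 39)]
    + ["JF729309"],
    "B": ["GQ396863", "GQ396949", "GQ396971"],
    "C": ["JF719322", "JF719323", "JF719329"],
    "D": ["GQ306091"],
    "E1": ["DQ228409", "DQ228403"],
    "E2": [f"DQ6289{n}" for n in range(32, 41)] + ["DQ530258"],
    "F": ["EU978852"],
    "G": ["EF423322", "EF423325", "EF423330", "EF423333", "EF423340",
          "FJ979854", "FJ979859"],
    "H": ["JF719330"],
    "I": ["DQ227793"],
    "J1": ["AY315176", "AY315177"],
    "J2": ["AY315174", "AY315175", "AY315178"],
    "K": ["FJ477327"],
    "L": [f"EU63602{n}" for n in range(4, 10)],
}


def glacier_survey_sites() -> SiteTable:
    """Site table for the global glacier survey (14 georeferenced sites)."""
    return SiteTable.from_records(_SITES)


def glacier_survey_accessions() -> dict[str, list[str]]:
    """GenBank accession ids grouped by site id."""
    return {k: list(v) for k, v in _ACCESSIONS.items()}


def glacier_survey_map() -> SeqSiteMap:
    """Sequence→site map with accession ids as sequence ids."""
    mapping = {
        acc: site for site, accs in _ACCESSIONS.items() for acc in accs
    }
    return SeqSiteMap.from_mapping(mapping)
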