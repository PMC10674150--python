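"""Offline place lookup and keyword-based hospital classification.

This module replaces the reverse-geocoding web service used in production
geofencing systems: a :class:`Gazetteer` maps a coordinate to the array of
nearby named, categorized places, and :func:`classify_places` decides
whether that array denotes a hospital using versioned include/exclude
keyword dictionaries.

The classification contract: a location is HOSPITAL when at least one
nearby place's name or category contains an include keyword and no nearby
place matches an exclude keyword; it is HEALTH_NONHOSPITAL when an include
keyword matched but an exclude keyword also matched (a gym or pharmacy
tagged "health", say); otherwise OTHER. Matching is case-insensitive
substring matching on lowercased text.

Dictionaries are versioned by study day, so iterative refinements of the
exclusion list (adding gym/pharmacy/dentist terms partway through a study)
are represented as data rather than code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .geo import haversine_m

__all__ = [
    "Classification",
    "Place",
    "KeywordDictionary",
    "PlaceQueryResult",
    "Gazetteer",
    "GazetteerParseError",
    "load_gazetteer",
    "load_dictionaries",
    "classify_places",
    "active_dictionary",
]

DEFAULT_QUERY_RADIUS_M = 300.0


class Classification(str, Enum):
    HOSPITAL = "HOSPITAL"
    HEALTH_NONHOSPITAL = "HEALTH_NONHOSPITAL"
    OTHER = "OTHER"


class GazetteerParseError(ValueError):
    """Raised for malformed gazetteer records; names the offending record."""


@dataclass(frozen=True)
class Place:
    """A named, categorized point location."""

    place_id: str
    name: str
    categories: frozenset[str]
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise GazetteerParseError(f"place {self.place_id!r}: latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise GazetteerParseError(f"place {self.place_id!r}: longitude {self.lon} outside [-180, 180]")
        if not self.categories:
            raise GazetteerParseError(f"place {self.place_id!r}: categories must be non-empty")
        object.__setattr__(self, "categories", frozenset(c.lower() for c in self.categories))


@dataclass(frozen=True)
class KeywordDictionary:
    """One version of the include/exclude keyword lists.

    ``effective_from_day`` is the study day (0-based) on which this
    version becomes active; versions are selected with
    :func:`active_dictionary`.
    """

    version_id: str
    effective_from_day: int
    include: frozenset[str]
    exclude: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", frozenset(t.lower() for t in self.include))
        object.__setattr__(self, "exclude", frozenset(t.lower() for t in self.exclude))
        if not self.include:
            raise ValueError(f"dictionary {self.version_id!r}: include list must be non-empty")
        overlap = self.include & self.exclude
        if overlap:
            raise ValueError(f"dictionary {self.version_id!r}: terms in both include and exclude: {sorted(overlap)}")


@dataclass(frozen=True)
class PlaceQueryResult:
    """Places within the query radius (nearest first) and their classification."""

    places: tuple[Place, ...]
    classification: Classification


def _place_matches(place: Place, terms: frozenset[str]) -> bool:
    text = [place.name.lower(), *place.categories]
    return any(term in t for term in terms for t in text)


def classify_places(
    places: Sequence[Place],
    kdict: KeywordDictionary,
    exclusion_scope: str = "array",
) -> Classification:
    """Classify an array of nearby places as HOSPITAL / HEALTH_NONHOSPITAL / OTHER.

    ``exclusion_scope="array"`` (default): a single excluded place anywhere
    in the array suppresses HOSPITAL. ``"place"``: only the include-matching
    places themselves are tested against the exclusion list, so a true
    hospital co-located with a gym still classifies as HOSPITAL.
    """
    if exclusion_scope not in ("array", "place"):
        raise ValueError(f"exclusion_scope must be 'array' or 'place', got {exclusion_scope!r}")
    include_hits = [p for p in places if _place_matches(p, kdict.include)]
    if not include_hits:
        return Classification.OTHER
    if exclusion_scope == "array":
        excluded = any(_place_matches(p, kdict.exclude) for p in places)
    else:
        excluded = all(_place_matches(p, kdict.exclude) for p in include_hits)
    return Classification.HEALTH_NONHOSPITAL if excluded else Classification.HOSPITAL


def active_dictionary(versions: Sequence[KeywordDictionary], study_day: int) -> KeywordDictionary:
    """Return the dictionary version in force on ``study_day``.

    The version with the largest ``effective_from_day`` <= study_day wins;
    the boundary day itself uses the new version.
    """
    if not versions:
        raise ValueError("no dictionary versions supplied")
    ordered = sorted(versions, key=lambda v: v.effective_from_day)
    days = [v.effective_from_day for v in ordered]
    if any(a >= b for a, b in zip(days, days[1:])):
        raise ValueError("effective_from_day values must be strictly increasing across versions")
    if study_day < ordered[0].effective_from_day:
        raise ValueError(
            f"study day {study_day} precedes the first dictionary version (day {ordered[0].effective_from_day})"
        )
    current = ordered[0]
    for v in ordered[1:]:
        if v.effective_from_day <= study_day:
            current = v
    return current


class Gazetteer:
    """A queryable collection of :class:`Place`, indexed for radius queries."""

    def __init__(self, places: Iterable[Place]):
        self.places: list[Place] = list(places)
        ids = [p.place_id for p in self.places]
        if len(set(ids)) != len(ids):
            raise GazetteerParseError("duplicate place_id in gazetteer")
        self._lat = np.array([p.lat for p in self.places], dtype=float)
        self._lon = np.array([p.lon for p in self.places], dtype=float)

    def __len__(self) -> int:
        return len(self.places)

    def query(self, lat: float, lon: float, radius_m: float = DEFAULT_QUERY_RADIUS_M) -> list[Place]:
        """All places within ``radius_m``, nearest first; ties broken by place_id."""
        if radius_m <= 0:
            raise ValueError("radius_m must be positive")
        if not self.places:
            return []
        d = haversine_m(lat, lon, self._lat, self._lon)
        d = np.atleast_1d(d)
        idx = np.nonzero(d <= radius_m)[0]
        hits = sorted(idx, key=lambda i: (d[i], self.places[i].place_id))
        return [self.places[i] for i in hits]

    def query_classified(
        self,
        lat: float,
        lon: float,
        kdict: KeywordDictionary,
        radius_m: float = DEFAULT_QUERY_RADIUS_M,
        exclusion_scope: str = "array",
    ) -> PlaceQueryResult:
        places = self.query(lat, lon, radius_m)
        return PlaceQueryResult(tuple(places), classify_places(places, kdict, exclusion_scope))


def _place_from_feature(i: int, feature: dict) -> Place:
    try:
        geom = feature["geometry"]
        if geom["type"] != "Point":
            raise KeyError("geometry.type")
        lon, lat = geom["coordinates"][:2]
        props = feature["properties"]
        name = props["name"]
        categories = props["categories"]
        place_id = props.get("place_id", f"feature-{i}")
    except (KeyError, TypeError, IndexError) as exc:
        raise GazetteerParseError(f"feature #{i}: missing or malformed field ({exc})") from exc
    if isinstance(categories, str):
        categories = [c.strip() for c in categories.split(",") if c.strip()]
    return Place(place_id=str(place_id), name=str(name), categories=frozenset(categories), lat=float(lat), lon=float(lon))


def load_gazetteer(path: str | Path) -> Gazetteer:
    """Load a gazetteer from GeoJSON (FeatureCollection of points) or 5-column TSV.

    TSV columns: ``place_id  name  categories  lat  lon`` with categories
    comma-separated. The format is chosen by file extension (.tsv/.txt vs
    anything else treated as GeoJSON).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        places = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["place_id", "name", "categories", "lat", "lon"]
            if header != expected:
                raise GazetteerParseError(f"TSV header {header} != {expected}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 5:
                    raise GazetteerParseError(f"line {lineno}: expected 5 columns, got {len(cols)}")
                pid, name, cats, lat, lon = cols
                try:
                    place = Place(pid, name, frozenset(c.strip() for c in cats.split(",") if c.strip()),
                                  float(lat), float(lon))
                except ValueError as exc:
                    raise GazetteerParseError(f"line {lineno}: {exc}") from exc
                places.append(place)
        return Gazetteer(places)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GazetteerParseError("not a GeoJSON FeatureCollection")
    return Gazetteer(_place_from_feature(i, f) for i, f in enumerate(doc.get("features", [])))


def gazetteer_to_geojson(gaz: Gazetteer) -> dict:
    """Serialize a gazetteer back to a GeoJSON FeatureCollection dict."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                "properties": {"place_id": p.place_id, "name": p.name, "categories": sorted(p.categories)},
            }
            for p in gaz.places
        ],
    }


def load_dictionaries(path: str | Path) -> list[KeywordDictionary]:
    """Load versioned keyword dictionaries from YAML.

    Layout: a list of mappings with keys ``version_id``,
    ``effective_from_day``, ``include``, ``exclude``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    versions = [
        KeywordDictionary(
            version_id=str(entry["version_id"]),
            effective_from_day=int(entry["effective_from_day"]),
            include=frozenset(entry["include"]),
            exclude=frozenset(entry.get("exclude") or []),
        )
        for entry in doc
    ]
    return sorted(versions, key=lambda v: v.effective_from_day)


def default_dictionaries() -> list[KeywordDictionary]:
    """Illustrative three-version dictionary set.

    v0 includes broad "health" terms and no exclusions, so gyms and
    pharmacies tagged as health establishments raise false alerts; v1
    (active from study day 210) excludes common nonhospital health
    facilities; v2 (day 365) extends the exclusion list. These lists are
    synthetic examples of the iterative-refinement pattern, not a
    transcription of any production dictionary.
    """
    return [
        KeywordDictionary("v0", 0, frozenset({"hospital", "medical center", "health"}), frozenset()),
        KeywordDictionary(
            "v1", 210,
            frozenset({"hospital", "medical center", "health"}),
            frozenset({"gym", "fitness", "pharmacy", "dentist"}),
        ),
        KeywordDictionary(
            "v2", 365,
            frozenset({"hospital", "medical center", "health"}),
            frozenset({"gym", "fitness", "pharmacy", "dentist", "aesthetic", "spa", "veterinar"}),
        ),
    ]
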