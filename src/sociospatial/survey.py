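"""Survey-side domain model: participants, well-being scores, activity
reports, gazetteers, and the file formats they travel in.

Scores
------
Three standardized health measures live on every participant:

* ``mcs`` — mental component score (SF-12v2 style), 0-100, higher = better;
* ``pcs`` — physical component score, 0-100, higher = better;
* ``isolation`` — perceived social isolation, 0-100, higher = more isolated.

Missing scores are stored as ``None`` and flagged explicitly; they are never
silently replaced by zero, and downstream support-score / density analyses
exclude the participant with a logged warning.

File formats
------------
* Participants: CSV with header ``id,community,home_x,home_y,mcs,pcs,isolation``.
* Activity reports: CSV with header
  ``participant_id,category,travel_min_low,travel_min_high,frequency``.
* Gazetteer: GeoJSON FeatureCollection of Point features with properties
  ``id`` and ``category``, or a CSV with ``id,category,x,y``. Coordinates are
  planar metres throughout (see :mod:`sociospatial.geo` for the lon/lat
  helper).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "WellBeingScores",
    "Participant",
    "ActivityReport",
    "Place",
    "Gazetteer",
    "TRAVEL_BINS",
    "FREQUENCIES",
    "read_participants",
    "write_participants",
    "read_activity_reports",
    "write_activity_reports",
    "read_gazetteer",
    "write_gazetteer",
    "inverse_health_score",
]

#: The fixed travel-time bins (minutes) a respondent can report.
TRAVEL_BINS: tuple[tuple[int, int], ...] = ((0, 10), (11, 20), (21, 30), (31, 40))

#: The fixed visit-frequency vocabulary.
FREQUENCIES: tuple[str, ...] = ("every_day", "once_a_week", "once_a_month")


def _check_score(name: str, value: float | None) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    v = float(value)
    if not (0.0 <= v <= 100.0):
        raise ValidationError(f"score '{name}' = {value!r} outside [0, 100]")
    return v


@dataclass(frozen=True)
class WellBeingScores:
    """Standardized well-being triplet; ``None`` marks a missing score."""

    mcs: float | None
    pcs: float | None
    isolation: float | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mcs", _check_score("mcs", self.mcs))
        object.__setattr__(self, "pcs", _check_score("pcs", self.pcs))
        object.__setattr__(self, "isolation", _check_score("isolation", self.isolation))

    def missing(self) -> tuple[str, ...]:
        """Names of the scores that are absent."""
        return tuple(
            n for n in ("mcs", "pcs", "isolation") if getattr(self, n) is None
        )


@dataclass(frozen=True)
class Participant:
    id: str
    community: str
    home: tuple[float, float]
    scores: WellBeingScores

    def __post_init__(self) -> None:
        x, y = self.home
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"participant {self.id!r}: non-finite home coordinates")


@dataclass(frozen=True)
class ActivityReport:
    participant_id: str
    category: str
    travel_bin: tuple[int, int]
    frequency: str

    def __post_init__(self) -> None:
        if tuple(self.travel_bin) not in TRAVEL_BINS:
            raise ValidationError(
                f"travel bin {self.travel_bin!r} not in the fixed set {TRAVEL_BINS}"
            )
        if self.frequency not in FREQUENCIES:
            raise ValidationError(
                f"frequency {self.frequency!r} not in {FREQUENCIES}"
            )


@dataclass(frozen=True)
class Place:
    id: str
    category: str
    location: tuple[float, float]

    def __post_init__(self) -> None:
        x, y = self.location
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"place {self.id!r}: non-finite coordinates")


class Gazetteer:
    """Ordered collection of places; the ordering defines the location-space
    index k = 0..L-1 used by location vectors.

    Places are kept sorted lexicographically by id so the index assignment is
    identical across runs and machines.
    """

    def __init__(self, places: Iterable[Place]):
        ordered = sorted(places, key=lambda p: p.id)
        seen: set[str] = set()
        for p in ordered:
            if p.id in seen:
                raise SchemaError(f"duplicate place id {p.id!r} in gazetteer")
            seen.add(p.id)
        self._places: tuple[Place, ...] = tuple(ordered)
        self._index: dict[str, int] = {p.id: k for k, p in enumerate(self._places)}

    @property
    def places(self) -> tuple[Place, ...]:
        return self._places

    def __len__(self) -> int:
        return len(self._places)

    def __iter__(self):
        return iter(self._places)

    def __contains__(self, place_id: str) -> bool:
        return place_id in self._index

    def __getitem__(self, place_id: str) -> Place:
        return self._places[self._index[place_id]]

    def index_of(self, place_id: str) -> int:
        return self._index[place_id]

    def by_category(self, category: str) -> tuple[Place, ...]:
        return tuple(p for p in self._places if p.category == category)

    def extended(self, extra: Iterable[Place]) -> "Gazetteer":
        """A new gazetteer with additional places (e.g. synthetic home
        entries) merged in; ordering is re-derived from ids."""
        return Gazetteer(list(self._places) + list(extra))

    def fingerprint(self) -> str:
        """Cheap identity of the location space, used to refuse cosine
        comparisons between vectors built against different gazetteers."""
        return f"L={len(self)};{self._places[0].id if self._places else ''};" + str(
            hash(tuple(p.id for p in self._places))
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Gazetteer) and self._places == other._places


# ---------------------------------------------------------------------------
# score transform


def inverse_health_score(mcs: float) -> float:
    """Invert a 0-100 well-being score so that *worse* well-being gets a
    *larger* value: HS = 100 - score.

    Used when a density surface or support score should up-weight people
    with poor mental (or physical) well-being, mirroring how the social
    isolation score already points in the "needs help" direction.
    """
    if mcs is None or (isinstance(mcs, float) and math.isnan(mcs)):
        raise ValidationError("inverse_health_score: score is missing")
    if not (0.0 <= mcs <= 100.0):
        raise ValidationError(f"inverse_health_score: {mcs!r} outside [0, 100]")
    return 100.0 - float(mcs)


# ---------------------------------------------------------------------------
# participants I/O

_PARTICIPANT_COLUMNS = ("id", "community", "home_x", "home_y", "mcs", "pcs", "isolation")


def read_participants(path: str | Path) -> list[Participant]:
    """Read a participant table (CSV). Row order is preserved.

    Raises :class:`SchemaError` for a missing required column or duplicate
    id, :class:`ValidationError` for a score outside [0, 100].
    """
    df = pd.read_csv(path, dtype={"id": str, "community": str})
    missing = [c for c in _PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participant file {path}: missing column(s) {missing}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"participant file {path}: duplicate id(s) {sorted(set(dupes))}")
    out: list[Participant] = []
    for row in df.itertuples(index=False):
        scores = WellBeingScores(
            mcs=None if pd.isna(row.mcs) else float(row.mcs),
            pcs=None if pd.isna(row.pcs) else float(row.pcs),
            isolation=None if pd.isna(row.isolation) else float(row.isolation),
        )
        out.append(
            Participant(
                id=str(row.id),
                community=str(row.community),
                home=(float(row.home_x), float(row.home_y)),
                scores=scores,
            )
        )
    return out


def write_participants(participants: Sequence[Participant], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in participants],
            "community": [p.community for p in participants],
            "home_x": [p.home[0] for p in participants],
            "home_y": [p.home[1] for p in participants],
            "mcs": [p.scores.mcs for p in participants],
            "pcs": [p.scores.pcs for p in participants],
            "isolation": [p.scores.isolation for p in participants],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# activity-report I/O

_REPORT_COLUMNS = (
    "participant_id",
    "category",
    "travel_min_low",
    "travel_min_high",
    "frequency",
)


def read_activity_reports(path: str | Path) -> list[ActivityReport]:
    df = pd.read_csv(path, dtype={"participant_id": str, "category": str, "frequency": str})
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"activity file {path}: missing column(s) {missing}")
    return [
        ActivityReport(
            participant_id=str(r.participant_id),
            category=str(r.category),
            travel_bin=(int(r.travel_min_low), int(r.travel_min_high)),
            frequency=str(r.frequency),
        )
        for r in df.itertuples(index=False)
    ]


def write_activity_reports(reports: Sequence[ActivityReport], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "category": [r.category for r in reports],
            "travel_min_low": [r.travel_bin[0] for r in reports],
            "travel_min_high": [r.travel_bin[1] for r in reports],
            "frequency": [r.frequency for r in reports],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gazetteer I/O


def read_gazetteer(path: str | Path) -> Gazetteer:
    """Read a gazetteer from GeoJSON (Point FeatureCollection) or CSV
    (columns ``id,category,x,y``); the returned index ordering is sorted by
    place id regardless of file order."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_gazetteer_geojson(path)
    return _read_gazetteer_csv(path)


def _read_gazetteer_geojson(path: Path) -> Gazetteer:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"gazetteer {path}: expected a GeoJSON FeatureCollection")
    places = []
    for feat in data.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError(
                f"gazetteer {path}: non-point geometry {geom.get('type')!r} "
                f"for feature {feat.get('properties', {}).get('id')!r}"
            )
        props = feat.get("properties") or {}
        if "id" not in props or "category" not in props:
            raise SchemaError(f"gazetteer {path}: feature missing id/category property")
        x, y = geom["coordinates"][:2]
        places.append(Place(id=str(props["id"]), category=str(props["category"]),
                            location=(float(x), float(y))))
    return Gazetteer(places)


def _read_gazetteer_csv(path: Path) -> Gazetteer:
    df = pd.read_csv(path, dtype={"id": str, "category": str})
    missing = [c for c in ("id", "category", "x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"gazetteer {path}: missing column(s) {missing}")
    return Gazetteer(
        Place(id=str(r.id), category=str(r.category), location=(float(r.x), float(r.y)))
        for r in df.itertuples(index=False)
    )


def write_gazetteer(gazetteer: Gazetteer, path: str | Path) -> None:
    """Write a gazetteer as GeoJSON (``.geojson``/``.json``) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [p.location[0], p.location[1]]},
                    "properties": {"id": p.id, "category": p.category},
                }
                for p in gazetteer
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(fc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        pd.DataFrame(
            {
                "id": [p.id for p in gazetteer],
                "category": [p.category for p in gazetteer],
                "x": [p.location[0] for p in gazetteer],
                "y": [p.location[1] for p in gazetteer],
            }
        ).to_csv(path, index=False, float_format="%.10g")
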