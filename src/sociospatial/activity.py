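"""From survey reports to location vectors.

A respondent does not report exact destinations — only a place *category*
("church", "shop", ...), a travel-time bin, and a visit-frequency category.
This module turns those reports into a per-participant **location vector**
V_i: a sparse vector over the gazetteer's location space whose entry V_ik is
the probability that participant i visits place k on a given day.

The geocoding proceeds in three steps:

1. *Home placement.* The home is registered to a (privacy-jittered) point;
   co-resident participants (couples) share one synthetic "home" gazetteer
   entry, which carries daily visit probability 1.
2. *Travel ring.* A reported travel-time bin becomes an annulus of
   reachable distance around the home. The default reachability model is
   Euclidean at a constant speed (800 m/min ≈ 48 km/h, rural driving); a
   precomputed participant→place reachability table can be plugged in for
   users with road networks. The printed bins (0-10, 11-20, ... minutes)
   are closed into contiguous annuli so every distance maps to exactly one
   bin.
3. *Visit probability.* Frequency maps to a daily probability (every day →
   1, once a week → 1/7, once a month → 1/30), prorated equally over all
   candidate places of the reported category inside the ring. When several
   reports land probability on the same place, daily visit events are
   treated as independent and combined as q = 1 − Π(1 − q_r), which keeps
   every entry a probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .geo import Point, distance, sample_disk
from .survey import ActivityReport, Gazetteer, Participant, Place, TRAVEL_BINS

__all__ = [
    "HOME_CATEGORY",
    "VectorConfig",
    "TravelRing",
    "LocationVector",
    "jitter_home",
    "travel_ring",
    "candidate_places",
    "visit_probability",
    "prorate",
    "build_location_vector",
    "build_location_vectors",
    "assign_home_places",
    "write_location_vectors",
    "read_location_vectors",
]

logger = logging.getLogger(__name__)

#: Category string used for synthetic per-household gazetteer entries.
HOME_CATEGORY = "home"

_VISIT_PROBABILITY = {
    "every_day": 1.0,
    "once_a_week": 1.0 / 7.0,
    "once_a_month": 1.0 / 30.0,
}


@dataclass(frozen=True)
class VectorConfig:
    """Parameters of the survey-to-vector step.

    speed_m_per_min
        Assumed travel speed for the Euclidean reachability default.
    home_jitter_radius_m
        Radius of the privacy jitter applied to each household's home
        coordinate (0 disables jittering, e.g. when homes were already
        jittered upstream).
    include_home_in_network / include_home_in_kde
        Whether the home entries participate in the co-location vectors
        used for the network, and in the density events, respectively.
        Homes are the only places with a stated probability of 1, so they
        dominate within-household similarity; density analysis typically
        wants *non-home* visits only.
    """

    speed_m_per_min: float = 800.0
    home_jitter_radius_m: float = 0.0
    include_home_in_network: bool = True
    include_home_in_kde: bool = False
    seed: int = 0
    #: Optional road-network override: (participant_id, place_id, bin) -> reachable?
    reachability: Callable[[str, Place, tuple[int, int]], bool] | None = None


@dataclass(frozen=True)
class TravelRing:
    """Annulus of distances reachable within a reported travel-time bin."""

    center: Point
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_inner < self.r_outer):
            raise ValidationError(
                f"travel ring requires 0 <= r_inner < r_outer, got "
                f"({self.r_inner}, {self.r_outer})"
            )

    def contains(self, point: Point) -> bool:
        d = distance(self.center, point)
        if self.r_inner == 0.0:
            return d <= self.r_outer
        return self.r_inner < d <= self.r_outer


@dataclass(frozen=True)
class LocationVector:
    """Sparse daily visit-probability vector over a gazetteer's places.

    Absent place id ⇒ probability 0. Every stored probability is in (0, 1].
    ``space`` is the fingerprint of the gazetteer the vector was indexed
    against; cosine comparisons across different spaces are refused.
    """

    owner: str
    probs: Mapping[str, float]
    space: str = ""

    def __post_init__(self) -> None:
        for pid, v in self.probs.items():
            if not (0.0 < v <= 1.0):
                raise ValidationError(
                    f"location vector for {self.owner!r}: V[{pid!r}] = {v} not in (0, 1]"
                )

    def drop_category(self, gazetteer: Gazetteer, category: str) -> "LocationVector":
        kept = {
            pid: v
            for pid, v in self.probs.items()
            if pid not in gazetteer or gazetteer[pid].category != category
        }
        return replace(self, probs=kept)


def jitter_home(
    centroid: Point, radius: float, seed: int | np.random.Generator
) -> Point:
    """Privacy jitter: a point uniform on the disk of ``radius`` metres
    about ``centroid``; deterministic for a fixed seed."""
    if radius < 0:
        raise ValidationError(f"jitter radius must be >= 0, got {radius}")
    if radius == 0:
        return (float(centroid[0]), float(centroid[1]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_disk(rng, centroid, radius)


def travel_ring(
    home: Point, travel_bin: tuple[int, int], speed_m_per_min: float
) -> TravelRing:
    """Annulus reachable from ``home`` within the reported bin at constant
    speed. Bins are made contiguous: (11, 20) min at 800 m/min becomes the
    annulus (8000, 16000] m, so bin edges leave no gap."""
    if speed_m_per_min <= 0:
        raise ValidationError(f"speed must be > 0, got {speed_m_per_min}")
    if tuple(travel_bin) not in TRAVEL_BINS:
        raise ValidationError(f"unknown travel bin {travel_bin!r}")
    low, high = travel_bin
    inner_min = 0.0 if low == 0 else float(low - 1)
    return TravelRing(
        center=(float(home[0]), float(home[1])),
        r_inner=inner_min * speed_m_per_min,
        r_outer=float(high) * speed_m_per_min,
    )


def candidate_places(
    gazetteer: Gazetteer, category: str, ring: TravelRing
) -> list[Place]:
    """All places of ``category`` inside the ring, ordered by place id
    (the gazetteer's own ordering). Empty result is valid."""
    return [p for p in gazetteer.by_category(category) if ring.contains(p.location)]


def visit_probability(frequency: str) -> float:
    """Daily visit probability for a reported frequency category:
    every_day → 1, once_a_week → 1/7, once_a_month → 1/30."""
    try:
        return _VISIT_PROBABILITY[frequency]
    except KeyError:
        raise ValidationError(f"unknown frequency {frequency!r}") from None


def prorate(p: float, candidates: Sequence[Place]) -> dict[str, float]:
    """Split a daily probability equally over the candidate places."""
    if not candidates:
        raise ValidationError("no candidate place to prorate over")
    share = p / len(candidates)
    return {place.id: share for place in candidates}


def _combine(acc: dict[str, float], contrib: Mapping[str, float]) -> None:
    # independent daily events: q = 1 - (1-q1)(1-q2)...
    for pid, q in contrib.items():
        if pid in acc:
            acc[pid] = 1.0 - (1.0 - acc[pid]) * (1.0 - q)
        else:
            acc[pid] = q


def build_location_vector(
    participant: Participant,
    reports: Iterable[ActivityReport],
    gazetteer: Gazetteer,
    config: VectorConfig = VectorConfig(),
    home_place: Place | None = None,
    space: str = "",
) -> tuple[LocationVector, list[ActivityReport]]:
    """Location vector for one participant.

    Returns the vector and the list of reports skipped because no candidate
    place matched (each is also logged). The home entry, when given, always
    carries probability 1.
    """
    probs: dict[str, float] = {}
    skipped: list[ActivityReport] = []
    for rep in reports:
        if rep.participant_id != participant.id:
            raise ValidationError(
                f"report for {rep.participant_id!r} passed to participant "
                f"{participant.id!r}"
            )
        if config.reachability is not None:
            cands = [
                p
                for p in gazetteer.by_category(rep.category)
                if config.reachability(participant.id, p, tuple(rep.travel_bin))
            ]
        else:
            ring = travel_ring(participant.home, rep.travel_bin, config.speed_m_per_min)
            cands = candidate_places(gazetteer, rep.category, ring)
        if not cands:
            logger.warning(
                "participant %s: no candidate %r place in travel ring %s; report skipped",
                participant.id, rep.category, rep.travel_bin,
            )
            skipped.append(rep)
            continue
        _combine(probs, prorate(visit_probability(rep.frequency), cands))
    if home_place is not None:
        probs[home_place.id] = 1.0
    return LocationVector(owner=participant.id, probs=probs, space=space), skipped


def assign_home_places(
    participants: Sequence[Participant],
    jitter_radius: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, Place], list[Place]]:
    """One synthetic gazetteer entry per household.

    Participants with identical home coordinates (couples) form a household
    and share a single home place. An optional privacy jitter displaces
    each household once, so co-residents stay co-located. Returns the
    participant→home-place map and the list of distinct home places.
    Household numbering follows the order in which homes first appear in
    the participant table, so output is deterministic for a fixed input.
    """
    rng = np.random.default_rng(seed)
    household_of: dict[tuple[float, float], Place] = {}
    places: list[Place] = []
    mapping: dict[str, Place] = {}
    for p in participants:
        key = (p.home[0], p.home[1])
        if key not in household_of:
            loc = jitter_home(p.home, jitter_radius, rng) if jitter_radius > 0 else p.home
            place = Place(
                id=f"home-{len(places):04d}", category=HOME_CATEGORY,
                location=(float(loc[0]), float(loc[1])),
            )
            household_of[key] = place
            places.append(place)
        mapping[p.id] = household_of[key]
    return mapping, places


def build_location_vectors(
    participants: Sequence[Participant],
    reports: Sequence[ActivityReport],
    gazetteer: Gazetteer,
    config: VectorConfig = VectorConfig(),
) -> tuple[dict[str, LocationVector], Gazetteer, list[ActivityReport]]:
    """Vectors for a whole survey.

    Builds per-household home entries, extends the gazetteer with them
    (defining the full location space), and geocodes every participant's
    reports. Returns (vectors by participant id, extended gazetteer,
    skipped reports).
    """
    home_of, home_places = assign_home_places(
        participants, jitter_radius=config.home_jitter_radius_m, seed=config.seed
    )
    extended = gazetteer.extended(home_places)
    space = extended.fingerprint()
    by_pid: dict[str, list[ActivityReport]] = {p.id: [] for p in participants}
    for rep in reports:
        if rep.participant_id not in by_pid:
            raise ValidationError(
                f"activity report references unknown participant {rep.participant_id!r}"
            )
        by_pid[rep.participant_id].append(rep)
    vectors: dict[str, LocationVector] = {}
    all_skipped: list[ActivityReport] = []
    for p in participants:
        # candidate lookup uses the real gazetteer; homes never match a
        # reported category, so passing `extended` would be equivalent
        vec, skipped = build_location_vector(
            p, by_pid[p.id], gazetteer, config, home_place=home_of[p.id], space=space
        )
        vectors[p.id] = vec
        all_skipped.extend(skipped)
    return vectors, extended, all_skipped


# ---------------------------------------------------------------------------
# long-format CSV I/O


def write_location_vectors(
    vectors: Mapping[str, LocationVector], path
) -> None:
    """Emit vectors as long-format CSV: participant_id,place_id,probability."""
    import pandas as pd

    rows = [
        (owner, pid, prob)
        for owner, vec in vectors.items()
        for pid, prob in sorted(vec.probs.items())
    ]
    pd.DataFrame(rows, columns=["participant_id", "place_id", "probability"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_location_vectors(path, space: str = "") -> dict[str, LocationVector]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"participant_id": str, "place_id": str})
    out: dict[str, LocationVector] = {}
    for owner, grp in df.groupby("participant_id", sort=False):
        out[str(owner)] = LocationVector(
            owner=str(owner),
            probs=dict(zip(grp["place_id"], grp["probability"].astype(float))),
            space=space,
        )
    return out
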