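"""Synthetic survey communities with known planted structure.

Real activity-survey data of this kind cannot be shared (home locations
are identifying), so this module generates fully synthetic communities in
the exact file formats the rest of the package consumes. The layout mimics
a small rural multi-community study: K communities of couples, each couple
sharing a home scattered around a community centre, with activity reports
drawn over the categories {church, restaurant, shop, friend, park}, the
frequency vocabulary {every_day, once_a_week, once_a_month} and the four
10-minute travel bins. Well-being scores are Normal(50, 10) clipped to
[0, 100].

Planted structure makes recovery testable end-to-end:

* a **hub** participant who reports every place category at every_day
  frequency — they should attain the top weighted degree centrality;
* an **isolated group** whose members get isolation scores at least two
  standard deviations above the mean and who all share an every-day visit
  that resolves uniquely to one **anchor place** — the top density hotspot
  should contain that place.

Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .geo import Point, sample_disk
from .survey import (
    ActivityReport,
    Gazetteer,
    Participant,
    Place,
    WellBeingScores,
    write_activity_reports,
    write_gazetteer,
    write_participants,
)

__all__ = ["CommunitySpec", "PlantedTruth", "SyntheticCommunity", "simulate", "truth_report"]

_DEFAULT_PLACES = {"church": 12, "restaurant": 10, "shop": 6, "friend": 9, "park": 6}
# qualitative ordering of reported activities: shopping most frequent,
# then eating out, visiting friends, church
_DEFAULT_CATEGORY_P = {"shop": 0.35, "restaurant": 0.25, "friend": 0.20, "church": 0.15, "park": 0.05}
_DEFAULT_FREQUENCY_P = {"every_day": 0.1, "once_a_week": 0.5, "once_a_month": 0.4}
_DEFAULT_BIN_P = {(0, 10): 0.70, (11, 20): 0.20, (21, 30): 0.07, (31, 40): 0.03}


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the generated study.

    Defaults mirror a three-community, 30-couple rural survey (60
    participants). ``planted_hub`` is a global participant index;
    ``planted_isolated_group`` is (size, anchor place category) and is
    planted in the first community.
    """

    n_communities: int = 3
    couples_per_community: int = 10
    places_per_category: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PLACES)
    )
    community_centers: tuple[Point, ...] | None = None
    community_radius: float = 2500.0
    place_scatter: float = 5000.0
    score_means: Mapping[str, float] = field(
        default_factory=lambda: {"mcs": 50.0, "pcs": 50.0, "isolation": 50.0}
    )
    score_sds: Mapping[str, float] = field(
        default_factory=lambda: {"mcs": 10.0, "pcs": 10.0, "isolation": 10.0}
    )
    reports_min: int = 3
    reports_max: int = 8
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_P)
    )
    frequency_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FREQUENCY_P)
    )
    travel_bin_probs: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_BIN_P)
    )
    planted_hub: int | None = None
    planted_isolated_group: tuple[int, str] | None = None
    seed: int = 0

    def centers(self) -> tuple[Point, ...]:
        if self.community_centers is not None:
            return tuple(self.community_centers)
        # default: communities on a ring of 30 km spacing
        k = self.n_communities
        if k == 1:
            return ((0.0, 0.0),)
        radius = 30_000.0 / (2.0 * math.sin(math.pi / k))
        return tuple(
            (radius * math.cos(2 * math.pi * m / k), radius * math.sin(2 * math.pi * m / k))
            for m in range(k)
        )

    def validate(self) -> None:
        if self.n_communities < 1 or self.couples_per_community < 1:
            raise ValidationError("counts must be positive")
        if self.community_radius <= 0:
            raise ValidationError("community_radius must be > 0")
        if any(c < 1 for c in self.places_per_category.values()):
            raise ValidationError("places_per_category counts must be positive")
        n = 2 * self.n_communities * self.couples_per_community
        if self.planted_hub is not None and not (0 <= self.planted_hub < n):
            raise ValidationError(f"planted_hub index {self.planted_hub} out of range")
        if self.planted_isolated_group is not None:
            size, cat = self.planted_isolated_group
            if cat not in self.places_per_category:
                raise ValidationError(f"anchor category {cat!r} has no places")
            if size > 2 * self.couples_per_community:
                raise ValidationError("planted isolated group larger than a community")
        if not (0 < self.reports_min <= self.reports_max):
            raise ValidationError("invalid reports_min/reports_max")


@dataclass(frozen=True)
class PlantedTruth:
    hub_id: str | None
    isolated_ids: tuple[str, ...]
    anchor_place_id: str | None
    anchor_location: Point | None


@dataclass(frozen=True)
class SyntheticCommunity:
    participants: tuple[Participant, ...]
    reports: tuple[ActivityReport, ...]
    gazetteer: Gazetteer
    truth: PlantedTruth


def _choice(rng: np.random.Generator, table: Mapping) -> object:
    keys = list(table.keys())
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def simulate(spec: CommunitySpec, out_dir: str | Path | None = None) -> SyntheticCommunity:
    """Generate a synthetic survey; optionally write the input files
    (participants.csv, activity.csv, gazetteer.geojson, truth.json) to
    ``out_dir``. Byte-identical output for identical (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = spec.centers()
    if len(centers) != spec.n_communities:
        raise ValidationError("community_centers length must equal n_communities")

    # --- gazetteer: round-robin places over communities -----------------
    places: list[Place] = []
    community_of_place: dict[str, int] = {}
    for cat in sorted(spec.places_per_category):
        for m in range(spec.places_per_category[cat]):
            comm = m % spec.n_communities
            loc = sample_disk(rng, centers[comm], spec.place_scatter)
            pid = f"{cat}-{m:03d}"
            places.append(Place(id=pid, category=cat, location=loc))
            community_of_place[pid] = comm

    anchor: Place | None = None
    if spec.planted_isolated_group is not None:
        _, anchor_cat = spec.planted_isolated_group
        # anchor sits at the first community's centre; rival places of the
        # same category are pushed out of reach of that community's
        # nearest travel ring so reports resolve uniquely to the anchor
        keep: list[Place] = []
        for p in places:
            if p.category != anchor_cat:
                keep.append(p)
                continue
            if anchor is None and community_of_place[p.id] == 0:
                anchor = Place(id=p.id, category=p.category, location=centers[0])
                keep.append(anchor)
            elif math.hypot(p.location[0] - centers[0][0], p.location[1] - centers[0][1]) < 12_000.0:
                far = centers[1 % len(centers)]
                keep.append(Place(id=p.id, category=p.category, location=sample_disk(rng, far, spec.place_scatter)))
            else:
                keep.append(p)
        if anchor is None:
            raise ValidationError("no place of the anchor category in the first community")
        places = keep
    gazetteer = Gazetteer(places)

    # --- participants ----------------------------------------------------
    participants: list[Participant] = []
    for comm in range(spec.n_communities):
        label = f"C{comm + 1}"
        for c in range(spec.couples_per_community):
            home = sample_disk(rng, centers[comm], spec.community_radius)
            for role in ("M", "F"):
                n = len(participants) + 1
                scores = WellBeingScores(
                    mcs=float(np.clip(rng.normal(spec.score_means["mcs"], spec.score_sds["mcs"]), 0, 100)),
                    pcs=float(np.clip(rng.normal(spec.score_means["pcs"], spec.score_sds["pcs"]), 0, 100)),
                    isolation=float(np.clip(rng.normal(spec.score_means["isolation"], spec.score_sds["isolation"]), 0, 100)),
                )
                participants.append(
                    Participant(id=f"{role}{n:02d}", community=label, home=home, scores=scores)
                )

    # --- planted isolated group (first community) ------------------------
    isolated_ids: tuple[str, ...] = ()
    if spec.planted_isolated_group is not None:
        size, anchor_cat = spec.planted_isolated_group
        comm_size = 2 * spec.couples_per_community
        pool = [i for i in range(comm_size) if i != (spec.planted_hub or -1)]
        chosen = pool[-size:]
        mu = spec.score_means["isolation"]
        sd = spec.score_sds["isolation"]
        for i in chosen:
            p = participants[i]
            iso = float(np.clip(mu + 2.0 * sd + abs(rng.normal(0.0, sd / 4.0)), 0, 100))
            participants[i] = Participant(
                id=p.id, community=p.community, home=p.home,
                scores=WellBeingScores(mcs=p.scores.mcs, pcs=p.scores.pcs, isolation=iso),
            )
        isolated_ids = tuple(participants[i].id for i in chosen)

    # --- activity reports -------------------------------------------------
    reports: list[ActivityReport] = []
    hub_id: str | None = None
    for idx, p in enumerate(participants):
        if spec.planted_hub is not None and idx == spec.planted_hub:
            hub_id = p.id
            for cat in sorted(spec.places_per_category):
                reports.append(
                    ActivityReport(p.id, cat, travel_bin=(0, 10), frequency="every_day")
                )
            continue
        n_rep = int(rng.integers(spec.reports_min, spec.reports_max + 1))
        for _ in range(n_rep):
            reports.append(
                ActivityReport(
                    p.id,
                    category=str(_choice(rng, spec.category_probs)),
                    travel_bin=tuple(_choice(rng, spec.travel_bin_probs)),
                    frequency=str(_choice(rng, spec.frequency_probs)),
                )
            )
        if p.id in isolated_ids:
            _, anchor_cat = spec.planted_isolated_group  # type: ignore[misc]
            reports.append(
                ActivityReport(p.id, anchor_cat, travel_bin=(0, 10), frequency="every_day")
            )

    truth = PlantedTruth(
        hub_id=hub_id,
        isolated_ids=isolated_ids,
        anchor_place_id=anchor.id if anchor is not None else None,
        anchor_location=anchor.location if anchor is not None else None,
    )
    result = SyntheticCommunity(
        participants=tuple(participants),
        reports=tuple(reports),
        gazetteer=gazetteer,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_participants(result.participants, out / "participants.csv")
        write_activity_reports(result.reports, out / "activity.csv")
        write_gazetteer(result.gazetteer, out / "gazetteer.geojson")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "hub_id": truth.hub_id,
                    "isolated_ids": list(truth.isolated_ids),
                    "anchor_place_id": truth.anchor_place_id,
                    "anchor_location": list(truth.anchor_location) if truth.anchor_location else None,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
    return result


def truth_report(
    truth: PlantedTruth,
    net=None,
    grid=None,
    spots=None,
    dyads=None,
) -> dict:
    """Recovery metrics of the planted structure from analysis outputs.

    Returns a dict with ``hub_dc_rank`` (1-based rank of the hub's
    weighted degree over all nodes), ``top_hotspot_contains_anchor``, and
    ``supporter_below_avg_isolation_fraction`` (fraction of isolated
    members whose best supporter is less isolated than the sample mean).
    Metrics whose inputs are absent are reported as ``None``.
    """
    from .network import best_supporter, weighted_degree

    out: dict = {
        "hub_dc_rank": None,
        "top_hotspot_contains_anchor": None,
        "supporter_below_avg_isolation_fraction": None,
    }
    if truth.hub_id is not None and net is not None:
        if truth.hub_id not in net:
            raise ValidationError(
                f"planted hub {truth.hub_id!r} not in the analysed network "
                "(outputs come from a different dataset?)"
            )
        dcs = sorted(
            (weighted_degree(net, i) for i in net.participants), reverse=True
        )
        hub_dc = weighted_degree(net, truth.hub_id)
        out["hub_dc_rank"] = 1 + sum(1 for d in dcs if d > hub_dc)
    if truth.anchor_location is not None and grid is not None and spots:
        anchor_cell = grid.cell_of(truth.anchor_location)
        out["top_hotspot_contains_anchor"] = spots[0].contains_cell(anchor_cell)
    if truth.isolated_ids and net is not None and dyads is not None:
        isos = [
            p.scores.isolation
            for p in net.participants.values()
            if p.scores.isolation is not None
        ]
        mean_iso = sum(isos) / len(isos)
        ok = 0
        found = 0
        for rid in truth.isolated_ids:
            if rid not in net:
                raise ValidationError(f"isolated member {rid!r} not in network")
            try:
                provider = best_supporter(rid, dyads)
            except Exception:
                continue
            found += 1
            prov_iso = net.participants[provider].scores.isolation
            if prov_iso is not None and prov_iso < mean_iso:
                ok += 1
        out["supporter_below_avg_isolation_fraction"] = (
            ok / found if found else None
        )
    return out
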