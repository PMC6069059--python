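"""Spatially weighted social network ("potential contact" network).

Two people who frequent the same places have a chance of meeting; the
degree of overlap between their activity spaces is therefore used as the
weight of an *inferred* social tie. For participants i and j with location
vectors V_i, V_j the edge weight is the cosine similarity

    w_ij = cos θ_ij = Σ_k V_ik V_jk / (‖V_i‖ ‖V_j‖)  ∈ [0, 1],

which is 1 for identical activity spaces and 0 for disjoint ones. On top
of the network this module derives the measures used to decide *who* an
intervention should involve:

* **weighted degree centrality** DC_i = Σ_{j≠i} w_ij — how widely a person
  potentially contacts others (the printed form of the sum would include a
  constant self term w_ii = 1; it is excluded here so isolates score 0);
* **leader ranking** — the most degree-central members among those in the
  top decile of the well-being distribution of their community;
* **support scores** SS_ij = w_ij · |HS_i − HS_j| — large when two people
  are likely to meet *and* differ strongly on a health measure, flagging
  who could support whom;
* **weighted betweenness** as an optional bridging measure.

Caveat: co-location implies *potential* face-to-face contact, not an
actual acquaintance; all measures inherit that interpretation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .activity import LocationVector
from .errors import MissingScoreError, NoSupporterError, SociospatialError, ValidationError
from .survey import Participant, WellBeingScores, inverse_health_score

__all__ = [
    "ColocationNetwork",
    "LeaderCandidate",
    "SupportDyad",
    "cosine_weight",
    "build_network",
    "weighted_degree",
    "rank_leaders",
    "select_leaders",
    "leaders_table",
    "support_score",
    "health_measure",
    "support_dyads",
    "best_supporter",
    "node_support_aggregate",
    "weighted_betweenness",
    "write_graphml",
    "edges_frame",
]

logger = logging.getLogger(__name__)


def cosine_weight(vi: LocationVector, vj: LocationVector) -> float:
    """Cosine similarity of two location vectors; 0 by convention when
    either vector is all-zero (no co-location evidence, no inferred tie)."""
    if vi.space and vj.space and vi.space != vj.space:
        raise ValidationError(
            f"location vectors for {vi.owner!r} and {vj.owner!r} were built "
            "against different gazetteers"
        )
    if not vi.probs or not vj.probs:
        return 0.0
    small, large = (vi.probs, vj.probs) if len(vi.probs) <= len(vj.probs) else (vj.probs, vi.probs)
    dot = sum(v * large.get(k, 0.0) for k, v in small.items())
    if dot == 0.0:
        return 0.0
    ni = math.sqrt(sum(v * v for v in vi.probs.values()))
    nj = math.sqrt(sum(v * v for v in vj.probs.values()))
    return dot / (ni * nj)


class ColocationNetwork:
    """n participants with symmetric co-location weights w_ij ∈ [0, 1].

    Zero-weight pairs are not stored but behave as weight 0; self-loops are
    never stored. Node attributes carry community and well-being scores.
    """

    def __init__(self, participants: Sequence[Participant]):
        self.participants: dict[str, Participant] = {}
        self.graph = nx.Graph()
        for p in participants:
            if p.id in self.participants:
                raise ValidationError(f"duplicate participant id {p.id!r}")
            self.participants[p.id] = p
            self.graph.add_node(
                p.id,
                community=p.community,
                mcs=float("nan") if p.scores.mcs is None else p.scores.mcs,
                pcs=float("nan") if p.scores.pcs is None else p.scores.pcs,
                isolation=float("nan") if p.scores.isolation is None else p.scores.isolation,
            )

    # -- basic queries ------------------------------------------------
    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, node: str) -> bool:
        return node in self.participants

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, i: str, j: str) -> float:
        if i not in self.participants or j not in self.participants:
            raise ValidationError(f"unknown node in weight({i!r}, {j!r})")
        if i == j:
            return 0.0
        data = self.graph.get_edge_data(i, j)
        return 0.0 if data is None else data["weight"]

    def set_weight(self, i: str, j: str, w: float) -> None:
        if i == j:
            raise ValidationError("self-loops are not stored")
        if not (0.0 <= w <= 1.0):
            raise ValidationError(f"weight {w} outside [0, 1]")
        if w > 0.0:
            self.graph.add_edge(i, j, weight=w)

    def communities(self) -> list[str]:
        return sorted({p.community for p in self.participants.values()})

    def members(self, community: str) -> list[Participant]:
        return [p for p in self.participants.values() if p.community == community]

    def subnetwork(self, community: str) -> "ColocationNetwork":
        """Within-community view: nodes filtered on the community label
        (cross-community edges are retained only in the full network)."""
        members = self.members(community)
        sub = ColocationNetwork(members)
        ids = {p.id for p in members}
        for i, j, data in self.graph.edges(data=True):
            if i in ids and j in ids:
                sub.graph.add_edge(i, j, weight=data["weight"])
        return sub


def build_network(
    vectors: Mapping[str, LocationVector], participants: Sequence[Participant]
) -> ColocationNetwork:
    """All n(n−1)/2 pairwise cosine weights; zero-weight pairs omitted from
    storage. Every participant must have a vector."""
    missing = [p.id for p in participants if p.id not in vectors]
    if missing:
        raise ValidationError(f"participants without location vectors: {missing}")
    net = ColocationNetwork(participants)
    ids = [p.id for p in participants]
    for a in range(len(ids)):
        vi = vectors[ids[a]]
        for b in range(a + 1, len(ids)):
            w = cosine_weight(vi, vectors[ids[b]])
            if w > 0.0:
                net.graph.add_edge(ids[a], ids[b], weight=min(w, 1.0))
    return net


def weighted_degree(net: ColocationNetwork, i: str) -> float:
    """DC_i = Σ_{j≠i} w_ij (self term excluded)."""
    if i not in net:
        raise ValidationError(f"unknown node {i!r}")
    return float(net.graph.degree(i, weight="weight"))


# ---------------------------------------------------------------------------
# leader ranking


@dataclass(frozen=True)
class LeaderCandidate:
    id: str
    community: str
    degree_centrality: float
    scores: WellBeingScores
    rank: int


def select_leaders(
    frame: pd.DataFrame,
    top_k: int = 2,
    decile: float = 0.1,
    well_being_column: str = "mcs",
    isolation_column: str | None = "isolation",
) -> pd.DataFrame:
    """Rank one community's candidate table.

    ``frame`` needs columns id, community, degree_centrality plus the score
    columns. Eligibility: well-being at or above its (1−decile) quantile
    within the community and, when ``isolation_column`` is given, isolation
    at or below its decile quantile. ``decile=1.0`` disables the filter and
    yields a pure degree-centrality ranking. Eligible rows are sorted by
    degree centrality descending, ties broken by higher well-being, then
    id; the top ``top_k`` are returned with a 1-based ``rank`` column.
    """
    if frame.empty:
        return frame.assign(rank=pd.Series(dtype=int))
    df = frame.dropna(subset=[well_being_column]).copy()
    wb_cut = df[well_being_column].quantile(1.0 - decile)
    eligible = df[well_being_column] >= wb_cut
    if isolation_column is not None and isolation_column in df.columns:
        iso = df[isolation_column].dropna()
        if not iso.empty:
            iso_ok = df[isolation_column].isna() | (
                df[isolation_column] <= iso.quantile(decile)
            )
            eligible &= iso_ok
    df = df[eligible]
    df = df.sort_values(
        by=["degree_centrality", well_being_column, "id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(top_k)
    df = df.reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def rank_leaders(
    net: ColocationNetwork,
    community: str,
    top_k: int = 2,
    decile: float = 0.1,
    well_being_column: str = "mcs",
    use_isolation_filter: bool = True,
) -> list[LeaderCandidate]:
    """Top-k leader candidates for one community: the most degree-central
    members within the top ``decile`` of the community's well-being
    distribution (and, by default, the low tail of its isolation
    distribution). Empty community → empty result."""
    members = net.members(community)
    if not members:
        return []
    frame = pd.DataFrame(
        {
            "id": [p.id for p in members],
            "community": community,
            "degree_centrality": [weighted_degree(net, p.id) for p in members],
            "mcs": [p.scores.mcs for p in members],
            "pcs": [p.scores.pcs for p in members],
            "isolation": [p.scores.isolation for p in members],
        }
    )
    picked = select_leaders(
        frame,
        top_k=top_k,
        decile=decile,
        well_being_column=well_being_column,
        isolation_column="isolation" if use_isolation_filter else None,
    )
    return [
        LeaderCandidate(
            id=row.id,
            community=community,
            degree_centrality=row.degree_centrality,
            scores=net.participants[row.id].scores,
            rank=int(row.rank),
        )
        for row in picked.itertuples(index=False)
    ]


def leaders_table(
    net: ColocationNetwork, top_k: int = 2, decile: float = 0.1, **kwargs
) -> pd.DataFrame:
    """Leader candidates for every community, one table."""
    rows = []
    for community in net.communities():
        for cand in rank_leaders(net, community, top_k=top_k, decile=decile, **kwargs):
            rows.append(
                {
                    "id": cand.id,
                    "community": cand.community,
                    "rank": cand.rank,
                    "degree_centrality": cand.degree_centrality,
                    "mcs": cand.scores.mcs,
                    "pcs": cand.scores.pcs,
                    "isolation": cand.scores.isolation,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["id", "community", "rank", "degree_centrality", "mcs", "pcs", "isolation"],
    )


# ---------------------------------------------------------------------------
# support scores and dyads


def health_measure(scores: WellBeingScores, measure: str) -> float:
    """HS value for a participant under a named measure.

    ``isolation`` is used as-is (higher already means worse); ``mental``
    and ``physical`` are inverted (HS = 100 − score) so that poor
    well-being gets the larger value."""
    if measure == "isolation":
        value = scores.isolation
        if value is None:
            raise MissingScoreError("isolation score missing")
        return value
    if measure == "mental":
        if scores.mcs is None:
            raise MissingScoreError("mental score missing")
        return inverse_health_score(scores.mcs)
    if measure == "physical":
        if scores.pcs is None:
            raise MissingScoreError("physical score missing")
        return inverse_health_score(scores.pcs)
    raise ValidationError(f"unknown measure {measure!r}")


def support_score(w_ij: float, hs_i: float, hs_j: float) -> float:
    """SS_ij = w_ij · |HS_i − HS_j|: high when contact is likely and the
    well-being gap is large."""
    if hs_i is None or hs_j is None:
        raise MissingScoreError("support_score: missing HS value")
    return w_ij * abs(hs_i - hs_j)


@dataclass(frozen=True)
class SupportDyad:
    receiver: str  # the participant with poor well-being
    provider: str
    support_score: float
    measure: str

    def __post_init__(self) -> None:
        if self.receiver == self.provider:
            raise ValidationError("support dyad cannot be a self-pair")


def _default_poor_rule(measure: str) -> Callable[[WellBeingScores], bool]:
    # "poor" = isolation above 50 or mental well-being under 50
    if measure == "isolation":
        return lambda s: s.isolation is not None and s.isolation > 50.0
    if measure == "mental":
        return lambda s: s.mcs is not None and s.mcs < 50.0
    if measure == "physical":
        return lambda s: s.pcs is not None and s.pcs < 50.0
    raise ValidationError(f"unknown measure {measure!r}")


def support_dyads(
    net: ColocationNetwork,
    measure: str = "isolation",
    poor_rule: Callable[[WellBeingScores], bool] | None = None,
    threshold: float = 1.0,
) -> list[SupportDyad]:
    """All support dyads for receivers flagged poor.

    For every participant the poor-rule flags (default: isolation > 50 for
    the isolation measure, score < 50 for mental/physical), every other
    participant with a usable score is a potential provider; dyads with
    SS > ``threshold`` are returned, sorted per receiver by SS descending
    (receivers in id order). Participants with the measure missing are
    excluded with a logged warning."""
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    rule = poor_rule if poor_rule is not None else _default_poor_rule(measure)
    hs: dict[str, float] = {}
    for pid, p in net.participants.items():
        try:
            hs[pid] = health_measure(p.scores, measure)
        except MissingScoreError:
            logger.warning("participant %s: %s measure missing; excluded from dyads",
                           pid, measure)
    dyads: list[SupportDyad] = []
    for rid in sorted(net.participants):
        if rid not in hs or not rule(net.participants[rid].scores):
            continue
        cands = []
        for pid in net.participants:
            if pid == rid or pid not in hs:
                continue
            ss = support_score(net.weight(rid, pid), hs[rid], hs[pid])
            if ss > threshold:
                cands.append(SupportDyad(rid, pid, ss, measure))
        cands.sort(key=lambda d: (-d.support_score, d.provider))
        dyads.extend(cands)
    return dyads


def best_supporter(receiver: str, dyads: Iterable[SupportDyad]) -> str:
    """Provider maximizing SS for the receiver; ties go to the provider id
    that sorts first. Raises :class:`NoSupporterError` if the receiver has
    no dyad."""
    mine = [d for d in dyads if d.receiver == receiver]
    if not mine:
        raise NoSupporterError(f"no supporter found for {receiver!r}")
    return min(mine, key=lambda d: (-d.support_score, d.provider)).provider


def node_support_aggregate(
    net: ColocationNetwork, measure: str = "isolation"
) -> dict[str, float]:
    """Node-level aggregate Σ_j w_ij·|HS_i − HS_j| — an opt-in variant that
    sums a node's support scores over all partners. Provided for
    exploration; the pairwise SS_ij is the primary quantity."""
    hs = {}
    for pid, p in net.participants.items():
        try:
            hs[pid] = health_measure(p.scores, measure)
        except MissingScoreError:
            continue
    return {
        i: sum(
            support_score(net.weight(i, j), hs[i], hs[j])
            for j in net.participants
            if j != i and j in hs
        )
        for i in net.participants
        if i in hs
    }


# ---------------------------------------------------------------------------
# betweenness


def weighted_betweenness(
    net: ColocationNetwork, transform: str = "one_minus_w"
) -> dict[str, float]:
    """Shortest-path betweenness with co-location weights turned into edge
    lengths (strong ties = short edges), normalized by (n−1)(n−2)/2.

    ``one_minus_w`` (default) uses length 1 − w, which is bounded and
    assigns length 0 to a certain-contact tie; ``inverse`` uses 1/w."""
    g = net.graph.copy()
    for i, j, data in g.edges(data=True):
        w = data["weight"]
        if transform == "one_minus_w":
            data["length"] = 1.0 - w
        elif transform == "inverse":
            data["length"] = math.inf if w == 0 else 1.0 / w
        else:
            raise ValidationError(f"unknown transform {transform!r}")
    return dict(nx.betweenness_centrality(g, weight="length", normalized=True))


# ---------------------------------------------------------------------------
# export


def write_graphml(net: ColocationNetwork, path: str | Path) -> None:
    """GraphML with node attributes (community, scores, degree centrality)
    and edge weights."""
    g = net.graph.copy()
    for node in g.nodes:
        g.nodes[node]["degree_centrality"] = weighted_degree(net, node)
    nx.write_graphml(g, str(path))


def edges_frame(net: ColocationNetwork) -> pd.DataFrame:
    """Edge list as a DataFrame (source, target, weight), id-sorted."""
    rows = sorted(
        (min(i, j), max(i, j), d["weight"]) for i, j, d in net.graph.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
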