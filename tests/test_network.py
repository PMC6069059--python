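"""Co-location network: cosine weights, centrality, leaders, dyads."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sociospatial.activity import LocationVector
from sociospatial.errors import (
    MissingScoreError,
    NoSupporterError,
    ValidationError,
)
from sociospatial.network import (
    ColocationNetwork,
    best_supporter,
    build_network,
    cosine_weight,
    health_measure,
    node_support_aggregate,
    rank_leaders,
    select_leaders,
    support_dyads,
    support_score,
    weighted_betweenness,
    weighted_degree,
)
from sociospatial.survey import WellBeingScores
from .conftest import make_participant


def vec(owner, **probs):
    return LocationVector(owner=owner, probs=probs)


class TestCosineWeight:
    def test_identical_vectors_give_one(self):
        v = vec("a", p1=0.3, p2=0.7)
        assert cosine_weight(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert cosine_weight(vec("a", p1=0.5), vec("b", p2=0.5)) == 0.0

    def test_half_overlap(self):
        # V_i = (1,1,0), V_j = (1,0,1): dot 1, norms sqrt2*sqrt2 -> 0.5
        v1 = vec("a", p1=1.0, p2=1.0)
        v2 = vec("b", p1=1.0, p3=1.0)
        assert cosine_weight(v1, v2) == pytest.approx(0.5)

    def test_zero_vector_convention(self):
        assert cosine_weight(vec("a"), vec("b", p1=1.0)) == 0.0

    def test_mismatched_spaces_rejected(self):
        v1 = LocationVector("a", {"p": 1.0}, space="G1")
        v2 = LocationVector("b", {"p": 1.0}, space="G2")
        with pytest.raises(ValidationError):
            cosine_weight(v1, v2)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_bounds_symmetry_scale_invariance(self, data):
        n = data.draw(st.integers(2, 6))
        probs = st.floats(min_value=0.0, max_value=1.0)
        d1 = {f"p{k}": v for k, v in enumerate(data.draw(st.lists(probs, min_size=n, max_size=n))) if v > 1e-9}
        d2 = {f"p{k}": v for k, v in enumerate(data.draw(st.lists(probs, min_size=n, max_size=n))) if v > 1e-9}
        v1, v2 = LocationVector("a", d1), LocationVector("b", d2)
        w = cosine_weight(v1, v2)
        assert 0.0 <= w <= 1.0 + 1e-12
        assert w == cosine_weight(v2, v1)
        c = data.draw(st.floats(min_value=0.01, max_value=1.0))
        scaled = LocationVector("a", {k: c * v for k, v in d1.items()})
        assert cosine_weight(scaled, v2) == pytest.approx(w, abs=1e-12)


class TestBuildNetwork:
    def test_disjoint_vectors_store_no_edges(self):
        parts = [make_participant(f"P{i}") for i in range(3)]
        vectors = {f"P{i}": vec(f"P{i}", **{f"q{i}": 1.0}) for i in range(3)}
        net = build_network(vectors, parts)
        assert net.n_edges == 0
        assert net.weight("P0", "P1") == 0.0

    def test_co_residents_sharing_only_home_have_weight_one(self):
        parts = [make_participant("A"), make_participant("B")]
        vectors = {"A": vec("A", home=1.0), "B": vec("B", home=1.0)}
        net = build_network(vectors, parts)
        assert net.weight("A", "B") == pytest.approx(1.0)

    def test_missing_vector_rejected(self):
        with pytest.raises(ValidationError):
            build_network({}, [make_participant("A")])

    def test_pairwise_weights_match_numpy_brute_force(self):
        rng = np.random.default_rng(7)
        n, L = 10, 12
        mats = rng.random((n, L)) * (rng.random((n, L)) < 0.6)
        parts = [make_participant(f"P{i}") for i in range(n)]
        vectors = {
            f"P{i}": vec(f"P{i}", **{f"p{k}": mats[i, k] for k in range(L) if mats[i, k] > 0})
            for i in range(n)
        }
        net = build_network(vectors, parts)
        assert net.n_edges <= n * (n - 1) // 2
        for i, j in itertools.combinations(range(n), 2):
            a, b = mats[i], mats[j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            expect = 0.0 if na == 0 or nb == 0 or a @ b == 0 else float(a @ b / (na * nb))
            assert net.weight(f"P{i}", f"P{j}") == pytest.approx(expect, abs=1e-12)
            assert net.weight(f"P{j}", f"P{i}") == net.weight(f"P{i}", f"P{j}")


class TestWeightedDegree:
    def test_isolated_node_has_zero(self):
        net = ColocationNetwork([make_participant("A")])
        assert weighted_degree(net, "A") == 0.0

    def test_star_hand_sum(self):
        parts = [make_participant(x) for x in "ABCD"]
        net = ColocationNetwork(parts)
        for leaf in "BCD":
            net.set_weight("A", leaf, 0.5)
        assert weighted_degree(net, "A") == pytest.approx(1.5)
        assert weighted_degree(net, "B") == pytest.approx(0.5)

    def test_bounded_by_n_minus_one(self):
        rng = np.random.default_rng(0)
        parts = [make_participant(f"P{i}") for i in range(8)]
        net = ColocationNetwork(parts)
        for i, j in itertools.combinations(range(8), 2):
            net.set_weight(f"P{i}", f"P{j}", float(rng.random()))
        assert all(weighted_degree(net, f"P{i}") <= 7.0 for i in range(8))

    def test_unknown_node_rejected(self):
        net = ColocationNetwork([make_participant("A")])
        with pytest.raises(ValidationError):
            weighted_degree(net, "Z")

    def test_matches_double_loop_reimplementation(self):
        rng = np.random.default_rng(3)
        parts = [make_participant(f"P{i}") for i in range(10)]
        net = ColocationNetwork(parts)
        w = {}
        for i, j in itertools.combinations(range(10), 2):
            if rng.random() < 0.5:
                val = float(rng.random())
                net.set_weight(f"P{i}", f"P{j}", val)
                w[(i, j)] = val
        for i in range(10):
            expect = sum(v for (a, b), v in w.items() if i in (a, b))
            assert weighted_degree(net, f"P{i}") == pytest.approx(expect, rel=1e-12)


class TestLeaderRanking:
    def test_pure_dc_ranking_when_filter_disabled(self):
        parts = [
            make_participant("A", "C1", mcs=50.0),
            make_participant("B", "C1", mcs=60.0),
            make_participant("C", "C1", mcs=55.0),
        ]
        net = ColocationNetwork(parts)
        net.set_weight("A", "B", 0.9)
        net.set_weight("B", "C", 0.8)
        leaders = rank_leaders(net, "C1", top_k=3, decile=1.0)
        assert [l.id for l in leaders] == ["B", "A", "C"]
        assert [l.rank for l in leaders] == [1, 2, 3]

    def test_ties_broken_by_mcs_then_id(self):
        parts = [
            make_participant("B", "C1", mcs=50.0),
            make_participant("A", "C1", mcs=50.0),
            make_participant("C", "C1", mcs=70.0),
        ]
        net = ColocationNetwork(parts)  # all DC 0: fully tied
        leaders = rank_leaders(net, "C1", top_k=3, decile=1.0)
        assert [l.id for l in leaders] == ["C", "A", "B"]

    def test_empty_community_gives_empty(self):
        net = ColocationNetwork([make_participant("A", "C1")])
        assert rank_leaders(net, "C9") == []

    def test_well_being_filter_excludes_low_scorers(self):
        parts = [
            make_participant("LOW", "C1", mcs=10.0, isolation=90.0),
            make_participant("HIGH", "C1", mcs=90.0, isolation=10.0),
        ]
        net = ColocationNetwork(parts)
        net.set_weight("LOW", "HIGH", 1.0)
        leaders = rank_leaders(net, "C1", top_k=2, decile=0.5)
        assert [l.id for l in leaders] == ["HIGH"]


class TestSupportScores:
    def test_arithmetic(self):
        assert support_score(0.5, 60.0, 40.0) == pytest.approx(10.0)
        assert support_score(0.9, 55.0, 55.0) == 0.0
        assert support_score(0.0, 10.0, 90.0) == 0.0

    def test_symmetry(self):
        assert support_score(0.37, 61.0, 44.0) == support_score(0.37, 44.0, 61.0)

    def test_missing_score_rejected(self):
        with pytest.raises(MissingScoreError):
            support_score(0.5, None, 40.0)

    def test_health_measure_directions(self):
        s = WellBeingScores(mcs=60.0, pcs=70.0, isolation=39.1)
        assert health_measure(s, "isolation") == 39.1
        assert health_measure(s, "mental") == pytest.approx(40.0)
        assert health_measure(s, "physical") == pytest.approx(30.0)
        with pytest.raises(MissingScoreError):
            health_measure(WellBeingScores(None, 50.0, 50.0), "mental")


class TestSupportDyads:
    def _net(self):
        parts = [
            make_participant("R", "C1", isolation=80.0),  # poor: iso > 50
            make_participant("S1", "C1", isolation=30.0),
            make_participant("S2", "C1", isolation=56.0),
            make_participant("S3", "C1", isolation=64.0),
        ]
        net = ColocationNetwork(parts)
        net.set_weight("R", "S1", 0.05)  # SS = 0.05*50 = 2.5
        net.set_weight("R", "S2", 0.05)  # SS = 0.05*24 = 1.2
        net.set_weight("R", "S3", 0.05)  # SS = 0.05*16 = 0.8
        return net

    def test_threshold_filters_and_sorts_descending(self):
        dyads = [d for d in support_dyads(self._net(), "isolation", threshold=1.0)
                 if d.receiver == "R"]
        assert [(d.provider, pytest.approx(d.support_score)) for d in dyads] == [
            ("S1", pytest.approx(2.5)),
            ("S2", pytest.approx(1.2)),
        ]

    def test_no_poor_nodes_gives_empty(self):
        parts = [make_participant(x, isolation=10.0) for x in "AB"]
        net = ColocationNetwork(parts)
        net.set_weight("A", "B", 1.0)
        assert support_dyads(net, "isolation") == []

    def test_threshold_zero_keeps_all_positive(self):
        dyads = [d for d in support_dyads(self._net(), "isolation", threshold=0.0)
                 if d.receiver == "R"]
        assert [d.provider for d in dyads] == ["S1", "S2", "S3"]

    def test_best_supporter_argmax_and_errors(self):
        dyads = support_dyads(self._net(), "isolation", threshold=0.0)
        assert best_supporter("R", dyads) == "S1"
        with pytest.raises(NoSupporterError):
            best_supporter("S1", dyads)

    def test_node_aggregate_matches_manual_sum(self):
        net = self._net()
        agg = node_support_aggregate(net, "isolation")
        assert agg["R"] == pytest.approx(2.5 + 1.2 + 0.8)


class TestWeightedBetweenness:
    def test_path_graph_middle_is_maximal(self):
        parts = [make_participant(x) for x in "ABC"]
        net = ColocationNetwork(parts)
        net.set_weight("A", "B", 0.5)
        net.set_weight("B", "C", 0.5)
        bc = weighted_betweenness(net)
        assert bc["B"] == max(bc.values()) and bc["B"] > 0

    def test_complete_uniform_graph_is_all_zero(self):
        parts = [make_participant(x) for x in "ABCD"]
        net = ColocationNetwork(parts)
        for i, j in itertools.combinations("ABCD", 2):
            net.set_weight(i, j, 0.5)
        assert all(v == pytest.approx(0.0) for v in weighted_betweenness(net).values())

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(11)
        names = list("ABCDE")
        parts = [make_participant(x) for x in names]
        net = ColocationNetwork(parts)
        weights = {}
        for i, j in itertools.combinations(names, 2):
            if rng.random() < 0.8:
                w = float(rng.uniform(0.1, 0.9))
                net.set_weight(i, j, w)
                weights[frozenset((i, j))] = w

        def paths(a, b, visited):
            if a == b:
                yield [b]
                return
            for c in names:
                if frozenset((a, c)) in weights and c not in visited:
                    for tail in paths(c, b, visited | {c}):
                        yield [a] + tail

        def length(path):
            return sum(1.0 - weights[frozenset((u, v))] for u, v in zip(path, path[1:]))

        expect = {x: 0.0 for x in names}
        for a, b in itertools.combinations(names, 2):
            all_paths = list(paths(a, b, {a}))
            if not all_paths:
                continue
            best = min(length(p) for p in all_paths)
            shortest = [p for p in all_paths if math.isclose(length(p), best, abs_tol=1e-12)]
            for v in names:
                if v in (a, b):
                    continue
                through = sum(1 for p in shortest if v in p[1:-1])
                expect[v] += through / len(shortest)
        n = len(names)
        scale = (n - 1) * (n - 2) / 2.0
        got = weighted_betweenness(net)
        for v in names:
            assert got[v] == pytest.approx(expect[v] / scale, abs=1e-9)


def test_select_leaders_on_plain_frame_preserves_tie_break_determinism():
    frame = pd.DataFrame(
        {
            "id": ["b", "a", "c"],
            "community": ["X"] * 3,
            "degree_centrality": [1.0, 1.0, 1.0],
            "mcs": [50.0, 50.0, 60.0],
            "isolation": [40.0, 40.0, 40.0],
        }
    )
    out = select_leaders(frame, top_k=3, decile=1.0)
    assert list(out["id"]) == ["c", "a", "b"]
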