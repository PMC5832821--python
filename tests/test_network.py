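"""Edge filtering, hub connectivity, recovery metrics, Cytoscape export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from anninfer import (Edge, EdgeList, SyntheticTruth, export_network,
                      filter_top_edges, hub_scores, recovery_report)
from anninfer import __version__
from anninfer.data import ValidationError


def brute_force_top_k(ids, values, k):
    """Independent oracle: sort all off-diagonal entries, take k."""
    entries = []
    for i, src in enumerate(ids):
        for j, tgt in enumerate(ids):
            if i != j:
                entries.append((src, tgt, float(values[i, j])))
    entries.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return entries[:min(k, len(entries))]


def brute_force_hubs(edges, marker_ids):
    """Independent loop-based accumulation oracle for connectivity/degree."""
    conn = dict.fromkeys(marker_ids, 0.0)
    deg = dict.fromkeys(marker_ids, 0)
    for e in edges:
        for end in (e.source, e.target):
            conn[end] += abs(e.influence)
            deg[end] += 1
    return conn, deg


def mann_whitney_auroc(scores_pos, scores_neg):
    """Pairwise-comparison AUROC oracle (ties count half)."""
    wins = 0.0
    for p in scores_pos:
        for n in scores_neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(scores_pos) * len(scores_neg))


class TestFilterTopEdges:
    def test_three_by_three_example(self):
        ids = ["A", "B", "C"]
        values = np.array([[0, 5, -4], [3, 0, -2], [1, 0.5, 0]])
        edges = filter_top_edges((ids, values), k=2)
        assert [(e.source, e.target, e.influence) for e in edges] == [
            ("A", "B", 5.0), ("A", "C", -4.0)]

    def test_k_clamps_to_all_offdiagonal(self):
        ids = ["A", "B", "C"]
        values = np.arange(9, dtype=float).reshape(3, 3)
        edges = filter_top_edges((ids, values), k=1000)
        assert len(edges) == 6

    def test_signs_follow_influence(self):
        ids = ["A", "B"]
        edges = filter_top_edges((ids, np.array([[0, -3.0], [2.0, 0]])), k=2)
        assert {e.sign for e in edges} == {"positive", "negative"}
        for e in edges:
            assert (e.sign == "positive") == (e.influence > 0)

    def test_matches_brute_force_exhaustively(self):
        # random matrices up to 12x12, every k
        rng = np.random.default_rng(13)
        for m in range(2, 13):
            ids = [f"M{i:02d}" for i in range(m)]
            values = rng.normal(size=(m, m))
            np.fill_diagonal(values, 0.0)
            for k in (1, 2, m, m * (m - 1), m * (m - 1) + 5):
                got = filter_top_edges((ids, values), k)
                expected = brute_force_top_k(ids, values, k)
                assert [(e.source, e.target, e.influence) for e in got] == expected

    def test_sorted_descending_by_magnitude(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(6, 6))
        np.fill_diagonal(values, 0)
        edges = filter_top_edges(([f"M{i}" for i in range(6)], values), 10)
        mags = [abs(e.influence) for e in edges]
        assert mags == sorted(mags, reverse=True)


class TestHubScores:
    def test_single_edge(self):
        edges = EdgeList((Edge("A", "B", 2.0),), 1)
        hubs = hub_scores(edges, ["A", "B", "C"]).set_index("marker_id")
        assert hubs.loc["A", "connectivity"] == 2.0
        assert hubs.loc["B", "connectivity"] == 2.0
        assert hubs.loc["C", "connectivity"] == 0.0
        assert hubs.loc["C", "degree"] == 0

    def test_star_centre_sums_all_influences(self):
        leaves = [f"L{i}" for i in range(4)]
        infl = [1.5, -2.0, 0.5, 3.0]
        edges = EdgeList(tuple(Edge("HUB", l, w) for l, w in zip(leaves, infl)), 4)
        hubs = hub_scores(edges, ["HUB"] + leaves).set_index("marker_id")
        assert hubs.loc["HUB", "connectivity"] == sum(abs(w) for w in infl)
        assert hubs.loc["HUB", "rank"] == 1

    def test_matches_brute_force_on_random_edgelists(self):
        rng = np.random.default_rng(21)
        ids = [f"M{i}" for i in range(10)]
        for trial in range(10):
            pairs = [(a, b) for a, b in itertools.permutations(ids, 2)]
            chosen = rng.choice(len(pairs), size=15, replace=False)
            edges = EdgeList(tuple(
                Edge(*pairs[c], float(rng.normal())) for c in chosen), 15)
            hubs = hub_scores(edges, ids).set_index("marker_id")
            conn, deg = brute_force_hubs(edges, ids)
            for m in ids:
                assert hubs.loc[m, "connectivity"] == pytest.approx(conn[m])
                assert hubs.loc[m, "degree"] == deg[m]

    def test_connectivity_conservation(self):
        rng = np.random.default_rng(5)
        ids = [f"M{i}" for i in range(8)]
        values = rng.normal(size=(8, 8))
        np.fill_diagonal(values, 0)
        edges = filter_top_edges((ids, values), 20)
        hubs = hub_scores(edges, ids)
        total = sum(abs(e.influence) for e in edges)
        assert hubs["connectivity"].sum() == pytest.approx(2 * total)

    def test_unknown_endpoint_rejected(self):
        edges = EdgeList((Edge("A", "X", 1.0),), 1)
        with pytest.raises(ValidationError):
            hub_scores(edges, ["A", "B"])


def _truth_with_edges(n_probes, edges):
    effects = np.zeros(n_probes)
    effects[0] = 2.0
    return SyntheticTruth(n_probes, 0, effects, tuple(edges), 0.5, 0)


class TestRecoveryReport:
    def _mapping(self, truth):
        return {truth.probe_id(g): g for g in range(truth.n_probes)}

    def test_perfect_recovery(self):
        truth = _truth_with_edges(4, [(1, 2, 1.5), (2, 3, -1.0)])
        edges = EdgeList((Edge("P0002", "P0003", 0.8),
                          Edge("P0003", "P0004", -0.5)), 2)
        rep = recovery_report(edges, truth, self._mapping(truth))
        assert rep.precision == 1.0 and rep.recall == 1.0
        assert rep.sign_accuracy == 1.0
        assert rep.auroc == 1.0

    def test_empty_edge_list(self):
        truth = _truth_with_edges(4, [(1, 2, 1.5)])
        rep = recovery_report(EdgeList((), 5), truth, self._mapping(truth))
        assert rep.recall == 0.0

    def test_wrong_sign_counts_against_sign_accuracy(self):
        truth = _truth_with_edges(3, [(1, 2, 1.5)])
        edges = EdgeList((Edge("P0002", "P0003", -0.8),), 1)
        rep = recovery_report(edges, truth, self._mapping(truth))
        assert rep.recall == 1.0
        assert rep.sign_accuracy == 0.0

    def test_auroc_matches_mann_whitney_oracle(self):
        # random scores over all ordered pairs of 5 markers, 4 planted edges
        rng = np.random.default_rng(17)
        truth = _truth_with_edges(5, [(0, 1, 1.0), (1, 2, -1.5),
                                      (3, 4, 2.0), (4, 0, 1.2)])
        pairs = [(i, j) for i in range(5) for j in range(5) if i != j]
        scores = {p: float(rng.random()) for p in pairs}
        edges = EdgeList(tuple(
            Edge(truth.probe_id(i), truth.probe_id(j), scores[(i, j)])
            for i, j in pairs), len(pairs))
        rep = recovery_report(edges, truth, self._mapping(truth))
        planted = set(truth.edge_set)
        pos = [scores[p] for p in pairs if p in planted]
        neg = [scores[p] for p in pairs if p not in planted]
        assert rep.auroc == pytest.approx(mann_whitney_auroc(pos, neg))

    def test_incomplete_mapping_rejected(self):
        truth = _truth_with_edges(3, [(1, 2, 1.0)])
        edges = EdgeList((Edge("P0002", "P0003", 1.0),), 1)
        with pytest.raises(ValidationError):
            recovery_report(edges, truth, {"P0002": 1})


FIVE_EDGES = EdgeList((
    Edge("MTA", "MTB", 2.5),
    Edge("MTB", "MTC", -1.25),
    Edge("MTC", "MTA", 1.0),
    Edge("MTD", "MTB", -0.5),
    Edge("MTA", "MTD", 0.25),
), 5)


class TestExportNetwork:
    def test_sif_relation_tokens(self, tmp_path):
        edges = EdgeList((Edge("A", "B", 1.0),), 1)
        hubs = hub_scores(edges, ["A", "B"])
        paths = export_network(edges, hubs, tmp_path / "net")
        assert paths["sif"].read_text() == "A\tactivates\tB\n"

    def test_golden_five_edge_fixture(self, tmp_path):
        hubs = hub_scores(FIVE_EDGES, ["MTA", "MTB", "MTC", "MTD"])
        paths = export_network(FIVE_EDGES, hubs, tmp_path / "net", seed=1)
        assert paths["sif"].read_text() == (
            "MTA\tactivates\tMTB\n"
            "MTB\trepresses\tMTC\n"
            "MTC\tactivates\tMTA\n"
            "MTD\trepresses\tMTB\n"
            "MTA\tactivates\tMTD\n")
        assert paths["edges"].read_text() == (
            f"# anninfer v{__version__} seed=1\n"
            "source\ttarget\tinfluence\tsign\n"
            "MTA\tMTB\t2.5\tpositive\n"
            "MTB\tMTC\t-1.25\tnegative\n"
            "MTC\tMTA\t1.0\tpositive\n"
            "MTD\tMTB\t-0.5\tnegative\n"
            "MTA\tMTD\t0.25\tpositive\n")
        # node attributes: connectivity = sum |influence| incident
        assert paths["nodes"].read_text() == (
            f"# anninfer v{__version__} seed=1\n"
            "marker_id\tconnectivity\tdegree\trank\n"
            "MTB\t4.25\t3\t1\n"
            "MTA\t3.75\t3\t2\n"
            "MTC\t2.25\t2\t3\n"
            "MTD\t0.75\t2\t4\n")

    def test_re_export_is_byte_identical(self, tmp_path):
        hubs = hub_scores(FIVE_EDGES, ["MTA", "MTB", "MTC", "MTD"])
        p1 = export_network(FIVE_EDGES, hubs, tmp_path / "a", seed=3)
        p2 = export_network(FIVE_EDGES, hubs, tmp_path / "b", seed=3)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
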