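"""Edge-table cleaning, induced subnetworks, temporal annotation, merging,
crosstalk extraction and direction-concordance classification."""

import numpy as np
import pandas as pd
import pytest

from consenseq.network import (annotate_first_de, build_subnetwork, classify_direction,
                               extract_crosstalk, load_edges, merge_networks,
                               write_graphml)
from consenseq.preprocess import ValidationError


def edges_df(rows):
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def write_edges(tmp_path, rows, name="edges.tsv", header=("node1", "node2", "combined_score")):
    path = tmp_path / name
    pd.DataFrame(rows, columns=list(header)).to_csv(path, sep="\t", index=False)
    return path


class TestLoadEdges:
    def test_both_orientations_collapse_to_one_edge(self, tmp_path):
        p = write_edges(tmp_path, [("a", "b", 500), ("b", "a", 500)])
        out = load_edges(p)
        assert len(out) == 1
        assert tuple(out.iloc[0][["node1", "node2"]]) == ("a", "b")

    def test_score_cutoff_boundary(self, tmp_path):
        p = write_edges(tmp_path, [("a", "b", 399), ("c", "d", 400)])
        out = load_edges(p, min_score=400)
        assert list(out.node1) == ["c"]

    def test_string_header_dialect_accepted(self, tmp_path):
        p = write_edges(tmp_path, [("a", "b", 700)], header=("protein1", "protein2", "combined_score"))
        assert len(load_edges(p)) == 1

    def test_self_loops_removed_and_max_score_kept(self, tmp_path):
        p = write_edges(tmp_path, [("a", "a", 900), ("a", "b", 500), ("b", "a", 800)])
        out = load_edges(p)
        assert len(out) == 1
        assert out.iloc[0].combined_score == 800

    def test_malformed_score_reports_row(self, tmp_path):
        p = write_edges(tmp_path, [("a", "b", "high")])
        with pytest.raises(ValidationError, match="row"):
            load_edges(p)

    def test_matches_bruteforce_filter(self, tmp_path):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(8)]
        rows = [(nodes[rng.integers(8)], nodes[rng.integers(8)], int(rng.integers(0, 1000)))
                for _ in range(20)]
        p = write_edges(tmp_path, rows)
        out = load_edges(p, min_score=400)
        expect = set()
        for a, b, s in rows:
            if a != b and s >= 400:
                expect.add(tuple(sorted((a, b))))
        assert set(map(tuple, out[["node1", "node2"]].to_numpy())) == expect


class TestBuildSubnetwork:
    def test_orphan_removed(self):
        g = build_subnetwork({"a", "b", "c"}, edges_df([("a", "b", 500)]))
        assert set(g.nodes) == {"a", "b"}
        assert g.graph["coverage"] == pytest.approx(2 / 3)

    def test_disconnected_candidates_warn_and_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            g = build_subnetwork({"x", "y"}, edges_df([("a", "b", 500)]))
        assert g.number_of_nodes() == 0

    def test_matches_bruteforce_induced_subgraph(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(40)]
        rows = []
        seen = set()
        while len(rows) < 100:
            a, b = rng.choice(40, 2, replace=False)
            key = tuple(sorted((nodes[a], nodes[b])))
            if key not in seen:
                seen.add(key)
                rows.append((key[0], key[1], 500))
        edges = edges_df(rows)
        cand = set(rng.choice(nodes, 30, replace=False))
        g = build_subnetwork(cand, edges)
        expect_edges = {tuple(sorted((a, b))) for a, b, _ in rows if a in cand and b in cand}
        expect_nodes = {n for e in expect_edges for n in e}
        assert set(g.nodes) == expect_nodes
        assert {tuple(sorted(e)) for e in g.edges} == expect_edges
        assert all(g.degree[n] > 0 for n in g.nodes)


class TestAnnotate:
    def _net(self):
        return build_subnetwork({"a", "b"}, edges_df([("a", "b", 500)]))

    def test_mid_onset_profile(self):
        lfc = pd.DataFrame({"a": [0.3, 0.6, 0.9], "b": [-0.2, 0.1, 0.3]}, index=[3, 6, 9]).T
        g = annotate_first_de(self._net(), lfc, 0.5, experiment="SB")
        assert g.nodes["a"]["first_de"] == "6h"
        assert [g.nodes["a"][f"dir_{t}h"] for t in (3, 6, 9)] == ["none", "up", "up"]
        assert g.nodes["b"]["first_de"] == "none"

    def test_early_down_profile(self):
        lfc = pd.DataFrame({"a": [-0.8, -1.2, -1.5], "b": [-0.8, -1.2, -1.5]}, index=[3, 6, 9]).T
        g = annotate_first_de(self._net(), lfc, 0.5)
        assert g.nodes["a"]["first_de"] == "3h"
        assert [g.nodes["a"][f"dir_{t}h"] for t in (3, 6, 9)] == ["down", "down", "down"]

    def test_missing_node_is_error(self):
        lfc = pd.DataFrame({"a": [1, 1, 1]}, index=[3, 6, 9]).T
        with pytest.raises(ValidationError, match="missing"):
            annotate_first_de(self._net(), lfc, 0.5)


def _annotated(nodes_edges, exp, lfc_vals):
    g = build_subnetwork(set().union(*[set(e[:2]) for e in nodes_edges]), edges_df(nodes_edges))
    lfc = pd.DataFrame(lfc_vals, index=[3, 6, 9]).T
    return annotate_first_de(g, lfc, 0.5, experiment=exp)


class TestMerge:
    def test_disjoint_networks_add(self):
        a = _annotated([("a", "b", 500)], "SB", {"a": [1, 1, 1], "b": [1, 1, 1]})
        b = _annotated([("c", "d", 600)], "SU", {"c": [1, 1, 1], "d": [1, 1, 1]})
        m = merge_networks(a, b)
        assert m.number_of_nodes() == 4
        assert m.nodes["a"]["experiment"] == "SB"
        assert m.nodes["c"]["experiment"] == "SU"

    def test_identical_networks_tag_both(self):
        a = _annotated([("a", "b", 500)], "SB", {"a": [1, 1, 1], "b": [1, 1, 1]})
        b = _annotated([("a", "b", 500)], "SU", {"a": [1, 1, 1], "b": [1, 1, 1]})
        m = merge_networks(a, b)
        assert m.number_of_nodes() == 2
        assert all(m.nodes[n]["experiment"] == "both" for n in m.nodes)
        assert m.nodes["a"]["first_de_sb"] == "3h" and m.nodes["a"]["first_de_su"] == "3h"

    def test_union_with_attribute_join_and_max_score(self):
        a = _annotated([("a", "b", 500)], "SB", {"a": [1, 1, 1], "b": [1, 1, 1]})
        b = _annotated([("a", "b", 700), ("b", "c", 600)], "SU",
                       {"a": [-1, -1, -1], "b": [1, 1, 1], "c": [1, 1, 1]})
        m = merge_networks(a, b)
        assert m.edges["a", "b"]["combined_score"] == 700
        assert m.nodes["a"]["dir_3h_sb"] == "up" and m.nodes["a"]["dir_3h_su"] == "down"
        assert m.nodes["c"]["experiment"] == "SU"

    def test_commutative_up_to_ordering(self):
        a = _annotated([("a", "b", 500)], "SB", {"a": [1, 1, 1], "b": [1, 1, 1]})
        b = _annotated([("b", "c", 600)], "SU", {"b": [1, 1, 1], "c": [1, 1, 1]})
        m1, m2 = merge_networks(a, b), merge_networks(b, a)
        assert set(m1.nodes) == set(m2.nodes)
        assert {tuple(sorted(e)) for e in m1.edges} == {tuple(sorted(e)) for e in m2.edges}
        for n in m1.nodes:
            assert m1.nodes[n] == m2.nodes[n]


class TestCrosstalk:
    def test_hand_trace(self):
        g = _annotated([("s", "a", 500), ("a", "b", 500)], "SB",
                       {"s": [1, 1, 1], "a": [1, 1, 1], "b": [1, 1, 1]})
        out = extract_crosstalk(g, {"s"})
        assert set(out.nodes) == {"s", "a"}
        assert {tuple(sorted(e)) for e in out.edges} == {("a", "s")}
        assert out.nodes["s"]["shared_target"] and not out.nodes["a"]["shared_target"]

    def test_empty_shared_set_warns(self):
        g = _annotated([("a", "b", 500)], "SB", {"a": [1, 1, 1], "b": [1, 1, 1]})
        with pytest.warns(UserWarning, match="empty"):
            out = extract_crosstalk(g, set())
        assert out.number_of_nodes() == 0

    def test_subset_of_merged_and_idempotent(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(25)]
        rows = list({tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(60)})
        g = _annotated([(a, b, 500) for a, b in rows], "SB",
                       {n: [1, 1, 1] for n in nodes})
        shared = set(rng.choice(sorted(g.nodes), 5, replace=False))
        out = extract_crosstalk(g, shared)
        assert set(out.nodes) <= set(g.nodes)
        again = extract_crosstalk(out, shared)
        assert set(again.nodes) == set(out.nodes)
        assert {tuple(sorted(e)) for e in again.edges} == {tuple(sorted(e)) for e in out.edges}

    def test_matches_bruteforce_neighborhood_scan(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(30)]
        rows = list({tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(80)})
        g = _annotated([(a, b, 500) for a, b in rows], "SB", {n: [1, 1, 1] for n in nodes})
        shared = set(rng.choice(sorted(g.nodes), 4, replace=False))
        out = extract_crosstalk(g, shared)
        keep = set(shared)
        for a, b in g.edges:
            if a in shared:
                keep.add(b)
            if b in shared:
                keep.add(a)
        assert set(out.nodes) == keep
        assert {tuple(sorted(e)) for e in out.edges} == \
            {tuple(sorted((a, b))) for a, b in g.edges if a in keep and b in keep}
        # every retained non-shared node touches a shared target
        for n in out.nodes:
            if n not in shared:
                assert any(nb in shared for nb in out.neighbors(n))


class TestClassify:
    def p(self, vals):
        return pd.Series(vals, index=[3, 6, 9])

    def test_same_signs_synergistic(self):
        assert classify_direction(self.p([0.2, 0.9, 1.2]), self.p([1.5, 0.4, 0.2]),
                                  0.0, 0.0) == "synergistic"

    def test_opposite_regulation_antagonistic(self):
        # down under TGF-beta inhibition, up under FGF inhibition
        assert classify_direction(self.p([-0.6, -1.1, -1.4]), self.p([0.8, 1.2, 0.9]),
                                  0.5, 0.7) == "antagonistic"

    def test_subthreshold_side_indeterminate(self):
        assert classify_direction(self.p([0.9, 0.2, 0.1]), self.p([0.0, 0.0, 0.0]),
                                  0.5, 0.7) == "indeterminate"


def test_graphml_bytes_deterministic(tmp_path):
    g = _annotated([("b", "a", 500), ("c", "a", 700)], "SB",
                   {"a": [1, 1, 1], "b": [-1, -1, -1], "c": [0, 0, 0]})
    write_graphml(g, tmp_path / "one.graphml")
    g2 = _annotated([("c", "a", 700), ("b", "a", 500)], "SB",
                    {"a": [1, 1, 1], "b": [-1, -1, -1], "c": [0, 0, 0]})
    write_graphml(g2, tmp_path / "two.graphml")
    assert (tmp_path / "one.graphml").read_bytes() == (tmp_path / "two.graphml").read_bytes()
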