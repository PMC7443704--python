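"""Adjacency counting, thresholds, budgets, pooling, census arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vpconn.circuit import (AdjacencyTable, UndefinedBudgetError,
                            adjacency_to_graphml, build_adjacency, census,
                            chamber_assignment, circuit_members, input_budget,
                            novel_type_count, percent_complete, pooled_total,
                            strong_targets, vp1d_vp4_total)
from vpconn.core import BoxVolume, Connector, Connectome
from tests.test_core import make_skeleton


def tiny_connectome():
    conn = Connectome()
    for sid in ("s1", "s2", "t1", "t2"):
        conn.skeletons[sid] = make_skeleton(sid, [(1, -1, 0, 0, 0), (2, 1, 1, 1, 1)])
    conn.volumes["box"] = BoxVolume("box", [0, 0, 0], [10, 10, 10])
    conn.connectors["c1"] = Connector("c1", [5, 5, 5], ("s1", 1),
                                      [("t1", 1), ("t1", 2)])
    conn.connectors["c2"] = Connector("c2", [5, 5, 5], ("s2", 1), [("t1", 1)])
    conn.connectors["c3"] = Connector("c3", [99, 5, 5], ("s1", 1), [("t2", 1)])
    return conn


def brute_force_adjacency(conn, sources, targets, volume=None):
    """Oracle: plain triple loop over connectors and links."""
    counts = {(s, t): 0 for s in sources for t in targets}
    for c in conn.connectors.values():
        if volume is not None:
            lo, hi = volume.lo, volume.hi
            if not np.all((c.location >= lo) & (c.location <= hi)):
                continue
        for ps, _pn in c.posts:
            if (c.pre[0], ps) in counts:
                counts[(c.pre[0], ps)] += 1
    return counts


class TestAdjacency:
    def test_polyadic_connector_counts_once_per_post_link(self):
        adj = build_adjacency(tiny_connectome(), ["s1"], ["t1"])
        assert adj.counts.loc["s1", "t1"] == 2

    def test_volume_restriction_removes_outside_connectors(self):
        conn = tiny_connectome()
        adj = build_adjacency(conn, ["s1"], ["t2"], conn.volumes["box"])
        assert adj.counts.loc["s1", "t2"] == 0

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            build_adjacency(tiny_connectome(), ["nope"], ["t1"])

    def test_compartment_restriction_filters_post_nodes(self):
        conn = tiny_connectome()
        adj = build_adjacency(conn, ["s1"], ["t1"],
                              compartments={"t1": {2}})
        assert adj.counts.loc["s1", "t1"] == 1

    def test_matches_brute_force_on_generator_instance(self, conn, gt):
        laca = conn.volumes["lACA_R"]
        q = gt.queries[0]
        targets = sorted(gt.partner_degrees[q])
        adj = build_adjacency(conn, [q], targets, laca)
        oracle = brute_force_adjacency(conn, [q], targets, laca)
        for t in targets:
            assert adj.counts.loc[q, t] == oracle[(q, t)]

    def test_exhausted_sampling_tally_equals_adjacency(self, conn, gt):
        from vpconn.sampling import enumerate_postsynapses, exhaustive_tally
        laca = conn.volumes["lACA_R"]
        q = gt.queries[0]
        tally = exhaustive_tally(enumerate_postsynapses(conn, [q], laca))
        adj = build_adjacency(conn, [q], sorted(tally), laca)
        assert {t: int(adj.counts.loc[q, t]) for t in tally} == tally

    def test_pooling_commutes_with_summation(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(0, 9, (4, 6)),
                              index=list("abcd"), columns=list("uvwxyz"))
        adj = AdjacencyTable(counts)
        pooled = adj.pooled(source_groups={"g1": ["a", "b"], "g2": ["c", "d"]},
                            target_groups={"h1": list("uvw"), "h2": list("xyz")})
        assert pooled.counts.loc["g1", "h1"] == counts.loc[["a", "b"],
                                                           list("uvw")].to_numpy().sum()
        assert pooled.counts.to_numpy().sum() == counts.to_numpy().sum()


class TestThresholds:
    def test_circuit_membership_includes_boundary(self):
        counts = pd.DataFrame([[7, 5, 4]], index=["q"], columns=["a", "b", "c"])
        assert circuit_members(AdjacencyTable(counts)) == {"a", "b"}

    def test_empty_adjacency_has_no_members(self):
        counts = pd.DataFrame(index=["q"], columns=[], dtype=int)
        assert circuit_members(AdjacencyTable(counts)) == set()

    def test_strong_targets_are_strictly_above_threshold(self):
        counts = pd.DataFrame([[151, 150]], index=["q"], columns=["a", "b"])
        assert strong_targets(AdjacencyTable(counts)) == {"a"}
        counts = pd.DataFrame([[150, 10]], index=["q"], columns=["a", "b"])
        assert strong_targets(AdjacencyTable(counts)) == set()

    def test_membership_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 20, (3, 10)))
        adj = AdjacencyTable(counts)
        prev = circuit_members(adj, 0)
        for th in range(1, 22):
            cur = circuit_members(adj, th)
            assert cur <= prev
            prev = cur

    def test_planted_members_recovered_exactly(self, conn, gt):
        laca = conn.volumes["lACA_R"]
        targets = sorted({p for d in gt.partner_degrees.values() for p in d})
        adj = build_adjacency(conn, gt.queries, targets, laca)
        want = {p for d in gt.partner_degrees.values()
                for p, c in d.items() if c >= 5}
        assert circuit_members(adj, 5) == want

    def test_planted_heavy_partner_is_strong_target(self):
        from vpconn.synth import SynthConfig, generate_connectome
        cfg = SynthConfig(seed=21, partner_degrees=[(1, 200), (20, 3)],
                          rn_counts={}, n_kcs=0, inputs_per_claw=0,
                          bouton_counts={}, rn_input_rate=0.0)
        c2, g2 = generate_connectome(cfg)
        targets = sorted({p for d in g2.partner_degrees.values() for p in d})
        adj = build_adjacency(c2, g2.queries, targets)
        heavy = {p for d in g2.partner_degrees.values()
                 for p, n in d.items() if n > 150}
        assert strong_targets(adj, 150) == heavy


class TestInputBudget:
    def test_heatmap_threshold_removes_small_cells(self):
        col = pd.Series({"A": 8, "B": 2, "C": 2})
        assert input_budget(col, "vp").to_dict() == {"A": 1.0}

    def test_identified_mode_uses_categories(self):
        col = pd.Series({"x": 70, "y": 30})
        out = input_budget(col, "identified",
                           categories={"x": "VP", "y": "olfactory"})
        assert out.to_dict() == pytest.approx({"VP": 0.7, "olfactory": 0.3})

    def test_zero_total_rejected(self):
        with pytest.raises(UndefinedBudgetError):
            input_budget(pd.Series({"A": 2, "B": 1}), "vp")

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=12))
    def test_retained_fractions_sum_to_one(self, cells):
        col = pd.Series({f"s{i}": v for i, v in enumerate(cells)})
        if (col > 2).any():
            assert input_budget(col, "vp").sum() == pytest.approx(1.0, abs=1e-12)
        else:
            with pytest.raises(UndefinedBudgetError):
                input_budget(col, "vp")


class TestCensus:
    def test_hemisphere_totals_pool_by_summation(self):
        assert pooled_total(52, 36) == 88

    def test_novel_types_subtract_known_and_misassociated(self):
        assert novel_type_count(38, 9, 6) == 23

    def test_percent_fully_reconstructed_one_decimal(self):
        assert percent_complete(20, 42) == 47.6

    def test_triad_rule_splits_chambers(self):
        assert chamber_assignment(14, 9) == (9, 5)
        assert chamber_assignment(14, 7) == (7, 7)

    def test_vp1d_vp4_side_totals(self):
        assert vp1d_vp4_total(14, 9) == 23
        assert vp1d_vp4_total(14, 7) == 21

    def test_negative_intermediate_rejected(self):
        with pytest.raises(ValueError):
            novel_type_count(5, 9, 6)
        with pytest.raises(ValueError):
            chamber_assignment(4, 9)

    def test_full_summary(self):
        out = census()
        assert out["vp_pn_total"] == 88
        assert out["novel_types"] == 23
        assert out["percent_complete"] == 47.6
        assert out["chamber_ii_vp4_R"] == 9
        assert out["vp1d_vp4_total_R"] == 23
        assert out["vp1d_vp4_total_L"] == 21


def test_graphml_export_roundtrip(tmp_path):
    import networkx as nx
    counts = pd.DataFrame([[3, 0], [1, 7]], index=["a", "b"], columns=["x", "y"])
    adjacency_to_graphml(AdjacencyTable(counts), tmp_path / "g.graphml")
    g = nx.read_graphml(tmp_path / "g.graphml")
    assert g["a"]["x"]["count"] == 3
    assert not g.has_edge("a", "y")
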