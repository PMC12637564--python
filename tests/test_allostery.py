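import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dmsd.allostery import (
    brute_force_steiner,
    build_graph,
    classify_edges,
    differential_fragments,
    metastate_intersections,
    prune_components,
    select_critical_nodes,
    steiner_pathway,
)
from dmsd.synthetic import generate_contact_tables


def contact_df(entries, replicates=2):
    """entries: (res_i, res_j, wt_freq, mut_freq)."""
    rows = []
    for i, j, wt, mut in entries:
        for cond, f in (("wt", wt), ("mutant", mut)):
            for rep in range(1, replicates + 1):
                rows.append((i, j, cond, rep, f))
    return pd.DataFrame(rows, columns=["res_i", "res_j", "condition", "replicate", "frequency"])


class TestBuildGraph:
    def test_low_frequency_pair_excluded(self):
        g = build_graph(contact_df([(1, 2, 0.005, 0.005), (2, 3, 0.5, 0.5)]))
        assert not g.has_edge("A:1", "A:2")
        assert g.has_edge("A:2", "A:3")

    def test_empty_table_gives_empty_graph(self):
        g = build_graph(pd.DataFrame(columns=["res_i", "res_j", "condition", "replicate", "frequency"]))
        assert len(g) == 0

    def test_replicate_means_and_diff(self):
        df = contact_df([(1, 2, 0.2, 0.6)])
        g = build_graph(df)
        e = g.edges["A:1", "A:2"]
        assert e["wt_mean"] == pytest.approx(0.2)
        assert e["diff"] == pytest.approx(0.4)

    def test_planted_pathway_edges_all_present(self):
        df = generate_contact_tables(30, list(range(5, 15)), effect=0.4, seed=6)
        g = build_graph(df)
        for a, b in zip(range(5, 14), range(6, 15)):
            assert g.has_edge(f"A:{a}", f"A:{b}")


class TestClassifyEdges:
    def test_conserved_before_differential(self):
        g = classify_edges(build_graph(contact_df([(1, 2, 0.9, 0.95)])), diff_threshold=0.03)
        assert g.edges["A:1", "A:2"]["edge_class"] == "conserved"

    def test_up_down_and_dropped(self):
        g0 = build_graph(
            contact_df([(1, 2, 0.2, 0.5), (3, 4, 0.5, 0.2), (5, 6, 0.2, 0.3)])
        )
        g = classify_edges(g0, diff_threshold=0.115)
        assert g.edges["A:1", "A:2"]["edge_class"] == "up"
        assert g.edges["A:3", "A:4"]["edge_class"] == "down"
        g = classify_edges(g0, diff_threshold=0.3)
        assert not g.has_edge("A:5", "A:6")

    def test_classes_mutually_exclusive(self):
        df = generate_contact_tables(25, [3, 4, 5, 6], effect=0.4, seed=7)
        g = classify_edges(build_graph(df), diff_threshold=0.3)
        for _u, _v, d in g.edges(data=True):
            assert d["edge_class"] in {"up", "down", "conserved", "neighbor"}

    def test_neighbor_relays_added(self):
        g0 = build_graph(
            contact_df([(10, 20, 0.2, 0.6), (10, 11, 0.3, 0.32)])
        )
        g = classify_edges(g0, diff_threshold=0.3)
        assert g.edges["A:10", "A:11"]["edge_class"] == "neighbor"


class TestPruneComponents:
    def _graph(self, sizes):
        g = nx.Graph()
        base = 0
        for s in sizes:
            nodes = [f"A:{base + i}" for i in range(s)]
            nx.add_path(g, nodes)
            base += s + 10
        return g

    def test_two_node_component_removed(self):
        g = prune_components(self._graph([2]))
        assert len(g) == 0

    def test_five_node_component_kept(self):
        g = prune_components(self._graph([5]))
        assert len(g) == 5

    def test_mixed_sizes(self):
        g = prune_components(self._graph([5, 3, 4]))
        sizes = sorted(len(c) for c in nx.connected_components(g))
        assert sizes == [4, 5]


class TestCriticalNodes:
    def test_union_semantics_without_fragments(self):
        df = contact_df([(1, 2, 0.5, 0.5), (2, 3, 0.2, 0.6)])
        g = classify_edges(build_graph(df), diff_threshold=0.3)
        terms = select_critical_nodes(g, 2, substrate_contacts=["A:3"])
        assert terms == {"A:2", "A:3"}

    def test_missing_mutation_site_rejected(self):
        df = contact_df([(1, 2, 0.2, 0.6)])
        g = classify_edges(build_graph(df), diff_threshold=0.3)
        with pytest.raises(ValueError, match="absent"):
            select_critical_nodes(g, 99)

    def test_cross_chain_contacts_become_terminals(self):
        rows = []
        for cond, f1, f2 in (("wt", 0.2, 0.9), ("mutant", 0.6, 0.9)):
            for rep in (1, 2):
                rows.append(("A:5", "B:2", cond, rep, f1))
                rows.append(("A:5", "A:6", cond, rep, f2))
        df = pd.DataFrame(rows, columns=["res_i", "res_j", "condition", "replicate", "frequency"])
        g = classify_edges(build_graph(df), diff_threshold=0.3)
        terms = select_critical_nodes(g, "A:6")
        assert {"A:5", "A:6", "B:2"} <= terms

    def test_fragment_residues_extended_downstream(self):
        df = contact_df([(1, 2, 0.2, 0.6), (2, 3, 0.2, 0.6)])
        g = classify_edges(build_graph(df), diff_threshold=0.3)
        terms = select_critical_nodes(g, 1, differential_fragment_residues=[2])
        assert {"A:2", "A:3"} <= terms  # 2 and its downstream neighbor 3


class TestSteiner:
    def _weighted_graph(self, edges):
        g = nx.Graph()
        for u, v, f in edges:
            g.add_edge(u, v, wt_mean=f, mut_mean=f, diff=0.0)
        return g

    def test_path_graph_unique_connector(self):
        g = self._weighted_graph([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5)])
        res = steiner_pathway(g, ["a", "d"])
        assert res.nodes == {"a", "b", "c", "d"}
        assert res.steiner_nodes == {"b", "c"}

    def test_star_center_is_single_steiner_node(self):
        g = self._weighted_graph([("x", l, 0.5) for l in ("p", "q", "r")])
        res = steiner_pathway(g, ["p", "q", "r"])
        assert res.steiner_nodes == {"x"}
        assert res.total_weight == pytest.approx(brute_force_steiner(g, ["p", "q", "r"]))

    def test_exact_on_trees(self, rng):
        for i in range(10):
            t = nx.random_labeled_tree(10, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(t, {n: f"n{n}" for n in t.nodes})
            for _u, _v, d in g.edges(data=True):
                f = rng.uniform(0.1, 0.9)
                d.update(wt_mean=f, mut_mean=f, diff=0.0)
            terminals = [f"n{n}" for n in rng.choice(10, size=4, replace=False)]
            res = steiner_pathway(g, terminals)
            assert res.total_weight == pytest.approx(brute_force_steiner(g, terminals))

    def test_two_approximation_on_random_graphs(self, rng):
        checked = 0
        for i in range(40):
            n = int(rng.integers(6, 13))
            g0 = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g0):
                continue
            g = nx.relabel_nodes(g0, {v: f"n{v}" for v in g0.nodes})
            for _u, _v, d in g.edges(data=True):
                f = rng.uniform(0.05, 0.95)
                d.update(wt_mean=f, mut_mean=f, diff=0.0)
            k = int(rng.integers(2, 6))
            terminals = [f"n{v}" for v in rng.choice(n, size=min(k, n), replace=False)]
            res = steiner_pathway(g, terminals)
            sub = nx.Graph(res.edges)
            assert set(terminals) <= set(sub.nodes) | set(terminals)
            if res.edges:
                assert nx.is_connected(sub)
            opt = brute_force_steiner(g, terminals)
            assert res.total_weight <= 2 * opt + 1e-9
            checked += 1
        assert checked >= 20

    def test_disconnected_terminals_rejected(self):
        g = self._weighted_graph([("a", "b", 0.5), ("c", "d", 0.5)])
        with pytest.raises(ValueError, match="different components"):
            steiner_pathway(g, ["a", "c"])

    def test_conserved_runs_collapse_into_supernodes(self):
        g = nx.Graph()
        chain = ["a", "m1", "m2", "m3", "b"]
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v, wt_mean=0.9, mut_mean=0.92, diff=0.02, edge_class="conserved")
        res = steiner_pathway(g, ["a", "b"])
        assert set(res.supernode_map) == {"m1", "m2", "m3"}
        assert len(set(res.supernode_map.values())) == 1


class TestMetastates:
    def test_binarization_boundary(self):
        t = {
            "m1": contact_df([(1, 2, 0.29, 0.29)])[lambda d: d.condition == "wt"],
            "m2": contact_df([(1, 2, 0.30, 0.30)])[lambda d: d.condition == "wt"],
        }
        out = metastate_intersections(t)
        assert out["m1"] == set()
        assert out["m2"] == {("A:1", "A:2")}

    def test_identical_states_intersection(self):
        df = contact_df([(1, 2, 0.5, 0.5), (3, 4, 0.4, 0.4)])
        out = metastate_intersections({"a": df, "b": df.copy()})
        assert out["shared"] == out["a"] == out["b"]

    def test_set_arithmetic(self):
        a = contact_df([(1, 2, 0.5, 0.5), (2, 3, 0.5, 0.5)])
        b = contact_df([(2, 3, 0.5, 0.5), (3, 4, 0.5, 0.5)])
        out = metastate_intersections({"a": a, "b": b})
        assert out["shared"] == {("A:2", "A:3")}
        assert out["a_only"] == {("A:1", "A:2")}


class TestFragments:
    def frag_df(self, pairs):
        rows = []
        for (fi, fj, wt, mut) in pairs:
            for cond, f in (("wt", wt), ("mutant", mut)):
                for rep, jit in ((1, 0.0), (2, 1e-4)):
                    rows.append((fi, fj, cond, rep, f + jit))
        return pd.DataFrame(rows, columns=["fragment_i", "fragment_j", "condition", "replicate", "frequency"])

    def test_identical_conditions_not_significant(self):
        out = differential_fragments(self.frag_df([(1, 2, 0.1, 0.1), (2, 3, 0.4, 0.4)]))
        assert (out.call == "ns").all()

    def test_32_fold_change_with_tight_replicates_is_up(self):
        out = differential_fragments(
            self.frag_df([(1, 2, 0.01, 0.32)] + [(k, k + 1, 0.1, 0.1) for k in range(2, 8)])
        )
        row = out.set_index(["fragment_i", "fragment_j"]).loc[(1, 2)]
        assert row.log2fc == pytest.approx(5.0, abs=0.01)
        if row.q < 1e-4:
            assert row.call == "up"

    def test_fold_change_gate_blocks_small_effects(self):
        out = differential_fragments(
            self.frag_df([(1, 2, 0.02, 0.02 * 2**3.9)])
        )
        row = out.iloc[0]
        assert row.log2fc < 4.0
        assert row.call == "ns"


class TestEndToEndPathway:
    def test_planted_pathway_recovered(self):
        planted = list(range(5, 15))
        df = generate_contact_tables(40, planted, effect=0.4, seed=8)
        g = classify_edges(build_graph(df), diff_threshold=0.3)
        g = prune_components(g)
        terminals = [f"A:{planted[0]}", f"A:{planted[-1]}"]
        res = steiner_pathway(g, terminals)
        planted_nodes = {f"A:{r}" for r in planted}
        overlap = len(res.nodes & planted_nodes) / len(planted_nodes)
        assert overlap >= 0.9
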