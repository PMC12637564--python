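"""Residue interaction graphs, differential edge classes, Steiner pathways.

Contact-frequency tables from wild-type and mutant simulations are reduced to
a residue graph (edges kept when either condition's replicate-mean frequency
exceeds 0.01), classified as up-/down-regulated in the mutant (mean-difference
threshold, variant specific), conserved (both means > 0.8 and |difference| <
0.1), or sequence-neighbor relay edges; small components (< 4 nodes) are
pruned. Minimal allosteric pathways connecting a set of critical residues are
extracted with a 2-approximation of the Steiner tree problem (metric closure
+ minimum spanning tree + shortest-path expansion + leaf pruning, deterministic
tie-breaks), and runs of conserved intermediates collapse into supernodes.
Structural-fragment count tables are compared between conditions by log2 fold
change with BH-corrected per-fragment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests


def _node(chain: str, resid: int) -> str:
    return f"{chain}:{resid}"


def parse_node(node) -> tuple[str, int] | None:
    """Nodes are 'A:123' strings (chain A = kinase, B = substrate) or bare ints
    (implicit chain A). Returns None for labels without residue structure."""
    if isinstance(node, (int, np.integer)):
        return "A", int(node)
    text = str(node)
    if ":" in text:
        chain, resid = text.split(":")
        return chain, int(resid)
    if text.isdigit():
        return "A", int(text)
    return None


def _canonical(node) -> str:
    parsed = parse_node(node)
    if parsed is None:
        return str(node)
    return _node(*parsed)


# --------------------------------------------------------------------------
# graph construction and classification
# --------------------------------------------------------------------------


def build_graph(tables: pd.DataFrame, freq_min: float = 0.01) -> nx.Graph:
    """Residue graph from a long-form contact table.

    ``tables`` has columns res_i, res_j, condition ('wt'/'mutant'), replicate,
    frequency. Replicate means are computed per condition first; an edge is
    kept iff max(wt_mean, mut_mean) > ``freq_min``. Self-pairs are dropped and
    symmetric duplicates merged.
    """
    df = tables.copy()
    if df.empty:
        return nx.Graph()
    conditions = set(df["condition"].unique())
    if not {"wt", "mutant"} <= conditions:
        raise ValueError("contact table must contain both 'wt' and 'mutant' conditions")
    df["u"] = df["res_i"].map(_canonical)
    df["v"] = df["res_j"].map(_canonical)
    swap = df["u"] > df["v"]
    df.loc[swap, ["u", "v"]] = df.loc[swap, ["v", "u"]].to_numpy()
    df = df[df["u"] != df["v"]]
    means = df.groupby(["u", "v", "condition"])["frequency"].mean().unstack("condition")
    means = means.reindex(columns=["wt", "mutant"]).fillna(0.0)
    graph = nx.Graph()
    for (u, v), row in means.iterrows():
        wt, mut = float(row["wt"]), float(row["mutant"])
        if max(wt, mut) > freq_min:
            graph.add_edge(u, v, wt_mean=wt, mut_mean=mut, diff=mut - wt)
    return graph


def classify_edges(graph: nx.Graph, diff_threshold: float) -> nx.Graph:
    """Classify edges as conserved / up / down; add neighbor relays; drop the rest.

    Conserved is tested first (both means > 0.8 and |diff| < 0.1), then
    up (mut - wt >= threshold) / down (wt - mut >= threshold); unclassified
    edges are dropped. Sequence-adjacent pairs touching a classified node are
    re-added as 'neighbor' relay edges when the contact existed in the input
    graph. Classes are mutually exclusive by construction.
    """
    if diff_threshold <= 0:
        raise ValueError("diff_threshold must be positive")
    out = nx.Graph()
    for u, v, data in graph.edges(data=True):
        wt, mut = data["wt_mean"], data["mut_mean"]
        diff = mut - wt
        if wt > 0.8 and mut > 0.8 and abs(diff) < 0.1:
            cls = "conserved"
        elif diff >= diff_threshold:
            cls = "up"
        elif -diff >= diff_threshold:
            cls = "down"
        else:
            continue
        out.add_edge(u, v, **data, edge_class=cls)
    classified_nodes = list(out.nodes)
    for node in classified_nodes:
        parsed = parse_node(node)
        if parsed is None:
            continue
        chain, resid = parsed
        for nb in (_node(chain, resid - 1), _node(chain, resid + 1)):
            if graph.has_edge(node, nb) and not out.has_edge(node, nb):
                data = graph.edges[node, nb]
                out.add_edge(node, nb, **data, edge_class="neighbor")
    return out


def prune_components(graph: nx.Graph, min_size: int = 4) -> nx.Graph:
    """Remove connected components with fewer than ``min_size`` nodes."""
    keep = [c for c in nx.connected_components(graph) if len(c) >= min_size]
    return graph.subgraph(set().union(*keep) if keep else set()).copy()


# --------------------------------------------------------------------------
# critical nodes and Steiner pathways
# --------------------------------------------------------------------------


def select_critical_nodes(
    graph: nx.Graph,
    mutation_site,
    substrate_contacts=(),
    differential_fragment_residues=(),
    extend_downstream: bool = True,
) -> set[str]:
    """Union of the four critical-residue categories, restricted to the graph.

    (1) the mutated residue; (2) substrate (chain B) residues with differential
    kinase contacts; (3) kinase (chain A) residues directly contacting the
    substrate; (4) residues of significant structural fragments, each extended
    one residue downstream. Explicit ``substrate_contacts`` are added to (2)/(3).
    """
    site = _canonical(mutation_site)
    if site not in graph:
        raise ValueError(f"mutation site {site} absent from graph")
    terminals = {site}
    for u, v, data in graph.edges(data=True):
        pu, pv = parse_node(u), parse_node(v)
        if pu is None or pv is None:
            continue
        if pu[0] != pv[0]:  # kinase-substrate contact
            if data.get("edge_class") in ("up", "down"):
                terminals.add(u if pu[0] == "B" else v)
            terminals.add(u if pu[0] == "A" else v)
    terminals.update(_canonical(n) for n in substrate_contacts if _canonical(n) in graph)
    for r in differential_fragment_residues:
        parsed = parse_node(r)
        if parsed is None:
            continue
        chain, resid = parsed
        cands = [resid, resid + 1] if extend_downstream else [resid]
        for rr in cands:
            n = _node(chain, rr)
            if n in graph:
                terminals.add(n)
    return terminals


@dataclass
class PathwayResult:
    terminals: set[str]
    steiner_nodes: set[str]
    edges: list[tuple[str, str]]
    total_weight: float
    supernode_map: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return self.terminals | self.steiner_nodes


def _edge_weight(data: dict) -> float:
    """Default traversal cost: 1 - mean contact frequency (strong contacts are cheap)."""
    return 1.0 - 0.5 * (data["wt_mean"] + data["mut_mean"])


def _weighted(graph: nx.Graph, unit_weights: bool) -> nx.Graph:
    g = graph.copy()
    for u, v, data in g.edges(data=True):
        data["weight"] = 1.0 if unit_weights else _edge_weight(data)
    return g


def steiner_pathway(
    graph: nx.Graph, terminals, unit_weights: bool = False, collapse_conserved: bool = True
) -> PathwayResult:
    """2-approximate minimum Steiner tree over the terminal set.

    Metric closure over terminals (Dijkstra), minimum spanning tree of the
    terminal complete graph (ties broken by sorted node pair), expansion of
    MST edges into shortest paths, MST of the expanded subgraph, and repeated
    pruning of non-terminal leaves. Runs of degree-2 non-terminal nodes whose
    incident edges are all conserved collapse into supernodes in the report.
    """
    terminals = sorted({_canonical(t) for t in terminals})
    missing = [t for t in terminals if t not in graph]
    if missing:
        raise ValueError(f"terminals absent from graph: {missing}")
    if len(terminals) == 1:
        return PathwayResult(set(terminals), set(), [], 0.0)
    g = _weighted(graph, unit_weights)
    dist: dict[str, dict] = {}
    paths: dict[str, dict] = {}
    for t in terminals:
        d, p = nx.single_source_dijkstra(g, t, weight="weight")
        dist[t], paths[t] = d, p
    for a, b in combinations(terminals, 2):
        if b not in dist[a]:
            raise ValueError(f"terminals {a} and {b} lie in different components")
    closure = nx.Graph()
    for a, b in combinations(terminals, 2):
        closure.add_edge(a, b, weight=dist[a][b], pair=(a, b))
    mst = nx.minimum_spanning_edges(closure, algorithm="kruskal", data=True)
    expanded = nx.Graph()
    # kruskal on edges sorted by (weight, node pair) for determinism
    for a, b, _data in sorted(mst, key=lambda e: (e[2]["weight"], e[0], e[1])):
        path = paths[a][b]
        nx.add_path(expanded, path)
    sub = g.edge_subgraph(expanded.edges).copy()
    tree = nx.minimum_spanning_tree(sub, weight="weight")
    # prune non-terminal leaves
    terminal_set = set(terminals)
    changed = True
    while changed:
        changed = False
        for node in sorted(tree.nodes):
            if tree.degree(node) <= 1 and node not in terminal_set:
                tree.remove_node(node)
                changed = True
    edges = sorted(tuple(sorted(e)) for e in tree.edges)
    total = float(sum(g.edges[e]["weight"] for e in edges))
    steiner_nodes = set(tree.nodes) - terminal_set
    supernode_map: dict[str, str] = {}
    if collapse_conserved:
        def is_collapsible(n: str) -> bool:
            return (
                n in steiner_nodes
                and tree.degree(n) == 2
                and all(g.edges[n, nb].get("edge_class") == "conserved" for nb in tree.neighbors(n))
            )
        visited: set[str] = set()
        run_id = 0
        for node in sorted(tree.nodes):
            if node in visited or not is_collapsible(node):
                continue
            run = [node]
            visited.add(node)
            frontier = [nb for nb in tree.neighbors(node)]
            while frontier:
                nb = frontier.pop()
                if nb in visited or not is_collapsible(nb):
                    continue
                visited.add(nb)
                run.append(nb)
                frontier.extend(tree.neighbors(nb))
            run_id += 1
            for n in run:
                supernode_map[n] = f"S{run_id}"
    return PathwayResult(
        terminals=terminal_set,
        steiner_nodes=steiner_nodes,
        edges=edges,
        total_weight=total,
        supernode_map=supernode_map,
    )


def brute_force_steiner(graph: nx.Graph, terminals, unit_weights: bool = False) -> float:
    """Exact minimum Steiner tree weight by exhaustive Steiner-node subsets.

    Exponential in the number of non-terminal nodes -- an oracle for small
    graphs only (<= ~15 nodes).
    """
    terminals = sorted({_canonical(t) for t in terminals})
    g = _weighted(graph, unit_weights)
    others = sorted(set(g.nodes) - set(terminals))
    best = np.inf
    for r in range(len(others) + 1):
        for extra in combinations(others, r):
            nodes = set(terminals) | set(extra)
            sub = g.subgraph(nodes)
            if not nx.is_connected(sub) or len(sub) < len(nodes):
                continue
            w = sum(d["weight"] for _u, _v, d in nx.minimum_spanning_edges(sub, data=True))
            best = min(best, w)
    return float(best)


# --------------------------------------------------------------------------
# metastates and fragments
# --------------------------------------------------------------------------


def metastate_contact_sets(
    tables: dict[str, pd.DataFrame], threshold: float = 0.3
) -> dict[str, set[tuple[str, str]]]:
    """Binarize per-metastate contact frequencies: present iff frequency >= threshold."""
    sets = {}
    for name, df in tables.items():
        freq = df.groupby([df["res_i"].map(_canonical), df["res_j"].map(_canonical)])[
            "frequency"
        ].mean()
        sets[name] = {tuple(sorted(pair)) for pair, f in freq.items() if f >= threshold}
    return sets


def metastate_intersections(
    tables: dict[str, pd.DataFrame], threshold: float = 0.3
) -> dict[str, set[tuple[str, str]]]:
    """Shared and unique contacts across metastates.

    Returns the binarized contact set per state, the intersection across all
    states (key ``shared``), and per-state unique contacts (``<name>_only``).
    """
    if len(tables) < 2:
        raise ValueError("need >=2 metastates")
    sets = metastate_contact_sets(tables, threshold)
    out: dict[str, set] = dict(sets)
    names = list(sets)
    shared = set.intersection(*sets.values())
    out["shared"] = shared
    for name in names:
        others = set.union(*(sets[n] for n in names if n != name)) if len(names) > 1 else set()
        out[f"{name}_only"] = sets[name] - others
    return out


def differential_fragments(
    counts: pd.DataFrame,
    fdr: float = 1e-4,
    log2fc_up: float = 4.0,
    log2fc_down: float = -4.0,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Differential structural-fragment statistics between wt and mutant.

    ``counts`` is long form: fragment_i, fragment_j, condition, replicate,
    frequency. log2FC is computed on pseudocounted replicate-mean frequencies;
    a per-fragment Welch t-test on logit frequencies feeds BH correction
    across fragments; calls require q < ``fdr`` AND the fold-change gate.
    """
    def logit(x):
        x = np.clip(x, 1e-9, 1 - 1e-9)
        return np.log(x / (1 - x))

    rows = []
    for (fi, fj), grp in counts.groupby(["fragment_i", "fragment_j"]):
        wt = grp.loc[grp["condition"] == "wt", "frequency"].to_numpy(dtype=float)
        mut = grp.loc[grp["condition"] == "mutant", "frequency"].to_numpy(dtype=float)
        if len(wt) < 2 or len(mut) < 2:
            raise ValueError("need >=2 replicates per condition for every fragment pair")
        lfc = float(np.log2((mut.mean() + pseudocount) / (wt.mean() + pseudocount)))
        if np.allclose(wt, mut[: len(wt)]) and np.isclose(wt.var(), 0) and np.isclose(mut.var(), 0) and lfc == 0:
            p = 1.0
        else:
            p = float(ttest_ind(logit(mut), logit(wt), equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
        rows.append({"fragment_i": fi, "fragment_j": fj, "log2fc": lfc, "p": p})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["call"] = "ns"
    out.loc[(out["q"] < fdr) & (out["log2fc"] > log2fc_up), "call"] = "up"
    out.loc[(out["q"] < fdr) & (out["log2fc"] < log2fc_down), "call"] = "down"
    return out


def graph_to_edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "res_i": u, "res_j": v,
            "wt_mean": d.get("wt_mean", np.nan), "mut_mean": d.get("mut_mean", np.nan),
            "diff": d.get("diff", np.nan), "edge_class": d.get("edge_class", ""),
        }
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows)
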