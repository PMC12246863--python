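"""Prize-collecting Steiner forest integration of transcriptome and kinome.

Evidence from both omics is placed on a PPI network: transcriptomic hits
(FDR < 0.05) are prized by the percentile rank of |log2FC| among hits,
kinase hits by their mean consensus score, dual-evidence nodes by the max of
the two. Edge costs invert the interaction confidence
(cost = 1 - confidence + eps). The solver seeks a forest F minimizing

    sum_{v not in F} beta * p(v)  +  sum_{e in F} c(e)  +  omega * (#trees)

so unclaimed prizes are paid as penalties, edges cost their weight and every
extra tree costs omega. The heuristic grows trees greedily from high-prize
terminals, merges trees when a connecting path pays for itself, and finishes
with an exact dynamic-programming prune of each candidate tree; on acyclic
inputs the DP alone already yields the optimum. A subset-enumeration brute
force serves as an independent oracle on small instances. Forest nodes are
ranked by the average of node prize and eigenvector centrality.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .transcriptome import percentile_rank

EDGE_COST_EPS = 1e-6


@dataclass
class PrizedNetwork:
    """PPI graph with node prizes, edge costs, and PCSF parameters."""

    graph: nx.Graph
    beta: float = 1.0
    omega: float = 2.0

    def __post_init__(self):
        if self.beta < 0 or self.omega < 0:
            raise ValueError("beta and omega must be >= 0")
        for u, v, d in self.graph.edges(data=True):
            if "cost" not in d:
                d["cost"] = edge_cost(d["confidence"])
        for _, d in self.graph.nodes(data=True):
            d.setdefault("prize", 0.0)
            d.setdefault("provenance", "none")

    def prizes(self) -> dict[str, float]:
        return {v: d["prize"] for v, d in self.graph.nodes(data=True)}


@dataclass
class SteinerForest:
    nodes: frozenset
    edges: frozenset
    labels: dict
    objective: float
    n_trees: int

    def validate(self, prized: "PrizedNetwork") -> None:
        """Structural invariants: forest, endpoint-closed, objective consistent."""
        if not self.nodes:
            assert not self.edges and self.n_trees == 0
            return
        sub = nx.Graph()
        sub.add_nodes_from(self.nodes)
        for u, v in self.edges:
            assert u in self.nodes and v in self.nodes, "edge endpoint not selected"
            sub.add_edge(u, v)
        assert nx.is_forest(sub), "selected edges contain a cycle"
        assert nx.number_connected_components(sub) == self.n_trees


def edge_cost(confidence: float, eps: float = EDGE_COST_EPS) -> float:
    """Inverse-confidence edge cost: 1 - confidence + eps (bounded in (eps, 1])."""
    if not 0.0 < confidence <= 1.0:
        raise ValueError("confidence must be in (0, 1]")
    return 1.0 - confidence + eps


def forest_objective(prized: PrizedNetwork, nodes: set, edges: set, n_trees: int) -> float:
    g = prized.graph
    penalty = sum(d["prize"] for v, d in g.nodes(data=True) if v not in nodes)
    cost = sum(g[u][v]["cost"] for u, v in edges)
    return prized.beta * penalty + cost + prized.omega * n_trees


def assign_prizes(network: nx.Graph, de_hits: pd.DataFrame, consensus: pd.DataFrame,
                  beta: float = 1.0, omega: float = 2.0) -> PrizedNetwork:
    """Place omic prizes on a PPI network.

    de_hits: DE rows already restricted to FDR < 0.05; prize = percentile
    rank of |log2FC| among those hits. consensus: kinase consensus table;
    prize = mean_score. Nodes hit by both take the max with provenance
    'rna+kinase'. Ids absent from the network are collected on the returned
    object's `unmapped` list with a warning.
    """
    if de_hits.empty and consensus.empty:
        raise ValueError("no transcriptomic or kinomic hits: nothing to integrate")
    g = network.copy()
    nx.set_node_attributes(g, 0.0, "prize")
    nx.set_node_attributes(g, "none", "provenance")
    unmapped: list[str] = []

    if len(de_hits):
        pct = percentile_rank(de_hits["log2FC"].abs().to_numpy())
        for gene, p in zip(de_hits["gene"], pct):
            if gene not in g:
                unmapped.append(gene)
                continue
            g.nodes[gene]["prize"] = float(p)
            g.nodes[gene]["provenance"] = "rna"
    for kinase, score in zip(consensus.get("kinase", []), consensus.get("mean_score", [])):
        if kinase not in g:
            unmapped.append(kinase)
            continue
        node = g.nodes[kinase]
        if node["provenance"] == "rna":
            node["prize"] = float(max(node["prize"], score))
            node["provenance"] = "rna+kinase"
        else:
            node["prize"] = float(score)
            node["provenance"] = "kinase"
    if unmapped:
        warnings.warn(f"{len(unmapped)} hit ids not in the network", stacklevel=2)
    prized = PrizedNetwork(g, beta=beta, omega=omega)
    prized.unmapped = unmapped
    return prized


# ---------------------------------------------------------------------------
# exact DP on trees (also the strong-pruning pass of the heuristic)

def _tree_dp(tree: nx.Graph, prizes: dict, beta: float, omega: float):
    """Optimal prize-collecting sub-forest *within* a given tree.

    Returns (objective contribution over this tree's nodes, node set, edge
    set, n_trees). B(v): v is in a component left open toward its parent;
    A(v): subtree fully resolved (v's component, if any, closed). Exclusion
    of v pays beta*p(v).
    """
    nodes = sorted(tree.nodes)
    if not nodes:
        return 0.0, set(), set(), 0
    total_obj, sel_nodes, sel_edges, n_trees = 0.0, set(), set(), 0
    seen = set()
    for root in nodes:
        if root in seen:
            continue
        comp = nx.node_connected_component(tree, root)
        seen |= comp
        # iterative post-order over the tree rooted at `root`
        parent = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for w in sorted(tree.neighbors(u)):
                if w != parent[u]:
                    parent[w] = u
                    order.append(w)
                    stack.append(w)
        A: dict = {}
        B: dict = {}
        choiceB: dict = {}  # child -> "open" (keep edge) or "closed"
        for u in reversed(order):
            b = 0.0
            a_excl = beta * prizes.get(u, 0.0)
            for w in sorted(tree.neighbors(u)):
                if w == parent[u]:
                    continue
                open_cost = B[w] + tree[u][w]["cost"]
                if open_cost < A[w]:
                    b += open_cost
                    choiceB[(u, w)] = "open"
                else:
                    b += A[w]
                    choiceB[(u, w)] = "closed"
                a_excl += A[w]
            B[u] = b
            A[u] = min(b + omega, a_excl)
        total_obj += A[root]
        # reconstruct: state 'A' or 'B' per node, top down
        stack2 = [(root, "A")]
        while stack2:
            u, state = stack2.pop()
            if state == "A":
                if A[u] == B[u] + omega:
                    # close a component at u (min() returned this branch)
                    n_trees += 1
                    state = "B"
                else:
                    # u excluded; children resolved independently
                    for w in sorted(tree.neighbors(u)):
                        if w != parent[u]:
                            stack2.append((w, "A"))
                    continue
            # state == "B": u selected
            sel_nodes.add(u)
            for w in sorted(tree.neighbors(u)):
                if w == parent[u]:
                    continue
                if choiceB[(u, w)] == "open":
                    sel_edges.add(frozenset((u, w)))
                    sel_nodes.add(w)
                    stack2.append((w, "B"))
                else:
                    stack2.append((w, "A"))
    # selected-but-not-via-edge nodes were added through "B" states only
    sel_edges = {tuple(sorted(e)) for e in sel_edges}
    return total_obj, sel_nodes, sel_edges, n_trees


def _reconstruct_forest(prized: PrizedNetwork, node_sets: list[set]):
    """Given candidate node groups, take the MST of each induced subgraph and
    DP-prune it; return merged (nodes, edges, n_trees)."""
    g = prized.graph
    prizes = prized.prizes()
    all_nodes: set = set()
    all_edges: set = set()
    n_trees = 0
    for group in node_sets:
        sub = g.subgraph(group)
        for comp in nx.connected_components(sub):
            mst = nx.minimum_spanning_tree(sub.subgraph(comp), weight="cost")
            _, nodes, edges, k = _tree_dp(mst, prizes, prized.beta, prized.omega)
            all_nodes |= nodes
            all_edges |= edges
            n_trees += k
    return all_nodes, all_edges, n_trees


def pcsf_solve(prized: PrizedNetwork) -> SteinerForest:
    """Heuristic PCSF: greedy growth + merge + exact per-tree DP pruning.

    Deterministic: ties break on sorted node ids. All-zero prizes yield the
    empty forest with objective 0.
    """
    g = prized.graph
    beta, omega = prized.beta, prized.omega
    prizes = prized.prizes()
    terminals = sorted((v for v, p in prizes.items() if p > 0),
                       key=lambda v: (-prizes[v], v))
    if not terminals:
        return SteinerForest(frozenset(), frozenset(), {}, 0.0, 0)

    if nx.is_forest(g):
        # acyclic input: the DP is exact on each component directly
        nodes, edges, k = _reconstruct_forest(prized, [set(g.nodes)])
    else:
        nodes, edges, k = _grow_and_merge(prized, terminals)

    obj = forest_objective(prized, nodes, edges, k)
    labels = {}
    for v in nodes:
        prov = g.nodes[v].get("provenance", "none")
        if prizes.get(v, 0) <= 0:
            labels[v] = "hidden"
        elif prov in ("kinase",):
            labels[v] = "terminal-kinase"
        elif prov == "rna+kinase":
            labels[v] = "terminal-rna+kinase"
        else:
            labels[v] = "terminal-rna"
    forest = SteinerForest(frozenset(nodes), frozenset(edges), labels, obj, k)
    forest.validate(prized)
    return forest


def _grow_and_merge(prized: PrizedNetwork, terminals: list):
    g = prized.graph
    beta, omega = prized.beta, prized.omega
    prizes = prized.prizes()

    trees: list[set] = []  # node groups (trees realized later via MST + DP)

    def in_forest(v):
        return any(v in t for t in trees)

    def path_gain(path, extra_excluded=()):
        """Prize collected along a path by nodes not already in the forest."""
        return sum(beta * prizes.get(w, 0.0) for w in path
                   if not in_forest(w) and w not in extra_excluded)

    # growth: repeatedly apply the globally best improving move among
    # open-singleton, join-existing-tree, and pair-two-unclaimed-terminals
    while True:
        unclaimed = [v for v in terminals if not in_forest(v)]
        best = (-1e-12, None)
        for v in unclaimed:
            lengths, paths = nx.single_source_dijkstra(g, v, weight="cost")
            delta = omega - beta * prizes[v]
            if delta < best[0]:
                best = (delta, ("new", [v]))
            for i, t in enumerate(trees):
                for tgt in sorted(t):
                    if tgt not in lengths:
                        continue
                    path = paths[tgt]
                    delta = lengths[tgt] - path_gain(path)
                    if delta < best[0]:
                        best = (delta, ("join", (i, path)))
            for w in unclaimed:
                if w <= v or w not in lengths:
                    continue
                path = paths[w]
                delta = lengths[w] + omega - path_gain(path)
                if delta < best[0]:
                    best = (delta, ("new", paths[w]))
        if best[1] is None:
            break
        action, payload = best[1]
        if action == "new":
            trees.append(set(payload))
        else:
            i, path = payload
            trees[i] |= set(path)
        # a path may touch other trees: merge any overlapping groups
        merged = True
        while merged:
            merged = False
            for i, j in itertools.combinations(range(len(trees)), 2):
                if trees[i] & trees[j]:
                    trees[i] |= trees.pop(j)
                    merged = True
                    break

    # merging phase: connect two trees when the path beats one omega
    improved = True
    while improved and len(trees) > 1:
        improved = False
        best = (np.inf, None)
        for i, j in itertools.combinations(range(len(trees)), 2):
            adj, path = _cheapest_between(g, trees[i], trees[j], beta, prizes, trees)
            if path is None:
                continue
            delta = adj - omega
            if delta < best[0]:
                best = (delta, (i, j, path))
        if best[1] is not None and best[0] < -1e-12:
            i, j, path = best[1]
            trees[i] |= trees[j] | set(path)
            trees.pop(j)
            improved = True

    return _reconstruct_forest(prized, trees)


def _cheapest_between(g, group_a, group_b, beta, prizes, trees):
    best = (np.inf, None)
    for src in sorted(group_a):
        lengths, paths = nx.single_source_dijkstra(g, src, weight="cost")
        for tgt in sorted(group_b):
            if tgt not in lengths:
                continue
            path = paths[tgt]
            gain = sum(beta * prizes.get(w, 0.0) for w in path[1:-1]
                       if not any(w in t for t in trees))
            adj = lengths[tgt] - gain
            if adj < best[0]:
                best = (adj, path)
    return best


def pcsf_brute_force(prized: PrizedNetwork, max_nodes: int = 12) -> SteinerForest:
    """Exact optimum by subset enumeration (test oracle, <= `max_nodes` nodes).

    For every node subset, the cheapest feasible forest is the minimum
    spanning forest of the induced subgraph; objective adds beta-weighted
    penalties for excluded prizes and omega per component.
    """
    g = prized.graph
    nodes = sorted(g.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes")
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    cost_mat = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        cost_mat[idx[u], idx[v]] = cost_mat[idx[v], idx[u]] = d["cost"]
    prizes = prized.prizes()
    total_prize = prized.beta * sum(prizes.values())

    # virtual-root trick: joining every selected node to a root at cost omega
    # makes "MST of the augmented subset graph" the exact cheapest forest for
    # that subset (each root edge opens one tree). csgraph drops exact zeros,
    # so omega is floored at a negligible positive value.
    root_cost = max(prized.omega, 1e-12)
    best = (0.0 + total_prize, frozenset(), frozenset(), 0)  # empty forest
    for mask in range(1, 2 ** n):
        sel = [i for i in range(n) if mask >> i & 1]
        k = len(sel)
        aug = np.zeros((k + 1, k + 1))
        aug[1:, 1:] = cost_mat[np.ix_(sel, sel)]
        aug[0, 1:] = aug[1:, 0] = root_cost
        mst = minimum_spanning_tree(csr_matrix(aug))
        rows, cols = mst.nonzero()
        n_comp = sum(1 for r, c in zip(rows, cols) if r == 0 or c == 0)
        mst_cost = float(mst.sum()) - n_comp * root_cost
        collected = prized.beta * sum(prizes[nodes[i]] for i in sel)
        obj = (total_prize - collected) + mst_cost + prized.omega * n_comp
        if obj < best[0] - 1e-12:
            edges = frozenset(
                tuple(sorted((nodes[sel[r - 1]], nodes[sel[c - 1]])))
                for r, c in zip(rows, cols) if r != 0 and c != 0)
            best = (float(obj), frozenset(nodes[i] for i in sel), edges, n_comp)
    obj, sel_nodes, sel_edges, n_comp = best
    labels = {v: ("hidden" if prizes.get(v, 0) <= 0 else "terminal") for v in sel_nodes}
    return SteinerForest(sel_nodes, sel_edges, labels, obj, n_comp)


# ---------------------------------------------------------------------------
# centrality, ranking, subnetworks

def eigencentrality(network: nx.Graph, weighted: bool = True, tol: float = 1e-10,
                    max_iter: int = 10000) -> dict:
    """Eigenvector centrality by power iteration, normalized so max = 1.

    Computed on the largest connected component of the (confidence-weighted)
    adjacency; nodes outside it, including isolated nodes, score 0.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = sorted(nx.connected_components(network), key=lambda c: (-len(c), min(c)))
    cc = sorted(comps[0])
    out = {v: 0.0 for v in network.nodes}
    if len(cc) == 1:
        out[cc[0]] = 1.0
        return out
    idx = {v: i for i, v in enumerate(cc)}
    n = len(cc)
    A = np.zeros((n, n))
    for u, v, d in network.subgraph(cc).edges(data=True):
        w = d.get("confidence", 1.0) if weighted else 1.0
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    # identity shift keeps the Perron vector but breaks the period-2
    # oscillation of bipartite (e.g. tree) adjacencies
    A = A + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(max_iter):
        x_new = A @ x
        norm = np.linalg.norm(x_new)
        if norm == 0:  # pragma: no cover
            break
        x_new /= norm
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")
    x = np.abs(x)
    x /= x.max()
    for v, i in idx.items():
        out[v] = float(x[i])
    return out


def rank_nodes(forest: SteinerForest, prized: PrizedNetwork,
               top_fraction: float = 0.10) -> tuple[pd.DataFrame, list]:
    """Rank forest nodes by the average of node prize and eigencentrality.

    Centrality is computed on the solved forest. Returns the full ranking
    (for preranked GSEA) and the top floor(top_fraction * n) slice (for ORA).
    """
    sub = nx.Graph()
    sub.add_nodes_from(forest.nodes)
    for u, v in forest.edges:
        sub.add_edge(u, v, **prized.graph[u][v])
    if sub.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "prize", "eigencentrality", "combined"]), []
    cent = eigencentrality(sub)
    prizes = prized.prizes()
    rows = [{"node": v, "prize": float(prizes.get(v, 0.0)),
             "eigencentrality": cent[v],
             "combined": (float(prizes.get(v, 0.0)) + cent[v]) / 2.0,
             "label": forest.labels.get(v, "hidden")}
            for v in sorted(forest.nodes)]
    ranking = pd.DataFrame(rows).sort_values(
        ["combined", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    k = int(np.floor(top_fraction * len(ranking)))
    return ranking, list(ranking["node"].iloc[:k])


def extract_subnetwork(forest: SteinerForest, members: set) -> nx.Graph:
    """Pathway subnetwork: forest members plus hidden nodes on the forest
    paths between them, with provenance labels preserved."""
    fg = nx.Graph()
    fg.add_nodes_from(forest.nodes)
    fg.add_edges_from(forest.edges)
    retained = sorted(set(members) & set(forest.nodes))
    keep: set = set(retained)
    for a, b in itertools.combinations(retained, 2):
        if nx.has_path(fg, a, b):
            keep |= set(nx.shortest_path(fg, a, b))
    sub = fg.subgraph(keep).copy()
    nx.set_node_attributes(sub, {v: forest.labels.get(v, "hidden") for v in sub.nodes},
                           "label")
    return sub
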