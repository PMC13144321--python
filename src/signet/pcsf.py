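"""Consensus subnetwork extraction with a randomized prize-collecting Steiner forest.

Terminals are the most PageRank-central nodes of a signed subnetwork,
prized by their (rescaled) centrality.  The PCSF objective minimized is
``sum(edge costs) - beta * sum(node prizes)`` with edge cost
``1 - confidence``; within each connected component at most one tree is
bought (possibly a singleton, possibly nothing).  The solver is an
approximation: strong pruning (the exact best-subtree dynamic program)
applied to the component's minimum spanning tree and to shortest-path
trees from several roots.  Robustness comes from re-solving under
multiplicative edge-cost noise and keeping high-frequency nodes/edges,
cycle-broken into a forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .propagation import SignedSubnetwork
from .types import edge_cost


@dataclass
class PCSFResult:
    node_frequency: pd.Series
    edge_frequency: dict               # frozenset({u,v}) -> frequency
    forest: nx.Graph
    objectives: list
    params: dict = field(default_factory=dict)


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, SignedSubnetwork) else network


def pagerank_centrality(network, damping: float = 0.85) -> pd.Series:
    """PageRank on the confidence-weighted graph (undirected = two arcs)."""
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    pr = nx.pagerank(g, alpha=damping, weight="confidence",
                     tol=1e-12, max_iter=2000)
    return pd.Series(pr).sort_index()


def select_terminals(centrality: pd.Series, n: int = 50) -> dict:
    """Top-n central nodes as terminals, prizes rescaled to max 1."""
    if n >= len(centrality):
        if n > len(centrality):
            warnings.warn("fewer nodes than requested terminals; using all",
                          stacklevel=2)
        top = centrality.sort_index()
    else:
        order = centrality.reset_index()
        order.columns = ["node", "c"]
        order = order.sort_values(["c", "node"], ascending=[False, True])
        top = order.head(n).set_index("node")["c"]
    return (top / top.max()).to_dict()


def _strong_prune(tree: nx.Graph, prizes: dict, beta: float,
                  costs: dict) -> tuple[float, object, list]:
    """Exact best subtree of `tree` (strong-pruning dynamic program).

    Every subtree has a unique topmost node in a rooted orientation, so
    one bottom-up pass computing the best downward subtree per node,
    maximized over nodes, is exact.  Returns (objective, top node, kept
    edges) with objective = cost - beta * prize.
    """
    root = next(iter(tree.nodes()))
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in tree.neighbors(v):
            if w not in parent:
                parent[w] = v
                stack.append(w)
    value = {}
    keep_children: dict = {v: [] for v in order}
    for v in reversed(order):
        val = beta * prizes.get(v, 0.0)
        for w in tree.neighbors(v):
            if parent.get(w) is v:
                c = costs[frozenset((v, w))]
                if value[w] - c > 1e-12:
                    val += value[w] - c
                    keep_children[v].append(w)
        value[v] = val
    best = max(sorted(value), key=lambda v: value[v])
    edges = []
    stack = [best]
    while stack:
        v = stack.pop()
        for w in keep_children[v]:
            edges.append((v, w))
            stack.append(w)
    return -value[best], best, edges


def pcsf_solve(network, prizes: dict, beta: float = 1.0,
               edge_costs: dict | None = None) -> tuple[nx.Graph, float]:
    """Approximate PCSF: best tree per connected component.

    Candidate trees are strong-pruned minimum-spanning and
    shortest-path trees; the empty solution (objective 0 per component)
    is allowed, so the returned objective is never positive.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    costs = {}
    for u, v, d in g.edges(data=True):
        c = (edge_costs[frozenset((u, v))] if edge_costs is not None
             else edge_cost(d.get("confidence", 0.5)))
        if c <= 0:
            raise ValueError(f"non-positive cost on edge ({u},{v})")
        costs[frozenset((u, v))] = float(c)
    if any(p < 0 for p in prizes.values()):
        raise ValueError("prizes must be non-negative")

    forest = nx.Graph()
    total = 0.0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        cg = nx.Graph()
        cg.add_nodes_from(sub.nodes())
        for u, v in sub.edges():
            cg.add_edge(u, v, cost=costs[frozenset((u, v))])
        candidates = [nx.minimum_spanning_tree(cg, weight="cost")]
        roots = sorted(comp, key=lambda n: (-prizes.get(n, 0.0), n))
        for r in roots[: min(len(roots), 8)]:
            t = nx.Graph()
            t.add_node(r)
            t.add_edges_from(_sp_tree_edges(cg, r))
            candidates.append(t)
        best_obj, best_edges, best_root = 0.0, [], None
        for tree in candidates:
            obj, top, edges = _strong_prune(tree, prizes, beta, costs)
            if obj < best_obj - 1e-12:
                best_obj, best_edges, best_root = obj, edges, top
        if best_obj < -1e-12:
            total += best_obj
            forest.add_node(best_root)
            for u, v in best_edges:
                forest.add_edge(u, v, cost=costs[frozenset((u, v))])
    return forest, total


def _sp_tree_edges(cg: nx.Graph, root):
    paths = nx.single_source_dijkstra_path(cg, root, weight="cost")
    edges = set()
    for p in paths.values():
        for u, v in zip(p[:-1], p[1:]):
            edges.add((u, v))
    return edges


def pcsf_randomized(network, prizes: dict, beta: float = 1.0,
                    n_iter: int = 4000, noise: float = 0.05,
                    freq_cutoff: float = 0.5, seed: int = 0) -> PCSFResult:
    """Re-solve PCSF under up-to-``noise`` multiplicative edge-cost noise.

    Node/edge consensus frequencies over ``n_iter`` solutions are
    thresholded at ``freq_cutoff``; cycle-closing low-frequency edges are
    dropped so the consensus is itself a forest.
    """
    if n_iter < 1 or not (0.0 <= noise < 1.0):
        raise ValueError("need n_iter >= 1 and noise in [0, 1)")
    g = _as_graph(network)
    base = {frozenset((u, v)): edge_cost(d.get("confidence", 0.5))
            for u, v, d in g.edges(data=True)}
    rng = np.random.default_rng(seed)
    node_count: dict = {n: 0 for n in g.nodes()}
    edge_count: dict = {e: 0 for e in base}
    objectives = []
    for _ in range(n_iter):
        jitter = {e: c * rng.uniform(1.0 - noise, 1.0 + noise)
                  for e, c in base.items()}
        forest, obj = pcsf_solve(g, prizes, beta=beta, edge_costs=jitter)
        objectives.append(obj)
        for n in forest.nodes():
            node_count[n] += 1
        for u, v in forest.edges():
            edge_count[frozenset((u, v))] += 1
    node_freq = pd.Series({n: c / n_iter for n, c in node_count.items()}).sort_index()
    edge_freq = {e: c / n_iter for e, c in edge_count.items()}

    consensus = nx.Graph()
    consensus.add_nodes_from(node_freq.index[node_freq >= freq_cutoff])
    kept = sorted(((f, tuple(sorted(e))) for e, f in edge_freq.items()
                   if f >= freq_cutoff), key=lambda t: (-t[0], t[1]))
    uf = {n: n for n in g.nodes()}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for f, (u, v) in kept:  # maximum-frequency spanning forest
        ru, rv = find(u), find(v)
        if ru != rv:
            uf[ru] = rv
            consensus.add_edge(u, v, frequency=f,
                               confidence=g[u][v].get("confidence"))
    return PCSFResult(node_frequency=node_freq, edge_frequency=edge_freq,
                      forest=consensus, objectives=objectives,
                      params={"beta": beta, "n_iter": n_iter, "noise": noise,
                              "freq_cutoff": freq_cutoff, "seed": seed})
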