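"""Signed network propagation: RWR, degree-preserving nulls, KDE filtering.

Seed proteins from the factor loadings are diffused over the
confidence-weighted interactome with a random walk with restart on the
symmetrically normalized adjacency (D^-1/2 A D^-1/2, which tempers hub
dominance).  Node significance is empirical, against random walks on
degree-preserving double-edge-swap rewirings of the network.  Retained
candidates are further filtered by the functional-similarity KDE rule,
and the positive- and negative-seed networks are merged into one signed
subnetwork per factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde

from .factors import SeedSet
from .types import validate_graph


@dataclass
class TransitionOperator:
    """Symmetric-normalized weighted adjacency with its node ordering."""

    matrix: sp.csr_matrix
    nodes: list
    index: dict

    def vector(self, weights: dict) -> np.ndarray:
        v = np.zeros(len(self.nodes))
        for n, w in weights.items():
            if n in self.index:
                v[self.index[n]] = w
        return v


@dataclass
class PropagationResult:
    scores: pd.Series                  # stationary probability per node
    empirical_p: pd.Series | None
    retained: list
    seeds: dict
    params: dict = field(default_factory=dict)


@dataclass
class SignedSubnetwork:
    """Node-induced subgraph with per-node sign labels {+, -} (or both)."""

    graph: nx.Graph
    signs: dict                        # node -> set of {"+", "-"}
    factor: int | str | None = None
    parent: nx.Graph | None = None

    @property
    def nodes(self):
        return set(self.graph.nodes())


def symmetric_normalize(graph: nx.Graph) -> TransitionOperator:
    """W = D^-1/2 A D^-1/2 on the confidence-weighted adjacency.

    Isolated nodes keep a zero row/column (excluded from the walk's
    support).  W is symmetric with spectral radius <= 1.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    A = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="confidence",
                                 format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    D = sp.diags(inv_sqrt)
    W = (D @ A @ D).tocsr()
    return TransitionOperator(matrix=W, nodes=nodes,
                              index={n: i for i, n in enumerate(nodes)})


def rwr(op: TransitionOperator, restart: dict | np.ndarray,
        damping: float = 0.95, tol: float = 1e-9,
        max_iter: int = 10_000) -> pd.Series:
    """Random walk with restart: fixed point of p = d W p + (1-d) p0.

    ``damping`` is the continuation probability (restart probability
    1 - d).  The converged vector is renormalized to sum 1 (symmetric
    normalization is not stochastic, so raw mass is arbitrary).
    """
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must be in (0, 1)")
    p0 = op.vector(restart) if isinstance(restart, dict) else np.asarray(restart, float)
    if p0.min() < 0 or p0.sum() <= 0:
        raise ValueError("restart vector must be non-negative with positive mass")
    p0 = p0 / p0.sum()
    p = p0.copy()
    W = op.matrix
    for _ in range(max_iter):
        nxt = damping * (W @ p) + (1.0 - damping) * p0
        delta = float(np.abs(nxt - p).sum())
        p = nxt
        if delta < tol:
            break
    else:
        raise RuntimeError(f"RWR did not converge; L1 residual {delta:.3e}")
    return pd.Series(p / p.sum(), index=op.nodes)


def rwr_closed_form(op: TransitionOperator, restart: dict | np.ndarray,
                    damping: float = 0.95) -> pd.Series:
    """Direct solve of (I - dW) p = (1-d) p0, renormalized (small graphs)."""
    p0 = op.vector(restart) if isinstance(restart, dict) else np.asarray(restart, float)
    p0 = p0 / p0.sum()
    n = len(op.nodes)
    M = np.eye(n) - damping * op.matrix.toarray()
    p = np.linalg.solve(M, (1.0 - damping) * p0)
    return pd.Series(p / p.sum(), index=op.nodes)


def _edge_arrays(graph: nx.Graph, nodes: list):
    index = {n: i for i, n in enumerate(nodes)}
    iu, iv, conf = [], [], []
    for u, v, d in graph.edges(data=True):
        iu.append(index[u])
        iv.append(index[v])
        conf.append(d["confidence"])
    return np.array(iu), np.array(iv), np.array(conf, float)


def _swap_edges(iu: np.ndarray, iv: np.ndarray, n_swaps: int, rng) -> None:
    """In-place double-edge swaps on integer endpoint arrays.

    Rejects self-loops and multi-edges; confidences stay attached to
    their array slot, i.e. they travel with the (rewired) edge.
    """
    edge_set = {(min(a, b), max(a, b)) for a, b in zip(iu.tolist(), iv.tolist())}
    m = len(iu)
    picks = rng.integers(m, size=(n_swaps, 2))
    flips = rng.random(n_swaps) < 0.5
    for t in range(n_swaps):
        i, j = picks[t]
        if i == j:
            continue
        u, v = int(iu[i]), int(iv[i])
        x, y = (int(iv[j]), int(iu[j])) if flips[t] else (int(iu[j]), int(iv[j]))
        if len({u, v, x, y}) < 4:
            continue
        e1 = (min(u, x), max(u, x))
        e2 = (min(v, y), max(v, y))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((min(u, v), max(u, v)))
        edge_set.discard((min(x, y), max(x, y)))
        edge_set.add(e1)
        edge_set.add(e2)
        iu[i], iv[i] = u, x
        iu[j], iv[j] = v, y


def degree_preserving_rewire(graph: nx.Graph, n_swaps: int | None = None,
                             seed: int = 0) -> nx.Graph:
    """Double-edge-swap rewiring; exact degree sequence, confidences travel.

    Attempts ``n_swaps`` swaps (default 10 x |E|), rejecting any swap
    that would create a self-loop or a multi-edge.
    """
    if graph.number_of_edges() < 2:
        raise ValueError("need >= 2 edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * graph.number_of_edges()
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())
    iu, iv, conf = _edge_arrays(graph, nodes)
    _swap_edges(iu, iv, n_swaps, rng)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for a, b, c in zip(iu.tolist(), iv.tolist(), conf.tolist()):
        out.add_edge(nodes[a], nodes[b], confidence=c)
    return out


def _dense_rwr(n: int, iu: np.ndarray, iv: np.ndarray, conf: np.ndarray,
               p0: np.ndarray, damping: float) -> np.ndarray:
    """Closed-form stationary scores (1-d)(I - dW)^-1 p0 on edge arrays.

    Equivalent to the iterative :func:`rwr` (checked to 1e-8 in the
    validation suite); used for the many small null networks where a
    direct dense solve is far cheaper than power iteration.
    """
    A = np.zeros((n, n))
    A[iu, iv] = conf
    A[iv, iu] = conf
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    W = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    p = np.linalg.solve(np.eye(n) - damping * W, (1.0 - damping) * p0)
    return p / p.sum()


def empirical_node_significance(graph: nx.Graph, restart: dict,
                                damping: float = 0.95, n_null: int = 1000,
                                seed: int = 0, observed: pd.Series | None = None,
                                tol: float = 1e-9) -> pd.Series:
    """Add-one empirical p per node against degree-preserving null walks.

    p(node) = (1 + #{nulls with score >= observed}) / (1 + n_null).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    op = symmetric_normalize(graph)
    if observed is None:
        observed = rwr(op, restart, damping=damping, tol=tol)
    obs = observed.reindex(op.nodes).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(op.nodes)
    p0 = op.vector(restart)
    p0 = p0 / p0.sum()
    n_swaps = 10 * graph.number_of_edges()
    exceed = np.zeros(n)
    if n <= 600:  # dense closed-form null walks (equivalent to rwr)
        iu0, iv0, conf = _edge_arrays(graph, op.nodes)
        for _ in range(n_null):
            iu, iv = iu0.copy(), iv0.copy()
            _swap_edges(iu, iv, n_swaps, rng)
            exceed += _dense_rwr(n, iu, iv, conf, p0, damping) >= obs
    else:
        for _ in range(n_null):
            null_graph = degree_preserving_rewire(
                graph, seed=int(rng.integers(2**31)))
            null_scores = rwr(symmetric_normalize(null_graph), restart,
                              damping=damping, tol=tol)
            exceed += (null_scores.reindex(op.nodes).to_numpy() >= obs)
    return pd.Series((1.0 + exceed) / (1.0 + n_null), index=op.nodes)


def semantic_similarity(ann: dict, u, v) -> float:
    """Jaccard index of two nodes' functional-term sets (0 if unannotated)."""
    a, b = ann.get(u), ann.get(v)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter / len(a | b) if inter or (a | b) else 0.0


def kde_filter(candidates: dict, seeds: list, ann: dict,
               cutoff: float = 0.5) -> tuple[list, dict]:
    """Keep candidates functionally similar to the seed set.

    Each candidate's mean Jaccard similarity to the seeds is computed; a
    Gaussian KDE (Silverman bandwidth) over these similarities defines a
    distribution whose ``cutoff`` quantile is the retention threshold.
    Returns (retained nodes, similarity per candidate).  Degenerate
    (constant) similarities retain everything.
    """
    if not candidates:
        raise ValueError("no candidates to filter")
    sims = {c: float(np.mean([semantic_similarity(ann, c, s) for s in seeds]))
            for c in candidates}
    if cutoff <= 0:
        return sorted(sims), sims
    values = np.array(list(sims.values()))
    if np.ptp(values) < 1e-12:
        warnings.warn("degenerate similarity distribution; retaining all",
                      stacklevel=2)
        return sorted(sims), sims
    kde = gaussian_kde(values, bw_method="silverman")
    lo = values.min() - 3 * np.sqrt(kde.covariance[0, 0])
    hi = values.max() + 3 * np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(lo, hi, 2048)
    dens = kde(grid)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    threshold = float(grid[np.searchsorted(cdf, min(cutoff, 1.0 - 1e-12))])
    retained = sorted(c for c, s in sims.items() if s >= threshold)
    if not retained:  # cutoff ~ 1: keep the top candidates
        top = max(sims.values())
        retained = sorted(c for c, s in sims.items() if s >= top - 1e-12)
    return retained, sims


def propagate_factor(graph: nx.Graph, seedset: SeedSet, damping: float = 0.95,
                     rwr_threshold: float = 0.01, kde_cutoff: float = 0.5,
                     n_null: int = 1000, p_threshold: float = 0.05,
                     ann: dict | None = None, seed: int = 0,
                     tol: float = 1e-9) -> tuple:
    """Propagate positive and negative seeds and filter to significant nodes.

    For each sign: restart mass proportional to |seed weight|; nodes are
    retained when score >= rwr_threshold x max score and empirical
    p <= p_threshold (seeds always retained); the KDE similarity filter
    then prunes candidates functionally unlike the seeds.  Returns a
    (positive, negative) pair of :class:`PropagationResult`.
    """
    validate_graph(graph)
    results = []
    rng = np.random.default_rng(seed)
    for side, weights in (("+", seedset.positive), ("-", seedset.negative)):
        present = {n: abs(w) for n, w in weights.items() if n in graph}
        dropped = set(weights) - set(present)
        if dropped:
            warnings.warn(f"{len(dropped)} seed(s) absent from graph", stacklevel=2)
        if not present:
            raise ValueError(f"no surviving seeds on side {side!r}")
        op = symmetric_normalize(graph)
        scores = rwr(op, present, damping=damping, tol=tol)
        emp = empirical_node_significance(
            graph, present, damping=damping, n_null=n_null,
            seed=int(rng.integers(2**31)), observed=scores, tol=tol)
        cut = rwr_threshold * scores.max()
        cand = set(scores.index[(scores >= cut) & (emp <= p_threshold)])
        cand |= set(present)
        if ann is not None and cand:
            retained, _ = kde_filter({c: scores[c] for c in cand},
                                     sorted(present), ann, cutoff=kde_cutoff)
            retained = sorted(set(retained) | set(present))
        else:
            retained = sorted(cand)
        results.append(PropagationResult(
            scores=scores, empirical_p=emp, retained=retained, seeds=dict(weights),
            params={"side": side, "damping": damping, "rwr_threshold": rwr_threshold,
                    "kde_cutoff": kde_cutoff, "n_null": n_null,
                    "p_threshold": p_threshold, "seed": seed},
        ))
    return tuple(results)


def build_signed_network(pos: PropagationResult, neg: PropagationResult,
                         graph: nx.Graph, factor=None) -> SignedSubnetwork:
    """Merge positive- and negative-seed retained nodes into a signed subgraph."""
    signs: dict = {}
    for n in pos.retained:
        signs.setdefault(n, set()).add("+")
    for n in neg.retained:
        signs.setdefault(n, set()).add("-")
    sub = graph.subgraph(signs).copy()
    return SignedSubnetwork(graph=sub, signs=signs, factor=factor, parent=graph)


def union_networks(a: SignedSubnetwork, b: SignedSubnetwork) -> SignedSubnetwork:
    """Node/edge union of two signed subnetworks of the same parent graph."""
    if a.parent is not None and b.parent is not None and a.parent is not b.parent:
        same = (set(a.parent.nodes()) == set(b.parent.nodes())
                and set(map(frozenset, a.parent.edges()))
                == set(map(frozenset, b.parent.edges())))
        if not same:
            raise ValueError("subnetworks come from different parent graphs")
    g = nx.Graph()
    g.add_nodes_from(a.graph.nodes(data=True))
    g.add_nodes_from(b.graph.nodes(data=True))
    g.add_edges_from(a.graph.edges(data=True))
    g.add_edges_from(b.graph.edges(data=True))
    signs: dict = {}
    for src in (a.signs, b.signs):
        for n, s in src.items():
            signs.setdefault(n, set()).update(s)
    factor = f"{a.factor}|{b.factor}" if a.factor != b.factor else a.factor
    return SignedSubnetwork(graph=g, signs=signs, factor=factor,
                            parent=a.parent if a.parent is not None else b.parent)
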