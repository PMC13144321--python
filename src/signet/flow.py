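"""Receptor cross-talk hubs and semantic-similarity-capacitated max flow.

Two seed sets — e.g., receptors deregulated by drug treatment and
receptors deregulated by the genotype — are each diffused over the
union network; nodes carrying high stationary probability from both
walks are cross-talk hubs (combined by geometric mean), with empirical
significance from degree-preserving network permutations.  Routes from
a source receptor to a sink effector are then traced by maximum flow
where each edge's capacity is the functional (Jaccard term) similarity
of its endpoints, so signal preferentially crosses functionally
coherent edges; edges above the 95th flow percentile form the reported
subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .propagation import (
    SignedSubnetwork,
    empirical_node_significance,
    rwr,
    semantic_similarity,
    symmetric_normalize,
)

CAPACITY_FLOOR = 1e-6


@dataclass
class CrosstalkResult:
    table: pd.DataFrame  # p_a, p_b, score (+ emp_p_a / emp_p_b when computed)
    seeds_a: dict
    seeds_b: dict
    params: dict = field(default_factory=dict)

    def top_hubs(self, n: int = 5) -> list:
        excl = set(self.seeds_a) | set(self.seeds_b)
        ranked = self.table.drop(index=[i for i in excl if i in self.table.index])
        ranked = ranked.sort_values(["score"], ascending=False, kind="mergesort")
        return list(ranked.head(n).index)


@dataclass
class FlowResult:
    source: object
    sink: object
    value: float
    edge_flows: pd.DataFrame  # u, v, capacity, flow (net per undirected edge)
    flagged: str | None = None


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, SignedSubnetwork) else network


def receptor_seed_vector(de: pd.DataFrame, receptors: list, alpha: float = 0.01,
                         direction: str = "up") -> dict:
    """Significant same-direction receptors, |LFC|-weighted, sum 1.

    Keeps receptors with adjusted p < alpha whose log-fold-change sign
    matches ``direction`` and normalizes the absolute LFCs into a
    probability vector.
    """
    if not receptors:
        raise ValueError("empty receptor list")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    rows = de.loc[[r for r in receptors if r in de.index]]
    hits = rows[(rows["adj_p"] < alpha) & (np.sign(rows["lfc"]) == sign)]
    if hits.empty:
        raise ValueError(
            f"no receptors pass adj_p < {alpha} with direction {direction!r}")
    w = hits["lfc"].abs()
    return (w / w.sum()).to_dict()


def kinase_seed_vector(kinomics: pd.DataFrame, nodes: list,
                       threshold: float = 1.0) -> dict:
    """Kinases with |median activity change| > threshold, normalized to sum 1."""
    tab = kinomics.set_index("kinase") if "kinase" in kinomics.columns else kinomics
    rows = tab.loc[[n for n in nodes if n in tab.index], "median_activity_change"]
    hits = rows[rows.abs() > threshold]
    if hits.empty:
        raise ValueError(f"no kinases exceed |change| > {threshold}")
    w = hits.abs()
    return (w / w.sum()).to_dict()


def crosstalk_propagate(network, vec_a: dict, vec_b: dict,
                        damping: float = 0.95,
                        combine: str = "geometric_mean") -> CrosstalkResult:
    """Diffuse two seed vectors and score their convergence per node.

    The combined cross-talk score is the geometric mean of the two
    stationary probabilities (``min`` and ``product`` available); hub
    ranking excludes the seed nodes themselves.
    """
    g = _as_graph(network)
    op = symmetric_normalize(g)
    pa = rwr(op, vec_a, damping=damping)
    pb = rwr(op, vec_b, damping=damping)
    comp_a: set = set()
    for s in vec_a:
        if s in g and s not in comp_a:
            comp_a |= nx.node_connected_component(g, s)
    if not any(s in comp_a for s in vec_b if s in g):
        warnings.warn("seed sets live in disconnected components", stacklevel=2)
    if combine == "geometric_mean":
        score = np.sqrt(pa * pb)
    elif combine == "min":
        score = np.minimum(pa, pb)
    elif combine == "product":
        score = pa * pb
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    table = pd.DataFrame({"p_a": pa, "p_b": pb, "score": score})
    return CrosstalkResult(table=table, seeds_a=dict(vec_a), seeds_b=dict(vec_b),
                           params={"damping": damping, "combine": combine})


def permutation_significance(network, seed_vector: dict, damping: float = 0.95,
                             n_perm: int = 10_000, seed: int = 0) -> pd.Series:
    """Add-one empirical p per node over degree-preserving permutations."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    return empirical_node_significance(_as_graph(network), seed_vector,
                                       damping=damping, n_null=n_perm, seed=seed)


def edge_capacities_from_similarity(network, ann: dict) -> dict:
    """capacity(u, v) = Jaccard term similarity + a small floor."""
    g = _as_graph(network)
    return {frozenset((u, v)): semantic_similarity(ann, u, v) + CAPACITY_FLOOR
            for u, v in g.edges()}


def max_flow(network, source, sink, capacities: dict) -> FlowResult:
    """Exact maximum flow between source and sink on bidirected edges.

    Each undirected edge becomes two opposite arcs of equal capacity;
    the per-edge net flow is reported.  Capacity feasibility and flow
    conservation are asserted on every run.
    """
    g = _as_graph(network)
    if source == sink:
        raise ValueError("source and sink must differ")
    for n in (source, sink):
        if n not in g:
            raise ValueError(f"node {n!r} not in network")
    if not nx.has_path(g, source, sink):
        return FlowResult(source, sink, 0.0,
                          pd.DataFrame(columns=["u", "v", "capacity", "flow"]),
                          flagged="disconnected")
    dg = nx.DiGraph()
    for u, v in g.edges():
        cap = float(capacities[frozenset((u, v))])
        dg.add_edge(u, v, capacity=cap)
        dg.add_edge(v, u, capacity=cap)
    value, flow = nx.maximum_flow(dg, source, sink)

    # feasibility + conservation audit
    net_out: dict = {}
    for u, targets in flow.items():
        for v, f in targets.items():
            assert f <= dg[u][v]["capacity"] + 1e-9, "capacity violated"
            net_out[u] = net_out.get(u, 0.0) + f
            net_out[v] = net_out.get(v, 0.0) - f
    for n, bal in net_out.items():
        if n not in (source, sink):
            assert abs(bal) < 1e-9, f"flow not conserved at {n}"
    assert abs(net_out.get(source, 0.0) - value) < 1e-9

    rows = []
    for u, v in g.edges():
        f = flow.get(u, {}).get(v, 0.0) - flow.get(v, {}).get(u, 0.0)
        uu, vv = (u, v) if f >= 0 else (v, u)
        rows.append({"u": uu, "v": vv,
                     "capacity": float(capacities[frozenset((u, v))]),
                     "flow": abs(f)})
    return FlowResult(source, sink, float(value), pd.DataFrame(rows))


def flow_subgraph(flow: FlowResult, percentile: float = 95.0) -> SignedSubnetwork:
    """High-flow subnetwork: edges at/above the flow percentile.

    The percentile is computed over edges with positive flow only; among
    the induced components, the one containing both endpoints is
    returned (or, flagged, the union of the two components containing
    the source and the sink).
    """
    pos = flow.edge_flows[flow.edge_flows["flow"] > 0]
    if pos.empty:
        warnings.warn("no positive flows; empty subgraph", stacklevel=2)
        return SignedSubnetwork(graph=nx.Graph(), signs={}, factor="flow")
    threshold = np.percentile(pos["flow"].to_numpy(), percentile)
    kept = pos[pos["flow"] >= threshold]
    g = nx.Graph()
    for r in kept.itertuples():
        g.add_edge(r.u, r.v, flow=r.flow, capacity=r.capacity)
    comps = list(nx.connected_components(g))
    chosen, flag = None, None
    for c in comps:
        if flow.source in c and flow.sink in c:
            chosen = set(c)
            break
    if chosen is None:
        chosen = set()
        for c in comps:
            if flow.source in c or flow.sink in c:
                chosen |= set(c)
        flag = "source_sink_disconnected"
        if not chosen:
            chosen = set(max(comps, key=len))
    sub = g.subgraph(chosen).copy()
    return SignedSubnetwork(graph=sub,
                            signs={n: {"+"} for n in sub.nodes()},
                            factor=f"flow:{flow.source}->{flow.sink}"
                            if flag is None else f"flow[{flag}]")
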