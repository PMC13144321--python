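"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: TSV edge lists (node_a, node_b, confidence), GMT sets
(annotations as plain members; regulons with a ``member:weight``
dialect), CSV omics matrices (features as rows, samples as columns,
empty cell = missing) with a sidecar sample-metadata CSV, GraphML for
subnetworks, and JSON for planted truth and run records.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import OmicsView, PlantedTruth, validate_graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tconfidence\n")
        for u, v in sorted(map(lambda e: tuple(sorted(e)), graph.edges())):
            fh.write(f"{u}\t{v}\t{graph[u][v]['confidence']:.6g}\n")


def read_edge_list(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or (lineno == 1 and line.lower().startswith("node_a")):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, "
                                 f"got {len(parts)}")
            u, v, conf = parts
            try:
                c = float(conf)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad confidence {conf!r}") from exc
            if graph.has_edge(u, v):
                warnings.warn(f"{path}:{lineno}: duplicate edge {u}-{v} "
                              "deduplicated", stacklevel=2)
                continue
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on {u}")
            graph.add_edge(u, v, confidence=c)
    validate_graph(graph)
    return graph


def write_gmt(sets: dict, path, weighted: bool = False) -> None:
    """Annotation sets (plain members) or regulons (member:weight)."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = sets[name]
            if weighted:
                cols = [f"{m}:{members[m]:.6g}" for m in sorted(members)]
            else:
                cols = sorted(members)
            fh.write("\t".join([name, "na"] + cols) + "\n")


def read_gmt(path, weighted: bool = False) -> dict:
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            name, _desc, *members = parts
            if weighted:
                entry = {}
                for m in members:
                    if ":" not in m:
                        raise ValueError(
                            f"{path}:{lineno}: expected member:weight, got {m!r}")
                    gene, w = m.rsplit(":", 1)
                    entry[gene] = float(w)
                out[name] = entry
            else:
                out[name] = set(members)
    return out


def write_matrix(view: OmicsView, path, meta_path) -> None:
    """Features as rows, samples as columns; empty cell = missing."""
    view.matrix.T.to_csv(path, na_rep="")
    view.sample_meta.loc[view.matrix.index].to_csv(meta_path)


def read_matrix(path, meta_path, view_label: str,
                feature_meta: pd.DataFrame | None = None) -> OmicsView:
    mat = pd.read_csv(path, index_col=0).T
    meta = pd.read_csv(meta_path, index_col=0)
    unknown = [s for s in mat.index if s not in meta.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown[:5]}")
    if view_label == "mrna":
        if mat.isna().any().any():
            raise ValueError("mRNA count matrix must not contain missing values")
        mat = mat.astype(np.int64)
    return OmicsView(view_label, mat, meta, feature_meta=feature_meta)


def write_graphml(network, path) -> None:
    g = network if isinstance(network, nx.Graph) else network.graph
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        attrs = {k: v for k, v in d.items() if v is not None}
        if hasattr(network, "signs") and n in network.signs:
            attrs["sign"] = "".join(sorted(network.signs[n]))
        out.add_node(n, **attrs)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, **{k: v2 for k, v2 in d.items() if v2 is not None})
    nx.write_graphml(out, path)


def write_de_table(de: pd.DataFrame, path) -> None:
    de.rename_axis("feature").to_csv(path, sep="\t")


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "receptors": sorted(truth.receptors),
        "tfs": sorted(truth.tfs),
        "kinases": sorted(truth.kinases),
        "planted_paths": [list(p) for p in truth.planted_paths],
        "convergence_hubs": sorted(truth.convergence_hubs),
        "factor_support": {str(k): v for k, v in truth.factor_support.items()},
        "planted_tf_activity": truth.planted_tf_activity,
        "planted_de": truth.planted_de,
        "support_mode": truth.support_mode,
        "nodes": list(truth.nodes),
        "site_map": truth.site_map,
        "regulons": truth.regulons,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> PlantedTruth:
    d = json.loads(Path(path).read_text())
    return PlantedTruth(
        receptors=set(d["receptors"]), tfs=set(d["tfs"]),
        kinases=set(d["kinases"]), planted_paths=d["planted_paths"],
        convergence_hubs=set(d["convergence_hubs"]),
        factor_support={int(k): v for k, v in d["factor_support"].items()},
        planted_tf_activity=d["planted_tf_activity"],
        planted_de=d["planted_de"], regulons=d.get("regulons"),
        support_mode=d.get("support_mode", "shared"),
        nodes=d.get("nodes", []), site_map=d.get("site_map", {}),
    )
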