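"""Shared in-memory containers for the pipeline.

Graphs are plain :class:`networkx.Graph` objects whose edges carry a
``confidence`` attribute in (0, 1]; the derived edge cost is
``1 - confidence``.  Omics matrices are wrapped in :class:`OmicsView`,
which pairs a samples x features :class:`pandas.DataFrame` with sample
and feature metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

VIEW_ORDER = ("mrna", "protein", "phospho")

TREATMENTS = ("untreated", "drugA", "drugB", "combination")
GENOTYPES = ("WT", "KO")


def edge_cost(confidence: float) -> float:
    """Map an interaction confidence in (0, 1] to a Steiner edge cost."""
    return 1.0 - confidence


@dataclass
class OmicsView:
    """One omics measurement matrix (samples x features) plus metadata.

    ``matrix`` holds raw counts for the mRNA view and log-abundances
    (NaN = not quantified) for the protein and phospho views.
    ``sample_meta`` is indexed by sample id with columns
    genotype / treatment / replicate / batch.  ``feature_meta`` is used
    by the phospho view to map site ids (``PROTEIN_RESIDUE_POSITION``,
    1-based) to parent proteins.
    """

    view_label: str
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.view_label not in VIEW_ORDER:
            raise ValueError(f"unknown view label {self.view_label!r}")
        missing = [s for s in self.matrix.index if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    @property
    def samples(self) -> list:
        return list(self.matrix.index)

    @property
    def features(self) -> list:
        return list(self.matrix.columns)

    def condition_labels(self) -> pd.Series:
        """genotype x treatment label per sample (imputation groups)."""
        meta = self.sample_meta.loc[self.matrix.index]
        return meta["genotype"].astype(str) + ":" + meta["treatment"].astype(str)

    def copy_with(self, matrix: pd.DataFrame) -> "OmicsView":
        return OmicsView(
            view_label=self.view_label,
            matrix=matrix,
            sample_meta=self.sample_meta,
            feature_meta=self.feature_meta,
        )


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic interactome.

    ``planted_paths`` are receptor -> ... -> effector node lists that exist
    as paths in the graph; ``convergence_hubs`` are nodes shared by at
    least two planted paths.  ``factor_support`` maps factor index
    (1..3) -> view label -> {feature: signed unit effect}.
    """

    receptors: set
    tfs: set
    kinases: set
    planted_paths: list
    convergence_hubs: set
    factor_support: dict
    planted_tf_activity: dict
    planted_de: dict
    regulons: Optional[dict] = None
    support_mode: str = "shared"
    nodes: list = field(default_factory=list)
    site_map: dict = field(default_factory=dict)  # phosphosite id -> parent protein

    def path_nodes(self) -> set:
        return {n for p in self.planted_paths for n in p}


@dataclass
class ViabilityTrace:
    """Live-cell fluorescence time course (wells x timepoints)."""

    timepoints: list
    matrix: pd.DataFrame  # wells x timepoints
    well_meta: pd.DataFrame  # genotype, gRNA, drug, replicate per well
    summary: Optional[dict] = None  # mean / sem / delta_drug_vs_vehicle frames


def validate_graph(graph: nx.Graph) -> None:
    """Check the WeightedGraph invariants (simple, confidences in (0,1])."""
    if any(u == v for u, v in graph.edges()):
        raise ValueError("graph contains self-loops")
    for u, v, d in graph.edges(data=True):
        c = d.get("confidence")
        if c is None or not (0.0 < c <= 1.0):
            raise ValueError(f"edge ({u},{v}) confidence {c!r} outside (0,1]")
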