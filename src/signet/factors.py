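"""Deterministic multi-view factorization with MOFA-style output semantics.

The variational factor-analysis machinery is replaced by a rank-K
truncated SVD of the feature-wise concatenation of the views, each view
first scaled to unit total variance so no single view dominates.  The
outputs keep the usual contract: per-sample factor scores, per-view
feature loadings, variance explained per view x factor, a sign
convention anchored on control samples, and conversion of loadings into
protein-level seed sets for network propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import VIEW_ORDER, OmicsView


@dataclass
class FactorModel:
    K: int
    scores: pd.DataFrame          # samples x K  (columns factor_1..factor_K)
    loadings: dict                # view -> features x K DataFrame
    view_scales: dict = field(default_factory=dict)
    singular_values: np.ndarray | None = None

    def factor_cols(self) -> list:
        return [f"factor_{k}" for k in range(1, self.K + 1)]


@dataclass
class SeedSet:
    """Extreme-quantile protein weights used as propagation restart mass."""

    positive: dict
    negative: dict
    factor: int
    quantile: float
    degenerate: bool = False


def fit_factors(views: list[OmicsView], K: int = 3) -> FactorModel:
    """Rank-K factorization of unit-variance-scaled, concatenated views.

    Views must share an identical ordered sample set and contain no
    missing values (select and impute first).  Scores are the left
    singular vectors scaled by the singular values; per-view loadings
    are the matching right-singular-vector rows rescaled by the inverse
    of the view scaling, so ``scores @ loadings[v].T`` reconstructs view
    v.  Deterministic up to sign; fix signs with :func:`orient_factors`.
    """
    if not views:
        raise ValueError("no views given")
    samples = views[0].samples
    for v in views[1:]:
        if v.samples != samples:
            raise ValueError(f"view {v.view_label!r} has a different sample set")
    blocks, scales, slices = [], {}, {}
    start = 0
    for v in views:
        X = v.matrix.to_numpy(float)
        if np.isnan(X).any():
            raise ValueError(f"view {v.view_label!r} contains missing values")
        X = X - X.mean(axis=0)
        norm = np.linalg.norm(X)
        s = 1.0 / norm if norm > 0 else 1.0
        blocks.append(X * s)
        scales[v.view_label] = s
        slices[v.view_label] = slice(start, start + X.shape[1])
        start += X.shape[1]
    Y = np.hstack(blocks)
    if K > min(Y.shape):
        raise ValueError(f"K={K} exceeds min(n_samples, total features)={min(Y.shape)}")
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    U, S, Vt = U[:, :K], S[:K], Vt[:K]
    cols = [f"factor_{k}" for k in range(1, K + 1)]
    scores = pd.DataFrame(U * S, index=samples, columns=cols)
    loadings = {}
    for v in views:
        Vv = Vt[:, slices[v.view_label]].T / scales[v.view_label]
        loadings[v.view_label] = pd.DataFrame(Vv, index=v.features, columns=cols)
    return FactorModel(K=K, scores=scores, loadings=loadings,
                       view_scales=scales, singular_values=S)


def variance_explained(model: FactorModel, views: list[OmicsView]) -> pd.DataFrame:
    """Fraction of each view's (centered) variance captured per factor.

    VE(v, k) = ||z_k w_{v,k}^T||_F^2 / ||X_v||_F^2; with orthogonal
    score columns the per-view sum over factors is at most 1.
    """
    rows = {}
    for v in views:
        X = v.matrix.to_numpy(float)
        X = X - X.mean(axis=0)
        total = float(np.sum(X**2))
        w = model.loadings[v.view_label].to_numpy(float)
        z = model.scores.to_numpy(float)
        ve = [float(np.sum(z[:, k] ** 2) * np.sum(w[:, k] ** 2)) / total
              if total > 0 else 0.0 for k in range(model.K)]
        rows[v.view_label] = ve
    return pd.DataFrame(rows, index=model.factor_cols()).T


def orient_factors(model: FactorModel, control_masks: dict) -> FactorModel:
    """Flip factor signs so control samples sit on the negative side.

    ``control_masks`` maps factor index (1-based) to a boolean Series
    over samples marking that factor's control group (untreated for the
    treatment factor, non-combination for the combination factor, WT for
    the genotype factor).  A factor is negated when its mean score over
    controls exceeds the mean over non-controls; the reconstruction
    ``scores @ loadings.T`` is invariant.
    """
    scores = model.scores.copy()
    loadings = {v: df.copy() for v, df in model.loadings.items()}
    for k in range(1, model.K + 1):
        mask = control_masks.get(k)
        if mask is None:
            continue
        mask = mask.reindex(scores.index).astype(bool)
        if not mask.any():
            raise ValueError(f"empty control set for factor {k}")
        col = f"factor_{k}"
        if scores.loc[mask, col].mean() > scores.loc[~mask, col].mean():
            scores[col] = -scores[col]
            for df in loadings.values():
                df[col] = -df[col]
    return FactorModel(K=model.K, scores=scores, loadings=loadings,
                       view_scales=dict(model.view_scales),
                       singular_values=model.singular_values)


def default_control_masks(sample_meta: pd.DataFrame) -> dict:
    """Treatment/combination/genotype control masks for the 3-factor design."""
    return {
        1: sample_meta["treatment"] == "untreated",
        2: sample_meta["treatment"] != "combination",
        3: sample_meta["genotype"] == "WT",
    }


def _signed_max_abs(values: pd.Series) -> float:
    idx = values.abs().idxmax()  # first occurrence wins on ties
    return float(values.loc[idx])


def protein_weights(model: FactorModel, factor: int,
                    site_map: dict | None = None,
                    aggregation: str = "max_abs") -> pd.Series:
    """Collapse one factor's loadings to a single signed weight per protein.

    Phosphosite loadings are first collapsed per protein by the signed
    value of maximal absolute weight; across views the same rule
    applies, ties broken toward the earlier view in canonical order
    (mrna, protein, phospho).  ``aggregation='mean'`` averages across
    views instead.
    """
    if not (1 <= factor <= model.K):
        raise ValueError(f"factor {factor} outside 1..{model.K}")
    col = f"factor_{factor}"
    per_view = {}
    for view in VIEW_ORDER:
        if view not in model.loadings:
            continue
        w = model.loadings[view][col]
        if view == "phospho":
            if site_map is None:
                raise ValueError("phospho view present but no site_map given")
            parents = pd.Series({s: site_map.get(s) for s in w.index})
            w = w.groupby(parents).apply(_signed_max_abs)
        per_view[view] = w
    combined: dict = {}
    for view in VIEW_ORDER:  # canonical order fixes cross-view ties
        if view not in per_view:
            continue
        for prot, val in per_view[view].items():
            if aggregation == "mean":
                combined.setdefault(prot, []).append(float(val))
            elif prot not in combined or abs(val) > abs(combined[prot]):
                combined[prot] = float(val)
    if aggregation == "mean":
        combined = {p: float(np.mean(v)) for p, v in combined.items()}
    return pd.Series(combined).sort_index()


def select_seeds(weights: pd.Series, q: float = 0.05, factor: int = 0) -> SeedSet:
    """Top and bottom ceil(q * n) proteins by weight, ID-order tie-break."""
    if not (0.0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    n = len(weights)
    k = int(np.ceil(q * n))
    if n < 2.0 / q:
        warnings.warn(f"only {n} proteins; {q:.0%}-quantile seed sets are tiny",
                      stacklevel=2)
    order = weights.reset_index()
    order.columns = ["protein", "w"]
    asc = order.sort_values(["w", "protein"], ascending=[True, True])
    desc = order.sort_values(["w", "protein"], ascending=[False, True])
    neg = asc.head(k)
    pos = desc.head(k)
    overlap = set(pos["protein"]) & set(neg["protein"])
    degenerate = weights.nunique() == 1
    if overlap:
        warnings.warn("seed quantiles overlap; dropping shared ids from the "
                      "negative set", stacklevel=2)
        neg = neg[~neg["protein"].isin(overlap)]
    return SeedSet(
        positive={r.protein: float(r.w) for r in pos.itertuples()},
        negative={r.protein: float(r.w) for r in neg.itertuples()},
        factor=factor,
        quantile=q,
        degenerate=degenerate,
    )
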