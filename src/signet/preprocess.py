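"""Per-view normalization, filtering, imputation and differential statistics.

mRNA counts go through a CPM expression filter, TMM effective library
sizes and a log-CPM transform.  Protein/phospho log-abundances go
through sample QC, within-condition mean imputation, median-centering
and unit scaling; phosphosites are additionally residualized on their
parent protein ("net phosphorylation") and duplicate site ids averaged.
Differential abundance uses Welch t tests with Benjamini-Hochberg
control; multi-omics feature selection uses one-way ANOVA with
view-specific thresholds.  Viability traces get MAD spike removal, a
window-3 rolling median, t0 baseline subtraction and a Welch endpoint
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import OmicsView, ViabilityTrace


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    out = pd.Series(np.nan, index=p.index, dtype=float)
    ok = p.notna()
    if ok.any():
        out[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------- mRNA


def cpm_filter(counts: OmicsView, threshold: float = 2.0) -> OmicsView:
    """Keep genes with counts-per-million > threshold in at least one sample."""
    mat = counts.matrix
    lib = mat.sum(axis=1)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero library for samples {bad}")
    cpm = mat.div(lib, axis=0) * 1e6
    keep = (cpm > threshold).any(axis=0)
    if not keep.any():
        warnings.warn("cpm_filter retained no genes", stacklevel=2)
    return counts.copy_with(mat.loc[:, keep])


def effective_library_sizes(counts: OmicsView) -> pd.Series:
    """TMM scale factors converting observed into effective library sizes.

    Trimmed mean of M-values: per sample vs a reference (the sample whose
    upper-quartile relative expression is closest to the mean upper
    quartile), genes expressed in both are trimmed 30% per tail on M and
    5% per tail on A, and the factor is 2**mean(M).  Factors are
    normalized to geometric mean 1.
    """
    mat = counts.matrix
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 samples for TMM")
    lib = mat.sum(axis=1)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero)}")
    rel = mat.div(lib, axis=0)
    uq = rel.apply(lambda r: np.quantile(r[r > 0], 0.75) if (r > 0).any() else 0.0,
                   axis=1)
    ref = (uq - uq.mean()).abs().idxmin()
    x_ref = mat.loc[ref].to_numpy(float)
    n_ref = float(lib[ref])

    factors = {}
    for s in mat.index:
        if s == ref:
            factors[s] = 1.0
            continue
        x = mat.loc[s].to_numpy(float)
        both = (x > 0) & (x_ref > 0)
        if both.sum() < 1:
            raise ValueError(f"no genes shared with reference for sample {s}")
        m = np.log2((x[both] / lib[s]) / (x_ref[both] / n_ref))
        a = 0.5 * np.log2((x[both] / lib[s]) * (x_ref[both] / n_ref))
        lo_m, hi_m = np.quantile(m, [0.30, 0.70])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        factors[s] = float(2.0 ** np.mean(m[keep])) if keep.any() else 1.0
    f = pd.Series(factors).reindex(mat.index)
    return f / np.exp(np.log(f).mean())  # geometric mean 1


def log_cpm(counts: OmicsView, scale_factors: pd.Series | None = None,
            prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes with a prior count."""
    mat = counts.matrix
    lib = mat.sum(axis=1).astype(float)
    f = (scale_factors.reindex(mat.index) if scale_factors is not None
         else pd.Series(1.0, index=mat.index))
    if (f <= 0).any():
        raise ValueError("scale factors must be positive")
    eff = lib * f
    return np.log2((mat + prior_count).div(eff + 1.0, axis=0) * 1e6)


# ------------------------------------------------- protein / phospho


def qc_filter_samples(view: OmicsView, min_quantified: int = 50) -> OmicsView:
    """Drop samples quantifying fewer than `min_quantified` features."""
    n_obs = view.matrix.notna().sum(axis=1)
    keep = n_obs >= min_quantified
    if not keep.any():
        raise ValueError("qc_filter_samples dropped every sample")
    return view.copy_with(view.matrix.loc[keep])


def impute_within_condition(view: OmicsView, min_quantified: int = 3) -> OmicsView:
    """Fill missing entries with the condition mean when it has >= 3 observed.

    Conditions are genotype x treatment groups; entries in conditions
    with fewer observed replicate values are left missing.
    """
    mat = view.matrix.copy()
    cond = view.condition_labels()
    for _, samples in mat.groupby(cond, sort=False).groups.items():
        block = mat.loc[samples]
        n_obs = block.notna().sum(axis=0)
        means = block.mean(axis=0)
        fill = means.where(n_obs >= min_quantified)
        mat.loc[samples] = block.fillna(fill)
    return view.copy_with(mat)


def median_center_scale(view: OmicsView) -> OmicsView:
    """Subtract each sample's median, then scale each feature to unit sd.

    Features with zero (or undefined) sd are set to 0.
    """
    mat = view.matrix.sub(view.matrix.median(axis=1), axis=0)
    sd = mat.std(axis=0, ddof=1)
    scaled = mat.div(sd.replace(0.0, np.nan), axis=1)
    zero_sd = sd.index[(sd == 0) | sd.isna()]
    scaled[zero_sd] = scaled[zero_sd].where(mat[zero_sd].isna(), 0.0)
    return view.copy_with(scaled)


def net_phosphorylation(phospho: OmicsView, protein: OmicsView) -> OmicsView:
    """Residualize each phosphosite on its parent protein's abundance.

    Per site, ordinary least squares of phospho on protein across the
    samples where both are observed; the residuals isolate
    phosphorylation changes independent of total protein.  Sites with no
    matched protein or < 3 paired observations pass through centered but
    unadjusted, flagged ``unmatched`` / ``insufficient_pairs`` in
    ``feature_meta['net_flag']``.
    """
    if phospho.feature_meta is None or "protein" not in phospho.feature_meta:
        raise ValueError("phospho view needs feature_meta with a 'protein' column")
    shared = [s for s in phospho.matrix.index if s in protein.matrix.index]
    out = phospho.matrix.copy()
    flags = {}
    for site in out.columns:
        parent = phospho.feature_meta.loc[site, "protein"]
        y_all = phospho.matrix[site]
        if parent not in protein.matrix.columns:
            out[site] = y_all - y_all.mean()
            flags[site] = "unmatched"
            continue
        x = protein.matrix.loc[shared, parent]
        y = y_all.loc[shared]
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or np.nanstd(x[ok]) == 0:
            out[site] = y_all - y_all.mean()
            flags[site] = "insufficient_pairs"
            continue
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        resid = y - (intercept + slope * x)
        out[site] = resid.reindex(out.index)
        flags[site] = "ok"
    feat = (phospho.feature_meta.copy() if phospho.feature_meta is not None
            else pd.DataFrame(index=out.columns))
    feat["net_flag"] = pd.Series(flags)
    return OmicsView(phospho.view_label, out, phospho.sample_meta, feature_meta=feat)


def aggregate_duplicate_sites(phospho: OmicsView) -> OmicsView:
    """Average rows sharing a phosphosite identifier (columns here)."""
    mat = phospho.matrix.T.groupby(level=0, sort=False).mean().T
    feat = None
    if phospho.feature_meta is not None:
        feat = phospho.feature_meta[~phospho.feature_meta.index.duplicated()]
        feat = feat.reindex(mat.columns)
    return OmicsView(phospho.view_label, mat, phospho.sample_meta, feature_meta=feat)


# ----------------------------------------------- differential statistics


def _resolve_groups(view: OmicsView, group) -> list:
    """A group is a list of sample ids or a metadata value to match."""
    if isinstance(group, str):
        meta = view.sample_meta.loc[view.matrix.index]
        cond = view.condition_labels()
        mask = ((meta["genotype"] == group) | (meta["treatment"] == group)
                | (cond == group))
        samples = list(meta.index[mask])
        if not samples:
            raise ValueError(f"no samples match group {group!r}")
        return samples
    return list(group)


def differential_abundance(view: OmicsView, contrast) -> pd.DataFrame:
    """Welch t per feature between two sample groups, BH-adjusted.

    ``contrast`` is a pair of sample-id lists or metadata values (e.g.
    ``("KO", "WT")``).  LFC = mean(a) - mean(b) on the (log-scale)
    matrix.  Features with < 2 observed values in a group are flagged
    ``insufficient``; zero-variance groups with unequal means get p = 0
    flagged ``degenerate``; identical degenerate groups get t = 0, p = 1.
    """
    a = _resolve_groups(view, contrast[0])
    b = _resolve_groups(view, contrast[1])
    xa_all = view.matrix.loc[a]
    xb_all = view.matrix.loc[b]
    if (not xa_all.isna().any().any() and not xb_all.isna().any().any()
            and len(a) >= 2 and len(b) >= 2):
        # complete-data fast path: vectorized Welch across features
        lfc = xa_all.mean() - xb_all.mean()
        va = xa_all.std(ddof=1)
        vb = xb_all.std(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(xa_all, xb_all, equal_var=False)
        res = pd.DataFrame({"lfc": lfc, "t": t, "p": p},
                           index=view.matrix.columns)
        res["flag"] = "ok"
        degen = (va == 0) & (vb == 0)
        res.loc[degen & (lfc == 0), ["t", "p"]] = [0.0, 1.0]
        bad = degen & (lfc != 0)
        res.loc[bad, "t"] = np.inf * np.sign(lfc[bad])
        res.loc[bad, "p"] = 0.0
        res.loc[bad, "flag"] = "degenerate"
        res["adj_p"] = bh_adjust(res["p"])
        return res[["lfc", "t", "p", "adj_p", "flag"]]
    rows = {}
    for feat in view.matrix.columns:
        xa = view.matrix.loc[a, feat].dropna().to_numpy(float)
        xb = view.matrix.loc[b, feat].dropna().to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            rows[feat] = (np.nan, np.nan, np.nan, "insufficient")
            continue
        lfc = xa.mean() - xb.mean()
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            if lfc == 0:
                rows[feat] = (0.0, 0.0, 1.0, "ok")
            else:
                rows[feat] = (lfc, np.inf * np.sign(lfc), 0.0, "degenerate")
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows[feat] = (lfc, float(t), float(p), "ok")
    res = pd.DataFrame.from_dict(
        rows, orient="index", columns=["lfc", "t", "p", "flag"]
    )
    res["adj_p"] = bh_adjust(res["p"])
    return res[["lfc", "t", "p", "adj_p", "flag"]]


@dataclass
class SelectedFeatures:
    """ANOVA-retained feature ids for one view, with their statistics."""

    view_label: str
    features: list
    stats: pd.DataFrame
    view: OmicsView  # the retained (optionally z-scored) submatrix


def anova_select(
    view: OmicsView,
    groups: pd.Series | None = None,
    fdr_threshold: float = 0.1,
    effect_threshold: float = 0.5,
    adjust: bool = True,
    zscore: bool = False,
) -> SelectedFeatures:
    """One-way ANOVA feature selection across condition groups.

    A feature is retained when its (BH-adjusted if ``adjust``) ANOVA p
    is below ``fdr_threshold`` and its effect — the maximum absolute
    difference between any group mean and the grand mean — exceeds
    ``effect_threshold``.  The phospho criterion uses adjusted P < 0.1
    with effect > 0.5 and z-scores the retained features; the stricter
    protein/mRNA criterion uses raw P < 0.001 with effect > 1.
    """
    if groups is None:
        groups = view.condition_labels()
    groups = groups.reindex(view.matrix.index)
    levels = groups.dropna().unique()
    if len(levels) < 2:
        raise ValueError("anova_select needs >= 2 groups")
    pvals, effects = {}, {}
    for feat in view.matrix.columns:
        col = view.matrix[feat]
        per_group = [col[groups == g].dropna().to_numpy(float) for g in levels]
        per_group = [g for g in per_group if len(g) >= 2]
        if len(per_group) < 2:
            pvals[feat], effects[feat] = np.nan, np.nan
            continue
        grand = np.concatenate(per_group).mean()
        effects[feat] = max(abs(g.mean() - grand) for g in per_group)
        if all(np.ptp(g) == 0 for g in per_group):
            pvals[feat] = 1.0 if effects[feat] == 0 else 0.0
            continue
        with np.errstate(invalid="ignore"):
            _, p = stats.f_oneway(*per_group)
        pvals[feat] = float(p)
    res = pd.DataFrame({"p": pd.Series(pvals), "effect": pd.Series(effects)})
    res["adj_p"] = bh_adjust(res["p"])
    crit_p = res["adj_p"] if adjust else res["p"]
    keep = ((crit_p < fdr_threshold) & (res["effect"] > effect_threshold)).fillna(False)
    feats = list(res.index[keep])
    sub = view.matrix.loc[:, feats]
    if zscore and feats:
        sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1).replace(0.0, np.nan)
        sub = sub.fillna(0.0)
    return SelectedFeatures(view.view_label, feats, res.loc[keep],
                            view.copy_with(sub))


# ----------------------------------------------------------- viability


def _rolling_median(x: np.ndarray, window: int = 3) -> np.ndarray:
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def smooth_viability(trace: ViabilityTrace) -> ViabilityTrace:
    """Despike, smooth and baseline-normalize fluorescence traces.

    Per well: points with |x - rolling median| > 3 x rolling MAD are
    replaced by linear interpolation of their neighbors; a window-3
    rolling median smooths the result, and the t0 value is subtracted.
    The returned trace carries a per-condition mean +/- SEM summary and
    per-timepoint drug-vs-vehicle differences.
    """
    if len(trace.timepoints) < 3:
        raise ValueError("need >= 3 timepoints")
    out = {}
    for well in trace.matrix.index:
        x = trace.matrix.loc[well].to_numpy(float)
        n = x.size
        spikes = np.zeros(n, dtype=bool)
        for i in range(n):  # Hampel rule; edge windows extended one-sided
            lo = min(max(0, i - 1), n - 3)
            win = x[lo:lo + 3]
            med = np.median(win)
            mad = np.median(np.abs(win - med))
            spikes[i] = np.abs(x[i] - med) > 3 * mad
        clean = pd.Series(np.where(spikes, np.nan, x))
        clean = clean.interpolate(limit_direction="both").to_numpy()
        smooth = _rolling_median(clean)
        out[well] = smooth - smooth[0]
    matrix = pd.DataFrame(out, index=trace.timepoints).T

    meta = trace.well_meta.loc[matrix.index]
    keys = ["genotype", "gRNA", "drug"]
    grouped = matrix.groupby([meta[k] for k in keys])
    mean = grouped.mean()
    sem = grouped.sem()
    deltas = {}
    for (g, grna) in mean.index.droplevel("drug").unique():
        if (g, grna, "drug") in mean.index and (g, grna, "DMSO") in mean.index:
            deltas[(g, grna)] = mean.loc[(g, grna, "drug")] - mean.loc[(g, grna, "DMSO")]
    summary = {"mean": mean, "sem": sem,
               "delta_drug_vs_vehicle": pd.DataFrame(deltas).T}
    return ViabilityTrace(trace.timepoints, matrix, trace.well_meta, summary=summary)


def endpoint_welch(trace: ViabilityTrace, group_a, group_b) -> tuple:
    """Welch two-sided t on final-timepoint values of two well groups.

    Groups are well-id lists or ``{meta_column: value}`` selections on
    ``well_meta``.
    """
    def wells(g):
        if isinstance(g, dict):
            mask = np.ones(len(trace.well_meta), dtype=bool)
            for k, v in g.items():
                mask &= (trace.well_meta[k] == v).to_numpy()
            return list(trace.well_meta.index[mask])
        return list(g)

    wa, wb = wells(group_a), wells(group_b)
    if len(wa) < 2 or len(wb) < 2:
        raise ValueError("need >= 2 wells per group")
    final = trace.matrix.iloc[:, -1]
    xa, xb = final.loc[wa].to_numpy(float), final.loc[wb].to_numpy(float)
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        if np.allclose(xa.mean(), xb.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance endpoint comparison")
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)
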