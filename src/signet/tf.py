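"""Transcription-factor activity from differential statistics (univariate linear model).

For each TF, a per-gene differential statistic (Welch t by default, LFC
optionally) is regressed on the TF's signed regulon weight vector
(weight for targets, 0 elsewhere, intercept included); the slope's
t-value is the activity estimate, with two-sided p from the t
distribution on n - 2 df and BH correction across TFs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust, effective_library_sizes, log_cpm
from .types import OmicsView


def ulm_activity(stat: pd.Series, regulons: dict,
                 min_targets: int = 5) -> pd.DataFrame:
    """Univariate linear model activity per TF.

    ``stat`` is a gene -> statistic vector covering the modeled genes; a
    TF is scored only when at least ``min_targets`` of its targets are
    covered (others are flagged and skipped).
    """
    stat = stat.dropna()
    genes = stat.index
    y = stat.to_numpy(float)
    rows = {}
    for tf, targets in regulons.items():
        overlap = [g for g in targets if g in genes]
        if len(overlap) < min_targets:
            rows[tf] = (np.nan, np.nan, np.nan, len(overlap), "too_few_targets")
            continue
        x = np.array([targets.get(g, 0.0) for g in genes], float)
        if np.ptp(x) == 0:
            rows[tf] = (0.0, 0.0, 1.0, len(overlap), "degenerate")
            continue
        res = stats.linregress(x, y)
        t = (res.slope / res.stderr if res.stderr > 0
             else np.sign(res.slope) * np.inf)
        rows[tf] = (float(res.slope), float(t), float(res.pvalue),
                    len(overlap), "ok")
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["slope", "t", "p", "n_targets_used", "flag"])
    out["adj_p"] = bh_adjust(out["p"])
    return out[["slope", "t", "p", "adj_p", "n_targets_used", "flag"]]


def activity_contrast(expr: OmicsView, groups: tuple, regulons: dict,
                      min_count: int = 10, min_targets: int = 5,
                      statistic: str = "t") -> pd.DataFrame:
    """TF activity for a two-group mRNA contrast.

    Genes with summed count below ``min_count`` are dropped; counts are
    log-CPM transformed on TMM effective library sizes; the per-gene
    Welch t (or LFC) between the groups feeds :func:`ulm_activity`.
    """
    from .preprocess import _resolve_groups, differential_abundance

    a = _resolve_groups(expr, groups[0])
    b = _resolve_groups(expr, groups[1])
    if set(a) & set(b):
        raise ValueError("contrast groups overlap")
    keep = expr.matrix.sum(axis=0) >= min_count
    filtered = expr.copy_with(expr.matrix.loc[:, keep])
    factors = effective_library_sizes(filtered)
    logmat = log_cpm(filtered, factors)
    logview = OmicsView("mrna", logmat, expr.sample_meta)
    de = differential_abundance(logview, (a, b))
    stat = de["t"] if statistic == "t" else de["lfc"]
    return ulm_activity(stat.replace([np.inf, -np.inf], np.nan), regulons,
                        min_targets=min_targets)
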