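"""Candidate-gene prioritization combining two independent measures.

A candidate regulator of stress-responsive shoot growth should (i) belong to
the development-induced, dose-repressed trend class whose expression tracks
shoot size under hard-agar stress, and (ii) be independently
drought-repressed in the pot-grown rosette experiment.  Eligible genes are
ranked by the strength of their per-gene expression-vs-shoot-area
correlation; the drought axis (coefficient and signed -log10 adjusted p) is
carried alongside for the two-axis scatter view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pseudobulk import PseudobulkMatrix

__all__ = ["gene_shoot_correlation", "combine_and_rank"]


def gene_shoot_correlation(zpb: PseudobulkMatrix, areas: np.ndarray) -> pd.DataFrame:
    """Per-gene Pearson correlation of z-scored expression with shoot area.

    Constant gene rows are flagged undefined (``r`` NaN, excluded later)
    rather than raising.  ``areas`` is the per-condition mean shoot area in
    column order.
    """
    areas = np.asarray(areas, dtype=float)
    n = zpb.values.shape[1]
    if len(areas) != n or n < 3:
        raise ValueError("need >= 3 paired conditions matching the columns")
    if areas.std() == 0:
        raise ValueError("shoot areas have zero variance")
    x = zpb.values
    xm = x - x.mean(axis=1, keepdims=True)
    am = areas - areas.mean()
    sx = np.sqrt((xm**2).sum(axis=1))
    sa = np.sqrt((am**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ am) / (sx * sa)
    defined = sx > 0
    r = np.where(defined, r, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = np.where(defined, np.clip(2 * stats.t.sf(np.abs(t), n - 2), np.finfo(float).tiny, 1.0), np.nan)
    return pd.DataFrame(
        {
            "gene_id": zpb.gene_ids,
            "r_shoot": r,
            "r_p": p,
            "defined": defined,
        }
    )


def combine_and_rank(
    shoot_corr: pd.DataFrame,
    rosette_fits: pd.DataFrame,
    trend_classes: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Filter-then-sort candidate ranking.

    Eligibility: member of the ``time_induced_dose_repressed`` class, with a
    significant negative drought coefficient in the rosette fits
    (``padj_drought < alpha``, ``coef_drought < 0``) and a defined shoot
    correlation.  Eligible genes are ranked by descending ``r_shoot``; ties
    break by ascending ``padj_drought`` then gene id.  Ineligible genes are
    carried unranked.
    """
    class3 = set(
        trend_classes.loc[
            trend_classes["trend_class"] == "time_induced_dose_repressed", "gene_id"
        ]
    )
    merged = shoot_corr.merge(
        rosette_fits[["gene_id", "coef_drought", "padj_drought"]],
        on="gene_id",
        how="inner",
        validate="1:1",
    )
    merged["in_class3"] = merged["gene_id"].isin(class3)
    merged["drought_neglog10_padj"] = -np.log10(merged["padj_drought"])
    merged["eligible"] = (
        merged["in_class3"]
        & merged["defined"]
        & (merged["padj_drought"] < alpha)
        & (merged["coef_drought"] < 0)
    )
    merged = merged.sort_values(
        ["eligible", "r_shoot", "padj_drought", "gene_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    n_eligible = int(merged["eligible"].sum())
    rank = np.full(len(merged), np.nan)
    rank[:n_eligible] = np.arange(1, n_eligible + 1)
    merged["rank"] = rank
    return merged.drop(columns=["defined"])
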