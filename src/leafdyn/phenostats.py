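"""Phenotype statistics: ANCOVA on growth trajectories and Welch's t-test.

The ANCOVA fits a parallel-slopes model ``response ~ covariate + group`` and
F-tests the group term by comparing residual sums of squares of the reduced
(covariate-only) and full models.  The genotype comparisons use Welch's
unequal-variance t statistic with Satterthwaite degrees of freedom and a
one-sided alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ancova_condition_effect", "welch_one_sided_t"]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float((r**2).sum()), beta


def ancova_condition_effect(
    records: pd.DataFrame,
    response: str = "area_mm2",
    group: str = "condition",
    covariate: str = "day",
    log_response: bool = False,
) -> dict:
    """F test of a two-level group effect adjusting for a quantitative
    covariate (e.g. drought vs well-watered shoot area over days).

    Returns ``{"F", "p", "group_coef", "df"}``; ``group_coef`` is the fitted
    offset of the second group level (sorted order) relative to the first.
    """
    levels = sorted(records[group].unique())
    if len(levels) < 2:
        raise ValueError("ANCOVA needs at least two groups")
    if len(levels) > 2:
        raise ValueError("only the two-group ANCOVA is supported")
    for lv in levels:
        if (records[group] == lv).sum() < 3:
            raise ValueError(f"group {lv!r} has fewer than 3 records")
    y = records[response].to_numpy(dtype=float)
    if log_response:
        y = np.log(y)
    x = records[covariate].to_numpy(dtype=float)
    g = (records[group] == levels[1]).to_numpy(dtype=float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), x, g])
    X_red = np.column_stack([np.ones(n), x])
    rss_full, beta = _rss(X_full, y)
    rss_red, _ = _rss(X_red, y)
    df_num = 1
    df_den = n - X_full.shape[1]
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")
    # residual sums at numerical zero (perfect fits) are treated as exact
    eps = 1e-12 * max(float(((y - y.mean()) ** 2).sum()), 1.0)
    if rss_full <= eps:
        F = np.inf if rss_red > eps else 0.0
    else:
        F = max(rss_red - rss_full, 0.0) / df_num / (rss_full / df_den)
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    p = min(max(p, 0.0), 1.0) if np.isfinite(F) else max(p, np.finfo(float).tiny)
    return {
        "F": float(F),
        "p": float(np.clip(p, np.finfo(float).tiny, 1.0)),
        "group_coef": float(beta[2]),
        "df": (df_num, df_den),
        "group_levels": levels,
    }


def welch_one_sided_t(sample_a, sample_b) -> dict:
    """Welch's t-test of ``mean(a) > mean(b)``.

    Returns ``{"t", "df_welch", "p"}``; identical samples give t = 0 and
    p = 0.5.  Each sample needs n >= 2 and nonzero variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate (zero-variance) samples")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(stats.t.sf(t, df))
    return {"t": float(t), "df_welch": float(df), "p": float(np.clip(p, np.finfo(float).tiny, 1.0))}
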