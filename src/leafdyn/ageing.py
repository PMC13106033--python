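"""Leaf-ageing inference: composite age covariate, gene-wise age + drought
model, classification, and quadratic display trends.

Leaf stage (rosette position, L1 oldest) and sampling day are collinear
descriptors of how old a leaf is, so they are combined into one composite
covariate::

    leaf_age = 23 + day - 2 * leaf_stage

Each gene is then modelled per cell type on log2 quantile-normalized
pseudobulk expression::

    expression ~ intercept + leaf_age + drought

with a binary drought indicator.  A gene is called ageing-induced when its
leaf-age coefficient is significant (BH-adjusted p < 0.01) and exceeds 0.04
(strictly), ageing-repressed for coefficient < -0.04, and drought-responsive
when the drought term is significant at the same level.  The 0.04 cut is in
the engine's log2-normalized units and is configurable.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._ols import CovariateError, genewise_ols
from .io import SampleTable
from .pseudobulk import PseudobulkMatrix

__all__ = [
    "compute_leaf_age",
    "check_collinearity",
    "adjust_pvalues_bh",
    "fit_age_drought_model",
    "classify_ageing_genes",
    "fit_quadratic_trend",
    "QuadraticTrend",
    "AgeingModel",
    "AgeingResults",
]

LEAF_AGE_INTERCEPT = 23
LEAF_AGE_STAGE_WEIGHT = 2


def compute_leaf_age(stage, day):
    """Composite leaf age ``23 + day - 2 * stage`` (integer-exact).

    ``stage`` is the rosette leaf position 1..15 (L1 oldest); ``day`` the
    sampling day.  Accepts scalars or arrays.
    """
    stage = np.asarray(stage)
    day = np.asarray(day)
    if np.any(stage < 1) or np.any(stage > 15):
        raise ValueError("leaf stage must be within 1..15")
    out = LEAF_AGE_INTERCEPT + day - LEAF_AGE_STAGE_WEIGHT * stage
    return out if out.ndim else out.item()


def check_collinearity(design: pd.DataFrame, vif_threshold: float = 5.0) -> dict:
    """Variance-inflation factors and condition number of a design.

    Each covariate's VIF is ``1 / (1 - R^2)`` from the auxiliary regression
    of that covariate on all others (with intercept); a constant covariate
    reports ``inf``.  ``flagged`` lists covariates whose VIF exceeds the
    threshold (exact collinearity always flags).
    """
    if len(design) < 2:
        raise ValueError("need at least 2 samples")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    vifs = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        if np.ptp(y) == 0:
            vifs[name] = np.inf
            continue
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    centered = X - X.mean(axis=0)
    scale = centered.std(axis=0)
    scale[scale == 0] = 1.0
    cond = float(np.linalg.cond(centered / scale))
    return {
        "vif": vifs,
        "condition_number": cond,
        "flagged": [k for k, v in vifs.items() if v > vif_threshold],
    }


def adjust_pvalues_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Applied separately per (cell type x coefficient) family by the callers.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_age_drought_model(
    pb: PseudobulkMatrix,
    samples: SampleTable,
    cell_type: str,
) -> pd.DataFrame:
    """Gene-wise OLS of log2-QN expression on {leaf_age, drought} for one
    cell type.  Returns a GeneFit table with BH-adjusted p per coefficient.
    """
    if pb.stage != "log_qn":
        raise ValueError("the ageing model expects log2 quantile-normalized input")
    sub = pb.select_group(cell_type)
    if len(sub.columns) < 4:
        raise CovariateError(
            f"cell type {cell_type!r} has {len(sub.columns)} pseudobulk columns; need >= 4"
        )
    meta = samples.lookup(sub.sample_ids)
    leaf_age = compute_leaf_age(
        meta["leaf_stage"].to_numpy(int), meta["day"].to_numpy(int)
    ).astype(float)
    drought = (meta["condition"] == "drought").to_numpy(float)
    X = np.column_stack([np.ones(len(meta)), leaf_age, drought])
    res = genewise_ols(X, sub.values.T, ["intercept", "leaf_age", "drought"])
    fits = pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "cell_type": cell_type,
            "intercept": res["coef"][0],
            "coef_age": res["coef"][1],
            "se_age": res["se"][1],
            "p_age": res["p"][1],
            "coef_drought": res["coef"][2],
            "se_drought": res["se"][2],
            "p_drought": res["p"][2],
        }
    )
    fits["padj_age"] = adjust_pvalues_bh(fits["p_age"])
    fits["padj_drought"] = adjust_pvalues_bh(fits["p_drought"])
    return fits


def classify_ageing_genes(
    fits: pd.DataFrame, alpha: float = 0.01, min_coef: float = 0.04
) -> pd.DataFrame:
    """Apply the significance-and-effect-size rule to a GeneFit table.

    induced: padj_age < alpha and coef_age > min_coef (strict);
    repressed: padj_age < alpha and coef_age < -min_coef;
    drought_responsive: padj_drought < alpha, with the drought direction
    taken from the sign of the drought coefficient.
    """
    sig_age = fits["padj_age"].to_numpy() < alpha
    coef = fits["coef_age"].to_numpy()
    ageing = np.where(
        sig_age & (coef > min_coef),
        "induced",
        np.where(sig_age & (coef < -min_coef), "repressed", "none"),
    )
    dr = fits["padj_drought"].to_numpy() < alpha
    direction = np.where(
        dr, np.where(fits["coef_drought"].to_numpy() > 0, "up", "down"), "none"
    )
    return pd.DataFrame(
        {
            "gene_id": fits["gene_id"],
            "cell_type": fits["cell_type"],
            "ageing": ageing,
            "drought_responsive": dr,
            "drought_direction": direction,
        }
    )


@dataclasses.dataclass
class QuadraticTrend:
    """Degree-2 polynomial display trend with pointwise confidence bands."""

    coefficients: np.ndarray  # (q0, q1, q2) for q0 + q1*a + q2*a^2
    cov: np.ndarray
    sigma2: float
    df_resid: int
    ci_level: float

    def predict(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        q0, q1, q2 = self.coefficients
        return q0 + q1 * ages + q2 * ages**2

    def ci_halfwidth(self, ages: np.ndarray) -> np.ndarray:
        """Pointwise CI half-width for the mean curve at ``ages``."""
        ages = np.asarray(ages, dtype=float)
        Xg = np.column_stack([np.ones_like(ages), ages, ages**2])
        var = np.einsum("ij,jk,ik->i", Xg, self.cov, Xg)
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2.0, self.df_resid) if self.df_resid > 0 else 0.0
        return tcrit * np.sqrt(np.maximum(var, 0.0))


def fit_quadratic_trend(
    ages: Sequence[float], values: Sequence[float], ci_level: float = 0.95
) -> QuadraticTrend:
    """Least-squares parabola ``value ~ q0 + q1*age + q2*age^2``.

    Needs >= 4 points over >= 3 distinct ages; the CI comes from the
    coefficient covariance and the t distribution at ``ci_level``.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct ages (rank deficiency)")
    if ci_level not in (0.95, 0.99):
        raise ValueError("ci_level must be 0.95 or 0.99")
    X = np.column_stack([np.ones_like(ages), ages, ages**2])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    df = len(ages) - 3
    sigma2 = float((resid**2).sum() / df) if df > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return QuadraticTrend(
        coefficients=coef, cov=cov, sigma2=sigma2, df_resid=df, ci_level=ci_level
    )


class AgeingModel:
    """Gene-wise leaf-age + drought model for one cell type.

    Parameters
    ----------
    pb
        ``log_qn``-stage pseudobulk matrix (all cell types; the model
        selects its own columns).
    samples
        Rosette sample covariates.
    cell_type
        Which pseudobulk group to model.
    """

    def __init__(self, pb: PseudobulkMatrix, samples: SampleTable, cell_type: str):
        self.pb = pb
        self.samples = samples
        self.cell_type = cell_type

    def diagnostics(self) -> dict:
        """Collinearity diagnostics of the raw {leaf_stage, day, drought}
        design, motivating the composite covariate."""
        meta = self.samples.lookup(self.pb.select_group(self.cell_type).sample_ids)
        design = pd.DataFrame(
            {
                "leaf_stage": meta["leaf_stage"].astype(float),
                "day": meta["day"].astype(float),
                "drought": (meta["condition"] == "drought").astype(float),
            }
        )
        return check_collinearity(design)

    def fit(self, alpha: float = 0.01, min_coef: float = 0.04) -> "AgeingResults":
        fits = fit_age_drought_model(self.pb, self.samples, self.cell_type)
        classes = classify_ageing_genes(fits, alpha=alpha, min_coef=min_coef)
        return AgeingResults(self, fits, classes, alpha, min_coef)


class AgeingResults:
    """Per-gene coefficient estimates and ageing/drought classifications."""

    def __init__(self, model, fits, classifications, alpha, min_coef):
        self.model = model
        self.fits = fits
        self.classifications = classifications
        self.alpha = alpha
        self.min_coef = min_coef

    @property
    def table(self) -> pd.DataFrame:
        return self.fits.merge(
            self.classifications, on=["gene_id", "cell_type"], validate="1:1"
        )

    def gene_sets(self) -> dict:
        """Directional sets used by the hormone-overlap stage."""
        t = self.table
        return {
            "ageing_up": set(t.loc[t["ageing"] == "induced", "gene_id"]),
            "ageing_down": set(t.loc[t["ageing"] == "repressed", "gene_id"]),
            "drought_up": set(t.loc[t["drought_direction"] == "up", "gene_id"]),
            "drought_down": set(t.loc[t["drought_direction"] == "down", "gene_id"]),
        }

    def trend(
        self, gene_id: str, ci_level: float = 0.95, condition: Optional[str] = None
    ) -> QuadraticTrend:
        """Quadratic display trend of one gene's expression against leaf age."""
        sub = self.model.pb.select_group(self.model.cell_type)
        meta = self.model.samples.lookup(sub.sample_ids)
        mask = np.ones(len(meta), dtype=bool)
        if condition is not None:
            mask = (meta["condition"] == condition).to_numpy()
        ages = compute_leaf_age(
            meta["leaf_stage"].to_numpy(int)[mask], meta["day"].to_numpy(int)[mask]
        )
        row = np.flatnonzero(sub.gene_ids == gene_id)
        if row.size != 1:
            raise KeyError(gene_id)
        return fit_quadratic_trend(ages, sub.values[row[0], mask], ci_level=ci_level)

    def summary(self) -> str:
        t = self.table
        n = len(t)
        lines = [
            f"Leaf-ageing model: cell type {self.model.cell_type!r}, {n} genes, "
            f"{len(self.model.pb.select_group(self.model.cell_type).columns)} pseudobulk columns",
            f"  thresholds: padj < {self.alpha}, |leaf-age coefficient| > {self.min_coef}",
            f"  ageing-induced:   {(t['ageing'] == 'induced').sum():6d}",
            f"  ageing-repressed: {(t['ageing'] == 'repressed').sum():6d}",
            f"  drought-responsive: {int(t['drought_responsive'].sum()):4d} "
            f"(up {(t['drought_direction'] == 'up').sum()}, "
            f"down {(t['drought_direction'] == 'down').sum()})",
        ]
        return "\n".join(lines)
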