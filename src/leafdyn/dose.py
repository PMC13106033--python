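"""Dose-response modelling over the hard-agar (HA) condition grid.

Genes are fitted per cell type on log2 quantile-normalized condition-level
pseudobulk with two quantitative covariates, sampling day and HA dose, and
assigned to trend classes by coefficient sign and significance:

``dose_induced_time_flat``
    dose term significant and positive, time term not significant —
    stress-responsive irrespective of development.
``dose_and_time_induced``
    both terms significant and positive.
``time_induced_dose_repressed``
    both significant, time positive, dose negative — development-induced
    but repressed in proportion to stress severity (the class whose mean
    trajectory tracks shoot area most closely).

Class-mean z-score trajectories across the grid are correlated with the
per-condition mean shoot area (Pearson).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import genewise_ols
from .ageing import adjust_pvalues_bh
from .io import SampleTable
from .pseudobulk import PseudobulkMatrix

__all__ = [
    "ConditionGrid",
    "build_condition_grid",
    "condition_key",
    "fit_time_dose_model",
    "classify_trend",
    "class_mean_trajectory",
    "correlate_with_shoot_area",
    "DoseResponseModel",
    "DoseResponseResults",
]

TREND_CLASSES = (
    "dose_induced_time_flat",
    "dose_and_time_induced",
    "time_induced_dose_repressed",
    "other",
    "none",
)


@dataclasses.dataclass
class ConditionGrid:
    doses: np.ndarray
    days: np.ndarray
    conditions: list  # of (dose, day)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


def condition_key(dose: float, day: int) -> str:
    """Stable string key for a (dose, day) condition column."""
    return f"dose{dose:g}_day{int(day)}"


def build_condition_grid(samples: SampleTable, allow_incomplete: bool = False) -> ConditionGrid:
    """Distinct sorted doses and days of the hard-agar samples.

    A ragged design (some (dose, day) cell without samples) raises unless
    ``allow_incomplete`` is set.
    """
    ha = samples.frame[samples.frame["experiment"] == "hard_agar"]
    if ha.empty:
        raise ValueError("no hard_agar samples present")
    if ha.duplicated(["ha_dose", "day", "sample_id"]).any():
        raise ValueError("duplicate (dose, day, sample) rows")
    doses = np.sort(ha["ha_dose"].unique())
    days = np.sort(ha["day"].unique()).astype(int)
    present = set(zip(ha["ha_dose"], ha["day"].astype(int)))
    full = [(do, da) for do in doses for da in days]
    missing = [c for c in full if c not in present]
    if missing and not allow_incomplete:
        raise ValueError(
            f"incomplete design: {len(missing)} of {len(full)} (dose, day) cells "
            f"have no samples (first missing: {missing[0]})"
        )
    conditions = [c for c in full if c in present]
    return ConditionGrid(doses=doses, days=days, conditions=conditions)


def fit_time_dose_model(
    pb: PseudobulkMatrix, samples: SampleTable, cell_type: str
) -> pd.DataFrame:
    """Gene-wise OLS on {day, dose}, both quantitative; BH per coefficient.

    ``pb`` is the log2-QN condition-level pseudobulk; columns are
    (cell_type, condition_key) pairs resolved back to (dose, day) via the
    sample table's hard-agar rows.
    """
    if pb.stage != "log_qn":
        raise ValueError("the dose model expects log2 quantile-normalized input")
    sub = pb.select_group(cell_type)
    lookup = _condition_lookup(samples)
    day = np.array([lookup[s][1] for s in sub.sample_ids], dtype=float)
    dose = np.array([lookup[s][0] for s in sub.sample_ids], dtype=float)
    X = np.column_stack([np.ones(len(day)), day, dose])
    res = genewise_ols(X, sub.values.T, ["intercept", "day", "dose"])
    fits = pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "cell_type": cell_type,
            "intercept": res["coef"][0],
            "coef_time": res["coef"][1],
            "se_time": res["se"][1],
            "p_time": res["p"][1],
            "coef_dose": res["coef"][2],
            "se_dose": res["se"][2],
            "p_dose": res["p"][2],
        }
    )
    fits["padj_time"] = adjust_pvalues_bh(fits["p_time"])
    fits["padj_dose"] = adjust_pvalues_bh(fits["p_dose"])
    return fits


def _condition_lookup(samples: SampleTable) -> Dict[str, tuple]:
    """condition_key -> (dose, day) for hard-agar samples and conditions."""
    ha = samples.frame[samples.frame["experiment"] == "hard_agar"]
    out = {}
    for _, r in ha.iterrows():
        key = condition_key(r["ha_dose"], r["day"])
        out[key] = (float(r["ha_dose"]), int(r["day"]))
        out[r["sample_id"]] = (float(r["ha_dose"]), int(r["day"]))
    return out


def classify_trend(fits: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Assign trend classes from coefficient signs and significance."""
    sig_d = fits["padj_dose"].to_numpy() < alpha
    sig_t = fits["padj_time"].to_numpy() < alpha
    cd = fits["coef_dose"].to_numpy()
    ct = fits["coef_time"].to_numpy()
    label = np.full(len(fits), "none", dtype=object)
    label[sig_d | sig_t] = "other"
    label[sig_d & ~sig_t & (cd > 0)] = "dose_induced_time_flat"
    label[sig_d & sig_t & (cd > 0) & (ct > 0)] = "dose_and_time_induced"
    label[sig_d & sig_t & (cd < 0) & (ct > 0)] = "time_induced_dose_repressed"
    return pd.DataFrame(
        {"gene_id": fits["gene_id"], "cell_type": fits["cell_type"], "trend_class": label}
    )


def class_mean_trajectory(
    zpb: PseudobulkMatrix, classes: pd.DataFrame, trend_class: str
) -> Optional[pd.Series]:
    """Mean z-score of the class's member genes per condition column.

    Returns None (with the caller expected to log) for an empty class.
    """
    members = set(classes.loc[classes["trend_class"] == trend_class, "gene_id"])
    if not members:
        return None
    mask = np.isin(zpb.gene_ids, list(members))
    traj = zpb.values[mask].mean(axis=0)
    return pd.Series(traj, index=[s for _, s in zpb.columns], name=trend_class)


def correlate_with_shoot_area(trajectory: Sequence[float], areas: Sequence[float]):
    """Pearson r (and two-sided t-based p) of a trajectory against area."""
    trajectory = np.asarray(trajectory, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(trajectory) != len(areas) or len(trajectory) < 3:
        raise ValueError("need >= 3 paired conditions")
    if trajectory.std() == 0 or areas.std() == 0:
        raise ValueError("zero variance on one side of the correlation")
    r, p = stats.pearsonr(trajectory, areas)
    return float(r), float(p)


class DoseResponseModel:
    """Two-quantitative-factor (day + HA dose) model for one cell type."""

    def __init__(
        self,
        pb: PseudobulkMatrix,
        samples: SampleTable,
        cell_type: str = "mesophyll",
        grid: Optional[ConditionGrid] = None,
    ):
        self.pb = pb
        self.samples = samples
        self.cell_type = cell_type
        self.grid = grid if grid is not None else build_condition_grid(samples, True)

    def fit(self, alpha: float = 0.01) -> "DoseResponseResults":
        fits = fit_time_dose_model(self.pb, self.samples, self.cell_type)
        classes = classify_trend(fits, alpha=alpha)
        return DoseResponseResults(self, fits, classes, alpha)


class DoseResponseResults:
    def __init__(self, model, fits, classes, alpha):
        self.model = model
        self.fits = fits
        self.classes = classes
        self.alpha = alpha

    @property
    def table(self) -> pd.DataFrame:
        return self.fits.merge(self.classes, on=["gene_id", "cell_type"], validate="1:1")

    def class_counts(self) -> pd.Series:
        return self.classes["trend_class"].value_counts()

    def trajectories(self, zpb: PseudobulkMatrix) -> Dict[str, pd.Series]:
        out = {}
        for cls in TREND_CLASSES[:3]:
            traj = class_mean_trajectory(zpb, self.classes, cls)
            if traj is not None:
                out[cls] = traj
        return out

    def condition_areas(self, column_ids: Iterable[str]) -> np.ndarray:
        """Mean shoot area per condition column, in column order."""
        ha = self.model.samples.frame
        ha = ha[ha["experiment"] == "hard_agar"].copy()
        ha["key"] = [
            condition_key(d, t) for d, t in zip(ha["ha_dose"], ha["day"])
        ]
        means = ha.groupby("key")["phenotype_area_mm2"].mean()
        return means.loc[list(column_ids)].to_numpy()

    def area_correlations(self, zpb: PseudobulkMatrix) -> pd.DataFrame:
        """Pearson r of each class-mean trajectory against mean shoot area."""
        rows = []
        for cls, traj in self.trajectories(zpb).items():
            areas = self.condition_areas(traj.index)
            r, p = correlate_with_shoot_area(traj.to_numpy(), areas)
            rows.append(
                {"trend_class": cls, "pearson_r": r, "pearson_p": p, "n_conditions": len(traj)}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        counts = self.class_counts()
        lines = [
            f"Dose-response model: cell type {self.model.cell_type!r}, "
            f"{len(self.fits)} genes over {self.model.grid.n_conditions} conditions "
            f"({len(self.model.grid.doses)} doses x {len(self.model.grid.days)} days)",
            f"  thresholds: padj < {self.alpha} per coefficient",
        ]
        for cls in TREND_CLASSES:
            lines.append(f"  {cls:28s} {int(counts.get(cls, 0)):6d}")
        return "\n".join(lines)
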