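"""Hormone-response detection and directional overlap with ageing sets.

Differential expression between one hormone treatment and the mock control
is assessed per cell class with a negative-binomial GLM likelihood-ratio
test on raw pseudobulk counts: the full model has an intercept plus a group
indicator (log link, log-library-size offset), the reduced model the
intercept only.  The NB dispersion is estimated per gene by the method of
moments under the full model and floored at 1e-8, so in the small-dispersion
limit the statistic reduces to a Poisson deviance difference.  The statistic
is referred to chi-square with 1 df and BH-adjusted within each
(hormone x cell class) family.

Genes responding to three or more hormones within a cell class are removed
as promiscuous.  The surviving directional sets are intersected with
ageing/drought gene sets of matching direction via a one-sided
(enrichment) Fisher exact test against a background of expressed genes.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .ageing import adjust_pvalues_bh
from .io import CELL_CLASSES, HORMONES, SampleTable
from .pseudobulk import PseudobulkMatrix

__all__ = [
    "lr_test_de",
    "filter_promiscuous",
    "OverlapResult",
    "directional_overlap_fisher",
    "summarize_hormone_association",
    "HormoneDEModel",
    "HormoneDEResults",
]

_DISPERSION_FLOOR = 1e-8


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; y, mu are genes x samples.

    Genes whose dispersion sits at the floor are evaluated with the exact
    Poisson log-likelihood (the NB limit), avoiding catastrophic gammaln
    cancellation at alpha -> 0.
    """
    mu = np.maximum(mu, 1e-300)
    out = np.empty(y.shape[0])
    poisson = alpha <= _DISPERSION_FLOOR
    if poisson.any():
        yp, mp = y[poisson], mu[poisson]
        out[poisson] = (yp * np.log(mp) - mp - special.gammaln(yp + 1.0)).sum(axis=1)
    nb = ~poisson
    if nb.any():
        yn, mn = y[nb], mu[nb]
        inv = 1.0 / alpha[nb][:, None]
        out[nb] = (
            special.gammaln(yn + inv)
            - special.gammaln(inv)
            - special.gammaln(yn + 1.0)
            + yn * np.log(alpha[nb][:, None] * mn)
            - (yn + inv) * np.log1p(alpha[nb][:, None] * mn)
        ).sum(axis=1)
    return out


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 25):
    """MLE of the per-gene rate ``m`` in ``mu_j = s_j * m`` at fixed dispersion.

    Newton iteration on log m; the score is monotone in log m so this
    converges globally.  Genes with zero total count get m = 0.
    """
    tot = y.sum(axis=1)
    m = tot / s.sum()
    pos = m > 0
    if not pos.any():
        return m
    b = np.log(m[pos])
    yp = y[pos]
    ap = alpha[pos][:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(b)[:, None]
        q = ap * mu / (1.0 + ap * mu)
        f = (yp - (yp + 1.0 / ap) * q).sum(axis=1)
        fp = -((yp + 1.0 / ap) * q * (1.0 - q)).sum(axis=1)
        step = np.clip(f / np.where(fp == 0, -1.0, fp), -4.0, 4.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-12:
            break
    m[pos] = np.exp(b)
    return m


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int = 2) -> np.ndarray:
    """Method-of-moments NB dispersion under fitted means, floored.

    The squared residuals carry a small-sample degrees-of-freedom
    correction ``J / (J - n_params)`` for the ``n_params`` fitted group
    means.
    """
    J = y.shape[1]
    scale = J / max(J - n_params, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (scale * (y - mu) ** 2 - mu).sum(axis=1)
        den = (mu**2).sum(axis=1)
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, _DISPERSION_FLOOR, None)


def lr_test_de(
    pb: PseudobulkMatrix,
    samples: SampleTable,
    cell_class: str,
    hormone: str,
    alpha_de: float = 0.05,
    moderate_dispersion: bool = True,
) -> pd.DataFrame:
    """NB-GLM LR test of one hormone against mock within one cell class.

    ``pb`` must be a raw-counts pseudobulk aggregated at cell-class level
    with per-sample columns.  Returns one row per gene with ``lr_stat``,
    ``p``, ``padj``, the effect direction, and the DE call at ``alpha_de``.

    With few replicate columns the per-gene moment estimator frequently
    underestimates the dispersion, which inflates the LR statistic for
    high-count genes.  ``moderate_dispersion`` therefore floors each gene's
    dispersion at the family median (computed across genes within this
    test), a light-touch analogue of the dispersion moderation standard DE
    engines perform; disable it to expose the raw per-gene estimator (e.g.
    for Poisson-limit checks).
    """
    if pb.stage != "raw_counts":
        raise ValueError("the LR test runs on raw pseudobulk counts")
    sub = pb.select_group(cell_class)
    meta = samples.lookup(sub.sample_ids)
    cond = meta["condition"].to_numpy()
    in_a = cond == f"hormone:{hormone}"
    in_b = cond == "mock"
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError(
            f"need >= 2 pseudobulk columns per group; got {int(in_a.sum())} for "
            f"{hormone} and {int(in_b.sum())} for mock in class {cell_class!r}"
        )
    y = sub.values[:, in_a | in_b]
    grp = in_a[in_a | in_b]
    libsize = y.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("a selected pseudobulk column has zero total count")
    ya, yb = y[:, grp], y[:, ~grp]
    sa, sb = libsize[grp], libsize[~grp]

    # moment dispersion under the full (two-group) model, Poisson group means
    mu_full0 = np.concatenate(
        [
            np.outer(ya.sum(axis=1) / sa.sum(), sa),
            np.outer(yb.sum(axis=1) / sb.sum(), sb),
        ],
        axis=1,
    )
    y_ordered = np.concatenate([ya, yb], axis=1)
    disp = _moment_dispersion(y_ordered, mu_full0)
    if moderate_dispersion:
        expressed = y_ordered.sum(axis=1) > 0
        if expressed.any():
            disp = np.maximum(disp, float(np.median(disp[expressed])))

    ma = _nb_group_mean(ya, sa, disp)
    mb = _nb_group_mean(yb, sb, disp)
    m0 = _nb_group_mean(y_ordered, np.concatenate([sa, sb]), disp)
    ll_full = _nb_loglik(ya, np.outer(ma, sa), disp) + _nb_loglik(
        yb, np.outer(mb, sb), disp
    )
    ll_red = _nb_loglik(y_ordered, np.outer(m0, np.concatenate([sa, sb])), disp)
    lr = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p = np.clip(stats.chi2.sf(lr, df=1), np.finfo(float).tiny, 1.0)

    allzero = y_ordered.sum(axis=1) == 0
    lr[allzero] = 0.0
    p[allzero] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        direction = np.where(ma > mb, "up", "down")
    direction = np.where(allzero | (ma == mb), "none", direction)

    out = pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "cell_class": cell_class,
            "hormone": hormone,
            "direction": direction,
            "lr_stat": lr,
            "p": p,
        }
    )
    out["padj"] = adjust_pvalues_bh(out["p"])
    out["de"] = out["padj"] < alpha_de
    return out


def filter_promiscuous(de: pd.DataFrame, max_hormones: int = 2) -> pd.DataFrame:
    """Remove genes DE under more than ``max_hormones`` hormones per class.

    Operates on the concatenated LR-test tables; a gene responding to three
    or more hormones within a cell class is dropped from all of that class's
    hormone sets (it may survive in another class).
    """
    if de.empty:
        return de.copy()
    hits = de[de["de"]]
    counts = hits.groupby(["cell_class", "gene_id"])["hormone"].nunique()
    promiscuous = set(counts[counts > max_hormones].index)
    keep = ~de.apply(
        lambda r: (r["cell_class"], r["gene_id"]) in promiscuous, axis=1
    )
    return de[keep].reset_index(drop=True)


@dataclasses.dataclass
class OverlapResult:
    """One directional hormone-set x ageing-set enrichment test."""

    hormone: str
    cell_class: str
    ageing_set: str
    overlap_genes: Set[str]
    table: Tuple[int, int, int, int]  # (a, b, c, d)
    fisher_p: float
    retained: bool


def directional_overlap_fisher(
    hormone_set: Set[str],
    ageing_set: Set[str],
    background: Set[str],
    hormone: str = "",
    cell_class: str = "",
    ageing_label: str = "",
    alpha: float = 0.05,
) -> OverlapResult:
    """One-sided Fisher exact test for over-representation of the overlap.

    2x2 table: [in both, hormone only; ageing only, neither] over the
    expressed-gene background.  ``retained`` means p < ``alpha``.
    """
    hormone_set, ageing_set, background = set(hormone_set), set(ageing_set), set(background)
    if not hormone_set <= background or not ageing_set <= background:
        raise ValueError("gene sets must be contained in the background")
    overlap = hormone_set & ageing_set
    a = len(overlap)
    b = len(hormone_set) - a
    c = len(ageing_set) - a
    d = len(background) - a - b - c
    # enrichment tail of the hypergeometric kernel on the fixed margins
    p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return OverlapResult(
        hormone=hormone,
        cell_class=cell_class,
        ageing_set=ageing_label,
        overlap_genes=overlap,
        table=(a, b, c, d),
        fisher_p=p,
        retained=p < alpha,
    )


def summarize_hormone_association(overlaps: Iterable[OverlapResult]) -> pd.DataFrame:
    """Per-hormone cell-class composition of retained overlap genes.

    Fractions sum to 1 within each hormone; empty input gives an empty
    frame.
    """
    rows = []
    for ov in overlaps:
        if not ov.retained:
            continue
        for g in sorted(ov.overlap_genes):
            rows.append(
                {
                    "hormone": ov.hormone,
                    "cell_class": ov.cell_class,
                    "ageing_set": ov.ageing_set,
                    "gene_id": g,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["hormone", "cell_class", "n_genes", "fraction"]
        )
    detail = pd.DataFrame(rows)
    counts = (
        detail.groupby(["hormone", "cell_class"])["gene_id"]
        .nunique()
        .rename("n_genes")
        .reset_index()
    )
    counts["fraction"] = counts["n_genes"] / counts.groupby("hormone")[
        "n_genes"
    ].transform("sum")
    return counts


class HormoneDEModel:
    """All (hormone x cell class) LR tests over one hormone experiment."""

    def __init__(self, pb_class: PseudobulkMatrix, samples: SampleTable):
        self.pb = pb_class
        self.samples = samples

    def fit(
        self,
        alpha_de: float = 0.05,
        max_hormones: int = 2,
        hormones: Iterable[str] = HORMONES,
        cell_classes: Iterable[str] = tuple(CELL_CLASSES),
    ) -> "HormoneDEResults":
        tables = [
            lr_test_de(self.pb, self.samples, cls, h, alpha_de=alpha_de)
            for cls in cell_classes
            for h in hormones
        ]
        de = pd.concat(tables, ignore_index=True)
        filtered = filter_promiscuous(de, max_hormones=max_hormones)
        return HormoneDEResults(self, de, filtered, alpha_de)


class HormoneDEResults:
    def __init__(self, model, de, filtered, alpha_de):
        self.model = model
        self.de = de
        self.filtered = filtered
        self.alpha_de = alpha_de

    def de_sets(self) -> Dict[Tuple[str, str, str], Set[str]]:
        """(cell_class, hormone, direction) -> surviving DE gene set."""
        hits = self.filtered[self.filtered["de"]]
        out: Dict[Tuple[str, str, str], Set[str]] = {}
        for (cls, h, d), grp in hits.groupby(["cell_class", "hormone", "direction"]):
            if d in ("up", "down"):
                out[(cls, h, d)] = set(grp["gene_id"])
        return out

    def background(self, cell_class: str) -> Set[str]:
        """Expressed genes: nonzero pseudobulk count in the class."""
        sub = self.model.pb.select_group(cell_class)
        return set(sub.gene_ids[sub.values.sum(axis=1) > 0])

    def overlap_with(
        self, ageing_sets: Mapping[str, Set[str]], alpha: float = 0.05
    ) -> list:
        """Directional Fisher tests of every DE set against every ageing set
        of matching direction.  ``ageing_sets`` keys must end in ``_up`` or
        ``_down``."""
        results = []
        for (cls, h, d), hset in sorted(self.de_sets().items()):
            bg = self.background(cls)
            for label, aset in sorted(ageing_sets.items()):
                if not label.endswith(f"_{d}"):
                    continue
                results.append(
                    directional_overlap_fisher(
                        hset & bg,
                        set(aset) & bg,
                        bg,
                        hormone=h,
                        cell_class=cls,
                        ageing_label=label,
                        alpha=alpha,
                    )
                )
        return results

    def summary(self) -> str:
        hits = self.filtered[self.filtered["de"]]
        lines = [
            f"Hormone DE (NB-GLM LR test, padj < {self.alpha_de}): "
            f"{len(hits)} calls across {hits['gene_id'].nunique()} genes"
        ]
        for cls, grp in hits.groupby("cell_class"):
            per = ", ".join(
                f"{h}:{n}" for h, n in grp["hormone"].value_counts().items()
            )
            lines.append(f"  {cls}: {per}")
        return "\n".join(lines)
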