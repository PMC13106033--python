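"""Parameter-recovery and calibration experiments on the synthetic designs.

Each function simulates data under the generator's study conditions, runs
the corresponding analysis stage, and scores the result against the planted
ground truth.  These experiments back the package's validation suite and
the reproduction script; problem sizes are chosen per experiment (full
2,000-gene designs for the recovery benchmarks, smaller replicated designs
for the 20-replicate calibration checks).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np

from .ageing import AgeingModel
from .candidates import combine_and_rank, gene_shoot_correlation
from .dose import DoseResponseModel, condition_key
from .hormones import HormoneDEModel
from .pipeline import prepare_celltype_matrix
from .pseudobulk import aggregate, filter_low_count_genes, filter_nuclei_by_umi, zscore_genes
from .simulate import SimConfig, simulate_hard_agar, simulate_hormone, simulate_rosette

__all__ = [
    "rosette_recovery",
    "trend_class_recovery",
    "null_coupling_correlations",
    "null_calibration",
    "decoupled_overlap_retentions",
    "hormone_coupling_recovery",
    "candidate_rank_runs",
]

_TREND_OF_ARCHETYPE = {
    "dose_only": "dose_induced_time_flat",
    "dose_time_concordant": "dose_and_time_induced",
    "time_induced_dose_repressed": "time_induced_dose_repressed",
}


def _ha_condition_key(samples):
    return {
        r["sample_id"]: condition_key(r["ha_dose"], r["day"])
        for _, r in samples.frame.iterrows()
    }


def rosette_recovery(seeds: Iterable[int], **overrides) -> Dict[str, float]:
    """Ageing-classification sensitivity/FDR and drought-advancement
    concordance on the default rosette design, pooled across seeds.

    Sensitivity counts the pure ageing archetypes; false discoveries are
    classified genes whose true age slope is exactly zero; concordance asks
    whether drought-advanced genes are flagged drought-responsive with the
    sign of their ageing direction.
    """
    tp = fp = pool = called = conc = adv_total = 0
    for seed in seeds:
        cfg = SimConfig(seed=seed, **overrides)
        nuclei, samples, gt = simulate_rosette(cfg)
        pb = prepare_celltype_matrix(nuclei, samples, "mesophyll")
        res = AgeingModel(pb, samples, "mesophyll").fit()
        tab = res.table.merge(gt, on="gene_id")
        is_called = (tab.ageing != "none").to_numpy()
        in_pool = tab.archetype.isin(["ageing_induced", "ageing_repressed"]).to_numpy()
        truly_flat = (tab.true_age_slope == 0).to_numpy()
        tp += int((is_called & in_pool).sum())
        pool += int(in_pool.sum())
        fp += int((is_called & truly_flat).sum())
        called += int(is_called.sum())
        adv = (tab.archetype == "drought_advanced").to_numpy()
        ok = (
            adv
            & tab.drought_responsive.to_numpy()
            & (np.sign(tab.coef_drought) == np.sign(tab.true_age_slope)).to_numpy()
        )
        conc += int(ok.sum())
        adv_total += int(adv.sum())
    return {
        "sensitivity": tp / pool if pool else float("nan"),
        "fdr": fp / called if called else 0.0,
        "advanced_concordance": conc / adv_total if adv_total else float("nan"),
        "n_genes_pooled": pool,
    }


def trend_class_recovery(seeds: Iterable[int], **overrides) -> Dict[str, float]:
    """Trend-class recovery and shoot-area association on the HA design.

    Cross-class confusion counts planted genes assigned to a *different*
    planted class (leakage into "other"/"none" is scored against recovery,
    not confusion).  The class-3 mean-z trajectory is correlated with the
    per-condition mean shoot area.
    """
    c3_hit = c3_total = cross = planted_total = 0
    rs = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, **overrides)
        nuclei, samples, gt = simulate_hard_agar(cfg)
        pb = prepare_celltype_matrix(
            nuclei, samples, "mesophyll", sample_key=_ha_condition_key(samples)
        )
        res = DoseResponseModel(pb, samples, "mesophyll").fit()
        tab = res.table.merge(gt, on="gene_id")
        planted = tab[tab.archetype.isin(_TREND_OF_ARCHETYPE)]
        own = planted.archetype.map(_TREND_OF_ARCHETYPE)
        c3 = planted.archetype == "time_induced_dose_repressed"
        c3_hit += int((c3 & (planted.trend_class == own)).sum())
        c3_total += int(c3.sum())
        cross += int(
            (
                planted.trend_class.isin(_TREND_OF_ARCHETYPE.values())
                & (planted.trend_class != own)
            ).sum()
        )
        planted_total += int(len(planted))
        zpb = zscore_genes(pb)
        corr = res.area_correlations(zpb).set_index("trend_class")
        if "time_induced_dose_repressed" in corr.index:
            rs.append(float(corr.loc["time_induced_dose_repressed", "pearson_r"]))
    return {
        "class3_recovery": c3_hit / c3_total if c3_total else float("nan"),
        "cross_class_confusion": cross / planted_total if planted_total else 0.0,
        "class3_area_r": float(np.mean(rs)) if rs else float("nan"),
        "n_class3_pooled": c3_total,
    }


def null_coupling_correlations(
    seeds: Iterable[int], **overrides
) -> np.ndarray:
    """|Pearson r| of the dose-only class mean vs shoot area when the
    phenotype is decoupled from dose (area_dose_decay = 0).

    The design plants only dose-responsive and null genes, isolating the
    dose-phenotype coupling from developmental growth shared over days.
    """
    defaults = dict(
        n_genes=600,
        nuclei_per_sample=16,
        shoots_per_condition=4,
        area_dose_decay=0.0,
        archetype_fractions={"dose_only": 0.2, "null": 0.8},
        plant_candidate_gene=False,
    )
    defaults.update(overrides)
    out = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, **defaults)
        nuclei, samples, gt = simulate_hard_agar(cfg)
        pb = prepare_celltype_matrix(
            nuclei, samples, "mesophyll", sample_key=_ha_condition_key(samples)
        )
        res = DoseResponseModel(pb, samples, "mesophyll").fit()
        corr = res.area_correlations(zscore_genes(pb)).set_index("trend_class")
        r = (
            float(corr.loc["dose_induced_time_flat", "pearson_r"])
            if "dose_induced_time_flat" in corr.index
            else 0.0
        )
        out.append(abs(r))
    return np.asarray(out)


def null_calibration(seeds: Iterable[int], alpha: float = 0.01, **overrides) -> np.ndarray:
    """Fraction of genes called at padj < alpha on all-null simulations."""
    defaults = dict(
        n_genes=500,
        nuclei_per_sample=20,
        archetype_fractions={"null": 1.0},
        plant_candidate_gene=False,
    )
    defaults.update(overrides)
    fracs = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, **defaults)
        nuclei, samples, _ = simulate_rosette(cfg)
        pb = prepare_celltype_matrix(nuclei, samples, "mesophyll")
        res = AgeingModel(pb, samples, "mesophyll").fit(alpha=alpha)
        fracs.append(float((res.fits.padj_age < alpha).mean()))
    return np.asarray(fracs)


def _ground_truth_ageing_sets(gt):
    return {
        "ageing_up": set(gt.loc[gt.true_age_slope > 0, "gene_id"]),
        "ageing_down": set(gt.loc[gt.true_age_slope < 0, "gene_id"]),
    }


def decoupled_overlap_retentions(seeds: Iterable[int], **overrides) -> int:
    """Total retained hormone-ageing overlaps across hormone simulations
    with zero hormone effect (any retention is spurious)."""
    defaults = dict(n_genes=500, nuclei_per_sample=30, effect_hormone=0.0)
    defaults.update(overrides)
    total = 0
    for seed in seeds:
        cfg = SimConfig(seed=seed, **defaults)
        nuclei, samples, gt = simulate_hormone(cfg)
        pb = filter_low_count_genes(
            aggregate(filter_nuclei_by_umi(nuclei), samples, level="cell_class")
        )
        res = HormoneDEModel(pb, samples).fit()
        total += sum(o.retained for o in res.overlap_with(_ground_truth_ageing_sets(gt)))
    return total


def hormone_coupling_recovery(seed: int, **overrides) -> float:
    """Fraction of planted (hormone, class, direction) couplings retained
    by the directional overlap stage against ground-truth ageing sets."""
    cfg = SimConfig(seed=seed, **overrides)
    nuclei, samples, gt = simulate_hormone(cfg)
    pb = filter_low_count_genes(
        aggregate(filter_nuclei_by_umi(nuclei), samples, level="cell_class")
    )
    res = HormoneDEModel(pb, samples).fit()
    overlaps = res.overlap_with(_ground_truth_ageing_sets(gt))
    planted = gt[gt.hormone != "."]
    combos = set(
        zip(
            planted.cell_types_affected,
            planted.hormone,
            np.where(planted.hormone_direction > 0, "up", "down"),
        )
    )
    retained = {
        (o.cell_class, o.hormone, "up" if o.ageing_set == "ageing_up" else "down")
        for o in overlaps
        if o.retained
    }
    return sum(1 for c in combos if c in retained) / len(combos)


def candidate_rank_runs(seeds: Iterable[int], **overrides) -> Dict[str, object]:
    """Rank of the planted candidate gene among eligible candidates across
    paired rosette + HA runs; a hit is a rank within the top 5%."""
    defaults = dict(n_genes=1000, nuclei_per_sample=24, shoots_per_condition=4)
    defaults.update(overrides)
    hits = 0
    percentiles = []
    n_runs = 0
    for seed in seeds:
        n_runs += 1
        cfg = SimConfig(seed=seed, **defaults)
        nuclei, samples, gt = simulate_hard_agar(cfg)
        pb = prepare_celltype_matrix(
            nuclei, samples, "mesophyll", sample_key=_ha_condition_key(samples)
        )
        dres = DoseResponseModel(pb, samples, "mesophyll").fit()
        zpb = zscore_genes(pb)
        areas = dres.condition_areas([s for _, s in zpb.columns])
        shoot_corr = gene_shoot_correlation(zpb, areas)
        nuclei_r, samples_r, _ = simulate_rosette(cfg)
        pbr = prepare_celltype_matrix(nuclei_r, samples_r, "mesophyll")
        ares = AgeingModel(pbr, samples_r, "mesophyll").fit()
        ranked = combine_and_rank(shoot_corr, ares.fits, dres.classes)
        n_eligible = int(ranked.eligible.sum())
        row = ranked.loc[ranked.gene_id == gt.gene_id.iloc[0], "rank"]
        rank = float(row.iloc[0]) if len(row) and np.isfinite(row.iloc[0]) else np.nan
        if n_eligible and np.isfinite(rank):
            percentiles.append(rank / n_eligible)
            if rank <= max(np.ceil(0.05 * n_eligible), 1):
                hits += 1
        else:
            percentiles.append(np.nan)
    return {"hits": hits, "n_runs": n_runs, "rank_percentiles": percentiles}
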