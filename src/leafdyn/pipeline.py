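"""End-to-end orchestration: simulate -> pseudobulk -> models -> candidates.

One configuration (YAML-compatible dict) drives every stage with the
thresholds of the study defaults: UMI >= 450, padj < 0.01 for the linear
models, padj < 0.05 for hormone DE and Fisher overlaps, |leaf-age
coefficient| > 0.04, promiscuity cut at > 2 hormones.  A run writes every
stage table as TSV plus a manifest recording the configuration, seed and
per-stage row counts; identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

import yaml

from . import __version__
from .ageing import AgeingModel
from .candidates import combine_and_rank, gene_shoot_correlation
from .dose import DoseResponseModel, condition_key
from .hormones import HormoneDEModel, summarize_hormone_association
from .io import CELL_CLASSES, CELL_TYPES, NucleusTable, SampleTable, write_results
from .pseudobulk import (
    PseudobulkMatrix,
    aggregate,
    filter_low_count_genes,
    filter_nuclei_by_umi,
    log_transform,
    quantile_normalize,
    zscore_genes,
)
from .simulate import SimConfig, simulate_hard_agar, simulate_hormone, simulate_rosette

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "prepare_celltype_matrix"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclasses.dataclass
class PipelineConfig:
    """Run configuration; defaults carry the study thresholds."""

    seed: int = 0
    outdir: str = "leafdyn_run"
    min_umi: int = 450
    min_total: int = 10
    min_samples: int = 3
    alpha_linear: float = 0.01
    alpha_de: float = 0.05
    alpha_fisher: float = 0.05
    min_coef: float = 0.04
    max_hormones: int = 2
    dose_cell_type: str = "mesophyll"
    ageing_cell_types: Optional[List[str]] = None
    simulate: Dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_linear", "alpha_de", "alpha_fisher"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ageing_cell_types is None:
            self.ageing_cell_types = list(CELL_TYPES)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.simulate)

    def as_dict(self) -> Dict:
        return dataclasses.asdict(self)


def prepare_celltype_matrix(
    nuclei: NucleusTable,
    samples: SampleTable,
    group: str,
    level: str = "cell_type",
    min_umi: int = 450,
    min_total: int = 10,
    min_samples: int = 3,
    sample_key=None,
) -> PseudobulkMatrix:
    """Filter nuclei, aggregate, gene-filter, quantile-normalize and log:
    the standard path from raw nuclei to one group's model-ready matrix.

    Quantile normalization is applied within the group's own columns, so
    cross-group composition differences are never normalized away.
    """
    kept = filter_nuclei_by_umi(nuclei, min_umi=min_umi)
    pb = aggregate(kept, samples, level=level, sample_key=sample_key)
    sub = pb.select_group(group)
    sub = filter_low_count_genes(sub, min_total=min_total, min_samples=min_samples)
    return log_transform(quantile_normalize(sub))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure raises :class:`PipelineError` carrying the stage name
    and an error code; the manifest on disk is then marked incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    manifest: Dict = {
        "leafdyn_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
        "complete": False,
    }
    manifest_path = outdir / "manifest.json"

    def _write_manifest():
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def _emit(name: str, table: pd.DataFrame):
        path = outdir / f"{name}.tsv"
        write_results(table, path)
        manifest["outputs"][name] = {"rows": int(len(table)), "sha256": _hash_file(path)}

    try:
        # ---- simulate ------------------------------------------------
        stage = "simulate"
        sim = config.sim_config()
        ros_nuc, ros_samp, truth = simulate_rosette(sim)
        hor_nuc, hor_samp, _ = simulate_hormone(sim)
        ha_nuc, ha_samp, _ = simulate_hard_agar(sim)
        manifest["stages"][stage] = {
            "rosette_nuclei": int(ros_nuc.n_nuclei),
            "hormone_nuclei": int(hor_nuc.n_nuclei),
            "hard_agar_nuclei": int(ha_nuc.n_nuclei),
            "n_genes": int(sim.n_genes),
        }
        _emit("ground_truth", truth)

        # ---- ageing (rosette) ---------------------------------------
        stage = "ageing"
        ageing_tables = []
        ageing_results = {}
        for ct in config.ageing_cell_types:
            pb_ct = prepare_celltype_matrix(
                ros_nuc, ros_samp, ct,
                min_umi=config.min_umi, min_total=config.min_total,
                min_samples=config.min_samples,
            )
            res = AgeingModel(pb_ct, ros_samp, ct).fit(
                alpha=config.alpha_linear, min_coef=config.min_coef
            )
            ageing_results[ct] = res
            ageing_tables.append(res.table)
        ageing_all = pd.concat(ageing_tables, ignore_index=True)
        manifest["stages"][stage] = {
            "cell_types": list(config.ageing_cell_types),
            "genes_fit": int(len(ageing_all)),
            "ageing_calls": int((ageing_all["ageing"] != "none").sum()),
            "drought_calls": int(ageing_all["drought_responsive"].sum()),
        }
        _emit("ageing_fits", ageing_all)

        # ---- hormones ------------------------------------------------
        stage = "hormones"
        kept = filter_nuclei_by_umi(hor_nuc, min_umi=config.min_umi)
        pb_cls = aggregate(kept, hor_samp, level="cell_class")
        pb_cls = filter_low_count_genes(
            pb_cls, min_total=config.min_total, min_samples=config.min_samples
        )
        hres = HormoneDEModel(pb_cls, hor_samp).fit(
            alpha_de=config.alpha_de, max_hormones=config.max_hormones
        )
        class_sets = _class_level_ageing_sets(ageing_results)
        overlaps = []
        for cls, sets in class_sets.items():
            sub = HormoneDEResultsView(hres, cls)
            overlaps.extend(sub.overlap(sets, alpha=config.alpha_fisher))
        overlap_table = pd.DataFrame(
            [
                {
                    "hormone": ov.hormone,
                    "cell_class": ov.cell_class,
                    "ageing_set": ov.ageing_set,
                    "a": ov.table[0],
                    "b": ov.table[1],
                    "c": ov.table[2],
                    "d": ov.table[3],
                    "fisher_p": ov.fisher_p,
                    "retained": ov.retained,
                    "overlap_genes": ";".join(sorted(ov.overlap_genes)),
                }
                for ov in overlaps
            ]
        )
        manifest["stages"][stage] = {
            "de_calls": int(hres.filtered["de"].sum()),
            "overlap_tests": int(len(overlap_table)),
            "retained_overlaps": int(overlap_table["retained"].sum())
            if len(overlap_table)
            else 0,
        }
        _emit("hormone_de", hres.filtered)
        _emit("hormone_overlaps", overlap_table)
        _emit(
            "hormone_summary",
            summarize_hormone_association(overlaps),
        )

        # ---- dose response (hard agar) -------------------------------
        stage = "dose_response"
        ha_key = {
            r["sample_id"]: condition_key(r["ha_dose"], r["day"])
            for _, r in ha_samp.frame.iterrows()
        }
        pb_ha = prepare_celltype_matrix(
            ha_nuc, ha_samp, config.dose_cell_type,
            min_umi=config.min_umi, min_total=config.min_total,
            min_samples=config.min_samples, sample_key=ha_key,
        )
        dres = DoseResponseModel(pb_ha, ha_samp, config.dose_cell_type).fit(
            alpha=config.alpha_linear
        )
        zpb = zscore_genes(pb_ha)
        traj_rows = []
        for cls, traj in dres.trajectories(zpb).items():
            for key, val in traj.items():
                traj_rows.append({"trend_class": cls, "condition": key, "mean_z": val})
        corr = dres.area_correlations(zpb)
        manifest["stages"][stage] = {
            "genes_fit": int(len(dres.fits)),
            "class_counts": {k: int(v) for k, v in dres.class_counts().items()},
        }
        _emit("dose_fits", dres.table)
        _emit("dose_trajectories", pd.DataFrame(traj_rows))
        _emit("dose_area_correlations", corr)

        # ---- candidates ----------------------------------------------
        stage = "candidates"
        areas = dres.condition_areas([s for _, s in zpb.columns])
        shoot_corr = gene_shoot_correlation(zpb, areas)
        meso_fits = ageing_results[config.dose_cell_type].fits
        ranked = combine_and_rank(
            shoot_corr, meso_fits, dres.classes, alpha=config.alpha_linear
        )
        manifest["stages"][stage] = {
            "scored": int(len(ranked)),
            "eligible": int(ranked["eligible"].sum()),
        }
        _emit("candidates", ranked)

        manifest["complete"] = True
        _write_manifest()
        for name, ctx in manifest["stages"].items():
            log.info("stage %s: %s", name, ctx)
        return manifest
    except PipelineError:
        _write_manifest()
        raise
    except Exception as exc:  # annotate with the failing stage
        _write_manifest()
        raise PipelineError(stage, type(exc).__name__, str(exc)) from exc


def _class_level_ageing_sets(ageing_results) -> Dict[str, Dict[str, set]]:
    """Union the per-cell-type directional sets into cell-class sets."""
    out: Dict[str, Dict[str, set]] = {}
    for cls, members in CELL_CLASSES.items():
        sets: Dict[str, set] = {
            "ageing_up": set(),
            "ageing_down": set(),
            "drought_up": set(),
            "drought_down": set(),
        }
        for ct in members:
            if ct in ageing_results:
                for k, v in ageing_results[ct].gene_sets().items():
                    sets[k] |= v
        out[cls] = sets
    return out


class HormoneDEResultsView:
    """Restrict a hormone-DE result to one cell class for overlap tests."""

    def __init__(self, results, cell_class: str):
        self.results = results
        self.cell_class = cell_class

    def overlap(self, ageing_sets, alpha: float = 0.05):
        from .hormones import directional_overlap_fisher

        out = []
        bg = self.results.background(self.cell_class)
        for (cls, h, d), hset in sorted(self.results.de_sets().items()):
            if cls != self.cell_class:
                continue
            for label, aset in sorted(ageing_sets.items()):
                if not label.endswith(f"_{d}"):
                    continue
                out.append(
                    directional_overlap_fisher(
                        hset & bg, set(aset) & bg, bg,
                        hormone=h, cell_class=cls, ageing_label=label, alpha=alpha,
                    )
                )
        return out
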