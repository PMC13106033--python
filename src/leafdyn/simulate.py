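"""Synthetic single-nucleus experiments with planted ground truth.

Three designs mirror the study layouts the analysis stages expect:

``rosette``
    15 leaf stages x 9 sampling days x {well-watered, drought}; substrate
    water content declines linearly from 100% to 21% over the drought
    time course.
``hormone``
    8 exogenous hormone treatments plus a mock control, several replicate
    rosettes each; hormone-responsive genes shift in one cell class only.
``hard_agar``
    8 hard-agar (HA) doses x 11 days, ~7 individual shoots per condition,
    each shoot carrying a shoot-area phenotype coupled to dose and day.

Counts are negative binomial via a gamma-Poisson mixture: gene ``g`` in a
nucleus of depth ``s`` has mean ``s * p_g`` where ``p`` is the softmax of
the per-gene log2 expression (baseline plus design effects plus biological
noise) over genes — UMI counts measure relative, not absolute, abundance,
so planted effects live on the measurable scale.  Per-nucleus depth is
log-normal, capped to ``[umi_min, umi_max]``.  Random streams are split
hierarchically (design -> sample) from one master seed, so identical
configs give bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CELL_CLASSES, CELL_TYPES, HORMONES, NucleusTable, SampleTable

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "ConfigError",
    "assign_archetypes",
    "simulate_rosette",
    "simulate_hormone",
    "simulate_hard_agar",
]

ARCHETYPES = (
    "ageing_induced",
    "ageing_repressed",
    "drought_advanced",
    "dose_only",
    "dose_time_concordant",
    "time_induced_dose_repressed",
    "hormone_responsive",
    "null",
)

_DEFAULT_FRACTIONS = {
    "ageing_induced": 0.05,
    "ageing_repressed": 0.05,
    "drought_advanced": 0.05,
    "dose_only": 0.10,
    "dose_time_concordant": 0.10,
    "time_induced_dose_repressed": 0.10,
    "hormone_responsive": 0.05,
    "null": 0.50,
}

# Mesophyll-dominant leaf composition; order follows CELL_TYPES.
_DEFAULT_PROPORTIONS = (0.40, 0.14, 0.05, 0.03, 0.09, 0.08, 0.11, 0.06, 0.04)

_CLASS_OF_TYPE = {t: c for c, members in CELL_CLASSES.items() for t in members}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass
class SimConfig:
    """Simulation parameters.

    Effect sizes are on the log2 scale: ``effect_age`` in log2-units per
    leaf-age day, ``effect_drought`` a log2 shift under drought,
    ``effect_dose`` per unit HA dose, ``effect_time`` per day,
    ``effect_hormone`` the acute treatment shift.  ``advancement_days_per_wc``
    converts percentage points of water lost into days of extra effective
    leaf age for drought-advanced genes.
    """

    seed: int = 0
    n_genes: int = 2000
    n_cell_types: int = 9
    archetype_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    effect_age: float = 0.1
    effect_drought: float = 0.5
    advancement_days_per_wc: float = 0.15
    effect_dose: float = 0.3
    effect_time: float = 0.15
    effect_hormone: float = 2.0
    nb_dispersion: float = 0.15
    biological_sd: float = 0.2
    nuclei_per_sample: int = 40
    depth_lognormal: tuple = (7.2, 0.4)
    umi_min: int = 150
    umi_max: int = 20000
    cell_type_proportions: Sequence[float] = _DEFAULT_PROPORTIONS
    # rosette design
    n_stages: int = 15
    n_days_rosette: int = 9
    wc_final: float = 21.0
    # hormone design
    hormone_replicates: int = 6
    hormone_age_coupling: bool = True
    # hard-agar design; the paper names 1x, 1.67x, 2x and 3.33x HA doses and
    # does not print the full 8-level grid, so the default spans 1.0-3.33.
    doses: Sequence[float] = (1.0, 1.33, 1.67, 2.0, 2.33, 2.67, 3.0, 3.33)
    n_days_ha: int = 11
    shoots_per_condition: int = 7
    area_baseline_mm2: float = 27.5
    area_growth_rate: float = 0.19
    area_dose_decay: float = 0.49
    area_noise_sd: float = 0.10
    plant_candidate_gene: bool = True

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cell_types <= 0 or self.nuclei_per_sample <= 0:
            raise ConfigError("n_genes, n_cell_types and nuclei_per_sample must be positive")
        if self.n_cell_types != len(CELL_TYPES):
            raise ConfigError(f"n_cell_types must be {len(CELL_TYPES)} (the atlas cell types)")
        total = sum(self.archetype_fractions.get(a, 0.0) for a in ARCHETYPES)
        extra = set(self.archetype_fractions) - set(ARCHETYPES)
        if extra:
            raise ConfigError(f"unknown archetypes: {sorted(extra)}")
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"archetype fractions sum to {total}, expected 1")
        if self.nb_dispersion < 0 or self.biological_sd < 0:
            raise ConfigError("nb_dispersion and biological_sd must be >= 0")
        if not (0 < self.umi_min <= self.umi_max):
            raise ConfigError("need 0 < umi_min <= umi_max")
        props = np.asarray(self.cell_type_proportions, dtype=float)
        if len(props) != self.n_cell_types or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ConfigError("cell_type_proportions must be a length-9 simplex vector")
        if len(self.doses) < 1 or any(d <= 0 for d in self.doses):
            raise ConfigError("doses must be positive")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def _streams(cfg: SimConfig, design: str):
    """Root SeedSequence children: (truth, baseline, design-specific)."""
    idx = {"truth": 0, "baseline": 1, "rosette": 2, "hormone": 3, "hard_agar": 4}
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(5)
    return children[idx["truth"]], children[idx["baseline"]], children[idx[design]]


def assign_archetypes(cfg: SimConfig) -> pd.DataFrame:
    """Draw the per-gene ground truth shared by all three designs.

    Effects per archetype (zero unless stated):

    - ``ageing_induced`` / ``ageing_repressed``: age slope +/- ``effect_age``.
    - ``drought_advanced``: age slope of random sign; its effective leaf age
      is advanced by ``advancement_days_per_wc`` per % water lost, which the
      main-effect model reads as a drought shift of concordant sign.
    - ``dose_only``: dose slope ``+effect_dose``.
    - ``dose_time_concordant``: dose ``+effect_dose``, time ``+effect_time``.
    - ``time_induced_dose_repressed``: dose ``-effect_dose``, time
      ``+effect_time``; in the rosette design these development-induced,
      stress-repressed genes also carry age slope ``+effect_age`` and drought
      shift ``-effect_drought`` (the photosynthesis-like profile).
    - ``hormone_responsive``: assigned one (hormone, cell class, direction)
      combination round-robin; shift ``effect_hormone`` in that class only.
      When ``hormone_age_coupling`` is set they also age with slope of the
      same sign, planting hormone-ageing couplings.
    - gene 0 becomes a planted candidate ("FRO6-like": age-induced,
      drought-repressed, strongly dose-repressed and phenotype-coupled)
      when ``plant_candidate_gene`` is set.
    """
    truth_ss, _, _ = _streams(cfg, "rosette")
    rng = np.random.default_rng(truth_ss)
    n = cfg.n_genes
    counts = {a: int(math.floor(cfg.archetype_fractions.get(a, 0.0) * n)) for a in ARCHETYPES}
    counts["null"] += n - sum(counts.values())
    labels = np.concatenate([[a] * counts[a] for a in ARCHETYPES])
    rng.shuffle(labels)
    gt = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "archetype": labels,
            "cell_types_affected": "all",
            "true_age_slope": 0.0,
            "true_drought_effect": 0.0,
            "true_time_slope": 0.0,
            "true_dose_slope": 0.0,
            "hormone": ".",
            "hormone_direction": 0,
        }
    )
    arch = gt["archetype"].to_numpy()
    gt.loc[arch == "ageing_induced", "true_age_slope"] = cfg.effect_age
    gt.loc[arch == "ageing_repressed", "true_age_slope"] = -cfg.effect_age
    adv = arch == "drought_advanced"
    gt.loc[adv, "true_age_slope"] = cfg.effect_age * rng.choice([-1.0, 1.0], size=int(adv.sum()))
    gt.loc[arch == "dose_only", "true_dose_slope"] = cfg.effect_dose
    conc = arch == "dose_time_concordant"
    gt.loc[conc, ["true_dose_slope", "true_time_slope"]] = [cfg.effect_dose, cfg.effect_time]
    tidr = arch == "time_induced_dose_repressed"
    gt.loc[tidr, ["true_dose_slope", "true_time_slope"]] = [-cfg.effect_dose, cfg.effect_time]
    gt.loc[tidr, ["true_age_slope", "true_drought_effect"]] = [cfg.effect_age, -cfg.effect_drought]

    horm = np.flatnonzero(arch == "hormone_responsive")
    # one direction per (hormone, class) pairing keeps each planted
    # coupling populated by several genes rather than splitting it
    combos = [
        (h, c, 1 if (i + j) % 2 == 0 else -1)
        for i, h in enumerate(HORMONES)
        for j, c in enumerate(CELL_CLASSES)
    ]
    for k, gi in enumerate(horm):
        h, c, d = combos[k % len(combos)]
        gt.loc[gi, ["hormone", "cell_types_affected", "hormone_direction"]] = [h, c, d]
        if cfg.hormone_age_coupling:
            gt.loc[gi, "true_age_slope"] = d * cfg.effect_age

    if cfg.plant_candidate_gene and n >= 1:
        gt.loc[0, "archetype"] = "candidate"
        gt.loc[0, ["hormone", "cell_types_affected", "hormone_direction"]] = [".", "all", 0]
        gt.loc[0, "true_age_slope"] = cfg.effect_age
        gt.loc[0, "true_drought_effect"] = -1.5 * cfg.effect_drought
        gt.loc[0, "true_time_slope"] = 2.0 * cfg.effect_time
        gt.loc[0, "true_dose_slope"] = -2.0 * cfg.effect_dose
    return gt


_LOW_BASELINE_ARCHETYPES = (
    "dose_only",
    "dose_time_concordant",
    "time_induced_dose_repressed",
)


def _baselines(cfg: SimConfig, gt: pd.DataFrame) -> np.ndarray:
    """Per-gene baseline log2 relative abundance (shared across designs).

    The transcriptome is log-normal (sd 1.25 log2).  Stress-inducible and
    seedling growth-programme genes sit 1.5 log2 units below the genome-wide
    baseline: they are induced from low basal expression, as canonical
    drought markers are, so their induction perturbs the relative abundance
    of the unaffected transcriptome as little as possible.  The planted
    candidate gene is fixed at the genome-wide median abundance (it is a
    well-expressed mesophyll gene, not a rare transcript).
    """
    _, base_ss, _ = _streams(cfg, "rosette")
    rng = np.random.default_rng(base_ss)
    base = rng.normal(loc=0.0, scale=1.25, size=cfg.n_genes)
    low = gt["archetype"].isin(_LOW_BASELINE_ARCHETYPES).to_numpy()
    base[low] = rng.normal(-1.5, 0.8, int(low.sum()))
    horm = (gt["hormone"] != ".").to_numpy()
    base[horm] = rng.normal(0.5, 0.8, int(horm.sum()))
    base[gt["archetype"].to_numpy() == "candidate"] = 0.0
    return base


def _draw_counts(rng, log2rel: np.ndarray, depths: np.ndarray, dispersion: float):
    """Gamma-Poisson counts for one block; genes x nuclei, dense.

    Relative abundances are renormalised within the block, so a nucleus's
    expected total equals its depth: UMI data carry relative, not absolute,
    expression, and planted effects are planted on the measurable scale.
    """
    rel = 2.0 ** (log2rel - log2rel.max())
    mu = rel[:, None] * (depths[None, :] / rel.sum())
    if dispersion > 0:
        mu = mu * rng.gamma(1.0 / dispersion, dispersion, size=mu.shape)
    return rng.poisson(mu)


def _depths(rng, cfg: SimConfig, n: int) -> np.ndarray:
    mu, sigma = cfg.depth_lognormal
    return np.clip(rng.lognormal(mu, sigma, size=n), cfg.umi_min, cfg.umi_max)


class _SparseBuilder:
    """Accumulates per-sample dense blocks into one CSR matrix."""

    def __init__(self, n_genes: int):
        self.n_genes = n_genes
        self.rows, self.cols, self.vals = [], [], []
        self.offset = 0

    def add(self, block: np.ndarray) -> None:
        r, c = np.nonzero(block)
        self.rows.append(r)
        self.cols.append(c + self.offset)
        self.vals.append(block[r, c])
        self.offset += block.shape[1]

    def build(self) -> sp.csr_matrix:
        if not self.rows:
            return sp.csr_matrix((self.n_genes, 0), dtype=np.int64)
        mat = sp.coo_matrix(
            (
                np.concatenate(self.vals).astype(np.int64),
                (np.concatenate(self.rows), np.concatenate(self.cols)),
            ),
            shape=(self.n_genes, self.offset),
        )
        return mat.tocsr()


def _finish(cfg, gt, builder, nucleus_rows, sample_rows):
    nuclei_meta = pd.DataFrame(nucleus_rows)
    table = NucleusTable(
        counts=builder.build(),
        gene_ids=gt["gene_id"].to_numpy(),
        nucleus_ids=nuclei_meta.pop("nucleus_id").to_numpy(),
        nucleus_meta=nuclei_meta,
    )
    samples = SampleTable(pd.DataFrame(sample_rows))
    table.validate_against(samples)
    return table, samples, gt


def simulate_rosette(cfg: SimConfig):
    """Rosette drought time course: 15 stages x 9 days x 2 conditions.

    Per gene and sample the log2 relative expression is::

        base + age_slope * leaf_age_eff + drought_effect * I(drought)

    with ``leaf_age = 23 + day - 2 * stage`` and, for drought-advanced genes
    under drought, ``leaf_age_eff = leaf_age + advancement * (100 - WC)``.
    """
    gt = assign_archetypes(cfg)
    base = _baselines(cfg, gt)
    age_slope = gt["true_age_slope"].to_numpy()
    drought_eff = gt["true_drought_effect"].to_numpy()
    advanced = (gt["archetype"] == "drought_advanced").to_numpy()

    _, _, design_ss = _streams(cfg, "rosette")
    n_samples = cfg.n_stages * cfg.n_days_rosette * 2
    sample_streams = design_ss.spawn(n_samples)
    props = np.asarray(cfg.cell_type_proportions)

    builder = _SparseBuilder(cfg.n_genes)
    nucleus_rows, sample_rows = [], []
    k = 0
    for stage in range(1, cfg.n_stages + 1):
        for day in range(1, cfg.n_days_rosette + 1):
            for condition in ("well_watered", "drought"):
                rng = np.random.default_rng(sample_streams[k])
                k += 1
                sid = f"R_s{stage:02d}_d{day}_{'D' if condition == 'drought' else 'W'}"
                age = 23 + day - 2 * stage
                if condition == "drought":
                    frac = (day - 1) / max(cfg.n_days_rosette - 1, 1)
                    wc = 100.0 - (100.0 - cfg.wc_final) * frac
                else:
                    wc = 100.0
                deficit = 100.0 - wc
                log2rel = base + age_slope * age + advanced * age_slope * (
                    cfg.advancement_days_per_wc * deficit
                )
                if condition == "drought":
                    log2rel = log2rel + drought_eff
                if cfg.biological_sd > 0:
                    log2rel = log2rel + rng.normal(0.0, cfg.biological_sd, cfg.n_genes)
                n_nuc = cfg.nuclei_per_sample
                types = rng.choice(len(CELL_TYPES), size=n_nuc, p=props)
                depths = _depths(rng, cfg, n_nuc)
                builder.add(_draw_counts(rng, log2rel, depths, cfg.nb_dispersion))
                for j in range(n_nuc):
                    nucleus_rows.append(
                        {
                            "nucleus_id": f"{sid}_n{j:04d}",
                            "sample_id": sid,
                            "cell_type": CELL_TYPES[types[j]],
                        }
                    )
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "experiment": "rosette",
                        "leaf_stage": stage,
                        "day": day,
                        "condition": condition,
                        "water_content_pct": wc,
                        "ha_dose": np.nan,
                        "phenotype_area_mm2": np.nan,
                    }
                )
    return _finish(cfg, gt, builder, nucleus_rows, sample_rows)


def simulate_hormone(cfg: SimConfig):
    """Acute hormone treatments: 8 hormones + mock, replicate rosettes.

    Hormone-responsive genes shift their log2 expression by
    ``direction * effect_hormone`` under their assigned treatment, in the
    nuclei of their assigned cell class only; all other genes are flat.
    """
    gt = assign_archetypes(cfg)
    base = _baselines(cfg, gt)
    _, _, design_ss = _streams(cfg, "hormone")
    treatments = list(HORMONES) + ["mock"]
    n_samples = len(treatments) * cfg.hormone_replicates
    sample_streams = design_ss.spawn(n_samples)
    props = np.asarray(cfg.cell_type_proportions)
    class_of = np.array([_CLASS_OF_TYPE[t] for t in CELL_TYPES])

    gt_h = gt["hormone"].to_numpy()
    gt_class = gt["cell_types_affected"].to_numpy()
    gt_dir = gt["hormone_direction"].to_numpy().astype(float)

    builder = _SparseBuilder(cfg.n_genes)
    nucleus_rows, sample_rows = [], []
    k = 0
    for treat in treatments:
        for rep in range(1, cfg.hormone_replicates + 1):
            rng = np.random.default_rng(sample_streams[k])
            k += 1
            sid = f"H_{treat.replace(',', '').replace('-', '')}_r{rep}"
            n_nuc = cfg.nuclei_per_sample
            bio = (
                rng.normal(0.0, cfg.biological_sd, cfg.n_genes)
                if cfg.biological_sd > 0
                else 0.0
            )
            types = rng.choice(len(CELL_TYPES), size=n_nuc, p=props)
            depths = _depths(rng, cfg, n_nuc)
            # expression differs by cell class for the treated samples only
            block = np.empty((cfg.n_genes, n_nuc), dtype=np.int64)
            for cls in CELL_CLASSES:
                in_cls = np.flatnonzero(class_of[types] == cls)
                if in_cls.size == 0:
                    continue
                shift = np.where(
                    (gt_h == treat) & (gt_class == cls), gt_dir * cfg.effect_hormone, 0.0
                )
                block[:, in_cls] = _draw_counts(
                    rng, base + bio + shift, depths[in_cls], cfg.nb_dispersion
                )
            builder.add(block)
            for j in range(n_nuc):
                nucleus_rows.append(
                    {
                        "nucleus_id": f"{sid}_n{j:04d}",
                        "sample_id": sid,
                        "cell_type": CELL_TYPES[types[j]],
                    }
                )
            sample_rows.append(
                {
                    "sample_id": sid,
                    "experiment": "hormone",
                    "leaf_stage": np.nan,
                    "day": 1,
                    "condition": "mock" if treat == "mock" else f"hormone:{treat}",
                    "water_content_pct": np.nan,
                    "ha_dose": np.nan,
                    "phenotype_area_mm2": np.nan,
                }
            )
    return _finish(cfg, gt, builder, nucleus_rows, sample_rows)


def simulate_hard_agar(cfg: SimConfig):
    """HA dose series: 8 doses x 11 days, ~7 shoots per condition.

    Gene log2 expression is ``base + time_slope * day + dose_slope * dose``;
    each shoot's area is ``A0 * exp(g*day) * exp(-k*(dose-1)) * exp(eps)``
    with ``eps ~ N(0, area_noise_sd)``, so development-induced,
    dose-repressed expression is coupled to shoot size by construction
    (decoupled when ``area_dose_decay`` is 0).
    """
    gt = assign_archetypes(cfg)
    base = _baselines(cfg, gt)
    time_slope = gt["true_time_slope"].to_numpy()
    dose_slope = gt["true_dose_slope"].to_numpy()

    _, _, design_ss = _streams(cfg, "hard_agar")
    n_conditions = len(cfg.doses) * cfg.n_days_ha
    n_samples = n_conditions * cfg.shoots_per_condition
    streams = design_ss.spawn(n_conditions + n_samples)
    condition_streams, sample_streams = streams[:n_conditions], streams[n_conditions:]
    props = np.asarray(cfg.cell_type_proportions)

    builder = _SparseBuilder(cfg.n_genes)
    nucleus_rows, sample_rows = [], []
    k = 0
    cond_idx = 0
    for di, dose in enumerate(cfg.doses):
        for day in range(1, cfg.n_days_ha + 1):
            log2rel = base + time_slope * day + dose_slope * dose
            if cfg.biological_sd > 0:
                # shared micro-environment of the condition's plate/day
                cond_rng = np.random.default_rng(condition_streams[cond_idx])
                log2rel = log2rel + cond_rng.normal(0.0, cfg.biological_sd, cfg.n_genes)
            cond_idx += 1
            for shoot in range(1, cfg.shoots_per_condition + 1):
                rng = np.random.default_rng(sample_streams[k])
                k += 1
                sid = f"HA_x{di}_d{day:02d}_s{shoot}"
                area = (
                    cfg.area_baseline_mm2
                    * math.exp(cfg.area_growth_rate * day)
                    * math.exp(-cfg.area_dose_decay * (dose - 1.0))
                    * math.exp(rng.normal(0.0, cfg.area_noise_sd))
                )
                n_nuc = cfg.nuclei_per_sample
                types = rng.choice(len(CELL_TYPES), size=n_nuc, p=props)
                depths = _depths(rng, cfg, n_nuc)
                builder.add(_draw_counts(rng, log2rel, depths, cfg.nb_dispersion))
                for j in range(n_nuc):
                    nucleus_rows.append(
                        {
                            "nucleus_id": f"{sid}_n{j:04d}",
                            "sample_id": sid,
                            "cell_type": CELL_TYPES[types[j]],
                        }
                    )
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "experiment": "hard_agar",
                        "leaf_stage": np.nan,
                        "day": day,
                        "condition": "ha",
                        "water_content_pct": np.nan,
                        "ha_dose": dose,
                        "phenotype_area_mm2": area,
                    }
                )
    return _finish(cfg, gt, builder, nucleus_rows, sample_rows)
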