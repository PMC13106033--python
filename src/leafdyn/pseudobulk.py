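"""Nucleus filtering, pseudobulk aggregation, quantile normalization, z-scores.

A :class:`PseudobulkMatrix` moves through stages ``raw_counts ->
quantile_normalized -> log_qn -> zscored``; each transformation returns a new
object and records the stage so downstream models can assert their input.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io import CELL_CLASSES, NucleusTable, SampleTable

__all__ = [
    "PseudobulkMatrix",
    "filter_nuclei_by_umi",
    "aggregate",
    "filter_low_count_genes",
    "quantile_normalize",
    "log_transform",
    "zscore_genes",
]

log = logging.getLogger(__name__)

_CLASS_OF_TYPE = {t: c for c, members in CELL_CLASSES.items() for t in members}


@dataclasses.dataclass
class PseudobulkMatrix:
    """Gene x (cell type/class, sample) matrix at a declared processing stage."""

    values: np.ndarray
    gene_ids: np.ndarray
    columns: list  # of (cell_type_or_class, sample_id)
    stage: str = "raw_counts"
    library_sizes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError("values shape does not match gene_ids x columns")
        if self.stage == "raw_counts" and self.library_sizes is None:
            self.library_sizes = self.values.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def sample_ids(self) -> list:
        return [s for _, s in self.columns]

    def column_mask(self, predicate: Callable) -> np.ndarray:
        return np.array([bool(predicate(ct, s)) for ct, s in self.columns])

    def select_group(self, group: str) -> "PseudobulkMatrix":
        """Columns whose cell type/class equals ``group``."""
        idx = [i for i, (ct, _) in enumerate(self.columns) if ct == group]
        return PseudobulkMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            columns=[self.columns[i] for i in idx],
            stage=self.stage,
            library_sizes=None if self.library_sizes is None else self.library_sizes[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "PseudobulkMatrix":
        mask = np.asarray(mask)
        return PseudobulkMatrix(
            values=self.values[mask],
            gene_ids=self.gene_ids[mask],
            columns=list(self.columns),
            stage=self.stage,
            library_sizes=self.library_sizes,
        )


def filter_nuclei_by_umi(nuclei: NucleusTable, min_umi: int = 450) -> NucleusTable:
    """Retain nuclei whose recomputed UMI total is at least ``min_umi``.

    The default reproduces the atlas quality threshold of 450 UMI per
    nucleus; order is preserved and an empty result is allowed.
    """
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    keep = nuclei.nucleus_meta["umi_total"].to_numpy() >= min_umi
    return nuclei.subset_nuclei(keep)


def aggregate(
    nuclei: NucleusTable,
    samples: SampleTable,
    level: str = "cell_type",
    sample_key: Optional[Mapping[str, str]] = None,
) -> PseudobulkMatrix:
    """Sum counts into (cell type or cell class, sample) pseudobulk columns.

    Nuclei labelled ``unassigned`` are excluded (their number is logged).
    Columns with zero contributing nuclei are absent rather than zero-filled.
    ``sample_key`` optionally maps sample ids onto pooled column keys (e.g.
    HA shoots onto their (dose, day) condition).
    """
    if level not in ("cell_type", "cell_class"):
        raise ValueError(f"unknown aggregation level {level!r}")
    nuclei.validate_against(samples)
    meta = nuclei.nucleus_meta
    ct = meta["cell_type"].astype(str)
    unassigned = ct == "unassigned"
    if unassigned.any():
        log.info("aggregate: excluding %d unassigned nuclei", int(unassigned.sum()))
    if level == "cell_class":
        group = ct.map(lambda t: _CLASS_OF_TYPE.get(t, "unassigned"))
    else:
        group = ct
    sid = meta["sample_id"].astype(str)
    if sample_key is not None:
        sid = sid.map(lambda s: sample_key.get(s, s))
    keys = list(zip(group, sid))
    keep = ~(group == "unassigned").to_numpy()
    seen: dict = {}
    col_index = np.full(len(keys), -1, dtype=np.int64)
    for i, key in enumerate(keys):
        if not keep[i]:
            continue
        if key not in seen:
            seen[key] = len(seen)
        col_index[i] = seen[key]
    n_cols = len(seen)
    rows = np.flatnonzero(keep)
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, col_index[rows])),
        shape=(len(keys), n_cols),
    )
    values = np.asarray((nuclei.counts @ indicator).todense())
    return PseudobulkMatrix(
        values=values,
        gene_ids=nuclei.gene_ids,
        columns=list(seen),
        stage="raw_counts",
    )


def filter_low_count_genes(
    pb: PseudobulkMatrix, min_total: int = 10, min_samples: int = 3
) -> PseudobulkMatrix:
    """Drop genes with row total < ``min_total`` or nonzero in fewer than
    ``min_samples`` columns.  Defaults are this package's; with both set to
    0 the matrix is returned unchanged (gene subset of all genes)."""
    if pb.stage != "raw_counts":
        raise ValueError("low-count filtering applies to the raw counts stage")
    totals = pb.values.sum(axis=1)
    nonzero = (pb.values > 0).sum(axis=1)
    return pb.subset_genes((totals >= min_total) & (nonzero >= min_samples))


def quantile_normalize(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Classic rank/row-mean quantile normalization across columns.

    Every output column has the identical sorted value multiset (the mean of
    the sorted input columns); ties within a column receive the mean of
    their tied reference values.  Idempotent.
    """
    if pb.stage not in ("raw_counts", "quantile_normalized"):
        raise ValueError("quantile normalization applies to raw counts")
    x = pb.values
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col_sorted = sorted_x[:, j]
        # average the reference over runs of tied values
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col_sorted)]))
        run_means = np.add.reduceat(reference, starts) / (ends - starts)
        assigned = np.repeat(run_means, ends - starts)
        out[order[:, j], j] = assigned
    return PseudobulkMatrix(
        values=out,
        gene_ids=pb.gene_ids,
        columns=list(pb.columns),
        stage="quantile_normalized",
        library_sizes=pb.library_sizes,
    )


def log_transform(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """log2(x + 1); the scale the gene-wise linear models operate on."""
    if pb.stage != "quantile_normalized":
        raise ValueError("log transform applies to the quantile-normalized stage")
    return PseudobulkMatrix(
        values=np.log2(pb.values + 1.0),
        gene_ids=pb.gene_ids,
        columns=list(pb.columns),
        stage="log_qn",
        library_sizes=pb.library_sizes,
    )


def zscore_genes(
    pb: PseudobulkMatrix, subset: Optional[Callable] = None
) -> PseudobulkMatrix:
    """Per-gene standardization (sample SD, n-1) over the selected columns.

    Constant genes map to all-zero rows.  ``subset`` is an optional
    ``(cell_type, sample_id) -> bool`` column predicate.
    """
    if pb.stage not in ("quantile_normalized", "log_qn"):
        raise ValueError("z-scoring applies to a normalized stage")
    if subset is not None:
        idx = np.flatnonzero(pb.column_mask(subset))
    else:
        idx = np.arange(len(pb.columns))
    if len(idx) < 2:
        raise ValueError("z-scoring needs at least 2 selected columns")
    x = pb.values[:, idx]
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return PseudobulkMatrix(
        values=z,
        gene_ids=pb.gene_ids,
        columns=[pb.columns[i] for i in idx],
        stage="zscored",
    )
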