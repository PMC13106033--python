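"""Reading and writing experiment data: sparse counts, metadata and result tables.

On disk an experiment is four text files: a Matrix Market coordinate file with
the gene x nucleus integer counts, two sidecar TSVs annotating the genes and
nuclei in file order, and one TSV of per-sample design covariates.  TSVs are
tab-separated UTF-8 with a header row and ``.`` for missing values.  Per-nucleus
UMI totals are always recomputed from the counts; a stored total is never
trusted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CELL_TYPES",
    "CELL_CLASSES",
    "HORMONES",
    "NucleusTable",
    "SampleTable",
    "ExperimentIOError",
    "ValidationError",
    "read_experiment",
    "write_experiment",
    "read_results",
    "write_results",
]

#: The nine leaf cell types resolved by the atlas.
CELL_TYPES = (
    "mesophyll",
    "epidermis",
    "guard",
    "trichome",
    "phloem",
    "xylem",
    "bundle_sheath",
    "hydathode",
    "myrosin_idioblast",
)

#: Pooled cell classes used when per-type nucleus counts are too sparse.
CELL_CLASSES: Mapping[str, frozenset] = {
    "mesophyll": frozenset({"mesophyll"}),
    "epidermal": frozenset({"epidermis", "guard", "trichome"}),
    "vasculature": frozenset(
        {"phloem", "xylem", "bundle_sheath", "hydathode", "myrosin_idioblast"}
    ),
}

#: Exogenous hormone treatments (plus the mock control).
HORMONES = ("ABA", "MJ", "ACC", "BR", "2,4-D", "SA", "CK", "GA")

_MISSING = "."


class ExperimentIOError(RuntimeError):
    """A file could not be loaded or its declared dimensions disagree."""


class ValidationError(ValueError):
    """Cross-references between tables failed to resolve."""


@dataclasses.dataclass
class NucleusTable:
    """Sparse gene x nucleus counts with per-nucleus metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, nuclei in columns.
    gene_ids, nucleus_ids
        Ordered unique identifiers matching the matrix axes.
    nucleus_meta
        One row per nucleus (file order) with at least ``sample_id`` and
        ``cell_type`` columns.  ``umi_total`` is (re)derived on construction.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    nucleus_ids: np.ndarray
    nucleus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.nucleus_ids)):
            raise ExperimentIOError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.nucleus_ids)} nuclei"
            )
        for name, ids in (("gene", self.gene_ids), ("nucleus", self.nucleus_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} identifiers")
        meta = self.nucleus_meta.reset_index(drop=True).copy()
        meta["umi_total"] = np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)
        self.nucleus_meta = meta

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    def subset_nuclei(self, mask: np.ndarray) -> "NucleusTable":
        """Column subset preserving order; ``mask`` is boolean or index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return NucleusTable(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            nucleus_ids=self.nucleus_ids[idx],
            nucleus_meta=self.nucleus_meta.iloc[idx],
        )

    def validate_against(self, samples: "SampleTable") -> None:
        """Raise :class:`ValidationError` listing unresolvable sample ids."""
        known = set(samples.frame["sample_id"])
        orphans = sorted(set(self.nucleus_meta["sample_id"]) - known)
        if orphans:
            raise ValidationError(
                "nuclei reference unknown sample ids: " + ", ".join(map(str, orphans))
            )


_SAMPLE_COLUMNS = [
    "sample_id",
    "experiment",
    "leaf_stage",
    "day",
    "condition",
    "water_content_pct",
    "ha_dose",
    "phenotype_area_mm2",
]

_EXPERIMENTS = {"rosette", "hormone", "hard_agar"}


@dataclasses.dataclass
class SampleTable:
    """Per-sample design covariates and phenotypes.

    A sample is one barcoded unit: an individual leaf (rosette design), a
    treated rosette (hormone design), or an individual shoot (hard-agar
    design).  Missing covariates are NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        missing = [c for c in ("sample_id", "experiment", "day", "condition") if c not in df]
        if missing:
            raise ValidationError(f"sample table lacks required columns: {missing}")
        for col in _SAMPLE_COLUMNS:
            if col not in df:
                df[col] = np.nan
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = set(df["experiment"]) - _EXPERIMENTS
        if bad:
            raise ValidationError(f"unknown experiment labels: {sorted(bad)}")
        for exp, required in (
            ("rosette", ["leaf_stage", "day", "condition"]),
            ("hard_agar", ["ha_dose", "day"]),
        ):
            sub = df[df["experiment"] == exp]
            for col in required:
                if sub[col].isna().any():
                    raise ValidationError(f"{exp} samples missing required field {col!r}")
        horm = df[df["experiment"] == "hormone"]
        if len(horm):
            allowed = {f"hormone:{h}" for h in HORMONES} | {"mock"}
            bad = set(horm["condition"]) - allowed
            if bad:
                raise ValidationError(f"unknown hormone conditions: {sorted(bad)}")
        self.frame = df[_SAMPLE_COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.frame[np.asarray(mask)])

    def lookup(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Rows for ``sample_ids`` in the given order."""
        indexed = self.frame.set_index("sample_id")
        return indexed.loc[list(sample_ids)].reset_index()


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_MISSING], keep_default_na=True)


def _write_tsv(df: pd.DataFrame, path: Path, float_digits: int = 6) -> None:
    df.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=_MISSING,
        float_format=f"%.{float_digits}g",
    )


def read_experiment(counts_path, genes_path, nuclei_path, samples_path):
    """Load a full experiment from disk and validate cross-references.

    Returns
    -------
    (NucleusTable, SampleTable)
        With per-nucleus UMI totals recomputed from the count matrix.
    """
    counts_path, genes_path = Path(counts_path), Path(genes_path)
    nuclei_path, samples_path = Path(nuclei_path), Path(samples_path)
    for p in (counts_path, genes_path, nuclei_path, samples_path):
        if not p.exists():
            raise ExperimentIOError(f"missing input file: {p}")
    counts = scipy.io.mmread(counts_path)
    genes = _read_tsv(genes_path)
    nuclei = _read_tsv(nuclei_path)
    if counts.shape[0] != len(genes):
        raise ExperimentIOError(
            f"{counts_path} declares {counts.shape[0]} genes but {genes_path} has "
            f"{len(genes)} rows"
        )
    if counts.shape[1] != len(nuclei):
        raise ExperimentIOError(
            f"{counts_path} declares {counts.shape[1]} nuclei but {nuclei_path} has "
            f"{len(nuclei)} rows"
        )
    samples = SampleTable(_read_tsv(samples_path))
    table = NucleusTable(
        counts=sp.csr_matrix(counts, dtype=np.int64),
        gene_ids=genes["gene_id"].to_numpy(),
        nucleus_ids=nuclei["nucleus_id"].to_numpy(),
        nucleus_meta=nuclei.drop(columns=["nucleus_id"]),
    )
    table.validate_against(samples)
    return table, samples


def write_experiment(outdir, nuclei: NucleusTable, samples: SampleTable, prefix="experiment"):
    """Write the four-file on-disk representation; returns the path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}.counts.mtx",
        "genes": outdir / f"{prefix}.genes.tsv",
        "nuclei": outdir / f"{prefix}.nuclei.tsv",
        "samples": outdir / f"{prefix}.samples.tsv",
    }
    scipy.io.mmwrite(paths["counts"], sp.coo_matrix(nuclei.counts), field="integer")
    _write_tsv(pd.DataFrame({"gene_id": nuclei.gene_ids}), paths["genes"])
    meta = nuclei.nucleus_meta.copy()
    meta.insert(0, "nucleus_id", nuclei.nucleus_ids)
    _write_tsv(meta, paths["nuclei"])
    _write_tsv(samples.frame, paths["samples"])
    return paths


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV (6 significant digits for floats).

    An empty table yields a header-only file.  Categorical fields round-trip
    exactly; floats round-trip to the serialized precision.
    """
    _write_tsv(table, Path(path))


def read_results(path) -> pd.DataFrame:
    return _read_tsv(Path(path))
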