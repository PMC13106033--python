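import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from leafdyn.io import NucleusTable, SampleTable


def make_nucleus_table(counts, sample_ids, cell_types, gene_ids=None):
    """Dense counts (genes x nuclei) plus per-nucleus labels -> NucleusTable."""
    counts = np.asarray(counts)
    n_genes, n_nuclei = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    return NucleusTable(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        nucleus_ids=np.array([f"n{i}" for i in range(n_nuclei)], dtype=object),
        nucleus_meta=pd.DataFrame({"sample_id": sample_ids, "cell_type": cell_types}),
    )


def make_sample_table(rows):
    return SampleTable(pd.DataFrame(rows))


def rosette_sample(sample_id, stage=1, day=1, condition="well_watered", wc=100.0):
    return {
        "sample_id": sample_id,
        "experiment": "rosette",
        "leaf_stage": stage,
        "day": day,
        "condition": condition,
        "water_content_pct": wc,
    }


@pytest.fixture(scope="session")
def tiny_rosette():
    """Small but complete rosette simulation shared across tests."""
    from leafdyn.simulate import SimConfig, simulate_rosette

    cfg = SimConfig(seed=11, n_genes=300, nuclei_per_sample=12)
    return cfg, simulate_rosette(cfg)
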