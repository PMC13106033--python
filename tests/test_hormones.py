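import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from leafdyn.hormones import (
    HormoneDEModel,
    directional_overlap_fisher,
    filter_promiscuous,
    lr_test_de,
    summarize_hormone_association,
)
from leafdyn.io import SampleTable
from leafdyn.pseudobulk import PseudobulkMatrix


def _hormone_setup(counts_a, counts_b, hormone="SA", cell_class="mesophyll"):
    """Two-group pseudobulk (genes x columns) with a matching sample table."""
    y = np.column_stack([counts_a, counts_b]).astype(float)
    na, nb = np.asarray(counts_a).shape[1], np.asarray(counts_b).shape[1]
    cols = [(cell_class, f"T{j}") for j in range(na)] + [
        (cell_class, f"M{j}") for j in range(nb)
    ]
    rows = [
        {"sample_id": s, "experiment": "hormone", "day": 1,
         "condition": f"hormone:{hormone}" if s.startswith("T") else "mock"}
        for _, s in cols
    ]
    pb = PseudobulkMatrix(
        values=y, gene_ids=[f"g{i}" for i in range(y.shape[0])], columns=cols,
        stage="raw_counts",
    )
    return pb, SampleTable(pd.DataFrame(rows))


class TestLRTest:
    def test_null_identity_on_duplicated_columns(self):
        col = np.array([[5], [9], [0], [40]])
        a = np.tile(col, (1, 3))
        pb, samples = _hormone_setup(a, a)
        out = lr_test_de(pb, samples, "mesophyll", "SA")
        np.testing.assert_allclose(out.lr_stat, 0, atol=1e-8)
        np.testing.assert_allclose(out.p, 1, atol=1e-8)

    def test_lr_nonnegative_on_random_data(self):
        rng = np.random.default_rng(12)
        pb, samples = _hormone_setup(
            rng.poisson(8, (50, 4)), rng.poisson(8, (50, 4))
        )
        out = lr_test_de(pb, samples, "mesophyll", "SA")
        assert (out.lr_stat >= 0).all()
        assert ((out.p > 0) & (out.p <= 1)).all()

    def test_poisson_limit_matches_deviance_oracle(self):
        """With the dispersion at its floor the LR statistic equals the
        Poisson deviance difference computed from explicit log-likelihoods.

        The 6-column toy repeats each group's count vector, so within-group
        residuals are zero and the moment dispersion is floored for every
        gene; the NB test then reduces exactly to the Poisson LR.
        """
        ca = np.array([12.0, 3.0, 25.0, 7.0, 1.0])
        cb = np.array([5.0, 3.0, 40.0, 2.0, 1.0])
        ya = np.tile(ca[:, None], (1, 3))
        yb = np.tile(cb[:, None], (1, 3))
        pb, samples = _hormone_setup(ya, yb)
        out = lr_test_de(pb, samples, "mesophyll", "SA", moderate_dispersion=False)

        def pois_ll(y, s, m):
            mu = np.maximum(np.outer(m, s), 1e-300)
            return (y * np.log(mu) - mu - special.gammaln(y + 1)).sum(axis=1)

        sa = np.full(3, ca.sum())
        sb = np.full(3, cb.sum())
        ma, mb = ya.sum(1) / sa.sum(), yb.sum(1) / sb.sum()
        m0 = (ya.sum(1) + yb.sum(1)) / (sa.sum() + sb.sum())
        lr_oracle = 2 * (
            pois_ll(ya, sa, ma) + pois_ll(yb, sb, mb)
            - pois_ll(np.column_stack([ya, yb]), np.concatenate([sa, sb]), m0)
        )
        np.testing.assert_allclose(out.lr_stat, np.maximum(lr_oracle, 0), atol=1e-6)
        np.testing.assert_allclose(
            out.p, np.clip(stats.chi2.sf(np.maximum(lr_oracle, 0), 1), 1e-300, 1),
            atol=1e-6,
        )

    def test_group_size_and_direction(self):
        rng = np.random.default_rng(14)
        ya = rng.poisson(40, (10, 4))
        yb = rng.poisson(5, (10, 4))
        ya[0], yb[0] = 5, 40  # one gene flipped
        pb, samples = _hormone_setup(ya, yb)
        out = lr_test_de(pb, samples, "mesophyll", "SA")
        assert out.direction[0] == "down"
        assert (out.direction[1:] == "up").all()
        with pytest.raises(ValueError, match=">= 2"):
            lr_test_de(*_hormone_setup(ya[:, :1], yb), "mesophyll", "SA")

    def test_all_zero_gene_skipped(self):
        ya = np.array([[0, 0, 0], [3, 6, 2]])
        yb = np.array([[0, 0, 0], [4, 4, 4]])
        pb, samples = _hormone_setup(ya, yb)
        out = lr_test_de(pb, samples, "mesophyll", "SA")
        assert out.p[0] == 1.0 and out.lr_stat[0] == 0.0 and out.direction[0] == "none"


class TestPromiscuityFilter:
    def frame(self, records):
        return pd.DataFrame(
            [
                {"gene_id": g, "cell_class": c, "hormone": h, "de": de}
                for g, c, h, de in records
            ]
        )

    def test_three_or_more_hormones_removed(self):
        de = self.frame(
            [("g1", "mesophyll", h, True) for h in ("SA", "ABA", "MJ")]
            + [("g2", "mesophyll", h, True) for h in ("SA", "ABA")]
        )
        out = filter_promiscuous(de)
        assert "g1" not in set(out.gene_id)
        assert (out.gene_id == "g2").sum() == 2

    def test_removal_is_per_cell_class(self):
        de = self.frame(
            [("g1", "mesophyll", h, True) for h in ("SA", "ABA", "MJ")]
            + [("g1", "epidermal", "SA", True)]
        )
        out = filter_promiscuous(de)
        assert set(out.cell_class) == {"epidermal"}

    def test_empty_input(self):
        assert filter_promiscuous(self.frame([])).empty


class TestFisherOverlap:
    def test_small_table_enumeration(self):
        # a=2, b=0, c=0, d=2: enrichment tail = C(2,2)C(2,0)/C(4,2) = 1/6
        bg = {"a", "b", "c", "d"}
        res = directional_overlap_fisher({"a", "b"}, {"a", "b"}, bg)
        assert res.table == (2, 0, 0, 2)
        assert res.fisher_p == pytest.approx(1 / 6, abs=1e-12)

    def test_no_overlap_large_background(self):
        bg = {f"g{i}" for i in range(1000)}
        res = directional_overlap_fisher({"g1", "g2"}, {"g10", "g11"}, bg)
        assert res.fisher_p > 0.9 and not res.retained

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(15)
        bg = {f"g{i}" for i in range(60)}
        a = set(rng.choice(sorted(bg), 12, replace=False))
        b = set(rng.choice(sorted(bg), 20, replace=False))
        p1 = directional_overlap_fisher(a, b, bg).fisher_p
        p2 = directional_overlap_fisher(b, a, bg).fisher_p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_background_containment_enforced(self):
        with pytest.raises(ValueError):
            directional_overlap_fisher({"x"}, {"a"}, {"a", "b"})


class TestSummary:
    def make(self, hormone, cls, genes, retained=True):
        from leafdyn.hormones import OverlapResult

        return OverlapResult(hormone, cls, "ageing_up", set(genes), (len(genes), 0, 0, 0),
                             0.01, retained)

    def test_fractions(self):
        ovs = [
            self.make("SA", "mesophyll", ["g1", "g2", "g3"]),
            self.make("SA", "vasculature", ["g4"]),
            self.make("CK", "mesophyll", ["g5"], retained=False),
        ]
        out = summarize_hormone_association(ovs)
        sa = out[out.hormone == "SA"].set_index("cell_class")
        assert sa.loc["mesophyll", "fraction"] == pytest.approx(0.75)
        assert sa.loc["vasculature", "fraction"] == pytest.approx(0.25)
        assert "CK" not in set(out.hormone)
        assert out.groupby("hormone")["fraction"].sum().sub(1).abs().max() < 1e-12

    def test_empty(self):
        assert summarize_hormone_association([]).empty


def test_model_over_simulated_experiment():
    from leafdyn.pseudobulk import aggregate, filter_nuclei_by_umi
    from leafdyn.simulate import SimConfig, simulate_hormone

    cfg = SimConfig(seed=17, n_genes=250, nuclei_per_sample=25, hormone_replicates=3)
    nuclei, samples, gt = simulate_hormone(cfg)
    pb = aggregate(filter_nuclei_by_umi(nuclei), samples, level="cell_class")
    res = HormoneDEModel(pb, samples).fit(hormones=("SA", "CK"))
    assert set(res.de.cell_class) == {"mesophyll", "epidermal", "vasculature"}
    assert set(res.de.hormone) == {"SA", "CK"}
    bg = res.background("mesophyll")
    assert bg and bg <= set(pb.gene_ids)
    assert "Hormone DE" in res.summary()
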