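import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from leafdyn.ageing import (
    AgeingModel,
    adjust_pvalues_bh,
    check_collinearity,
    classify_ageing_genes,
    compute_leaf_age,
    fit_age_drought_model,
    fit_quadratic_trend,
)
from leafdyn._ols import CovariateError, genewise_ols
from leafdyn.pipeline import prepare_celltype_matrix
from leafdyn.pseudobulk import PseudobulkMatrix
from leafdyn.io import SampleTable

from conftest import rosette_sample


class TestLeafAge:
    @pytest.mark.parametrize(
        "stage,day,expected", [(1, 1, 22), (12, 1, 0), (15, 9, 2), (8, 5, 12)]
    )
    def test_formula(self, stage, day, expected):
        assert compute_leaf_age(stage, day) == expected

    def test_vectorized(self):
        np.testing.assert_array_equal(
            compute_leaf_age([1, 15], [1, 9]), [22, 2]
        )

    def test_stage_range_enforced(self):
        with pytest.raises(ValueError):
            compute_leaf_age(0, 1)
        with pytest.raises(ValueError):
            compute_leaf_age(16, 1)


class TestCollinearity:
    def test_orthogonal_design_unit_vif(self):
        design = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        diag = check_collinearity(design)
        assert diag["vif"]["a"] == pytest.approx(1.0)
        assert diag["vif"]["b"] == pytest.approx(1.0)
        assert diag["flagged"] == []

    def test_duplicated_covariate_infinite_vif(self):
        x = np.arange(6.0)
        diag = check_collinearity(pd.DataFrame({"a": x, "b": x}))
        assert diag["vif"]["a"] == np.inf
        assert "a" in diag["flagged"] and "b" in diag["flagged"]

    def test_constant_covariate_infinite_vif(self):
        diag = check_collinearity(pd.DataFrame({"a": [1.0] * 5, "b": np.arange(5.0)}))
        assert diag["vif"]["a"] == np.inf

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        design = pd.DataFrame(
            {"a": x, "b": 0.8 * x + rng.normal(size=30), "c": rng.normal(size=30)}
        )
        diag = check_collinearity(design)
        for j, name in enumerate(design.columns):
            y = design[name].to_numpy()
            others = np.column_stack(
                [np.ones(30), design.drop(columns=[name]).to_numpy()]
            )
            beta, *_ = np.linalg.lstsq(others, y, rcond=None)
            r2 = 1 - ((y - others @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert diag["vif"][name] == pytest.approx(1 / (1 - r2), rel=1e-10)


class TestBH:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            adjust_pvalues_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_tied(self):
        assert adjust_pvalues_bh([0.2]).tolist() == [0.2]
        np.testing.assert_allclose(adjust_pvalues_bh([0.4, 0.4, 0.4]), [0.4] * 3)

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [np.nan]):
            with pytest.raises(ValueError):
                adjust_pvalues_bh(bad)

    def test_matches_stepup_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 12))
            got = adjust_pvalues_bh(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj, 1)
            np.testing.assert_allclose(got, expected, atol=1e-12)


def _rosette_pb(Y, ages_stage_day, droughts):
    """Build a log_qn-stage pseudobulk and matching sample table."""
    rows, cols = [], []
    for j, ((stage, day), dr) in enumerate(zip(ages_stage_day, droughts)):
        sid = f"S{j}"
        cols.append(("mesophyll", sid))
        rows.append(
            rosette_sample(sid, stage=stage, day=day,
                           condition="drought" if dr else "well_watered")
        )
    pb = PseudobulkMatrix(
        values=np.asarray(Y, float),
        gene_ids=[f"g{i}" for i in range(np.asarray(Y).shape[0])],
        columns=cols,
        stage="log_qn",
    )
    return pb, SampleTable(pd.DataFrame(rows))


class TestAgeDroughtModel:
    def design(self):
        rng = np.random.default_rng(9)
        stages = rng.integers(1, 16, 20)
        days = rng.integers(1, 10, 20)
        droughts = np.tile([0, 1], 10)
        return stages, days, droughts

    def test_exact_linear_fit(self):
        stages, days, droughts = self.design()
        age = compute_leaf_age(stages, days)
        Y = (2.0 * age)[None, :]
        pb, samples = _rosette_pb(Y, list(zip(stages, days)), droughts)
        fits = fit_age_drought_model(pb, samples, "mesophyll")
        assert fits.coef_age[0] == pytest.approx(2.0, abs=1e-10)
        assert fits.coef_drought[0] == pytest.approx(0.0, abs=1e-10)

    def test_constant_gene_null_result(self):
        stages, days, droughts = self.design()
        Y = np.full((1, 20), 5.0)
        pb, samples = _rosette_pb(Y, list(zip(stages, days)), droughts)
        fits = fit_age_drought_model(pb, samples, "mesophyll")
        assert fits.coef_age[0] == 0.0 and fits.p_age[0] == 1.0

    def test_matches_normal_equations_oracle(self):
        stages, days, droughts = self.design()
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(30, 20))
        pb, samples = _rosette_pb(Y, list(zip(stages, days)), droughts)
        fits = fit_age_drought_model(pb, samples, "mesophyll")
        age = compute_leaf_age(stages, days).astype(float)
        X = np.column_stack([np.ones(20), age, droughts.astype(float)])
        xtx_inv = np.linalg.inv(X.T @ X)
        for i in range(30):
            beta = xtx_inv @ X.T @ Y[i]
            resid = Y[i] - X @ beta
            s2 = (resid**2).sum() / (20 - 3)
            se = np.sqrt(np.diag(xtx_inv) * s2)
            t = beta / se
            p = 2 * stats.t.sf(np.abs(t), 17)
            assert fits.coef_age[i] == pytest.approx(beta[1], abs=1e-8)
            assert fits.se_age[i] == pytest.approx(se[1], abs=1e-8)
            assert fits.p_age[i] == pytest.approx(p[1], abs=1e-8)
            assert fits.p_drought[i] == pytest.approx(p[2], abs=1e-8)

    def test_constant_covariate_raises_named_error(self):
        stages, days, _ = self.design()
        Y = np.ones((2, 20))
        pb, samples = _rosette_pb(Y, list(zip(stages, days)), np.zeros(20, int))
        with pytest.raises(CovariateError, match="drought"):
            fit_age_drought_model(pb, samples, "mesophyll")


class TestClassification:
    def fits(self, coef_age, padj_age, coef_drought=0.0, padj_drought=1.0):
        return pd.DataFrame(
            {
                "gene_id": ["g0"], "cell_type": ["mesophyll"],
                "coef_age": [coef_age], "padj_age": [padj_age],
                "coef_drought": [coef_drought], "padj_drought": [padj_drought],
            }
        )

    @pytest.mark.parametrize(
        "coef,padj,expected",
        [
            (0.05, 0.005, "induced"),
            (0.04, 0.001, "none"),     # strict > on the coefficient
            (-0.05, 0.005, "repressed"),
            (-0.04, 0.001, "none"),
            (0.05, 0.01, "none"),      # strict < on adjusted p
        ],
    )
    def test_threshold_rules(self, coef, padj, expected):
        out = classify_ageing_genes(self.fits(coef, padj))
        assert out.ageing[0] == expected

    def test_drought_direction(self):
        out = classify_ageing_genes(self.fits(0, 1, coef_drought=-0.3, padj_drought=0.002))
        assert bool(out.drought_responsive[0]) and out.drought_direction[0] == "down"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        coef=st.floats(-1, 1), padj=st.floats(1e-6, 1),
        dcoef=st.floats(0, 0.5), dpadj=st.floats(0, 0.5),
    )
    def test_monotone_in_evidence(self, coef, padj, dcoef, dpadj):
        """Strengthening evidence (larger |coef|, smaller padj) never flips
        a classified gene back to 'none'."""
        base = classify_ageing_genes(self.fits(coef, padj)).ageing[0]
        stronger = classify_ageing_genes(
            self.fits(coef + np.sign(coef) * dcoef, max(padj - dpadj, 1e-9))
        ).ageing[0]
        if base != "none":
            assert stronger == base


class TestQuadraticTrend:
    def test_exact_parabola(self):
        a = np.array([0.0, 1, 2, 3, 4])
        y = 1 + 2 * a - a**2
        tr = fit_quadratic_trend(a, y)
        np.testing.assert_allclose(tr.coefficients, [1, 2, -1], atol=1e-10)
        np.testing.assert_allclose(tr.predict(a), y, atol=1e-10)
        assert tr.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_constant_data(self):
        tr = fit_quadratic_trend([0, 1, 2, 3], [7.0] * 4)
        np.testing.assert_allclose(tr.coefficients, [7, 0, 0], atol=1e-10)

    def test_matches_polyfit_oracle_with_ci(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 30, 25)
        y = rng.normal(size=25)
        tr = fit_quadratic_trend(a, y, ci_level=0.99)
        X = np.column_stack([np.ones(25), a, a**2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(tr.coefficients, beta, atol=1e-8)
        resid = y - X @ beta
        s2 = (resid**2).sum() / 22
        cov = s2 * np.linalg.inv(X.T @ X)
        grid = np.linspace(0, 30, 7)
        Xg = np.column_stack([np.ones(7), grid, grid**2])
        half = stats.t.ppf(0.995, 22) * np.sqrt(np.diag(Xg @ cov @ Xg.T))
        np.testing.assert_allclose(tr.ci_halfwidth(grid), half, atol=1e-8)
        assert (tr.ci_halfwidth(grid) >= 0).all()

    def test_insufficient_distinct_ages(self):
        with pytest.raises(ValueError):
            fit_quadratic_trend([1, 1, 2, 2], [0, 1, 2, 3])


def test_model_results_surface(tiny_rosette):
    cfg, (nuclei, samples, gt) = tiny_rosette
    pb = prepare_celltype_matrix(nuclei, samples, "mesophyll")
    model = AgeingModel(pb, samples, "mesophyll")
    diag = model.diagnostics()
    assert set(diag["vif"]) == {"leaf_stage", "day", "drought"}
    res = model.fit()
    assert (res.table.padj_age >= res.table.p_age - 1e-15).all()
    assert set(res.gene_sets()) == {"ageing_up", "ageing_down", "drought_up", "drought_down"}
    text = res.summary()
    assert "mesophyll" in text and "ageing-induced" in text
    gene = res.table.gene_id.iloc[0]
    tr = res.trend(gene, ci_level=0.95)
    assert tr.coefficients.shape == (3,)
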