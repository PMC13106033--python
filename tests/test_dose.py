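import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leafdyn.dose import (
    DoseResponseModel,
    build_condition_grid,
    class_mean_trajectory,
    classify_trend,
    condition_key,
    correlate_with_shoot_area,
    fit_time_dose_model,
)
from leafdyn.io import SampleTable
from leafdyn.pseudobulk import PseudobulkMatrix

DOSES = (1.0, 1.33, 1.67, 2.0, 2.33, 2.67, 3.0, 3.33)


def _ha_samples(doses=DOSES, days=range(1, 12), area=None):
    rows = []
    for do in doses:
        for da in days:
            rows.append(
                {
                    "sample_id": condition_key(do, da),
                    "experiment": "hard_agar",
                    "day": da,
                    "condition": "ha",
                    "ha_dose": do,
                    "phenotype_area_mm2": area(do, da) if area else 30.0 * da,
                }
            )
    return SampleTable(pd.DataFrame(rows))


def _ha_pb(Y, samples):
    cols = [("mesophyll", s) for s in samples.frame.sample_id]
    return PseudobulkMatrix(
        values=np.asarray(Y, float),
        gene_ids=[f"g{i}" for i in range(np.asarray(Y).shape[0])],
        columns=cols,
        stage="log_qn",
    )


def _design(samples):
    d = samples.frame
    return d.day.to_numpy(float), d.ha_dose.to_numpy(float)


class TestGrid:
    def test_default_is_88_conditions(self):
        grid = build_condition_grid(_ha_samples())
        assert grid.n_conditions == 88
        assert len(grid.doses) == 8 and len(grid.days) == 11

    def test_single_condition(self):
        grid = build_condition_grid(_ha_samples(doses=(1.0,), days=[1]))
        assert grid.n_conditions == 1

    def test_missing_cell_raises_unless_allowed(self):
        samples = _ha_samples()
        frame = samples.frame[
            ~((samples.frame.ha_dose == 2.0) & (samples.frame.day == 5))
        ]
        with pytest.raises(ValueError, match="incomplete"):
            build_condition_grid(SampleTable(frame))
        grid = build_condition_grid(SampleTable(frame), allow_incomplete=True)
        assert grid.n_conditions == 87


class TestTwoFactorFit:
    def test_exact_time_effect(self):
        samples = _ha_samples()
        day, dose = _design(samples)
        fits = fit_time_dose_model(_ha_pb((3.0 * day)[None, :], samples), samples, "mesophyll")
        assert fits.coef_time[0] == pytest.approx(3.0, abs=1e-10)
        assert fits.coef_dose[0] == pytest.approx(0.0, abs=1e-10)

    def test_exact_dose_effect(self):
        samples = _ha_samples()
        day, dose = _design(samples)
        fits = fit_time_dose_model(_ha_pb((-1.0 * dose)[None, :], samples), samples, "mesophyll")
        assert fits.coef_dose[0] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        samples = _ha_samples()
        day, dose = _design(samples)
        rng = np.random.default_rng(20)
        Y = rng.normal(size=(25, 88))
        fits = fit_time_dose_model(_ha_pb(Y, samples), samples, "mesophyll")
        X = np.column_stack([np.ones(88), day, dose])
        xtx_inv = np.linalg.inv(X.T @ X)
        for i in range(25):
            beta = xtx_inv @ X.T @ Y[i]
            resid = Y[i] - X @ beta
            se = np.sqrt(np.diag(xtx_inv) * (resid**2).sum() / 85)
            p = 2 * stats.t.sf(np.abs(beta / se), 85)
            assert fits.coef_time[i] == pytest.approx(beta[1], abs=1e-8)
            assert fits.coef_dose[i] == pytest.approx(beta[2], abs=1e-8)
            assert fits.p_time[i] == pytest.approx(p[1], abs=1e-8)
            assert fits.p_dose[i] == pytest.approx(p[2], abs=1e-8)


class TestClassification:
    def fits(self, pt, ct, pd_, cd):
        return pd.DataFrame(
            {
                "gene_id": ["g0"], "cell_type": ["mesophyll"],
                "padj_time": [pt], "coef_time": [ct],
                "padj_dose": [pd_], "coef_dose": [cd],
            }
        )

    @pytest.mark.parametrize(
        "pt,ct,pdose,cd,expected",
        [
            (0.5, 1.0, 0.005, 1.2, "dose_induced_time_flat"),
            (0.001, 0.8, 0.001, 0.5, "dose_and_time_induced"),
            (0.001, 0.8, 0.001, -0.5, "time_induced_dose_repressed"),
            (0.5, 0.1, 0.5, 0.1, "none"),
            (0.001, -0.8, 0.001, -0.5, "other"),  # time-repressed pattern
            (0.001, 0.8, 0.5, -0.5, "other"),     # time only
        ],
    )
    def test_rules(self, pt, ct, pdose, cd, expected):
        out = classify_trend(self.fits(pt, ct, pdose, cd))
        assert out.trend_class[0] == expected

    def test_affine_dose_rescaling_invariance(self):
        samples = _ha_samples()
        day, dose = _design(samples)
        rng = np.random.default_rng(21)
        Y = (
            0.2 * day + rng.choice([-0.5, 0.5], 30)[:, None] * dose
            + 0.3 * rng.normal(size=(30, 88))
        )
        fits1 = fit_time_dose_model(_ha_pb(Y, samples), samples, "mesophyll")
        frame2 = samples.frame.copy()
        frame2["ha_dose"] = 2.5 * frame2["ha_dose"] + 1.0
        samples2 = SampleTable(frame2)
        pb2 = PseudobulkMatrix(
            values=Y, gene_ids=fits1.gene_id.tolist(),
            columns=[("mesophyll", s) for s in frame2.sample_id], stage="log_qn",
        )
        fits2 = fit_time_dose_model(pb2, samples2, "mesophyll")
        c1 = classify_trend(fits1).trend_class
        c2 = classify_trend(fits2).trend_class
        assert (c1 == c2).all()


class TestTrajectory:
    def classes(self, mapping):
        return pd.DataFrame(
            {
                "gene_id": list(mapping),
                "cell_type": "mesophyll",
                "trend_class": list(mapping.values()),
            }
        )

    def zpb(self, Y):
        samples = _ha_samples()
        pb = _ha_pb(Y, samples)
        pb.stage = "zscored"
        return pb

    def test_single_gene_identity(self):
        Y = np.random.default_rng(22).normal(size=(3, 88))
        z = self.zpb(Y)
        traj = class_mean_trajectory(z, self.classes({"g0": "dose_induced_time_flat",
                                                      "g1": "none", "g2": "none"}),
                                     "dose_induced_time_flat")
        np.testing.assert_allclose(traj.to_numpy(), Y[0])

    def test_opposite_rows_cancel(self):
        v = np.random.default_rng(23).normal(size=88)
        z = self.zpb(np.vstack([v, -v]))
        traj = class_mean_trajectory(
            z, self.classes({"g0": "other", "g1": "other"}), "other"
        )
        np.testing.assert_allclose(traj.to_numpy(), 0, atol=1e-12)

    def test_empty_class_returns_none(self):
        z = self.zpb(np.zeros((1, 88)))
        assert class_mean_trajectory(z, self.classes({"g0": "none"}), "other") is None


class TestCorrelation:
    def test_proportional_and_antiproportional(self):
        area = np.linspace(10, 100, 20)
        assert correlate_with_shoot_area(3 * area, area)[0] == pytest.approx(1.0)
        assert correlate_with_shoot_area(-area, area)[0] == pytest.approx(-1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(24)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = correlate_with_shoot_area(x, y + 5)
        xm, ym = x - x.mean(), (y + 5) - (y + 5).mean()
        r_o = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        t = r_o * np.sqrt(28 / (1 - r_o**2))
        p_o = 2 * stats.t.sf(abs(t), 28)
        assert r == pytest.approx(r_o, abs=1e-12)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            correlate_with_shoot_area([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate_with_shoot_area([1.0, 2.0], [1.0, 2.0])


def test_model_results_surface():
    from leafdyn.pipeline import prepare_celltype_matrix
    from leafdyn.simulate import SimConfig, simulate_hard_agar

    cfg = SimConfig(seed=25, n_genes=250, nuclei_per_sample=8, shoots_per_condition=2)
    nuclei, samples, gt = simulate_hard_agar(cfg)
    key = {
        r["sample_id"]: condition_key(r["ha_dose"], r["day"])
        for _, r in samples.frame.iterrows()
    }
    pb = prepare_celltype_matrix(nuclei, samples, "mesophyll", sample_key=key)
    res = DoseResponseModel(pb, samples, "mesophyll").fit()
    assert res.model.grid.n_conditions == 88
    from leafdyn.pseudobulk import zscore_genes

    zpb = zscore_genes(pb)
    corr = res.area_correlations(zpb)
    assert set(corr.columns) >= {"trend_class", "pearson_r", "pearson_p"}
    assert "Dose-response model" in res.summary()
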