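import numpy as np
import pandas as pd
import pytest

from conftest import make_model_data
from rivertrends import glmm, records, simulate
from rivertrends.errors import DesignError, FitError, UsageError
from _oracles import exact_marginal_loglik_grouped_intercept


def agg_frame(n_sites=3, years=(2002, 2003), counts=5):
    rows = []
    for s in range(n_sites):
        for y in years:
            rows.append({"site_id": f"s{s}", "year": y, "count": counts})
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_national_design_columns(self):
        data = glmm.build_design(agg_frame())
        assert data.X.shape == (6, 2)
        assert data.fixed_names == ["(Intercept)", "year"]

    def test_year_coding_2019_is_17(self):
        data = glmm.build_design(agg_frame(years=(2002, 2019)))
        assert set(data.t) == {0.0, 17.0}

    def test_pre_study_year_rejected(self):
        with pytest.raises(DesignError):
            glmm.build_design(agg_frame(years=(1999, 2003)))

    def test_interaction_design_with_six_classes(self):
        rows = []
        for i, cls in enumerate(
            ["Calcareous/High", "Calcareous/Low", "Organic/High",
             "Organic/Low", "Siliceous/High", "Siliceous/Low"]
        ):
            for y in (2002, 2003):
                rows.append({"site_id": f"s{i}", "year": y, "count": 2})
        agg = pd.DataFrame(rows)
        tmap = {f"s{i}": cls for i, cls in enumerate(
            ["Calcareous/High", "Calcareous/Low", "Organic/High",
             "Organic/Low", "Siliceous/High", "Siliceous/Low"])}
        data = glmm.build_design(agg, typology_map=tmap, interaction=True)
        assert data.X.shape[1] == 12  # intercept, year, 5 mains, 5 interactions
        assert data.reference_class == "Calcareous/High"

    def test_unclassified_site_listed(self):
        tmap = {"s0": "Calcareous/High", "s1": "excluded", "s2": "Calcareous/Low"}
        with pytest.raises(DesignError, match="s1"):
            glmm.build_design(agg_frame(), typology_map=tmap, interaction=True)


class TestLaplaceAgainstQuadrature:
    """Laplace marginal log-likelihood vs adaptive numerical integration."""

    @pytest.mark.parametrize(
        "y,sd,b0",
        [
            ([3, 7, 1, 0, 5], 0.5, 1.0),
            ([10, 2, 4, 8, 0, 1, 3, 6], 0.8, 1.2),
            ([0, 0, 2, 1], 1.2, 0.3),
            ([15, 22, 9, 14, 30, 11], 0.3, 2.5),
            ([1, 4, 2, 7, 3, 5, 8], 1.0, 0.9),
        ],
    )
    def test_olre_only_fixtures(self, y, sd, b0):
        y = np.array(y, float)
        n = len(y)
        data = make_model_data(y, np.arange(n) % 3, np.zeros(n, int))
        structure = glmm.RandomStructure(
            site_intercept=False, site_slope=False, year=False, olre=True
        )
        ll = glmm.laplace_loglik(
            data, structure, glmm.VarianceComponents(sd_olre=sd), np.array([b0])
        )
        exact = exact_marginal_loglik_grouped_intercept(
            y, np.full(n, b0), np.arange(n), sd
        )
        assert abs(ll - exact) <= 0.5

    def test_shared_site_intercept_fixture(self):
        y = np.array([4, 6, 3, 5, 9, 7], float)
        s = np.array([0, 0, 0, 1, 1, 1])
        data = make_model_data(y, np.array([0, 1, 2, 0, 1, 2]), s)
        structure = glmm.RandomStructure(
            site_intercept=True, site_slope=False, site_correlation=False,
            year=False, olre=False,
        )
        ll = glmm.laplace_loglik(
            data, structure, glmm.VarianceComponents(sd_site_intercept=0.7),
            np.array([1.5]),
        )
        exact = exact_marginal_loglik_grouped_intercept(y, np.full(6, 1.5), s, 0.7)
        assert abs(ll - exact) <= 0.5


class TestFit:
    def simulated_fit(self, beta1, seed, n_sites=60, **sim_kwargs):
        spec = (
            simulate.GroupSpec(
                "Ephemeroptera", (("Baetis", "Baetidae"),), 3.0, beta1, "herbivore"
            ),
        )
        defaults = dict(
            n_sites=n_sites, taxa_spec=spec, sd_site_intercept=0.5,
            sd_site_slope=0.03, sd_year=0.05, sd_olre=0.5,
            p_season_sampled=1.0, seed=seed,
        )
        defaults.update(sim_kwargs)
        cfg = simulate.SimulationConfig(**defaults)
        sites = simulate.generate_sites(cfg)
        recs, _ = simulate.generate_survey(sites, cfg)
        agg, _ = records.aggregate_counts(
            recs, "group", taxonomy=simulate.taxonomy_table(cfg.taxa_spec)
        )
        return glmm.build_design(agg), sites

    def test_null_slope_within_two_se(self):
        data, _ = self.simulated_fit(0.0, seed=101)
        fit = glmm.fit_poisson_glmm(data)
        assert abs(fit.beta["year"]) < 2.0 * fit.se["year"]
        assert fit.n_params == 2 + 5
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(fit.n_obs)
        )
        assert ((fit.pvalues >= 0) & (fit.pvalues <= 1)).all()
        vc = fit.vc
        assert min(vc.sd_site_intercept, vc.sd_site_slope, vc.sd_year, vc.sd_olre) >= 0

    def test_all_zero_counts_rejected(self):
        data = make_model_data(np.zeros(10), np.arange(10) % 5, np.arange(10) % 2)
        with pytest.raises(FitError):
            glmm.fit_poisson_glmm(data)

    def test_single_year_rejected(self):
        data = make_model_data(np.ones(6), np.zeros(6), np.arange(6) % 3)
        with pytest.raises(FitError):
            glmm.fit_poisson_glmm(data)


class TestDerivedQuantities:
    def test_flat_predictions(self):
        fit = _fit_stub(beta0=0.0, beta1=0.0)
        yhat = glmm.predict_year_means(fit, np.arange(18))
        assert np.allclose(yhat, 1.0)

    def test_doubling_slope_prediction_ratio(self):
        fit = _fit_stub(beta0=1.0, beta1=np.log(2) / 17.0)
        yhat = glmm.predict_year_means(fit, np.arange(18))
        assert yhat[-1] / yhat[0] == pytest.approx(2.0)

    def test_slope_change_identity(self):
        # Population-level Psi equals 100*(exp(17*b1)-1) to 1e-9.
        for b1 in (-0.043, -0.014, 0.0, 0.008, 0.052):
            fit = _fit_stub(beta0=2.0, beta1=b1)
            yhat = glmm.predict_year_means(fit, np.arange(18))
            psi = glmm.total_change(yhat)
            assert psi == pytest.approx(100 * (np.exp(17 * b1) - 1), abs=1e-9)

    def test_printed_slope_implies_printed_change(self):
        fit = _fit_stub(beta0=-1.218, beta1=0.052)
        yhat = glmm.predict_year_means(fit, np.arange(18))
        assert glmm.total_change(yhat) == pytest.approx(142.1, abs=1.0)

    def test_total_change_arithmetic(self):
        assert glmm.total_change([100.0, 119.0]) == pytest.approx(19.0)
        assert glmm.total_change([50.0, 50.0]) == 0.0
        assert glmm.total_change([100.0, 48.2]) == pytest.approx(-51.8)
        with pytest.raises(UsageError):
            glmm.total_change([0.0, 5.0])

    def test_annual_growth_rate(self):
        assert round(glmm.annual_growth_rate(142.1), 2) == 7.89
        assert glmm.annual_growth_rate(0.0) == 0.0
        assert round(glmm.annual_growth_rate(-21.7), 2) == -1.21
        with pytest.raises(UsageError):
            glmm.annual_growth_rate(10.0, 0)

    def test_round_trip_with_divisor(self):
        psi = 37.3
        assert glmm.annual_growth_rate(psi, 18) * 18 == psi


class TestCompareModels:
    def test_identical_models_give_zero(self):
        fit = _fit_stub(beta0=1.0, beta1=0.01, loglik=-100.0, n_params=5)
        cmp = glmm.compare_models(fit, fit)
        assert cmp.lrt == 0.0 and cmp.delta_aic == 0.0 and cmp.df == 0

    def test_aic_definition(self):
        fit = _fit_stub(beta0=1.0, beta1=0.0, loglik=-100.0, n_params=5)
        assert fit.aic == pytest.approx(210.0)

    def test_non_nested_rejected(self):
        a = _fit_stub(beta0=1.0, beta1=0.0, n_obs=50)
        b = _fit_stub(beta0=1.0, beta1=0.0, n_obs=60)
        with pytest.raises(UsageError):
            glmm.compare_models(a, b)


class TestTypologySlopes:
    def test_delta_method_on_covariance_fixture(self):
        cov = np.array(
            [
                [0.04, 0.0, 0.0, -0.01],
                [0.0, 0.01, 0.0, -0.004],
                [0.0, 0.0, 0.09, 0.0],
                [-0.01, -0.004, 0.0, 0.02],
            ]
        )
        fit = _fit_stub(
            beta0=1.0,
            beta1=0.02,
            extra={"typology[Siliceous/Low]": 0.3, "year:typology[Siliceous/Low]": -0.05},
            cov=cov,
            classes=["Calcareous/High", "Siliceous/Low"],
        )
        out = glmm.typology_slopes(fit)
        ref = out[out["typology"] == "Calcareous/High"].iloc[0]
        other = out[out["typology"] == "Siliceous/Low"].iloc[0]
        assert ref["slope"] == pytest.approx(0.02)
        assert ref["se"] == pytest.approx(0.1)
        assert other["slope"] == pytest.approx(-0.03)
        # var(a+b) = var(a) + var(b) + 2 cov(a, b)
        assert other["se"] == pytest.approx(np.sqrt(0.01 + 0.02 + 2 * (-0.004)))

    def test_zero_interactions_collapse_to_common_slope(self):
        cov = np.eye(4) * 0.01
        fit = _fit_stub(
            beta0=1.0,
            beta1=0.015,
            extra={"typology[Organic/Low]": 0.0, "year:typology[Organic/Low]": 0.0},
            cov=cov,
            classes=["Calcareous/High", "Organic/Low"],
        )
        out = glmm.typology_slopes(fit)
        assert np.allclose(out["slope"], 0.015)


def _fit_stub(
    beta0, beta1, *, loglik=-10.0, n_params=7, n_obs=100, extra=None, cov=None,
    classes=None,
):
    names = ["(Intercept)", "year"] + list((extra or {}).keys())
    values = [beta0, beta1] + list((extra or {}).values())
    beta = pd.Series(values, index=names)
    if cov is None:
        cov = np.eye(len(beta)) * 1e-4
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)
    z = beta / se
    from scipy import stats

    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    return glmm.FitResult(
        beta=beta,
        se=se,
        zvalues=z,
        pvalues=p,
        vc=glmm.VarianceComponents(),
        loglik=loglik,
        n_obs=n_obs,
        n_params=n_params,
        aic=-2 * loglik + 2 * n_params,
        bic=-2 * loglik + n_params * np.log(n_obs),
        converged=True,
        grad_norm=0.0,
        n_outer_evals=0,
        cov_beta=cov,
        structure=glmm.RandomStructure(),
        reference_class=(classes or [None])[0],
        typology_classes=classes or [],
    )
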