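"""Residual surfaces, VPC, information criteria and stratified summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import salbupop as sp
from salbupop.diagnostics import (
    individual_parameters_frame,
    information_criteria,
    outlier_proportion,
    residual_table,
    stratified_summary,
    vpc,
)
from salbupop.initials import nca_informed_initials
from salbupop.nlme import evaluate_model


@pytest.fixture(scope="module")
def self_sim():
    """Dataset simulated from the reference model, evaluated under the same
    (correctly specified) model — the NPDE/coverage null case."""
    gen = sp.default_popmodel()
    ds = sp.simulate_dataset(sp.default_virtual_cohort(), gen, seed=101)
    fit = evaluate_model(ds, gen, compute_loglik=False)
    return gen, ds, fit


class TestResidualTable:
    def test_iwres_zero_when_observations_equal_ipred(self):
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.0, "cl": 5.0, "v1": 20.0},
            omega={},
            a=0.5, b=0.0, error_model="constant",
        )
        from salbupop.pkmodel import get_model

        times = np.linspace(0.5, 24, 15)
        f = get_model("one_compartment").predict_subjects(
            np.array([[1.0, 5.0, 20.0]]), [600.0], times[None, :]
        )[0]
        rows = [{"ID": 1, "TIME": 0.0, "AMT": 600.0, "DV": np.nan, "EVID": 1, "MDV": 1}]
        rows += [
            {"ID": 1, "TIME": t, "AMT": 0.0, "DV": v, "EVID": 0, "MDV": 0}
            for t, v in zip(times, f)
        ]
        ds = sp.PKDataset(pd.DataFrame(rows))
        fit = evaluate_model(ds, model, compute_loglik=False)
        table = residual_table(fit, k_sim=50, seed=1)
        np.testing.assert_allclose(table.IWRES, 0.0, atol=1e-8)

    def test_npde_standard_normal_under_null(self, self_sim):
        _, _, fit = self_sim
        table = residual_table(fit, k_sim=500, seed=5)
        assert len(table) == 448
        assert abs(table.NPDE.mean()) < 0.1
        assert 0.85 < table.NPDE.var() < 1.15

    def test_two_simulation_rank_arithmetic(self, self_sim):
        _, _, fit = self_sim
        table = residual_table(fit, k_sim=2, seed=7)
        pde = stats.norm.cdf(table.NPDE.to_numpy())
        assert set(np.round(pde, 9)) <= {0.25, 0.5, 0.75}


class TestOutlierProportion:
    def test_zero_when_all_points_at_prediction(self):
        model = sp.default_popmodel()
        f = np.linspace(0.1, 50, 100)
        assert outlier_proportion(f, f, model) == 0.0

    def test_one_when_displaced_ten_sigma(self):
        model = sp.default_popmodel()
        f = np.linspace(0.1, 50, 100)
        y = f + 10 * model.g(f)
        assert outlier_proportion(y, f, model) == 1.0

    def test_nominal_coverage_against_true_predictions(self):
        # measured against the generating predictions, the 90% interval
        # excludes 10% of points up to Monte-Carlo error
        gen = sp.default_popmodel()
        rng = np.random.default_rng(0)
        f = np.linspace(0.5, 60, 5000)
        y = f + gen.g(f) * rng.standard_normal(5000)
        frac = outlier_proportion(y, f, gen, level=0.90)
        assert frac == pytest.approx(0.10, abs=2 * math.sqrt(0.1 * 0.9 / 5000) + 0.01)

    def test_ebe_based_fraction_below_nominal(self, self_sim):
        # conditional-mode predictions track the data, so the empirical
        # outlier fraction falls at or below the nominal 10%
        _, ds, fit = self_sim
        obs = ds.observations()
        frac = outlier_proportion(
            obs.DV.to_numpy(), fit.ipred()[fit.arrays.mask], fit.model
        )
        assert 0.005 < frac < 0.12


class TestVpc:
    def test_degenerate_variability_collapses_bands(self):
        model = sp.PopModel(
            theta={"ka": 3.71, "cl": 24.33, "v1": 1.0, "q": 10.59, "v2": 0.0066},
            omega={},
            a=1e-12, b=0.0, error_model="constant",
        )
        ds = sp.simulate_dataset(sp.default_virtual_cohort(), model, seed=3)
        fit = evaluate_model(ds, model, compute_loglik=False)
        bands = vpc(fit, k_sim=40, seed=4)
        # every observed percentile curve coincides with the prediction
        # median (band widths are at the 1e-12 noise scale of the residual)
        np.testing.assert_allclose(
            bands.table.observed, bands.table.pi_median, atol=1e-7
        )

    def test_bands_ordered_within_bins(self, self_sim):
        _, _, fit = self_sim
        bands = vpc(fit, k_sim=200, seed=6).table
        for _, grp in bands.groupby("bin_time"):
            grp = grp.sort_values("percentile")
            assert grp.observed.is_monotonic_increasing or len(grp) < 2
            assert grp.pi_median.is_monotonic_increasing

    def test_coverage_and_misspecification_contrast(self, wc_model, wc_dataset):
        ok = evaluate_model(wc_dataset, wc_model, compute_loglik=False)
        v_ok = vpc(ok, k_sim=300, seed=12)
        bad_fit = sp.fit_saem(
            wc_dataset,
            nca_informed_initials(wc_dataset, structural="one_compartment"),
            sp.SaemSettings(n_explore=150, n_smooth=100, seed=3,
                            compute_se=False, compute_loglik=False),
        )
        v_bad = vpc(bad_fit, k_sim=300, seed=12)
        assert v_ok.outlier_fraction() <= 0.25
        assert v_bad.outlier_fraction() > v_ok.outlier_fraction()

    def test_sparse_bins_merged(self, wc_model):
        ds = sp.simulate_dataset(sp.sample_cohort(n=6, seed=2), wc_model, seed=5)
        df = ds.df.copy()
        # leave only two observations at the last nominal time
        drop = df[(df.TIME == 12.0) & (df.EVID == 0)].index[2:]
        ds2 = sp.PKDataset(df.drop(index=drop))
        fit = evaluate_model(ds2, wc_model, compute_loglik=False)
        bands = vpc(fit, k_sim=30, seed=8)
        assert 12.0 in bands.merged_bins


class TestInformationCriteria:
    def test_formulas(self):
        census = {"p_random": 3, "p_fixed": 2, "p_total": 5}
        aic, bic, bicc = information_criteria(100.0, census, 32, 448)
        assert aic == pytest.approx(110.0)
        assert bic == pytest.approx(100 + 5 * math.log(32))
        assert bicc == pytest.approx(100 + 3 * math.log(32) + 2 * math.log(448))

    def test_bicc_collapses_to_bic_without_error_params(self):
        census = {"p_random": 4, "p_fixed": 0, "p_total": 4}
        _, bic, bicc = information_criteria(50.0, census, 20, 100)
        assert bicc == bic

    def test_penalty_tradeoff_arithmetic(self):
        # a parameter is worth keeping only if it buys more than its penalty
        small = {"p_random": 3, "p_fixed": 2, "p_total": 5}
        large = {"p_random": 4, "p_fixed": 2, "p_total": 6}
        drop = 2.0  # -2LL improvement from the extra parameter
        _, _, b_small = information_criteria(100.0, small, 32, 448)
        _, _, b_large = information_criteria(100.0 - drop, large, 32, 448)
        assert b_large > b_small  # log(32) ~ 3.47 > 2


class TestStratifiedSummary:
    def test_single_stratum_equals_whole_cohort(self, wc_fit):
        params = individual_parameters_frame(wc_fit)
        cov = wc_fit.arrays.covariates
        table = stratified_summary(
            params, cov, {"all": ("AGE", (("everyone", 0.0, 200.0),))}
        )
        from salbupop.nca import summarize_geometric

        gm, gsd = summarize_geometric(params["cl"])
        row = table[table.parameter == "cl"].iloc[0]
        assert row.geo_mean == pytest.approx(gm)
        assert row.geo_sd == pytest.approx(gsd)
        assert row.n == len(params)

    def test_planted_age_effect_orders_clearance(self):
        # clearance raised in the young stratum must show up as a higher
        # young-stratum geometric mean
        cohort = sp.sample_cohort(n=120, seed=13)
        model = sp.demo_popmodel()
        cov = cohort.to_frame().set_index("ID")
        rng = np.random.default_rng(5)
        eta = 0.1 * rng.standard_normal((len(cov), 5))
        params = pd.DataFrame(
            model.individual_matrix(cov, eta),
            columns=list(model.param_names),
            index=cov.index,
        )
        table = stratified_summary(params, cov)
        young = table[
            (table.stratum_var == "age_group")
            & (table.stratum == "5-22")
            & (table.parameter == "cl")
        ].geo_mean.iloc[0]
        old = table[
            (table.stratum_var == "age_group")
            & (table.stratum == "23-65")
            & (table.parameter == "cl")
        ].geo_mean.iloc[0]
        assert young > old

    def test_singleton_stratum_flagged(self, wc_fit):
        params = individual_parameters_frame(wc_fit)
        cov = wc_fit.arrays.covariates.copy()
        first = params.index[0]
        strata = {
            "oddone": (
                "AGE",
                ((
                    "one",
                    float(cov.loc[first, "AGE"]) - 1e-6,
                    float(cov.loc[first, "AGE"]) + 1e-6,
                ),),
            )
        }
        cov2 = cov.copy()
        table = stratified_summary(params, cov2, strata)
        ones = table[(table.n == 1) & (table.parameter == "cl")]
        if len(ones):
            assert (ones.flag == "singleton").all()
            assert ones.geo_sd.isna().all()

    def test_empty_stratum_omitted_with_flag(self, wc_fit):
        params = individual_parameters_frame(wc_fit)
        cov = wc_fit.arrays.covariates
        strata = {"impossible": ("AGE", (("nobody", 500.0, 600.0),))}
        table = stratified_summary(params, cov, strata)
        assert (table.flag == "empty").all()
        assert table.parameter.isna().all()
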