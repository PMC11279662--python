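"""Mixed-effects machinery: hierarchy, conditionals, likelihood, SAEM."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import salbupop as sp
from salbupop.data import DesignSpec
from salbupop.initials import nca_informed_initials
from salbupop.nlme import (
    conditional_mcmc,
    evaluate_model,
    individual_parameters,
    loglik_importance,
)
from salbupop.pkmodel import get_model


class TestPopModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            sp.PopModel(theta={"ka": 1.0})  # incomplete theta
        with pytest.raises(ValueError):
            sp.PopModel(
                theta={"ka": 1, "cl": 1, "v1": 1, "q": 1, "v2": 1},
                a=0.0, b=0.0,
            )
        with pytest.raises(ValueError):
            sp.PopModel(
                theta={"ka": 1, "cl": 1, "v1": 1, "q": 1, "v2": 1},
                correlations={("ka", "q"): 1.2},
            )

    def test_omega_matrix_structure(self, wc_model):
        om = wc_model.omega_matrix()
        assert om.shape == (5, 5)
        np.testing.assert_allclose(np.diag(om), [0.04, 0.0625, 0.0225, 0.04, 0.04])
        assert om[0, 3] == pytest.approx(0.3 * 0.2 * 0.2)
        assert om[0, 1] == 0.0
        assert np.all(np.linalg.eigvalsh(om) > 0)


class TestIndividualParameters:
    MODEL = sp.PopModel(
        theta={"ka": 2.0, "cl": 8.0, "v1": 5.0, "q": 3.0, "v2": 10.0},
        omega={"ka": 0.2, "cl": 0.3},
    )

    def test_zero_eta_gives_typical(self):
        vals = individual_parameters(self.MODEL, {}, np.zeros(5))
        assert vals == pytest.approx(self.MODEL.theta)

    def test_no_iiv_forces_typical(self, rng):
        # parameters without an omega entry never vary
        for _ in range(5):
            eta = np.zeros(5)
            eta[[0, 1]] = rng.standard_normal(2)
            vals = individual_parameters(self.MODEL, {}, eta)
            assert vals["v1"] == pytest.approx(5.0)
            assert vals["q"] == pytest.approx(3.0)

    def test_monte_carlo_log_mean(self, rng):
        n = 4000
        etas = 0.3 * rng.standard_normal(n)
        logs = [
            math.log(
                individual_parameters(self.MODEL, {}, np.array([0, e, 0, 0, 0]))["cl"]
            )
            for e in etas[:400]
        ]
        assert np.mean(logs) == pytest.approx(math.log(8.0), abs=3 * 0.3 / math.sqrt(400))


class TestConditionalDistribution:
    def test_ebe_recovers_known_eta_noise_free(self):
        model = sp.PopModel(
            theta={"ka": 1.5, "cl": 5.0, "v1": 10.0, "q": 3.0, "v2": 20.0},
            omega={"ka": 0.2, "cl": 0.25, "v1": 0.2, "q": 0.2, "v2": 0.2},
            a=0.0, b=1e-4, error_model="proportional",
        )
        eta_true = np.array([0.1, -0.15, 0.05, 0.2, -0.1])
        sm = get_model("two_compartment")
        names = ["ka", "cl", "v1", "q", "v2"]
        th = np.array([[model.theta[p] * math.exp(e) for p, e in zip(names, eta_true)]])
        times = np.linspace(0.1, 48, 30)
        f = sm.predict_subjects(th, np.array([600.0]), times[None, :])[0]
        rows = [{"ID": 1, "TIME": 0.0, "AMT": 600.0, "DV": np.nan, "EVID": 1, "MDV": 1}]
        rows += [
            {"ID": 1, "TIME": t, "AMT": 0.0, "DV": y, "EVID": 0, "MDV": 0}
            for t, y in zip(times, f)
        ]
        ds = sp.PKDataset(pd.DataFrame(rows))
        out = conditional_mcmc(model, ds, 1, n_samples=10, seed=3, burn=30, thin=2)
        assert np.abs(out["eta_mode"] - eta_true).max() < 1e-4

    def test_chain_matches_quadrature_posterior(self):
        # scalar random effect: the MCMC posterior mean must match dense
        # numerical integration of the conditional density
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.0, "cl": 5.0, "v1": 20.0},
            omega={"cl": 0.3},
            a=0.5, b=0.0, error_model="constant",
        )
        cohort = sp.Cohort(sp.default_virtual_cohort().subjects[:1])
        ds = sp.simulate_dataset(cohort, model, seed=9)
        out = conditional_mcmc(model, ds, 1, n_samples=400, seed=11, burn=200, thin=3)
        chain = out["eta_samples"][:, 1]

        arr = ds.to_fit_arrays()
        sm = get_model("one_compartment")
        grid = np.linspace(-1.2, 1.2, 2001)
        ll = []
        for e in grid:
            th = np.array([1.0, 5.0 * math.exp(e), 20.0])
            fi = sm.predict_subjects(th[None, :], arr.dose, arr.times)[0]
            res = (arr.y[0] - fi) / 0.5
            ll.append(-0.5 * np.sum(res[arr.mask[0]] ** 2) - 0.5 * e**2 / 0.09)
        w = np.exp(np.array(ll) - max(ll))
        w /= w.sum()
        post_mean = float((grid * w).sum())
        post_sd = float(np.sqrt(((grid - post_mean) ** 2 * w).sum()))
        mc_err = 3 * post_sd / math.sqrt(len(chain) / 5)  # conservative ESS
        assert chain.mean() == pytest.approx(post_mean, abs=mc_err)

    def test_omega_floor_collapses_conditional_mass(self):
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.0, "cl": 5.0, "v1": 20.0},
            omega={"cl": 1e-6},
            a=0.5, b=0.0, error_model="constant",
        )
        cohort = sp.Cohort(sp.default_virtual_cohort().subjects[:1])
        ds = sp.simulate_dataset(cohort, model, seed=9)
        out = conditional_mcmc(model, ds, 1, n_samples=100, seed=2, burn=50, thin=1)
        assert np.abs(out["eta_samples"][:, 1]).max() < 1e-4

    def test_unknown_subject_rejected(self, ref_dataset):
        with pytest.raises(ValueError):
            conditional_mcmc(sp.default_popmodel(), ref_dataset, 999, 10, 0)


class TestMarginalLikelihood:
    def _tiny_dataset(self, model, n=4, seed=9):
        cohort = sp.Cohort(sp.default_virtual_cohort().subjects[:n])
        return sp.simulate_dataset(cohort, model, seed=seed)

    def test_no_iiv_collapses_to_closed_form(self):
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.0, "cl": 5.0, "v1": 20.0},
            omega={},
            a=0.5, b=0.0, error_model="constant",
        )
        ds = self._tiny_dataset(model)
        m2ll, per, _ = loglik_importance(dataset=ds, model=model, n_is=10, seed=1)
        arr = ds.to_fit_arrays()
        sm = get_model("one_compartment")
        th = np.array([1.0, 5.0, 20.0])
        hand = 0.0
        for i in range(arr.n_subjects):
            fi = sm.predict_subjects(th[None, :], arr.dose[i : i + 1], arr.times[i : i + 1])[0]
            res = arr.y[i] - fi
            msk = arr.mask[i]
            hand += np.sum(-0.5 * np.log(2 * np.pi * 0.25) - res[msk] ** 2 / 0.5)
        assert m2ll == pytest.approx(-2 * hand, rel=1e-12)

    def test_estimate_stabilizes_with_more_draws(self, wc_model):
        ds = self._tiny_dataset(wc_model, n=6)
        v1, _, _ = loglik_importance(dataset=ds, model=wc_model, n_is=5000, seed=21)
        v2, _, _ = loglik_importance(dataset=ds, model=wc_model, n_is=10000, seed=22)
        assert abs(v1 - v2) < 0.5

    def test_duplicate_observation_adds_analytic_term(self):
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.0, "cl": 5.0, "v1": 20.0},
            omega={},
            a=0.5, b=0.0, error_model="constant",
        )
        ds = self._tiny_dataset(model, n=2)
        m2ll, _, _ = loglik_importance(dataset=ds, model=model, n_is=10, seed=1)
        # duplicate one observation row of subject 1
        df = ds.df.copy()
        row = df[(df.ID == 1) & (df.EVID == 0)].iloc[3]
        dup = sp.PKDataset(pd.concat([df, row.to_frame().T], ignore_index=True))
        m2ll_dup, _, _ = loglik_importance(dataset=dup, model=model, n_is=10, seed=1)
        sm = get_model("one_compartment")
        f = sm.predict_subjects(
            np.array([[1.0, 5.0, 20.0]]), np.array([600.0]),
            np.array([[row.TIME]]),
        )[0, 0]
        term = -0.5 * math.log(2 * math.pi * 0.25) - (row.DV - f) ** 2 / 0.5
        assert m2ll_dup - m2ll == pytest.approx(-2 * term, rel=1e-9)

    def test_unit_rescaling_shifts_by_jacobian(self):
        # multiplying concentrations (and a, and the volume scale) by 10
        # shifts -2LL by exactly n * 2 * log(10)
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.0, "cl": 5.0, "v1": 20.0},
            omega={},
            a=0.5, b=0.0, error_model="constant",
        )
        ds = self._tiny_dataset(model, n=3)
        n_obs = len(ds.observations())
        df = ds.df.copy()
        df.loc[df.EVID == 0, "DV"] *= 10.0
        scaled = sp.PKDataset(df)
        model10 = dataclasses.replace(
            model, theta={"ka": 1.0, "cl": 0.5, "v1": 2.0}, a=5.0
        )
        v, _, _ = loglik_importance(dataset=ds, model=model, n_is=10, seed=1)
        v10, _, _ = loglik_importance(dataset=scaled, model=model10, n_is=10, seed=1)
        assert v10 - v == pytest.approx(2 * n_obs * math.log(10.0), rel=1e-10)


class TestSaem:
    def test_near_deterministic_recovery_within_one_percent(self):
        truth = sp.PopModel(
            theta={"ka": 1.5, "cl": 5.0, "v1": 10.0, "q": 3.0, "v2": 20.0},
            omega={"ka": 0, "cl": 0, "v1": 0, "q": 0, "v2": 0},
            a=0.0, b=0.005, error_model="proportional",
        )
        times = tuple(np.concatenate([[0.0], np.geomspace(0.25, 48, 19)]))
        ds = sp.simulate_dataset(
            sp.sample_cohort(n=32, seed=4), truth, DesignSpec(times=times), seed=7
        )
        init = nca_informed_initials(ds, a0=0.005, b0=0.02)
        fit = sp.fit_saem(
            ds, init,
            sp.SaemSettings(n_explore=200, n_smooth=150, seed=9,
                            compute_se=False, compute_loglik=False),
        )
        for p, v in truth.theta.items():
            assert fit.model.theta[p] == pytest.approx(v, rel=0.01), p
        assert fit.flags.get("iiv_collapsed")

    def test_wc_parameter_and_error_recovery(self, wc_fit, wc_model):
        # all five structural parameters are identifiable on this design
        for p, v in wc_model.theta.items():
            assert fit_rel_err(wc_fit, p, v) < 0.20, p
        se = {r.parameter: r.se for r in wc_fit.se_table.itertuples()}
        assert abs(wc_fit.model.a - wc_model.a) < 3 * se["a"]
        assert abs(wc_fit.model.b - wc_model.b) < 3 * se["b"]

    def test_subject_order_invariance(self, wc_dataset, wc_model):
        settings = sp.SaemSettings(
            n_explore=60, n_smooth=40, seed=13, compute_se=False,
            compute_loglik=False,
        )
        init = nca_informed_initials(wc_dataset)
        fit1 = sp.fit_saem(wc_dataset, init, settings)
        shuffled = sp.PKDataset(
            wc_dataset.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        fit2 = sp.fit_saem(shuffled, init, settings)
        for p in fit1.model.theta:
            assert fit1.model.theta[p] == pytest.approx(fit2.model.theta[p], rel=1e-9)

    def test_smoothing_phase_objective_stabilizes(self):
        # clean one-compartment fixture: the stochastic-approximation
        # objective must settle once the step size decays
        model = sp.PopModel(
            structural="one_compartment",
            theta={"ka": 1.5, "cl": 5.0, "v1": 10.0},
            omega={"ka": 0.2, "cl": 0.2, "v1": 0.15},
            a=0.05, b=0.10,
        )
        design = DesignSpec(
            times=(0.0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24), dose_ug=600
        )
        ds = sp.simulate_dataset(sp.sample_cohort(n=24, seed=8), model, design, seed=31)
        fit = sp.fit_saem(
            ds, nca_informed_initials(ds, structural="one_compartment"),
            sp.SaemSettings(n_explore=200, n_smooth=300, seed=13,
                            compute_se=False, compute_loglik=False),
        )
        tail = fit.trace.query("phase == 'smooth'").tail(50)["objective_smoothed"]
        assert tail.max() - tail.min() < 1.0

    def test_divergence_raises_with_trace(self, wc_dataset):
        bad = sp.PopModel(
            theta={"ka": 1e8, "cl": 1e-8, "v1": 1e8, "q": 1.0, "v2": 1.0},
            omega={"ka": 5.0, "cl": 5.0, "v1": 5.0, "q": 5.0, "v2": 5.0},
            a=1e-9, b=1e-9,
        )
        settings = sp.SaemSettings(n_explore=10, n_smooth=5, seed=1,
                                   compute_se=False, compute_loglik=False)
        try:
            fit = sp.fit_saem(wc_dataset, bad, settings)
        except RuntimeError as err:
            assert hasattr(err, "trace")
        else:  # even absurd starts may survive; the fit must then be finite
            assert np.isfinite(fit.trace["objective"]).all()


class TestStandardErrors:
    def test_rse_is_percent_ratio(self, wc_fit):
        t = wc_fit.se_table
        ok = t[np.isfinite(t.se)]
        np.testing.assert_allclose(
            ok.rse_percent, 100 * ok.se / ok.estimate.abs(), rtol=1e-12
        )

    def test_se_calibration_against_replicates(self, wc_model, wc_design):
        # median linearization SE of Cl across refits should match the
        # empirical SD of the Cl estimates (reduced replicate count)
        n_rep = 24
        ests, ses = [], []
        settings = sp.SaemSettings(
            n_explore=120, n_smooth=80, seed=0, compute_loglik=False
        )
        for r in range(n_rep):
            ds = sp.simulate_dataset(
                sp.sample_cohort(n=32, seed=4), wc_model, wc_design, seed=1000 + r
            )
            fit = sp.fit_saem(
                ds, nca_informed_initials(ds),
                dataclasses.replace(settings, seed=2000 + r),
            )
            ests.append(fit.model.theta["cl"])
            se_row = fit.se_table.query("parameter == 'cl'")
            ses.append(float(se_row.se.iloc[0]))
        emp_sd = np.std(ests, ddof=1)
        med_se = np.median(ses)
        assert med_se == pytest.approx(emp_sd, rel=0.5)


def fit_rel_err(fit, name, truth):
    return abs(fit.model.theta[name] / truth - 1.0)
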