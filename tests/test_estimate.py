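"""FOCE-I objective, population fit, EBEs, stepwise selection, bootstrap, VPC."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import roots_hermite

import voripk as vp
from voripk.estimate import CovariateEffect, FOCEModel
from voripk.structural import PopPKParams, ResidualSpec


TOY = pd.DataFrame(
    {
        "ID": [1, 1, 2, 3],
        "AMT": [40.0, 40.0, 55.0, 80.0],
        "II": 12.0,
        "WT": [6.0, 6.0, 8.0, 10.0],
        "DV": [0.9, 1.4, 0.5, 2.8],
    }
)


def quadrature_ofv(data: pd.DataFrame, params: PopPKParams, n_nodes: int = 21) -> float:
    """Independent oracle: -2 log marginal likelihood by adaptive
    Gauss-Hermite quadrature over the subject random effect."""
    nodes, weights = roots_hermite(n_nodes)
    omega2 = params.omega2_cl
    total = 0.0
    for _, sub in data.groupby("ID"):
        amt = sub["AMT"].to_numpy()
        tau = sub["II"].to_numpy()
        wt = sub["WT"].to_numpy()
        dv = sub["DV"].to_numpy()
        tvcl, tvv = vp.typical_params(params, wt)

        def g(eta):
            pred = vp.ss_trough(amt, tau, tvcl * np.exp(eta), tvv, params.ka)
            var = np.maximum(params.sigma.variance(pred), 1e-30)
            return float(np.sum((dv - pred) ** 2 / var + np.log(var)) + eta**2 / omega2)

        span = 5 * np.sqrt(omega2)
        mode = minimize_scalar(g, bounds=(-span, span), method="bounded",
                               options={"xatol": 1e-10}).x
        h = 1e-4
        curv = (g(mode + h) - 2 * g(mode) + g(mode - h)) / h**2
        s = np.sqrt(2.0 / max(curv, 1e-10))
        g0 = g(mode)
        vals = np.array([np.exp(-0.5 * (g(mode + np.sqrt(2) * s * z) - g0) + z**2)
                         for z in nodes])
        integral = np.sqrt(2) * s * float(np.sum(weights * vals))
        total += -2 * (np.log(integral) - 0.5 * g0
                       - 0.5 * np.log(2 * np.pi * omega2)
                       - 0.5 * len(dv) * np.log(2 * np.pi))
    return total


class TestFoceObjective:
    def test_degenerate_omega_equals_els(self):
        params = PopPKParams(omega2_cl=0.0)
        got = vp.foce_ofv(TOY, params)
        cl, v = vp.typical_params(params, TOY["WT"].to_numpy())
        pred = vp.ss_trough(TOY["AMT"], TOY["II"], cl, v, params.ka)
        var = params.sigma.variance(pred)
        els = float(np.sum((TOY["DV"] - pred) ** 2 / var + np.log(var)
                    + np.log(2 * np.pi)))
        assert got == pytest.approx(els, rel=1e-4)

    def test_matches_quadrature_on_toy(self):
        params = PopPKParams()  # omega2 = 0.674, proportional 25%
        assert vp.foce_ofv(TOY, params) == pytest.approx(
            quadrature_ofv(TOY, params), abs=0.5)

    def test_additive_over_subjects(self):
        params = PopPKParams()
        doubled = pd.concat(
            [TOY, TOY.assign(ID=TOY["ID"] + 10)], ignore_index=True)
        assert vp.foce_ofv(doubled, params) == pytest.approx(
            2 * vp.foce_ofv(TOY, params), rel=1e-10)


class TestFitPopulation:
    def test_noise_free_self_consistency(self):
        spec = vp.CohortSpec(n_subjects=40, seed=11, titration=False)
        coh = vp.generate_cohort(spec)
        truth = PopPKParams(omega2_cl=1e-10,
                            sigma=ResidualSpec("additive", cv_prop=0.0, sd_add=1e-6))
        df = vp.simulate_troughs(coh, truth, seed=5, spec=spec)
        df = df[df["BQL"] == 0]
        fit = vp.fit_population(
            df,
            init=PopPKParams(theta_cl=15.0, theta_v=600.0, omega2_cl=0.01,
                             sigma=ResidualSpec("proportional", cv_prop=0.05)),
            compute_se=False,
            bounds={"cv_prop": (1e-4, 1.0), "omega2_cl": (1e-9, 4.0)},
        )
        assert fit.params_hat.theta_cl == pytest.approx(17.9, rel=1e-3)
        assert fit.params_hat.theta_v == pytest.approx(788.0, rel=5e-3)

    def test_fit_report_contract(self, study_fit):
        assert np.isfinite(study_fit.ofv)
        assert set(study_fit.rse_pct) >= {"theta_cl", "theta_v", "omega2_cl"}
        assert len(study_fit.ebes) == 76
        assert {"ID", "ETA_CL", "CL_IND", "V_IND"} <= set(study_fit.ebes.columns)

    def test_ofv_at_optimum_not_worse_than_truth(self, study_fit):
        truth_x = study_fit.model.pack(PopPKParams())
        assert study_fit.ofv <= study_fit.model.agh_ofv(truth_x) + 1e-6


class TestEmpiricalBayes:
    def test_mode_at_prior_when_obs_equals_typical(self):
        params = PopPKParams(omega2_cl=0.3,
                             sigma=ResidualSpec("additive", cv_prop=0.0, sd_add=0.2))
        cl, v = vp.typical_params(params, 8.0)
        dv = vp.ss_trough(55.0, 12.0, cl, v, params.ka)
        sub = pd.DataFrame({"ID": [1], "AMT": [55.0], "II": [12.0],
                            "WT": [8.0], "DV": [dv]})
        eta, cl_i, _ = vp.empirical_bayes(params, sub, error_kind="additive")
        assert abs(eta) < 1e-6
        assert cl_i == pytest.approx(cl)

    def test_prior_dominates_as_omega_vanishes(self):
        params = PopPKParams(omega2_cl=1e-12)
        sub = pd.DataFrame({"ID": [1], "AMT": [55.0], "II": [12.0],
                            "WT": [8.0], "DV": [6.0]})
        eta, _, _ = vp.empirical_bayes(params, sub)
        assert eta == 0.0

    def test_matches_independent_grid_search(self, study_df, study_fit):
        params = study_fit.params_hat
        omega2 = params.omega2_cl
        rng = np.random.default_rng(0)
        ids = rng.choice(study_df["ID"].unique(), size=20, replace=False)
        span = 5 * np.sqrt(omega2)
        grid = np.arange(-span, span, 1e-4)
        for sid in ids:
            sub = study_df[study_df["ID"] == sid]
            amt, tau = sub["AMT"].to_numpy(), sub["II"].to_numpy()
            wt, dv = sub["WT"].to_numpy(), sub["DV"].to_numpy()
            tvcl, tvv = vp.typical_params(params, wt)
            pred = vp.ss_trough(amt[:, None], tau[:, None],
                                tvcl[:, None] * np.exp(grid), tvv[:, None], params.ka)
            var = params.sigma.variance(pred)
            obj = np.sum((dv[:, None] - pred) ** 2 / var + np.log(var), axis=0) \
                + grid**2 / omega2
            eta_grid = grid[np.argmin(obj)]
            eta, _, _ = vp.empirical_bayes(params, sub)
            assert abs(eta - eta_grid) < 1e-3


class TestShrinkage:
    def test_degenerate_cases(self):
        assert vp.eta_shrinkage([0.0, 0.0, 0.0], 0.5) == pytest.approx(100.0)
        etas = np.array([-1.0, 1.0])
        sd = np.std(etas, ddof=1)
        assert vp.eta_shrinkage(etas, sd**2) == pytest.approx(0.0)
        assert np.isnan(vp.eta_shrinkage([0.1, 0.2], 0.0))

    def test_rich_design_shrinks_less_than_sparse(self):
        # same truth; 5 troughs per subject vs 1.  A tight prior (omega2 =
        # 0.05) makes a single 25%-noise trough genuinely weak, so the
        # sparse-design EBEs must shrink visibly more than the rich ones.
        spec = vp.CohortSpec(n_subjects=60, seed=13, extra_sample_p=0.0,
                             titration=False)
        coh = vp.generate_cohort(spec)
        rich_coh = pd.concat([coh] * 5, ignore_index=True)
        params = PopPKParams(omega2_cl=0.05)
        sparse = vp.simulate_troughs(coh, params, seed=1, spec=spec)
        rich = vp.simulate_troughs(rich_coh, params, seed=1, spec=spec)
        shrinks = {}
        for name, df in (("sparse", sparse), ("rich", rich)):
            model = FOCEModel(df)
            eta = model.conditional_modes(model.pack(params))
            shrinks[name] = vp.eta_shrinkage(eta, params.omega2_cl)
        assert shrinks["rich"] < shrinks["sparse"]


class TestStepwise:
    def test_no_candidates_returns_base(self, study_df):
        fit, trace = vp.stepwise_covariates(study_df, {})
        assert fit.cov_effects == ()
        assert list(trace["step"]) == ["base"]

    def test_planted_power_covariate_detected(self):
        spec = vp.CohortSpec(n_subjects=80, seed=21, titration=False)
        coh = vp.generate_cohort(spec)
        p = PopPKParams()
        rng = np.random.default_rng(42)
        ids, sidx = np.unique(coh["ID"], return_inverse=True)
        eta = np.sqrt(p.omega2_cl) * rng.standard_normal(len(ids))
        med = coh["ALP"].median()
        cl_t, v_t = vp.typical_params(p, coh["WT"].to_numpy())
        cl_i = cl_t * (coh["ALP"] / med) ** 0.5 * np.exp(eta[sidx])
        pred = vp.ss_trough(coh["AMT"], coh["II"], cl_i, v_t, p.ka)
        conc = np.maximum(pred * (1 + 0.25 * rng.standard_normal(len(pred))), 0)
        coh["DV"] = np.where(conc < 0.25, 0.125, conc)
        coh["BQL"] = (conc < 0.25).astype(int)

        fit, trace = vp.stepwise_covariates(coh, {"ALP": "power", "TAC": "factor"})
        names = [e.name for e in fit.cov_effects]
        assert "ALP" in names
        theta = fit.cov_thetas[names.index("ALP")]
        assert theta == pytest.approx(0.5, abs=0.25)
        assert (trace["step"] == "forward-add").any()


class TestBootstrap:
    def test_reproducible_and_well_ordered(self, study_df):
        a = vp.bootstrap(study_df, n=3, seed=7, maxiter=150)
        b = vp.bootstrap(study_df, n=3, seed=7, maxiter=150)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)
        s = a.summary
        assert (s["ci2.5"] <= s["median"]).all()
        assert (s["median"] <= s["ci97.5"]).all()
        assert 0.0 <= a.minimization_success_rate <= 100.0


class TestVpc:
    def test_self_consistent_coverage(self, study_fit):
        # simulate a dataset from the fitted model itself, then check its
        # observed percentiles sit inside the fitted model's own bands
        params = study_fit.params_hat
        design = study_fit.model.frame.copy()
        spec = vp.CohortSpec(titration=False)
        sim = vp.simulate_troughs(design, params, seed=31, spec=spec)
        res = vp.vpc(study_fit, data=sim, n_sim=300, seed=17)
        t = res.table
        inside = (t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"])
        assert inside.mean() >= 0.9

    def test_single_replicate_bands_degenerate(self, study_fit):
        res = vp.vpc(study_fit, n_sim=1, seed=3)
        assert np.allclose(res.table["sim_lo"], res.table["sim_hi"])

    def test_determinism(self, study_fit):
        a = vp.vpc(study_fit, n_sim=20, seed=5).table
        b = vp.vpc(study_fit, n_sim=20, seed=5).table
        pd.testing.assert_frame_equal(a, b)
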