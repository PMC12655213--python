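"""FOCE engine: conditional likelihood, MAP etas, population fits."""

import math

import numpy as np
import pandas as pd
import pytest

from mcubed.nlme import (
    CovariateEffect, EstimationData, FitConfig, FOCEEngine, PopModel,
    bsv_percent_cv, fit_population, foce_objective, foce_ofv,
    gof_quantities, individual_conditional_nll, initial_model, map_eta,
    typical_value,
)
from tests.conftest import TRUE_2CMT, simulate_homogeneous


def one_compartment_frame(cl=3.0, v1=40.0, times=(2.0, 6.0, 11.5),
                          dv=None):
    from mcubed.compartmental import DoseEvent, concentration
    events = [DoseEvent(0.0, 1000.0, 1.0)]
    conc = concentration({"CL": cl, "V1": v1}, events, np.array(times))
    rows = [{"ID": 1, "TIME": 0.0, "AMT": 1000.0, "RATE": 1000.0,
             "EVID": 1, "MDV": 1, "DV": np.nan}]
    for t, c in zip(times, dv if dv is not None else conc):
        rows.append({"ID": 1, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                     "EVID": 0, "MDV": 0, "DV": c})
    return pd.DataFrame(rows), conc


class TestTypicalValue:
    def test_reference_covariates_return_tvpop(self):
        effects = [CovariateEffect("CL", "CLCR", "power", 0.765, 75.0),
                   CovariateEffect("CL", "FLAG", "categorical", 0.881)]
        tv = typical_value(effects, 2.75, {"CLCR": 75.0, "FLAG": 0.0})
        assert tv == pytest.approx(2.75)

    def test_power_effect_log_domain(self):
        effects = [CovariateEffect("CL", "CLCR", "power", 0.765, 75.0)]
        expected = 2.75 * math.exp(0.765 * math.log(150.0 / 75.0))
        assert typical_value(effects, 2.75, {"CLCR": 150.0}) \
            == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.673, abs=2e-3)

    def test_categorical_multiplier(self):
        effects = [CovariateEffect("CL", "FLAG", "categorical", 0.881)]
        assert typical_value(effects, 1.0, {"FLAG": 1.0}) \
            == pytest.approx(1.881)

    def test_nonpositive_covariate_under_power_rejected(self):
        effects = [CovariateEffect("CL", "CLCR", "power", 0.7, 75.0)]
        with pytest.raises(ValueError):
            typical_value(effects, 2.75, {"CLCR": 0.0})


class TestConditionalNll:
    def test_zero_residual_closed_form(self):
        frame, conc = one_compartment_frame()
        model = PopModel(theta={"CL": 3.0, "V1": 40.0}, omega2={"CL": 0.09},
                         sigma2=0.04, n_compartments=1)
        nll = individual_conditional_nll(model, np.zeros(1), frame)
        sigma = math.sqrt(0.04)
        expected = sum(math.log(c * sigma * math.sqrt(2 * math.pi))
                       for c in conc) \
            + 0.5 * math.log(2 * math.pi * 0.09)
        assert nll == pytest.approx(expected, rel=1e-9)

    def test_flat_prior_limit_drops_quadratic(self):
        frame, _ = one_compartment_frame()
        big, small = 1e8, 1.0
        m_big = PopModel(theta={"CL": 3.0, "V1": 40.0},
                         omega2={"CL": big}, sigma2=0.04, n_compartments=1)
        m_small = PopModel(theta={"CL": 3.0, "V1": 40.0},
                           omega2={"CL": small}, sigma2=0.04,
                           n_compartments=1)
        eta = np.array([1.5])
        quad_big = individual_conditional_nll(m_big, eta, frame) \
            - individual_conditional_nll(m_big, np.zeros(1), frame)
        # with a flat prior the eta quadratic penalty vanishes; the
        # remaining difference comes from the data term only
        data_term = quad_big
        quad_small = individual_conditional_nll(m_small, eta, frame) \
            - individual_conditional_nll(m_small, np.zeros(1), frame)
        assert quad_small - data_term == pytest.approx(0.5 * 1.5 ** 2,
                                                       rel=1e-6)


class TestMapEta:
    def test_interpolation_limit_single_observation(self):
        # tiny residual variance, one observation: the MAP eta makes the
        # individual prediction match the observation
        frame, conc = one_compartment_frame(times=(6.0,))
        frame.loc[frame["EVID"] == 0, "DV"] = conc[0] * 1.3
        model = PopModel(theta={"CL": 3.0, "V1": 40.0}, omega2={"CL": 1.0},
                         sigma2=1e-6, n_compartments=1)
        eta = map_eta(model, frame)
        engine = FOCEEngine(frame, 1)
        pred = engine.make_pred_fn(model)(eta[None, :])
        assert pred[0] == pytest.approx(conc[0] * 1.3, rel=1e-3)

    def test_known_eta_recovered_with_rich_sampling(self):
        from mcubed.compartmental import DoseEvent, concentration
        true_eta = 0.4
        events = [DoseEvent(0.0, 1000.0, 1.0)]
        times = np.linspace(1.5, 11.5, 8)
        conc = concentration({"CL": 3.0 * math.exp(true_eta), "V1": 40.0},
                             events, times)
        rows = [{"ID": 1, "TIME": 0.0, "AMT": 1000.0, "RATE": 1000.0,
                 "EVID": 1, "MDV": 1, "DV": np.nan}]
        rng = np.random.default_rng(0)
        for t, c in zip(times, conc):
            rows.append({"ID": 1, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                         "EVID": 0, "MDV": 0,
                         "DV": c * (1 + rng.normal(0, 0.02))})
        model = PopModel(theta={"CL": 3.0, "V1": 40.0}, omega2={"CL": 0.2},
                         sigma2=4e-4, n_compartments=1)
        eta = map_eta(model, pd.DataFrame(rows))
        assert eta[0] == pytest.approx(true_eta, abs=0.05)


class TestObjective:
    def test_matches_linear_mixed_model_closed_form(self):
        # prediction linear in eta with additive error: FOCE is exact and
        # must equal the marginal multivariate-normal -2 log likelihood
        rng = np.random.default_rng(42)
        S, n = 25, 4
        omega2, sigma2, a, b = 0.3, 0.5, 10.0, 2.0
        rows = []
        for s in range(1, S + 1):
            eta = rng.normal(0, math.sqrt(omega2))
            rows.append({"ID": s, "TIME": 0.0, "AMT": 100.0, "RATE": 100.0,
                         "EVID": 1, "MDV": 1, "DV": np.nan})
            for j in range(n):
                rows.append({"ID": s, "TIME": 1.0 + j, "AMT": 0.0,
                             "RATE": 0.0, "EVID": 0, "MDV": 0,
                             "DV": a + b * eta
                             + rng.normal(0, math.sqrt(sigma2))})
        data = EstimationData(pd.DataFrame(rows))

        def pred_fn(etas):
            return a + b * etas[data.obs_subj, 0]

        ofv, _, _ = foce_ofv(pred_fn, data, np.array([[omega2]]), sigma2,
                             kind="additive")
        from scipy.stats import multivariate_normal
        ll = 0.0
        for s in range(S):
            ys = data.obs_y[data.obs_subj == s]
            C = sigma2 * np.eye(len(ys)) \
                + b * b * omega2 * np.ones((len(ys), len(ys)))
            ll += multivariate_normal.logpdf(ys, mean=a * np.ones(len(ys)),
                                             cov=C)
        assert ofv == pytest.approx(-2.0 * ll, abs=1e-4)

    def test_degenerate_omega_reduces_to_weighted_ls(self):
        frame, conc = one_compartment_frame()
        model = PopModel(theta={"CL": 3.0, "V1": 40.0}, omega2={"CL": 0.0},
                         sigma2=0.04, n_compartments=1)
        ofv = foce_objective(model, frame)
        expected = sum((0.0) ** 2 / (0.04 * c * c)
                       + math.log(2 * math.pi * 0.04 * c * c)
                       for c in conc)
        assert ofv == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_subject_relabeling(self, homogeneous_frame):
        model = PopModel(theta=dict(TRUE_2CMT), omega2={"CL": 0.09},
                         sigma2=0.04)
        ofv1 = foce_objective(model, homogeneous_frame)
        relabeled = homogeneous_frame.copy()
        ids = relabeled["ID"].unique()
        mapping = dict(zip(ids, np.roll(1000 + ids, 13)))
        relabeled["ID"] = relabeled["ID"].map(mapping)
        relabeled = relabeled.sort_values(["ID", "TIME"],
                                          kind="stable").reset_index(
                                              drop=True)
        ofv2 = foce_objective(model, relabeled)
        assert ofv1 == pytest.approx(ofv2, abs=1e-6)


class TestPopulationFit:
    def test_nesting_never_raises_ofv(self, homogeneous_frame):
        cfg = FitConfig(compute_se=False, restarts=0)
        base = PopModel(theta=dict(TRUE_2CMT), omega2={"CL": 0.09},
                        sigma2=0.04, fixed={"V1", "Q2", "V2"})
        bf = fit_population(homogeneous_frame, base, cfg)
        full = bf.model.copy()
        full.effects.append(CovariateEffect("CL", "CLCR", "power", 0.0,
                                            75.0))
        ff = fit_population(homogeneous_frame, full, cfg)
        assert ff.ofv <= bf.ofv + 1e-3

    def test_parameter_recovery_mean_bias(self):
        """Fixed effects recovered within 5%, the CLcr exponent within
        10%, and BSV (as %CV) within 25% over repeated simulations."""
        cfg = FitConfig(compute_se=False, restarts=0)
        start = PopModel(theta={"CL": 2.2, "V1": 38.0, "Q2": 5.0,
                                "V2": 60.0},
                         effects=[CovariateEffect("CL", "CLCR", "power",
                                                  0.5, 75.0)],
                         omega2={"CL": 0.15}, sigma2=0.06)
        rows = []
        for rep in range(10):
            frame = simulate_homogeneous(300 + rep, n_subjects=80,
                                         n_samples=5,
                                         sample_window=(96.5, 108.0))
            fit = fit_population(frame, start.copy(), cfg)
            rows.append({"CL": fit.estimates["CL"],
                         "V1": fit.estimates["V1"],
                         "theta": fit.estimates["theta_CLCR"],
                         "cv": fit.estimates["bsv_cv_CL"]})
        means = pd.DataFrame(rows).mean()
        assert means["CL"] == pytest.approx(TRUE_2CMT["CL"], rel=0.05)
        assert means["V1"] == pytest.approx(TRUE_2CMT["V1"], rel=0.05)
        assert means["theta"] == pytest.approx(0.75, rel=0.10)
        assert means["cv"] == pytest.approx(bsv_percent_cv(0.09), rel=0.25)

    def test_bsv_cv_monotone_in_omega2(self):
        grid = np.linspace(0.01, 1.0, 25)
        cvs = [bsv_percent_cv(w) for w in grid]
        assert all(b > a for a, b in zip(cvs, cvs[1:]))

    def test_initial_model_magnitudes(self, homogeneous_frame):
        model = initial_model(homogeneous_frame)
        assert 0.5 < model.theta["CL"] < 15.0
        assert model.theta["V1"] > 0


class TestGof:
    def test_zero_residual_data_has_zero_cwres(self):
        frame, conc = one_compartment_frame()
        # with proportional error the conditional mode matches the data
        # exactly only in the small-sigma limit (the log-variance term
        # carries an eta gradient of order sigma^2)
        model = PopModel(theta={"CL": 3.0, "V1": 40.0},
                         omega2={"CL": 0.04}, sigma2=1e-6,
                         n_compartments=1)
        table = gof_quantities(model, frame)
        assert np.allclose(table["DV"], table["IPRED"], rtol=1e-4)
        assert np.all(np.abs(table["CWRES"]) < 0.01)

    def test_cwres_standardized_under_correct_model(self,
                                                    homogeneous_frame):
        model = PopModel(theta=dict(TRUE_2CMT),
                         effects=[CovariateEffect("CL", "CLCR", "power",
                                                  0.75, 75.0)],
                         omega2={"CL": 0.09}, sigma2=0.04)
        table = gof_quantities(model, homogeneous_frame)
        assert abs(table["CWRES"].mean()) < 0.25
        assert table["CWRES"].std() == pytest.approx(1.0, abs=0.2)
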