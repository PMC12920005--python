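import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import binate as bn
from binate.exceptions import (BinateWarning, EstimationError,
                               PositivityError)

METHODS = ["regression", "ipw", "aipw", "tmle"]


def run_method(data, method, estimand, om=None, pm=None, ipw_form="hajek"):
    if om is None and method != "ipw":
        om = bn.fit_outcome_regression(data)
    if pm is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BinateWarning)
            pm = bn.fit_propensity(data)
    if method == "regression":
        return bn.estimate_regression(data, om, estimand,
                                      propensity_for_se=pm)
    if method == "ipw":
        return bn.estimate_ipw(data, pm, estimand, ipw_form)
    if method == "aipw":
        return bn.estimate_aipw(data, om, pm, estimand)
    return bn.estimate_tmle(data, om, pm, estimand)


def stratified_oracle(data, estimand):
    """Brute-force group-by estimator: per-stratum cell means, averaged
    over the empirical covariate distribution."""
    df = pd.DataFrame({"T": data.T, "Y": data.Y})
    key = [tuple(r) for r in data.W.to_numpy()]
    df["S"] = key
    cells = df.groupby(["S", "T"])["Y"].mean().unstack()
    sizes = df.groupby("S").size() / len(df)
    mu1 = float((cells[1] * sizes).sum())
    mu0 = float((cells[0] * sizes).sum())
    if estimand.name == "BATE":
        return mu1 - mu0
    mut = mu1 if estimand.cab_direction == 1 else mu0
    return mut - float(df["Y"].mean())


def random_dataset(seed, n=120, levels=2):
    rng = np.random.default_rng(seed)
    W = rng.integers(0, levels, n).astype(float)
    T = (rng.random(n) < 0.3 + 0.4 * (W > 0)).astype(int)
    # ensure both arms in every stratum
    for s in range(levels):
        idx = np.flatnonzero(W == s)
        T[idx[0]], T[idx[1]] = 0, 1
    Y = rng.normal(W * 2.0 + T * (1.0 + W), 1.0)
    Wdf = pd.get_dummies(pd.Series(W).astype(int), prefix="W",
                         drop_first=True, dtype=float)
    if Wdf.shape[1] == 0:
        Wdf = pd.DataFrame({"W": W})
    return bn.BinarizedDataset(W=Wdf, T=T, Y=Y)


class TestExactToyValues:
    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("estimand, expected", [
        (bn.BATE, 3.0), (bn.cab(1), 1.5), (bn.cab(0), -1.5)])
    def test_all_methods_match_hand_arithmetic(self, toy4, toy4_models,
                                               method, estimand, expected):
        om, pm = toy4_models
        res = run_method(toy4, method, estimand, om, pm)
        assert res.estimate == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("method", METHODS)
    def test_constant_outcome_gives_zero(self, method):
        data = bn.BinarizedDataset(W=pd.DataFrame({"W": [0.0, 0.0, 1.0, 1.0]}),
                                   T=np.array([0, 1, 0, 1]), Y=np.full(4, 5.0))
        for est in (bn.BATE, bn.cab(1)):
            res = run_method(data, method, est)
            assert res.estimate == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("form", ["ht", "hajek"])
    def test_ipw_forms_on_toy(self, toy4, toy4_models, form):
        _, pm = toy4_models
        res = bn.estimate_ipw(toy4, pm, bn.BATE, form)
        assert res.estimate == pytest.approx(3.0, abs=1e-12)
        res = bn.estimate_ipw(toy4, pm, bn.cab(1), form)
        assert res.estimate == pytest.approx(1.5, abs=1e-12)


class TestEstimatorStructure:
    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bate_composes_from_cab_directions(self, method, seed):
        """BATE = CAB(1) - CAB(0) exactly, for every method."""
        data = random_dataset(seed, levels=3)
        om = bn.fit_outcome_regression(data)
        pm = bn.fit_propensity(data)
        bate = run_method(data, method, bn.BATE, om, pm).estimate
        cab1 = run_method(data, method, bn.cab(1), om, pm).estimate
        cab0 = run_method(data, method, bn.cab(0), om, pm).estimate
        assert bate == pytest.approx(cab1 - cab0, abs=1e-10)

    @pytest.mark.parametrize("method", METHODS)
    def test_complement_region_negates_bate(self, method):
        rng = np.random.default_rng(3)
        n = 150
        W = pd.DataFrame({"W": rng.integers(0, 2, n).astype(float)})
        A = rng.normal(5 + 2 * W["W"].to_numpy(), 1)
        Y = rng.normal(A + 3 * W["W"].to_numpy(), 1)
        obs = bn.ObservationalDataset(W=W, A=A, Y=Y)
        region = bn.BinarizationSpec.at_least(6.0)
        d1 = bn.apply_binarization(obs, region)
        d2 = bn.apply_binarization(obs, region.complement())
        e1 = run_method(d1, method, bn.BATE).estimate
        e2 = run_method(d2, method, bn.BATE).estimate
        assert e1 == pytest.approx(-e2, abs=1e-10)

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("estimand", [bn.BATE, bn.cab(1), bn.cab(0)])
    def test_oracle_equivalence_saturated(self, method, estimand):
        """With discrete covariates and saturated nuisances, every method
        collapses to the brute-force stratified estimator."""
        data = random_dataset(7, n=200, levels=3)
        om = bn.fit_outcome_regression(data, "saturated")
        pm = bn.fit_propensity(data, "stratum")
        res = run_method(data, method, estimand, om, pm)
        assert res.estimate == pytest.approx(
            stratified_oracle(data, estimand), abs=1e-8)

    @pytest.mark.parametrize("method", ["aipw", "tmle"])
    @pytest.mark.parametrize("estimand", [bn.BATE, bn.cab(1)])
    def test_influence_curve_mean_is_zero(self, sim_sample, method, estimand):
        res = run_method(sim_sample, method, estimand)
        assert abs(np.mean(res.ic_values)) < 1e-10
        assert res.se > 0
        assert res.ci[0] <= res.estimate <= res.ci[1]

    @pytest.mark.parametrize("estimand", [bn.BATE, bn.cab(1), bn.cab(0)])
    def test_tmle_solves_eif_equation(self, sim_sample, estimand):
        """After targeting, the empirical mean of the efficient influence
        curve at the TMLE estimate is zero."""
        om = bn.fit_outcome_regression(sim_sample, "additive")  # off-target
        pm = bn.fit_propensity(sim_sample)
        res = bn.estimate_tmle(sim_sample, om, pm, estimand)
        assert abs(np.mean(res.ic_values)) < 1e-8

    def test_tmle_with_zero_residuals_equals_plugin(self, toy4, toy4_models):
        om, pm = toy4_models
        reg = bn.estimate_regression(toy4, om, bn.BATE, propensity_for_se=pm)
        tmle = bn.estimate_tmle(toy4, om, pm, bn.BATE)
        assert tmle.estimate == pytest.approx(reg.estimate, abs=1e-10)

    def test_null_outcome_model_reduces_aipw_to_ht_ipw(self, sim_sample):
        class Zero:
            def fit(self, X, y): pass
            def predict(self, X): return np.zeros(len(X))

        om0 = bn.fit_outcome_regression(sim_sample, learner=Zero())
        pm = bn.fit_propensity(sim_sample)
        for est in (bn.BATE, bn.cab(1)):
            aipw = bn.estimate_aipw(sim_sample, om0, pm, est)
            ht = bn.estimate_ipw(sim_sample, pm, est, "ht")
            assert aipw.estimate == pytest.approx(ht.estimate, abs=1e-10)

    def test_hajek_equals_stratified_with_stratum_propensity(self, sim_sample):
        pm = bn.fit_propensity(sim_sample, "stratum")
        res = bn.estimate_ipw(sim_sample, pm, bn.BATE, "hajek")
        assert res.estimate == pytest.approx(
            stratified_oracle(sim_sample, bn.BATE), abs=1e-8)


class TestPositivityEnforcement:
    def _pm_fixed(self, probs):
        return bn.PropensityModel("fixed", lambda W: np.asarray(probs),
                                  len(probs))

    def test_bate_fails_on_one_sided_propensity(self, toy4):
        pm = self._pm_fixed([0.5, 0.5, 1.0, 1.0])
        with pytest.raises(PositivityError):
            bn.estimate_ipw(toy4, pm, bn.BATE)

    def test_one_way_positivity_logic(self, toy4):
        """pi = 1 somewhere breaks BATE and CAB(0) but not CAB(1), whose
        treated-arm weights 1/pi stay finite; symmetrically pi = 0 only
        breaks estimands that weight the treated arm."""
        pm = self._pm_fixed([0.5, 0.5, 0.9, 1.0])
        with pytest.raises(PositivityError):
            bn.estimate_ipw(toy4, pm, bn.cab(0))
        res = bn.estimate_ipw(toy4, pm, bn.cab(1))
        assert np.isfinite(res.estimate)
        pm0 = self._pm_fixed([0.0, 0.5, 0.5, 0.5])
        with pytest.raises(PositivityError):
            bn.estimate_ipw(toy4, pm0, bn.cab(1))
        assert np.isfinite(bn.estimate_ipw(toy4, pm0, bn.cab(0)).estimate)

    def test_degenerate_cab_is_zero_and_flagged(self):
        data = bn.BinarizedDataset(W=pd.DataFrame({"W": [0.0, 1.0]}),
                                   T=np.array([1, 1]), Y=np.array([2.0, 4.0]))
        res = bn.estimate_regression(data, None, bn.cab(1))
        assert res.estimate == 0.0
        assert "degenerate" in res.config

    def test_error_message_cites_diagnostics(self, toy4):
        pm = self._pm_fixed([0.0, 0.5, 0.5, 0.5])
        with pytest.raises(PositivityError, match="at 0"):
            bn.estimate_aipw(toy4, bn.fit_outcome_regression(toy4), pm,
                             bn.BATE)


@pytest.fixture(scope="module")
def big_sample():
    obs = bn.sample_dgp(100_000, 17)
    return bn.apply_binarization(obs, bn.BinarizationSpec.at_least(6.0))


class TestDoubleRobustness:
    @pytest.mark.parametrize("method", ["aipw", "tmle"])
    @pytest.mark.parametrize("broken", ["outcome", "propensity"])
    def test_single_misspecification_stays_consistent(self, big_sample,
                                                      method, broken):
        """AIPW/TMLE remain near the quadrature truth when exactly one
        nuisance is deliberately misspecified."""
        truths = bn.true_parameter_values()
        om = bn.fit_outcome_regression(
            big_sample, "additive" if broken == "outcome" else "saturated")
        pm = bn.fit_propensity(
            big_sample, "marginal" if broken == "propensity" else "logistic")
        for est, truth in ((bn.BATE, truths.bate), (bn.cab(1), truths.cab1)):
            res = run_method(big_sample, method, est, om, pm)
            assert abs(res.estimate - truth) < 3 * res.se


class TestIntervalsAndBootstrap:
    def test_wald_quantiles(self):
        lo, hi = bn.wald_interval(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    def test_wald_degenerate_and_nested(self):
        assert bn.wald_interval(2.0, 0.0, 0.95) == (2.0, 2.0)
        l95 = bn.wald_interval(1.0, 2.0, 0.95)
        l99 = bn.wald_interval(1.0, 2.0, 0.99)
        assert l99[0] < l95[0] < l95[1] < l99[1]

    def test_bootstrap_reproducible_and_near_ic_se(self, sim_sample):
        cfg = bn.EstimatorConfig(method="aipw", estimand=bn.BATE)
        b1 = bn.bootstrap_se(sim_sample, cfg, B=300, seed=42)
        b2 = bn.bootstrap_se(sim_sample, cfg, B=300, seed=42)
        assert b1.se == b2.se  # bit-for-bit under a fixed seed
        ic_se = bn.fit_and_estimate(sim_sample, cfg).se
        assert abs(b1.se - ic_se) / ic_se < 0.20

    def test_bootstrap_constant_outcome_gives_zero_se(self):
        data = bn.BinarizedDataset(
            W=pd.DataFrame({"W": np.tile([0.0, 0.0, 1.0, 1.0], 10)}),
            T=np.tile([0, 1, 0, 1], 10), Y=np.full(40, 3.0))
        cfg = bn.EstimatorConfig(method="regression", estimand=bn.BATE)
        boot = bn.bootstrap_se(data, cfg, B=50, seed=1)
        assert boot.se == pytest.approx(0.0, abs=1e-12)

    def test_report_serializes(self, toy4, toy4_models):
        om, pm = toy4_models
        res = bn.estimate_aipw(toy4, om, pm, bn.cab(1))
        d = res.to_dict()
        assert d["estimate"] == pytest.approx(1.5)
        assert d["direction"] == 1
        assert "variance_caveat" in d
        res.to_json()  # round-trips without error
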