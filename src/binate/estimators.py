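"""Point estimation and inference for the two binarization estimands.

Estimands
---------
- BATE (binarized average treatment effect):
      psi = E[mu(1, W)] - E[mu(0, W)],
  the contrast between the treated and control truncation policies.
- CAB (causal attributable effect of binarization, direction t):
      psi = E[mu(t, W)] - E[Y],
  the contrast between one truncation policy and the status-quo world.

Algebraically BATE = CAB(1) - CAB(0); every estimator here preserves that
identity exactly because the E[Y] terms cancel and the TMLE fluctuates the
two arms separately.

Estimators
----------
regression plug-in, IPW (Horvitz-Thompson or Hajek), AIPW, and TMLE.
AIPW/TMLE are doubly robust in the point estimate; the influence-curve
variance estimators are consistent only when both nuisances are (this
caveat is carried in every report).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, special, stats

from .data import BinarizedDataset
from .exceptions import (BinateWarning, EstimationError, FluctuationWarning,
                         PositivityError)
from .nuisance import (OutcomeModel, OverlapDiagnostics, PropensityModel,
                       fit_outcome_regression, fit_propensity,
                       overlap_diagnostics)

__all__ = [
    "EstimandSpec",
    "BATE",
    "cab",
    "EstimateResult",
    "EstimatorConfig",
    "estimate_regression",
    "estimate_ipw",
    "estimate_aipw",
    "estimate_tmle",
    "fit_and_estimate",
    "bootstrap_se",
    "BootstrapResult",
    "wald_interval",
]

#: The report metadata caveat on influence-curve variance estimators.
IC_VARIANCE_CAVEAT = ("influence-curve variance estimators are only "
                      "consistent when both the outcome regression and the "
                      "propensity score estimators are consistent")


@dataclass(frozen=True)
class EstimandSpec:
    """Which estimand: the two-policy contrast or the attributable effect."""

    name: str
    cab_direction: Optional[int] = None

    def __post_init__(self):
        if self.name not in ("BATE", "CAB"):
            raise ValueError(f"unknown estimand {self.name!r}")
        if self.name == "CAB":
            if self.cab_direction not in (0, 1):
                raise ValueError("CAB requires cab_direction in {0, 1}")
        elif self.cab_direction is not None:
            raise ValueError("cab_direction is only meaningful for CAB")

    def label(self) -> str:
        if self.name == "BATE":
            return "BATE"
        return f"CAB(t={self.cab_direction})"


BATE = EstimandSpec("BATE")


def cab(direction: int = 1) -> EstimandSpec:
    """The attributable effect of binarization in the given direction."""
    return EstimandSpec("CAB", direction)


@dataclass
class EstimateResult:
    """A point estimate with its uncertainty and provenance."""

    estimand: EstimandSpec
    method: str
    estimate: float
    se: float
    ci: Tuple[float, float]
    level: float
    n: int
    se_method: str = "influence-curve"
    ic_values: Optional[np.ndarray] = None
    diagnostics: Optional[OverlapDiagnostics] = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand.name,
            "direction": self.estimand.cab_direction,
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "se_method": self.se_method,
            "ci": list(self.ci),
            "level": self.level,
            "n": self.n,
            "diagnostics": self.diagnostics.to_dict() if self.diagnostics else None,
            "config": self.config,
            "variance_caveat": IC_VARIANCE_CAVEAT,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def wald_interval(estimate: float, se: float,
                  level: float = 0.95) -> Tuple[float, float]:
    """estimate ± z_{(1+level)/2} * se."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    return (estimate - z * se, estimate + z * se)


def _ic_se(ic: np.ndarray) -> float:
    n = len(ic)
    if n < 2:
        return 0.0
    return float(np.std(ic, ddof=1) / np.sqrt(n))


def _arm_weight(indicator: np.ndarray, p_arm: np.ndarray) -> np.ndarray:
    """indicator / p_arm, with 0/anything = 0 so one-way positivity suffices."""
    out = np.zeros(len(indicator), dtype=float)
    mask = indicator.astype(bool)
    bad = mask & (p_arm <= 0)
    if bad.any():
        raise PositivityError(
            f"{int(bad.sum())} units have zero propensity for their own arm")
    out[mask] = 1.0 / p_arm[mask]
    return out


def _require_overlap(pm: PropensityModel, data: BinarizedDataset,
                     estimand: EstimandSpec
                     ) -> Tuple[np.ndarray, OverlapDiagnostics]:
    diag = overlap_diagnostics(pm, data, estimand)
    if diag.verdict == "fail":
        raise PositivityError(
            f"positivity fails for {diag.estimand}: fitted propensities in "
            f"[{diag.min_propensity:.3g}, {diag.max_propensity:.3g}] "
            f"({diag.n_at_zero} at 0, {diag.n_at_one} at 1)")
    return pm.predict(data.W), diag


def _result(estimand, method, psi, ic, level, n, diag, config,
            se_method="influence-curve", se=None) -> EstimateResult:
    if se is None:
        se = _ic_se(ic)
    return EstimateResult(
        estimand=estimand, method=method, estimate=float(psi), se=se,
        ci=wald_interval(float(psi), se, level), level=level, n=n,
        se_method=se_method, ic_values=ic, diagnostics=diag, config=config)


def estimate_regression(data: BinarizedDataset, om: Optional[OutcomeModel],
                        estimand: EstimandSpec, level: float = 0.95,
                        propensity_for_se: Optional[PropensityModel] = None
                        ) -> EstimateResult:
    """G-computation plug-in: impute both potential outcomes, average.

    The SE is the efficient influence curve evaluated with the fitted
    outcome model and a propensity fitted internally (default logistic)
    unless one is supplied — a documented approximation, labelled in the
    report; bootstrap is the principled alternative.

    Degenerate edge: when every unit already has T = t, the CAB(t) plug-in
    equals the sample mean contrast with itself and is exactly 0; this is
    reported (flagged), not raised.
    """
    T, Y, n = data.T, data.Y, data.n
    cfg = {"outcome_spec": getattr(om, "model_spec", None),
           "se_note": "EIF evaluated at regression nuisances (approximation)"}
    if estimand.name == "CAB" and (T == estimand.cab_direction).all():
        cfg["degenerate"] = (f"all units have T={estimand.cab_direction}; "
                             "CAB plug-in is 0 by construction")
        return _result(estimand, "regression", 0.0, np.zeros(n), level, n,
                       None, cfg)
    if om is None:
        raise EstimationError("an outcome model is required")

    mu1 = om.predict(1, data.W)
    mu0 = om.predict(0, data.W)
    if propensity_for_se is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BinateWarning)
            propensity_for_se = fit_propensity(data)
    p = np.clip(propensity_for_se.predict(data.W), 1e-12, 1 - 1e-12)

    mu_obs = np.where(T == 1, mu1, mu0)
    resid = Y - mu_obs
    if estimand.name == "BATE":
        psi = float(np.mean(mu1 - mu0))
        h = T / p - (1 - T) / (1 - p)
        ic = h * resid + (mu1 - mu0) - psi
    else:
        t = estimand.cab_direction
        mut = mu1 if t == 1 else mu0
        psi = float(np.mean(mut) - np.mean(Y))
        ind = T if t == 1 else 1 - T
        parm = p if t == 1 else 1 - p
        ic = (ind / parm) * (Y - mut) + mut - Y - psi
    return _result(estimand, "regression", psi, ic, level, n, None, cfg)


def estimate_ipw(data: BinarizedDataset, pm: PropensityModel,
                 estimand: EstimandSpec, form: str = "hajek",
                 level: float = 0.95) -> EstimateResult:
    """Inverse probability weighting.

    ``form="hajek"`` (default) normalizes weights within each arm, making
    the estimate invariant to outcome location shifts; ``"ht"`` is the
    unnormalized Horvitz-Thompson form.
    """
    if form not in ("hajek", "ht"):
        raise ValueError(f"unknown IPW form {form!r}")
    T, Y, n = data.T, data.Y, data.n
    p, diag = _require_overlap(pm, data, estimand)
    cfg = {"propensity_spec": pm.model_spec, "ipw_form": form}

    def arm_mean(indicator, p_arm):
        w = _arm_weight(indicator, p_arm)
        if form == "ht":
            m = float(np.mean(w * Y))
            ic = w * Y - m
            return m, ic
        wbar = float(np.mean(w))
        if wbar <= 0:
            raise EstimationError("zero weight-sum in an arm (Hajek)")
        m = float(np.sum(w * Y) / np.sum(w))
        ic = w * (Y - m) / wbar
        return m, ic

    if estimand.name == "BATE":
        m1, ic1 = arm_mean(T, p)
        m0, ic0 = arm_mean(1 - T, 1 - p)
        psi, ic = m1 - m0, ic1 - ic0
    else:
        t = estimand.cab_direction
        ind = T if t == 1 else 1 - T
        parm = p if t == 1 else 1 - p
        mt, ict = arm_mean(ind, parm)
        ybar = float(Y.mean())
        psi, ic = mt - ybar, ict - (Y - ybar)
    return _result(estimand, "ipw", psi, ic, level, n, diag, cfg)


def _aipw_summands(data, om, pm, estimand):
    T, Y = data.T, data.Y
    p, diag = _require_overlap(pm, data, estimand)
    if estimand.name == "BATE":
        mu1, mu0 = om.predict(1, data.W), om.predict(0, data.W)
        s = (_arm_weight(T, p) * (Y - mu1)
             - _arm_weight(1 - T, 1 - p) * (Y - mu0)
             + mu1 - mu0)
    else:
        t = estimand.cab_direction
        mut = om.predict(t, data.W)
        ind = T if t == 1 else 1 - T
        parm = p if t == 1 else 1 - p
        s = _arm_weight(ind, parm) * (Y - mut) + mut - Y
    return s, diag


def estimate_aipw(data: BinarizedDataset, om: OutcomeModel,
                  pm: PropensityModel, estimand: EstimandSpec,
                  level: float = 0.95) -> EstimateResult:
    """Augmented IPW: doubly robust one-step estimator.

    The per-unit influence-curve values are the centered summands; the SE
    is their sample SD over sqrt(n).
    """
    s, diag = _aipw_summands(data, om, pm, estimand)
    psi = float(s.mean())
    ic = s - psi
    cfg = {"outcome_spec": om.model_spec, "propensity_spec": pm.model_spec}
    return _result(estimand, "aipw", psi, ic, level, data.n, diag, cfg)


def _solve_fluctuation(h_obs: np.ndarray, y_s: np.ndarray,
                       logit_mu_obs: np.ndarray) -> float:
    """Solve the logistic fluctuation score sum(H (y - expit(l + eps H))) = 0.

    The score is strictly decreasing in eps, so a bracketed root is unique.
    Raises EstimationError when no finite bracket exists (separation-like
    degeneracy); callers fall back to AIPW.
    """
    def score(eps):
        return float(np.sum(h_obs * (y_s - special.expit(
            logit_mu_obs + eps * h_obs))))

    scale = float(np.sum(np.abs(h_obs)))
    if scale == 0.0:
        return 0.0
    if abs(score(0.0)) <= 1e-12 * scale:
        return 0.0
    lo, hi = -1.0, 1.0
    for _ in range(60):
        if score(lo) * score(hi) < 0:
            return float(optimize.brentq(score, lo, hi, xtol=1e-14))
        lo *= 2.0
        hi *= 2.0
        if hi > 1e6:
            break
    raise EstimationError("fluctuation did not converge (no finite root)")


def estimate_tmle(data: BinarizedDataset, om: OutcomeModel,
                  pm: PropensityModel, estimand: EstimandSpec,
                  level: float = 0.95, guard: float = 1e-6) -> EstimateResult:
    """Targeted maximum likelihood.

    Y is rescaled to [0, 1] using the sample range widened by a relative
    guard band; each arm's outcome regression is fluctuated on the logit
    scale with clever covariate 1{T=t}/pi_t(W), so the empirical mean of
    the efficient influence curve is zero at the final estimate and the
    BATE composes exactly from the two CAB directions. The E[Y] component
    of the CAB needs no targeting — its efficient estimator is the sample
    mean. A non-convergent fluctuation falls back to AIPW with a warning.
    """
    T, Y, n = data.T, data.Y, data.n
    p, diag = _require_overlap(pm, data, estimand)
    cfg = {"outcome_spec": om.model_spec, "propensity_spec": pm.model_spec,
           "fluctuation": "per-arm logistic, clever covariate 1{T=t}/pi_t"}

    ymin, ymax = float(Y.min()), float(Y.max())
    yrange = ymax - ymin
    if yrange <= 0:
        # constant outcome: every contrast is exactly 0
        return _result(estimand, "tmle", 0.0, np.zeros(n), level, n, diag, cfg)
    lo = ymin - guard * yrange
    width = yrange * (1 + 2 * guard)
    y_s = (Y - lo) / width

    def fluctuate_arm(t: int) -> np.ndarray:
        """Return the targeted mu-tilde(t, W) on the [0,1] scale."""
        mu_t = (om.predict(t, data.W) - lo) / width
        mu_t = np.clip(mu_t, guard / 2, 1 - guard / 2)
        ind = (T == t).astype(float)
        p_arm = p if t == 1 else 1 - p
        h_obs = _arm_weight(ind, p_arm)
        eps = _solve_fluctuation(h_obs, y_s, special.logit(mu_t))
        h_pred = _arm_weight(np.ones(n), p_arm)
        return special.expit(special.logit(mu_t) + eps * h_pred)

    try:
        if estimand.name == "BATE":
            mu1_s, mu0_s = fluctuate_arm(1), fluctuate_arm(0)
            psi = float(width * (mu1_s.mean() - mu0_s.mean()))
            mu1, mu0 = mu1_s * width + lo, mu0_s * width + lo
            ic = (_arm_weight(T, p) * (Y - mu1)
                  - _arm_weight(1 - T, 1 - p) * (Y - mu0)
                  + mu1 - mu0 - psi)
        else:
            t = estimand.cab_direction
            mut_s = fluctuate_arm(t)
            mut = mut_s * width + lo
            psi = float(mut.mean() - Y.mean())
            ind = T if t == 1 else 1 - T
            p_arm = p if t == 1 else 1 - p
            ic = _arm_weight(ind, p_arm) * (Y - mut) + mut - Y - psi
    except EstimationError as exc:
        warnings.warn(f"TMLE fluctuation failed ({exc}); falling back to "
                      "AIPW", FluctuationWarning, stacklevel=2)
        res = estimate_aipw(data, om, pm, estimand, level)
        res.method = "tmle"
        res.config = {**cfg, "fallback": "aipw"}
        return res
    return _result(estimand, "tmle", psi, ic, level, n, diag, cfg)


@dataclass(frozen=True)
class EstimatorConfig:
    """Everything needed to re-fit nuisances and recompute one estimate."""

    method: str = "aipw"
    estimand: EstimandSpec = BATE
    outcome_spec: str = "saturated"
    outcome_family: str = "auto"
    propensity_spec: str = "logistic"
    propensity_clip: Optional[Tuple[float, float]] = None
    ipw_form: str = "hajek"
    level: float = 0.95

    def to_dict(self) -> dict:
        d = asdict(self)
        d["estimand"] = self.estimand.label()
        return d


def fit_and_estimate(data: BinarizedDataset,
                     config: EstimatorConfig) -> EstimateResult:
    """Fit the nuisances a method needs, then estimate. One-stop pipeline."""
    method = config.method
    if method not in ("regression", "ipw", "aipw", "tmle"):
        raise EstimationError(f"unknown method {method!r}")
    om = pm = None
    # every method needs the propensity: the weighting methods directly,
    # the regression plug-in only inside its IC-based SE
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BinateWarning)
            pm = fit_propensity(data, config.propensity_spec,
                                clip=config.propensity_clip)
    except EstimationError:
        if method != "regression":
            raise
    if method != "ipw":
        degenerate_cab = (config.estimand.name == "CAB"
                          and (data.T == config.estimand.cab_direction).all())
        if not degenerate_cab:
            om = fit_outcome_regression(data, config.outcome_spec,
                                        family=config.outcome_family)
    if method == "regression":
        res = estimate_regression(data, om, config.estimand, config.level,
                                  propensity_for_se=pm)
    elif method == "ipw":
        res = estimate_ipw(data, pm, config.estimand, config.ipw_form,
                           config.level)
    elif method == "aipw":
        res = estimate_aipw(data, om, pm, config.estimand, config.level)
    else:
        res = estimate_tmle(data, om, pm, config.estimand, config.level)
    res.config = {**config.to_dict(), **res.config}
    return res


@dataclass
class BootstrapResult:
    se: float
    ci: Tuple[float, float]
    level: float
    n_replicates: int
    n_dropped: int
    estimates: np.ndarray

    def to_dict(self) -> dict:
        return {"se": self.se, "ci": list(self.ci), "level": self.level,
                "n_replicates": self.n_replicates,
                "n_dropped": self.n_dropped}


def bootstrap_se(data: BinarizedDataset, config: EstimatorConfig,
                 B: int = 500, seed: int = 0) -> BootstrapResult:
    """Nonparametric bootstrap: resample rows, re-fit nuisances, re-estimate.

    Replicates on which estimation fails (e.g. an empty arm) are dropped
    and counted; more than 10% dropped is an error. The percentile CI uses
    the configured level. Fully reproducible under the seed.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    ests = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", BinateWarning)
                res = fit_and_estimate(data.subset(idx), config)
            ests.append(res.estimate)
        except EstimationError:
            dropped += 1
    if dropped > 0.10 * B:
        raise EstimationError(
            f"{dropped} of {B} bootstrap replicates failed (>10%)")
    ests = np.asarray(ests)
    se = float(np.std(ests, ddof=1)) if len(ests) > 1 else 0.0
    alpha = 1 - config.level
    ci = (float(np.quantile(ests, alpha / 2)),
          float(np.quantile(ests, 1 - alpha / 2)))
    return BootstrapResult(se=se, ci=ci, level=config.level,
                           n_replicates=len(ests), n_dropped=dropped,
                           estimates=ests)
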