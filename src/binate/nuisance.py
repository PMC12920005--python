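"""Nuisance functions: outcome regression and generalized propensity.

Both estimands require at most two nuisance functions of the binarized
data: the outcome regression mu(t, w) = E[Y | T=t, W=w] and the propensity
pi(w) = Pr(T=1 | W=w). They are fitted here behind prediction contracts so
that estimators never see a model object's internals, and any learner
exposing ``fit(X, y)`` / ``predict(X)`` can stand in for the parametric
defaults.

Model specs
-----------
Preset strings:

- ``"saturated"`` (outcome default): intercept + T + W + T:W. With fully
  discrete covariates this is the saturated model, so the regression
  plug-in is consistent by construction.
- ``"additive"``: intercept + T + W (no interaction).
- ``"treatment-only"``: intercept + T.
- ``"logistic"`` (propensity default): logistic regression of T on W.
- ``"stratum"`` (propensity): empirical treated fraction per distinct
  covariate row (the saturated propensity for discrete W).
- ``"marginal"`` (propensity): the overall treated fraction, ignoring W.

Any string containing ``~`` is treated as a patsy formula over the mapped
column names plus ``T`` (e.g. ``"Y ~ T + W + T:W"``); the grammar is
patsy's. Alternatively pass a learner object via ``learner=``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .data import BinarizedDataset
from .exceptions import EstimationError, SeparationWarning

__all__ = [
    "OutcomeModel",
    "PropensityModel",
    "OverlapDiagnostics",
    "fit_outcome_regression",
    "fit_propensity",
    "overlap_diagnostics",
]

SEPARATION_TOL = 1e-8
OVERLAP_TOL = 1e-8


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency (coarse but actionable)
        raise EstimationError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"columns: {list(names)}")


def _preset_design(W: pd.DataFrame, T: np.ndarray, spec: str
                   ) -> Tuple[np.ndarray, list]:
    Wm = W.to_numpy(dtype=float)
    cols = [np.ones(len(T)), T.astype(float)]
    names = ["const", "T"]
    if spec in ("saturated", "additive"):
        for j, c in enumerate(W.columns):
            cols.append(Wm[:, j])
            names.append(str(c))
    if spec == "saturated":
        for j, c in enumerate(W.columns):
            cols.append(T.astype(float) * Wm[:, j])
            names.append(f"T:{c}")
    return np.column_stack(cols), names


class OutcomeModel:
    """Fitted outcome regression with a both-arms prediction contract.

    ``predict(t, W)`` imputes mu-hat(t, w) for every row regardless of the
    arm actually observed — both potential-outcome predictions are always
    available.
    """

    def __init__(self, model_spec: str, predict_fn, n_fit: int,
                 family: str):
        self.model_spec = model_spec
        self._predict = predict_fn
        self.fitted_on_n = n_fit
        self.family = family

    def predict(self, t: int, W: pd.DataFrame) -> np.ndarray:
        if t not in (0, 1):
            raise ValueError("t must be 0 or 1")
        out = np.asarray(self._predict(t, W), dtype=float)
        if not np.all(np.isfinite(out)):
            raise EstimationError("outcome model produced non-finite predictions")
        if len(out) != len(W):
            raise EstimationError("prediction length mismatch")
        return out


def fit_outcome_regression(data: BinarizedDataset,
                           model_spec: str = "saturated",
                           family: str = "auto",
                           learner=None) -> OutcomeModel:
    """Fit mu(t, w) = E[Y | T=t, W=w].

    ``family="auto"`` picks logistic regression when Y is binary and
    ordinary least squares otherwise; ``"gaussian"`` / ``"binomial"``
    force the choice. See module docstring for ``model_spec`` values.
    """
    T, Y, W = data.T, data.Y, data.W
    n1 = int(T.sum())
    if family == "auto":
        family = "binomial" if set(np.unique(Y)) <= {0.0, 1.0} else "gaussian"

    if learner is not None:
        X = np.column_stack([T.astype(float), W.to_numpy(dtype=float)])
        learner.fit(X, Y)

        def predict_learner(t, Wnew):
            Xn = np.column_stack([
                np.full(len(Wnew), float(t)), Wnew.to_numpy(dtype=float)])
            return learner.predict(Xn)

        return OutcomeModel("learner", predict_learner, data.n, family)

    if n1 == 0 or n1 == data.n:
        raise EstimationError(
            "outcome regression with a treatment term requires both arms; "
            f"treated count is {n1} of {data.n}")

    if "~" in model_spec:
        frame = W.copy()
        frame["T"] = T.astype(float)
        frame["Y"] = Y
        ymat, X = patsy.dmatrices(model_spec, frame, return_type="dataframe")
        design_info = X.design_info
        _check_rank(X.to_numpy(), X.columns)
        yvec = ymat.to_numpy().ravel()
        res = _fit_glm(yvec, X.to_numpy(), family)

        def predict_formula(t, Wnew):
            fnew = Wnew.copy()
            fnew["T"] = float(t)
            (Xn,) = patsy.build_design_matrices([design_info], fnew)
            return _glm_predict(res, np.asarray(Xn), family)

        return OutcomeModel(model_spec, predict_formula, data.n, family)

    if model_spec not in ("saturated", "additive", "treatment-only"):
        raise EstimationError(f"unknown outcome model spec {model_spec!r}")
    X, names = _preset_design(W, T, model_spec)
    _check_rank(X, names)
    res = _fit_glm(Y, X, family)

    def predict_preset(t, Wnew):
        Xn, _ = _preset_design(Wnew, np.full(len(Wnew), t), model_spec)
        return _glm_predict(res, Xn, family)

    return OutcomeModel(model_spec, predict_preset, data.n, family)


def _fit_glm(y: np.ndarray, X: np.ndarray, family: str):
    if family == "gaussian":
        return sm.OLS(y, X).fit()
    if family == "binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    raise EstimationError(f"unknown outcome family {family!r}")


def _glm_predict(res, X: np.ndarray, family: str) -> np.ndarray:
    return np.asarray(res.predict(X), dtype=float)


class PropensityModel:
    """Fitted propensity pi(w) = Pr(T=1 | W=w) with optional clipping."""

    def __init__(self, model_spec: str, predict_fn, n_fit: int,
                 clip: Optional[Tuple[float, float]] = None):
        self.model_spec = model_spec
        self._predict = predict_fn
        self.fitted_on_n = n_fit
        self.clip = clip
        self.n_clipped_low = 0
        self.n_clipped_high = 0

    def predict_raw(self, W: pd.DataFrame) -> np.ndarray:
        p = np.asarray(self._predict(W), dtype=float)
        if len(p) != len(W):
            raise EstimationError("propensity prediction length mismatch")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise EstimationError("propensity predictions outside [0, 1]")
        return np.clip(p, 0.0, 1.0)

    def predict(self, W: pd.DataFrame) -> np.ndarray:
        p = self.predict_raw(W)
        if self.clip is not None:
            lo, hi = self.clip
            self.n_clipped_low = int((p < lo).sum())
            self.n_clipped_high = int((p > hi).sum())
            p = np.clip(p, lo, hi)
        return p


def fit_propensity(data: BinarizedDataset,
                   model_spec: str = "logistic",
                   clip: Optional[Tuple[float, float]] = None,
                   learner=None) -> PropensityModel:
    """Fit pi(w) = Pr(T=1 | W=w).

    Perfect separation (fitted probabilities at 0 or 1, including a
    constant-T sample) warns and continues with the finite-iteration fit;
    whether the result is usable is decided per estimand by
    :func:`overlap_diagnostics`. Clipping is off by default.
    """
    T, W = data.T, data.W

    if learner is not None:
        learner.fit(W.to_numpy(dtype=float), T.astype(float))

        def predict_learner(Wnew):
            return learner.predict(Wnew.to_numpy(dtype=float))

        return PropensityModel("learner", predict_learner, data.n, clip)

    if model_spec == "marginal":
        rate = float(T.mean())
        pm = PropensityModel("marginal", lambda Wn: np.full(len(Wn), rate),
                             data.n, clip)
        _warn_if_separated(np.array([rate]))
        return pm

    if T.min() == T.max():
        rate = float(T[0])
        warnings.warn(
            f"T is constant ({T[0]}); propensity is degenerate at {rate}",
            SeparationWarning, stacklevel=2)
        return PropensityModel(model_spec,
                               lambda Wn: np.full(len(Wn), rate),
                               data.n, clip)

    if model_spec == "stratum":
        key = [tuple(row) for row in W.to_numpy(dtype=float)]
        tab = pd.DataFrame({"key": key, "T": T}).groupby("key")["T"].mean()
        rates = tab.to_dict()

        def predict_stratum(Wnew):
            knew = [tuple(row) for row in Wnew.to_numpy(dtype=float)]
            missing = [k for k in knew if k not in rates]
            if missing:
                raise EstimationError(
                    f"stratum propensity has no data for stratum {missing[0]}")
            return np.array([rates[k] for k in knew])

        pm = PropensityModel("stratum", predict_stratum, data.n, clip)
        _warn_if_separated(tab.to_numpy())
        return pm

    if "~" in model_spec:
        (X,) = [patsy.dmatrix(model_spec.split("~")[-1].strip(), W,
                              return_type="dataframe")]
        design_info = X.design_info
        _check_rank(X.to_numpy(), X.columns)
        res = _fit_glm(T.astype(float), X.to_numpy(), "binomial")

        def predict_formula(Wnew):
            (Xn,) = patsy.build_design_matrices([design_info], Wnew)
            return res.predict(np.asarray(Xn))

        pm = PropensityModel(model_spec, predict_formula, data.n, clip)
        _warn_if_separated(pm.predict_raw(W))
        return pm

    if model_spec != "logistic":
        raise EstimationError(f"unknown propensity model spec {model_spec!r}")

    X = np.column_stack([np.ones(data.n), W.to_numpy(dtype=float)])
    _check_rank(X, ["const"] + list(W.columns))
    res = _fit_glm(T.astype(float), X, "binomial")

    def predict_logistic(Wnew):
        Xn = np.column_stack([np.ones(len(Wnew)), Wnew.to_numpy(dtype=float)])
        return res.predict(Xn)

    pm = PropensityModel("logistic", predict_logistic, data.n, clip)
    _warn_if_separated(pm.predict_raw(W))
    return pm


def _warn_if_separated(p: np.ndarray) -> None:
    if np.any(p < SEPARATION_TOL) or np.any(p > 1 - SEPARATION_TOL):
        warnings.warn(
            "fitted propensities reached 0 or 1 (separation); continuing "
            "with finite-iteration estimates — check overlap diagnostics",
            SeparationWarning, stacklevel=3)


@dataclass
class OverlapDiagnostics:
    """Positivity check, specialized to the estimand.

    The binarized ATE needs two-way positivity (0 < pi < 1 everywhere);
    the attributable effect in direction t needs only the t-arm bound.
    """

    estimand: str
    min_propensity: float
    max_propensity: float
    n_at_zero: int
    n_at_one: int
    n_clipped_low: int = 0
    n_clipped_high: int = 0
    verdict: str = "pass"

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand,
            "min_propensity": self.min_propensity,
            "max_propensity": self.max_propensity,
            "n_at_zero": self.n_at_zero,
            "n_at_one": self.n_at_one,
            "n_clipped_low": self.n_clipped_low,
            "n_clipped_high": self.n_clipped_high,
            "verdict": self.verdict,
        }


def overlap_diagnostics(pm: PropensityModel, data: BinarizedDataset,
                        estimand) -> OverlapDiagnostics:
    """Evaluate fitted propensities against the estimand's positivity need.

    ``estimand`` is an :class:`~binate.estimators.EstimandSpec` or one of
    the strings ``"BATE"``, ``"CAB1"``, ``"CAB0"``.
    """
    name, direction = _estimand_key(estimand)
    p = pm.predict(data.W)
    at_zero = int((p <= OVERLAP_TOL).sum())
    at_one = int((p >= 1 - OVERLAP_TOL).sum())
    if name == "BATE":
        ok = at_zero == 0 and at_one == 0
        label = "BATE"
    elif direction == 1:
        ok = at_zero == 0
        label = "CAB(t=1)"
    else:
        ok = at_one == 0
        label = "CAB(t=0)"
    return OverlapDiagnostics(
        estimand=label,
        min_propensity=float(p.min()), max_propensity=float(p.max()),
        n_at_zero=at_zero, n_at_one=at_one,
        n_clipped_low=pm.n_clipped_low, n_clipped_high=pm.n_clipped_high,
        verdict="pass" if ok else "fail")


def _estimand_key(estimand) -> Tuple[str, Optional[int]]:
    if isinstance(estimand, str):
        s = estimand.upper()
        if s == "BATE":
            return "BATE", None
        if s in ("CAB", "CAB1"):
            return "CAB", 1
        if s == "CAB0":
            return "CAB", 0
        raise ValueError(f"unknown estimand {estimand!r}")
    return estimand.name, getattr(estimand, "cab_direction", None)
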