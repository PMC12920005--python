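"""Data model: observational datasets, binarization regions, ingestion.

A continuous exposure ``A`` is recoded into a binary treatment
``T = 1{A in region}`` where the region is a finite union of intervals on
the real line with explicit open/closed endpoints.  Downstream estimators
consume only ``(W, T, Y)``; the original exposure is retained solely for
density diagnostics and never influences an estimate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, DegenerateArmWarning

__all__ = [
    "Interval",
    "BinarizationSpec",
    "ObservationalDataset",
    "BinarizedDataset",
    "ColumnSpec",
    "ValidationReport",
    "load_dataset",
    "apply_binarization",
    "validate_dataset",
]


@dataclass(frozen=True)
class Interval:
    """A real interval with explicitly tagged endpoints.

    ``lower`` may be ``-inf`` and ``upper`` may be ``+inf``; infinite
    endpoints are always treated as open.
    """

    lower: float
    upper: float
    closed_lower: bool = True
    closed_upper: bool = False

    def __post_init__(self):
        lo, hi = float(self.lower), float(self.upper)
        if math.isnan(lo) or math.isnan(hi):
            raise ConfigurationError("interval endpoints must not be NaN")
        if lo > hi:
            raise ConfigurationError(f"empty interval: ({lo}, {hi})")
        if lo == hi and not (self.closed_lower and self.closed_upper):
            raise ConfigurationError(f"degenerate open interval at {lo}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if math.isinf(lo):
            object.__setattr__(self, "closed_lower", False)
        if math.isinf(hi):
            object.__setattr__(self, "closed_upper", False)

    def contains(self, a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        above = a >= self.lower if self.closed_lower else a > self.lower
        below = a <= self.upper if self.closed_upper else a < self.upper
        return above & below

    def __str__(self):
        lb = "[" if self.closed_lower else "("
        ub = "]" if self.closed_upper else ")"
        return f"{lb}{self.lower}, {self.upper}{ub}"


class BinarizationSpec:
    """A finite union of disjoint intervals defining ``T = 1{A in region}``.

    The convention for a single cut-off ``c`` is the region ``[c, inf)``
    (closed on the left), so an exposure exactly at the cut-off is treated.
    Endpoint tags can be overridden by constructing intervals explicitly.
    """

    def __init__(self, intervals: Sequence[Interval]):
        ivs = sorted(intervals, key=lambda iv: (iv.lower, iv.upper))
        if not ivs:
            raise ConfigurationError("binarization region must be non-empty")
        for prev, cur in zip(ivs, ivs[1:]):
            overlap = cur.lower < prev.upper or (
                cur.lower == prev.upper and cur.closed_lower and prev.closed_upper
            )
            if overlap:
                raise ConfigurationError(
                    f"region intervals overlap: {prev} and {cur}"
                )
        self.intervals: tuple[Interval, ...] = tuple(ivs)

    @classmethod
    def at_least(cls, cutoff: float) -> "BinarizationSpec":
        """Region ``[cutoff, inf)``: treated means at or above the cut-off."""
        return cls([Interval(cutoff, math.inf, closed_lower=True)])

    @classmethod
    def below(cls, cutoff: float) -> "BinarizationSpec":
        """Region ``(-inf, cutoff)``: treated means strictly below."""
        return cls([Interval(-math.inf, cutoff, closed_upper=False)])

    @classmethod
    def interval(cls, lower: float, upper: float,
                 closed: str = "left") -> "BinarizationSpec":
        closed_lower = closed in ("left", "both")
        closed_upper = closed in ("right", "both")
        return cls([Interval(lower, upper, closed_lower, closed_upper)])

    def contains(self, a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        out = np.zeros(a.shape, dtype=bool)
        for iv in self.intervals:
            out |= iv.contains(a)
        return out

    def complement(self) -> "BinarizationSpec":
        """The region's complement in R, endpoint tags flipped."""
        out = []
        cursor, cursor_closed = -math.inf, False
        for iv in self.intervals:
            if cursor < iv.lower or (cursor == iv.lower and cursor_closed
                                     and not iv.closed_lower):
                out.append(Interval(cursor, iv.lower,
                                    closed_lower=cursor_closed,
                                    closed_upper=not iv.closed_lower))
            cursor, cursor_closed = iv.upper, not iv.closed_upper
        if cursor < math.inf:
            out.append(Interval(cursor, math.inf, closed_lower=cursor_closed))
        if not out:
            raise ConfigurationError(
                "region covers the whole line; its complement is empty")
        return BinarizationSpec(out)

    def __str__(self):
        return " U ".join(str(iv) for iv in self.intervals)

    def __repr__(self):
        return f"BinarizationSpec({self})"


def _check_columns(df: pd.DataFrame, like: str) -> None:
    bad = df.isna()
    if bad.to_numpy().any():
        col = bad.any(axis=0).idxmax() if isinstance(bad, pd.DataFrame) else like
        row = int(bad[col].idxmax()) if isinstance(bad, pd.DataFrame) else int(bad.idxmax())
        raise DataError(f"missing value in column {col!r} at row {row}")


def _validate_vector(x: pd.Series, name: str) -> np.ndarray:
    if x.isna().any():
        row = int(x.isna().idxmax())
        raise DataError(f"missing value in column {name!r} at row {row}")
    try:
        arr = pd.to_numeric(x).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataError(f"column {name!r} is not numeric: {exc}") from exc
    if not np.all(np.isfinite(arr)):
        row = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise DataError(f"non-finite value in column {name!r} at row {row}")
    return arr


def _encode_covariates(W: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """One-hot encode non-numeric covariate columns, recording the map."""
    encoding: dict[str, list] = {}
    numeric_cols = []
    for col in W.columns:
        if pd.api.types.is_numeric_dtype(W[col]):
            numeric_cols.append(col)
        else:
            encoding[col] = sorted(W[col].astype(str).unique().tolist())
    if not encoding:
        return W.astype(float), {}
    enc = pd.get_dummies(W, columns=list(encoding), drop_first=True, dtype=float)
    return enc.astype(float), encoding


@dataclass
class ObservationalDataset:
    """Observed data O = (W, A, Y) with a continuous exposure."""

    W: pd.DataFrame
    A: np.ndarray
    Y: np.ndarray
    ids: Optional[np.ndarray] = None
    covariate_encoding: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.W)
        if n < 1:
            raise DataError("dataset must contain at least one row")
        if len(self.A) != n or len(self.Y) != n:
            raise DataError("W, A, Y must share the same length")
        _check_columns(self.W, "W")
        if np.isnan(self.A).any() or np.isnan(self.Y).any():
            raise DataError("A and Y must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.W)


@dataclass
class BinarizedDataset:
    """Estimator input (W, T, Y); ``A`` is carried for diagnostics only.

    Estimators read exclusively W, T, and Y — the value of A never enters
    an estimate, because the binarized treatment carries all the exposure
    information the estimands require.
    """

    W: pd.DataFrame
    T: np.ndarray
    Y: np.ndarray
    A: Optional[np.ndarray] = None
    ids: Optional[np.ndarray] = None
    region: Optional[BinarizationSpec] = None
    covariate_encoding: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self):
        self.T = np.asarray(self.T)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.W)
        if n < 1:
            raise DataError("dataset must contain at least one row")
        if len(self.T) != n or len(self.Y) != n:
            raise DataError("W, T, Y must share the same length")
        vals = np.unique(self.T[~pd.isna(self.T)])
        if not np.all(np.isin(vals, [0, 1])):
            raise DataError(f"T must be binary in {{0,1}}; found values {vals}")
        self.T = self.T.astype(int)
        _check_columns(self.W, "W")
        if np.isnan(self.Y).any():
            raise DataError("Y must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.W)

    def subset(self, idx: np.ndarray) -> "BinarizedDataset":
        return BinarizedDataset(
            W=self.W.iloc[idx].reset_index(drop=True),
            T=self.T[idx],
            Y=self.Y[idx],
            A=None if self.A is None else self.A[idx],
            region=self.region,
            covariate_encoding=dict(self.covariate_encoding),
        )


@dataclass(frozen=True)
class ColumnSpec:
    """Maps table columns onto roles. Exactly one of exposure/treatment."""

    covariates: Sequence[str]
    outcome: str
    exposure: Optional[str] = None   # continuous A
    treatment: Optional[str] = None  # pre-binarized T
    ids: Optional[str] = None

    def __post_init__(self):
        if (self.exposure is None) == (self.treatment is None):
            raise ConfigurationError(
                "exactly one of exposure (A) or treatment (T) must be mapped")
        if not self.covariates:
            raise ConfigurationError("at least one covariate column required")


def load_dataset(source, columns: ColumnSpec
                 ) -> Union[ObservationalDataset, BinarizedDataset]:
    """Read a delimited text table and return the typed dataset.

    ``source`` is a path or file handle for an RFC-4180 CSV with a header
    row. Returns :class:`ObservationalDataset` when an exposure column is
    mapped, :class:`BinarizedDataset` when a treatment column is mapped.
    Row order is preserved; missing or unparseable cells are rejected.
    """
    df = pd.read_csv(source)
    wanted = list(columns.covariates) + [columns.outcome]
    wanted.append(columns.exposure or columns.treatment)
    if columns.ids:
        wanted.append(columns.ids)
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"columns {missing} not found; table has {list(df.columns)}")

    W_raw = df[list(columns.covariates)]
    _check_columns(W_raw, "W")
    W, encoding = _encode_covariates(W_raw)
    Y = _validate_vector(df[columns.outcome], columns.outcome)
    ids = df[columns.ids].to_numpy() if columns.ids else None

    if columns.exposure is not None:
        A = _validate_vector(df[columns.exposure], columns.exposure)
        return ObservationalDataset(W=W, A=A, Y=Y, ids=ids,
                                    covariate_encoding=encoding)
    t_raw = df[columns.treatment]
    if t_raw.isna().any():
        row = int(t_raw.isna().idxmax())
        raise DataError(
            f"missing value in column {columns.treatment!r} at row {row}")
    t = _validate_vector(t_raw, columns.treatment)
    bad = ~np.isin(t, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(
            f"column {columns.treatment!r} must be binary; "
            f"row {row} has value {t[row]}")
    return BinarizedDataset(W=W, T=t.astype(int), Y=Y, ids=ids,
                            covariate_encoding=encoding)


def apply_binarization(data: ObservationalDataset,
                       spec: BinarizationSpec) -> BinarizedDataset:
    """Recode the continuous exposure: ``T_i = 1{A_i in region}``.

    Endpoint open/closed tags are honored exactly. No rows are dropped.
    Emits :class:`DegenerateArmWarning` when every unit lands in the same
    arm (BATE estimation will later fail positivity).
    """
    T = spec.contains(data.A).astype(int)
    if T.min() == T.max():
        arm = "control" if T[0] == 1 else "treated"
        warnings.warn(
            f"binarization left the {arm} arm empty (all T = {T[0]})",
            DegenerateArmWarning, stacklevel=2)
    return BinarizedDataset(W=data.W, T=T, Y=data.Y, A=data.A.copy(),
                            ids=data.ids, region=spec,
                            covariate_encoding=dict(data.covariate_encoding))


@dataclass
class ValidationReport:
    """Arm counts and stratum-level overlap warnings; reporting only."""

    n: int
    n_treated: int
    n_control: int
    stratum_counts: dict
    warnings: list

    def to_json(self) -> str:
        return json.dumps({
            "n": self.n,
            "n_treated": self.n_treated,
            "n_control": self.n_control,
            "stratum_counts": {str(k): v for k, v in self.stratum_counts.items()},
            "warnings": self.warnings,
        }, indent=2)


def validate_dataset(data: BinarizedDataset,
                     max_stratum_levels: int = 20) -> ValidationReport:
    """Count arms overall and within discrete covariate strata.

    Covariates with at most ``max_stratum_levels`` distinct values are
    treated as discrete and cross-tabulated against T; a stratum with an
    empty arm yields a warning naming the stratum. Never raises.
    """
    T = data.T
    n1 = int(T.sum())
    n0 = int(data.n - n1)
    warns = []
    if n1 == 0:
        warns.append("empty treated arm (no T=1 rows)")
    if n0 == 0:
        warns.append("empty control arm (no T=0 rows)")
    stratum_counts: dict = {}
    for col in data.W.columns:
        vals = data.W[col]
        levels = vals.unique()
        if len(levels) > max_stratum_levels:
            continue
        for lv in sorted(levels):
            mask = (vals == lv).to_numpy()
            c1 = int(T[mask].sum())
            c0 = int(mask.sum() - c1)
            stratum_counts[(col, lv)] = {"1": c1, "0": c0}
            for arm, c in (("1", c1), ("0", c0)):
                if c == 0 and mask.sum() > 0:
                    warns.append(
                        f"stratum {col}={lv} has no T={arm} rows")
    return ValidationReport(n=data.n, n_treated=n1, n_control=n0,
                            stratum_counts=stratum_counts, warnings=warns)
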