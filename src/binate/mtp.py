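"""Truncation modified treatment policies (MTPs).

Binarizing a continuous exposure at a region 𝒜 is equivalent to contrasting
two stochastic policies: under the "treated" policy the exposure follows its
observed conditional law renormalized onto 𝒜,

    p̃₁(a | w) = 1{a ∈ 𝒜} · p(a | w) / π(w),    π(w) = Pr(A ∈ 𝒜 | W = w),

and under the "control" policy the law is renormalized onto the complement.
Truncation preserves *relative self-selection*: for any a, a′ inside the
region, p̃(a|w)/p̃(a′|w) = p(a|w)/p(a′|w).

This module evaluates, renormalizes, and tabulates these laws for
interpretation and visualization. Estimation never needs them — the
estimators consume only the binarized treatment — so nothing in the
estimators module calls into here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .data import BinarizationSpec
from .exceptions import PositivityError

__all__ = [
    "DiscreteExposureLaw",
    "ContinuousExposureLaw",
    "GaussianExposureLaw",
    "TruncatedExposureLaw",
    "renormalize_discrete",
    "truncate_law",
    "relative_self_selection_check",
    "density_profile",
]

#: π(w) below this is treated as mathematically undefined, not merely a
#: finite-sample overlap problem (those are diagnosed in the nuisance module).
POSITIVITY_TOL = 1e-12

PMF_TOL = 1e-9
DENSITY_TOL = 1e-6


class DiscreteExposureLaw:
    """Conditional pmf of A given W over finite support, per covariate value."""

    kind = "discrete"

    def __init__(self, pmf_by_w: Mapping[object, Mapping[float, float]]):
        self.pmf_by_w = {w: dict(pmf) for w, pmf in pmf_by_w.items()}
        for w, pmf in self.pmf_by_w.items():
            probs = np.array(list(pmf.values()), dtype=float)
            if (probs < 0).any():
                raise ValueError(f"negative pmf value for w={w}")
            if abs(probs.sum() - 1.0) > PMF_TOL:
                raise ValueError(
                    f"pmf for w={w} sums to {probs.sum()}, expected 1")

    def pmf(self, w) -> dict:
        return self.pmf_by_w[w]

    def mass(self, a, w) -> float:
        return self.pmf_by_w[w].get(float(a), 0.0)


class ContinuousExposureLaw:
    """Conditional density of A given W with a finite integration range.

    ``density(a, w)`` must be vectorized in ``a``. The integration range
    (per w) bounds all quadrature; it must capture essentially all mass.
    """

    kind = "continuous"

    def __init__(self, density: Callable[[np.ndarray, object], np.ndarray],
                 integration_range: Union[Tuple[float, float],
                                          Callable[[object], Tuple[float, float]]]):
        self._density = density
        self._range = integration_range

    def density(self, a, w) -> np.ndarray:
        return np.asarray(self._density(np.asarray(a, dtype=float), w))

    def integration_range(self, w) -> Tuple[float, float]:
        if callable(self._range):
            return self._range(w)
        return self._range

    def check_normalization(self, w, tol: float = DENSITY_TOL) -> float:
        lo, hi = self.integration_range(w)
        total, _ = integrate.quad(lambda a: float(self.density(a, w)), lo, hi,
                                  limit=200)
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"density for w={w} integrates to {total}, expected 1")
        return total


class GaussianExposureLaw(ContinuousExposureLaw):
    """A | W = w ~ Normal(mean(w), sd(w)); range mean ± 10 sd."""

    def __init__(self, mean: Callable[[object], float],
                 sd: Union[float, Callable[[object], float]] = 1.0):
        self.mean_fn = mean
        self.sd_fn = sd if callable(sd) else (lambda w, s=float(sd): s)

        def dens(a, w):
            return stats.norm.pdf(a, self.mean_fn(w), self.sd_fn(w))

        def rng(w):
            m, s = self.mean_fn(w), self.sd_fn(w)
            return (m - 10.0 * s, m + 10.0 * s)

        super().__init__(dens, rng)


def _region_segments(region: BinarizationSpec,
                     lo: float, hi: float) -> list[tuple[float, float]]:
    """Clip the region's intervals to [lo, hi] for quadrature."""
    segs = []
    for iv in region.intervals:
        a, b = max(iv.lower, lo), min(iv.upper, hi)
        if a < b:
            segs.append((a, b))
    return segs


def renormalize_discrete(pmf: Mapping[float, float],
                         region) -> dict:
    """Condition a pmf on a region: zero outside, rescaled inside.

    ``region`` may be a set of support values or a :class:`BinarizationSpec`.
    Raises :class:`PositivityError` when the region carries zero mass.
    """
    if isinstance(region, BinarizationSpec):
        member = lambda a: bool(region.contains(a))
    else:
        allowed = set(region)
        member = lambda a: a in allowed
    if not any(member(a) for a in pmf):
        raise PositivityError("region contains no support points")
    total = float(sum(p for a, p in pmf.items() if member(a)))
    if total <= POSITIVITY_TOL:
        raise PositivityError(
            f"region has probability {total}; conditional law undefined")
    return {a: (p / total if member(a) else 0.0) for a, p in pmf.items()}


@dataclass
class TruncatedExposureLaw:
    """The law of A conditional on A ∈ region, per covariate value."""

    base: Union[DiscreteExposureLaw, ContinuousExposureLaw]
    region: BinarizationSpec

    def normalizer(self, w) -> float:
        """π(w) = Pr(A ∈ region | W = w)."""
        if self.base.kind == "discrete":
            pi = float(sum(p for a, p in self.base.pmf(w).items()
                           if bool(self.region.contains(a))))
        else:
            lo, hi = self.base.integration_range(w)
            pi = 0.0
            for a, b in _region_segments(self.region, lo, hi):
                val, _ = integrate.quad(
                    lambda x: float(self.base.density(x, w)), a, b,
                    epsabs=1e-12, epsrel=1e-12, limit=200)
                pi += val
        if pi <= POSITIVITY_TOL:
            raise PositivityError(
                f"Pr(A in region | W={w}) = {pi}; truncated law undefined")
        return pi

    def density(self, a, w) -> np.ndarray:
        """1{a ∈ region} · p(a|w) / π(w)  (continuous base)."""
        pi = self.normalizer(w)
        a = np.asarray(a, dtype=float)
        inside = self.region.contains(a)
        return np.where(inside, self.base.density(a, w) / pi, 0.0)

    def pmf(self, w) -> dict:
        """Renormalized pmf (discrete base)."""
        if self.base.kind != "discrete":
            raise TypeError("pmf() requires a discrete base law")
        return renormalize_discrete(self.base.pmf(w), self.region)

    def mean_outcome(self, fn: Callable[[np.ndarray], np.ndarray], w,
                     epsabs: float = 1e-10) -> float:
        """E[fn(A) | A ∈ region, W = w] by summation or adaptive quadrature."""
        if self.base.kind == "discrete":
            pmf = self.pmf(w)
            return float(sum(p * fn(np.asarray(a)) for a, p in pmf.items()))
        pi = self.normalizer(w)
        lo, hi = self.base.integration_range(w)
        total = 0.0
        for a, b in _region_segments(self.region, lo, hi):
            val, _ = integrate.quad(
                lambda x: float(fn(np.asarray(x)) * self.base.density(x, w)),
                a, b, epsabs=epsabs, limit=400)
            total += val
        return total / pi


def truncate_law(base, region: BinarizationSpec) -> TruncatedExposureLaw:
    """Build the truncated (renormalized) law of A given A ∈ region."""
    return TruncatedExposureLaw(base=base, region=region)


def relative_self_selection_check(law: TruncatedExposureLaw, a, a_prime, w
                                  ) -> Tuple[float, float]:
    """Return (truncated ratio, base ratio) at two points inside the region.

    Their equality is the defining property of the truncation MTP: imposing
    the cut-off rescales, but never reweights, the law inside the region.
    """
    for point in (a, a_prime):
        if not bool(law.region.contains(point)):
            raise ValueError(f"exposure value {point} lies outside the region")
    if law.base.kind == "discrete":
        base_a = law.base.mass(a, w)
        base_ap = law.base.mass(a_prime, w)
        pmf = law.pmf(w)
        trunc_a, trunc_ap = pmf.get(float(a), 0.0), pmf.get(float(a_prime), 0.0)
    else:
        base_a = float(law.base.density(a, w))
        base_ap = float(law.base.density(a_prime, w))
        trunc_a = float(law.density(a, w))
        trunc_ap = float(law.density(a_prime, w))
    if base_ap <= 0.0 or base_a <= 0.0:
        raise ValueError("base law has zero density at a requested point")
    return trunc_a / trunc_ap, base_a / base_ap


def density_profile(base: ContinuousExposureLaw, region: BinarizationSpec,
                    w_values: Sequence, grid: Sequence[float]) -> pd.DataFrame:
    """Tabulate base, treated-policy, and control-policy densities.

    One row per (w, a) with columns ``(w, a, p_base, p_tilde1, p_tilde0)``;
    the treated policy truncates to the region, the control policy to its
    complement. Plotting is left to the caller.
    """
    grid = np.asarray(grid, dtype=float)
    law1 = truncate_law(base, region)
    law0 = truncate_law(base, region.complement())
    rows = []
    for w in w_values:
        lo, hi = base.integration_range(w)
        if grid.min() < lo or grid.max() > hi:
            raise ValueError(
                f"grid exceeds the integration range ({lo}, {hi}) for w={w}")
        p_base = np.asarray(base.density(grid, w), dtype=float)
        p1 = law1.density(grid, w)
        p0 = law0.density(grid, w)
        rows.append(pd.DataFrame({
            "w": w, "a": grid, "p_base": p_base,
            "p_tilde1": p1, "p_tilde0": p0,
        }))
    return pd.concat(rows, ignore_index=True)
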