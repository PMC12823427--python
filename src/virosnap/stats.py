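"""Risk-difference estimation and noninferiority statistics.

The central method is the Miettinen-Nurminen (MN) score interval for a
difference of two binomial proportions: the 100(1-alpha)% confidence bounds
are the values of delta at which

    z(delta) = (p1_hat - p2_hat - delta) / se_tilde(delta)

equals the +/- standard-normal quantile, where ``se_tilde`` uses the
maximum-likelihood estimates of (p1, p2) restricted to p1 - p2 = delta,
inflated by N/(N-1) (the feature distinguishing MN from the otherwise
identical Farrington-Manning interval).  The restricted MLE has a closed-form
trigonometric solution of a cubic; the score statistic is monotone in delta,
so each bound is found by bisection.  Unlike the Wald interval, the MN bounds
are finite and informative even with zero events in one arm.

Stratified analyses pool stratum-specific differences with
Cochran-Mantel-Haenszel weights ``n1k * n2k / (n1k + n2k)`` and solve the
weighted score equation; with a single stratum this reduces exactly to the
unstratified interval.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, norm

BISECTION_TOL = 1e-10


class CiMethod(str, enum.Enum):
    MN_SCORE = "mn_score"
    CMH_MN_SCORE = "cmh_mn_score"
    WALD = "wald"


class Bound(str, enum.Enum):
    LOWER = "lower"
    UPPER = "upper"


@dataclass(frozen=True)
class TwoByTwo:
    """Events/totals for the two arms (arm 1 = long-acting, arm 2 = oral)."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        for x, n in ((self.x1, self.n1), (self.x2, self.n2)):
            if n < 0:
                raise ValueError("totals must be >= 0")
            if not 0 <= x <= n:
                raise ValueError("events must satisfy 0 <= x <= n")

    @property
    def p1(self) -> float:
        return self.x1 / self.n1

    @property
    def p2(self) -> float:
        return self.x2 / self.n2

    @property
    def diff(self) -> float:
        return self.p1 - self.p2


@dataclass(frozen=True)
class StratumCounts:
    label: str
    counts: TwoByTwo


@dataclass(frozen=True)
class DiffCI:
    """Risk-difference point estimate and CI, in percentage points."""

    estimate: float
    lower: float
    upper: float
    alpha: float
    method: CiMethod

    def __post_init__(self) -> None:
        if not self.lower - 1e-9 <= self.estimate <= self.upper + 1e-9:
            raise ValueError("bounds must bracket the estimate")


@dataclass(frozen=True)
class NoninferiorityDecision:
    margin: float  # percentage points, > 0
    bound_used: Bound
    met: bool


@dataclass(frozen=True)
class SampleSizeSpec:
    p1: float
    p2: float
    margin: float
    alpha: float = 0.05  # two-sided
    power: float = 0.90

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0 < p < 1:
                raise ValueError("proportions must be in (0, 1)")
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for reported tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# restricted MLE and score statistic


def _restricted_p2(x1: int, n1: int, x2: int, n2: int, delta: float) -> float:
    """Constrained MLE of p2 under p1 - p2 = delta (closed-form cubic root)."""
    N = n1 + n2
    L3 = N
    L2 = (n1 + 2 * n2) * delta - N - (x1 + x2)
    L1 = (n2 * delta - N - 2 * x2) * delta + (x1 + x2)
    L0 = x2 * delta * (1 - delta)
    q = L2**3 / (27 * L3**3) - L1 * L2 / (6 * L3**2) + L0 / (2 * L3)
    p_inner = L2**2 / (9 * L3**2) - L1 / (3 * L3)
    p_ = math.sqrt(max(p_inner, 0.0))
    if p_ == 0.0:
        return -L2 / (3 * L3)
    a_ = (math.pi + math.acos(min(1.0, max(-1.0, q / p_**3)))) / 3.0
    return 2 * p_ * math.cos(a_) - L2 / (3 * L3)


def mn_score_z(t: TwoByTwo, delta: float, variance_inflation: bool = True) -> float:
    """The MN score statistic at difference ``delta`` (proportion scale)."""
    p2t = min(max(_restricted_p2(t.x1, t.n1, t.x2, t.n2, delta), 0.0), 1.0)
    p1t = min(max(p2t + delta, 0.0), 1.0)
    N = t.n1 + t.n2
    var = p1t * (1 - p1t) / t.n1 + p2t * (1 - p2t) / t.n2
    if variance_inflation:
        var *= N / (N - 1)
    num = t.diff - delta
    if var <= 0.0:
        return math.inf if num > 0 else (-math.inf if num < 0 else 0.0)
    return num / math.sqrt(var)


def mn_score_ci(t: TwoByTwo, alpha: float = 0.05) -> DiffCI:
    """Miettinen-Nurminen score CI for the risk difference, in pp."""
    if t.n1 == 0 or t.n2 == 0:
        raise ValueError("both arms must have at least one participant")
    zc = norm.ppf(1 - alpha / 2)
    d = t.diff
    eps = 1e-12

    def f_lower(delta: float) -> float:
        return mn_score_z(t, delta) - zc

    def f_upper(delta: float) -> float:
        return mn_score_z(t, delta) + zc

    # z is monotone decreasing in delta; lower root lies below the estimate
    lower = brentq(f_lower, -1 + eps, d, xtol=BISECTION_TOL) if f_lower(-1 + eps) > 0 else -1.0
    upper = brentq(f_upper, d, 1 - eps, xtol=BISECTION_TOL) if f_upper(1 - eps) < 0 else 1.0
    return DiffCI(100 * d, 100 * lower, 100 * upper, alpha, CiMethod.MN_SCORE)


def cmh_weights(strata: Sequence[StratumCounts]) -> np.ndarray:
    return np.array([
        s.counts.n1 * s.counts.n2 / (s.counts.n1 + s.counts.n2) for s in strata
    ])


def cmh_mn_z(strata: Sequence[StratumCounts], delta: float) -> float:
    """CMH-weighted MN score statistic at ``delta``."""
    w = cmh_weights(strata)
    w = w / w.sum()
    d_hat = float(sum(wk * s.counts.diff for wk, s in zip(w, strata)))
    var = 0.0
    for wk, s in zip(w, strata):
        t = s.counts
        p2t = min(max(_restricted_p2(t.x1, t.n1, t.x2, t.n2, delta), 0.0), 1.0)
        p1t = min(max(p2t + delta, 0.0), 1.0)
        Nk = t.n1 + t.n2
        var += wk**2 * (p1t * (1 - p1t) / t.n1 + p2t * (1 - p2t) / t.n2) * Nk / (Nk - 1)
    num = d_hat - delta
    if var <= 0.0:
        return math.inf if num > 0 else (-math.inf if num < 0 else 0.0)
    return num / math.sqrt(var)


def cmh_mn_ci(strata: Sequence[StratumCounts], alpha: float = 0.05) -> DiffCI:
    """Stratified (CMH-weighted) MN score CI, in percentage points.

    Strata with an arm entirely missing cannot contribute a difference and
    are excluded with a warning.  With one stratum the result equals
    :func:`mn_score_ci` exactly.
    """
    usable = []
    for s in strata:
        if s.counts.n1 == 0 or s.counts.n2 == 0:
            warnings.warn(f"stratum {s.label!r} has an empty arm; excluded",
                          stacklevel=2)
            continue
        usable.append(s)
    if not usable:
        raise ValueError("no stratum with both arms represented")
    if len(usable) == 1:
        # degenerate stratification: identical to the unstratified interval
        inner = mn_score_ci(usable[0].counts, alpha)
        return DiffCI(inner.estimate, inner.lower, inner.upper, alpha,
                      CiMethod.CMH_MN_SCORE)
    zc = norm.ppf(1 - alpha / 2)
    w = cmh_weights(usable)
    w = w / w.sum()
    d_hat = float(sum(wk * s.counts.diff for wk, s in zip(w, usable)))
    eps = 1e-12

    def f_lower(delta: float) -> float:
        return cmh_mn_z(usable, delta) - zc

    def f_upper(delta: float) -> float:
        return cmh_mn_z(usable, delta) + zc

    lower = brentq(f_lower, -1 + eps, d_hat, xtol=BISECTION_TOL) if f_lower(-1 + eps) > 0 else -1.0
    upper = brentq(f_upper, d_hat, 1 - eps, xtol=BISECTION_TOL) if f_upper(1 - eps) < 0 else 1.0
    return DiffCI(100 * d_hat, 100 * lower, 100 * upper, alpha, CiMethod.CMH_MN_SCORE)


def wald_ci(t: TwoByTwo, alpha: float = 0.05) -> DiffCI:
    """Normal-approximation (Wald) CI for the risk difference, in pp."""
    if t.n1 == 0 or t.n2 == 0:
        raise ValueError("both arms must have at least one participant")
    zc = norm.ppf(1 - alpha / 2)
    se = math.sqrt(t.p1 * (1 - t.p1) / t.n1 + t.p2 * (1 - t.p2) / t.n2)
    d = t.diff
    return DiffCI(100 * d, 100 * (d - zc * se), 100 * (d + zc * se), alpha,
                  CiMethod.WALD)


def homogeneity_test(levels: Sequence[StratumCounts]) -> tuple[float, float, int]:
    """CMH-weighted chi-square test of homogeneity of risk differences.

    The statistic is the weighted sum of squared deviations of level-specific
    risk differences about their CMH-weighted mean, each deviation scaled by
    the level's estimated variance; levels with zero weight or zero estimated
    variance are dropped.  Returns (statistic, p-value, df).
    """
    usable = []
    for s in levels:
        t = s.counts
        if t.n1 == 0 or t.n2 == 0:
            continue
        v = t.p1 * (1 - t.p1) / t.n1 + t.p2 * (1 - t.p2) / t.n2
        if v <= 0:
            continue
        usable.append((s, v))
    if len(usable) < 2:
        raise ValueError("homogeneity test needs >= 2 usable levels")
    w = cmh_weights([s for s, _ in usable])
    w = w / w.sum()
    diffs = np.array([s.counts.diff for s, _ in usable])
    variances = np.array([v for _, v in usable])
    d_bar = float((w * diffs).sum())
    stat = float(((diffs - d_bar) ** 2 / variances).sum())
    df = len(usable) - 1
    return stat, float(chi2.sf(stat, df)), df


def noninferiority_decision(
    ci: DiffCI, margin: float, bound_used: Bound
) -> NoninferiorityDecision:
    """Noninferiority is met when the relevant CI bound stays strictly inside
    the margin: lower bound above ``-margin``, or upper bound below ``margin``
    (all in percentage points)."""
    if margin <= 0:
        raise ValueError("margin must be > 0")
    if bound_used is Bound.LOWER:
        met = ci.lower > -margin
    else:
        met = ci.upper < margin
    return NoninferiorityDecision(margin, bound_used, met)


def ni_sample_size(spec: SampleSizeSpec) -> int:
    """Per-group sample size for a noninferiority comparison of proportions.

    ``ceil((z_{1-alpha/2} + z_{power})^2 * (p1 q1 + p2 q2) / (margin - |p1-p2|)^2)``.
    """
    drift = abs(spec.p1 - spec.p2)
    if spec.margin <= drift:
        raise ValueError("margin must exceed |p1 - p2| (no power otherwise)")
    za = norm.ppf(1 - spec.alpha / 2)
    zb = norm.ppf(spec.power)
    num = (za + zb) ** 2 * (spec.p1 * (1 - spec.p1) + spec.p2 * (1 - spec.p2))
    return math.ceil(num / (spec.margin - drift) ** 2)
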