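"""Exact and classical inference primitives used by the cohort analysis.

Every statistic is implemented from first principles:

* two-sided Fisher exact test for 2x2 tables by complete enumeration of
  the conditional hypergeometric support with integer-exact weights;
* Pearson chi-square (optional Yates continuity correction);
* Wilcoxon signed-rank with the exact null distribution for small
  untied samples and a tie-corrected normal approximation otherwise;
* Kaplan-Meier product-limit estimator and the two-group log-rank test;
* univariate Cox proportional-hazards regression (Breslow ties) by
  safeguarded Newton iteration;
* cohort-median dichotomization and the fixed-precision p-value
  truncation used when reporting association tables.

scipy is used only for chi-square / normal tail probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist

from ctcpanel.errors import DegenerateDataError, RangeError

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "CoxResult",
    "KMCurve",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "wilcoxon_signed_rank",
    "km_estimate",
    "km_median_survival",
    "logrank_test",
    "cox_univariate",
    "cox_score_test",
    "median_split",
    "truncate_p",
]

#: relative tolerance when deciding which tables are "as extreme" as the
#: observed one under the minimum-likelihood two-sided Fisher criterion
_FISHER_RELATIVE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 cross-classification (rows = category levels)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if int(v) != v or v < 0:
                raise RangeError(f"count {name}={v} must be a non-negative integer")
        if self.n < 1:
            raise RangeError("table must hold at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0 + 1e-15:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: log hazard ratio with Wald inference."""

    coef: float
    hazard_ratio: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    n_events: int
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival_prob: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        s = 1.0
        for time, prob in zip(self.event_times, self.survival_prob):
            if time <= t:
                s = prob
            else:
                break
        return s


# ---------------------------------------------------------------------------
# exact tests on counts


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by complete support enumeration.

    Conditional on both margins, cell ``a`` follows a hypergeometric
    law; the two-sided p-value sums the point probabilities of every
    table in the support whose probability does not exceed that of the
    observed table (minimum-likelihood criterion, with a tiny relative
    tolerance guarding against ties broken by rounding). Weights are
    binomial coefficients kept as exact integers, so the sum is exact
    up to the final float conversion.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return TestResult(0.0, 1.0, "fisher_exact", n=table.n, flags=("degenerate_margin",))
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    total = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += w
        # integer-exact "w <= w_obs" plus the relative-tolerance band
        if w <= w_obs or (w - w_obs) * 10**9 <= w_obs * int(_FISHER_RELATIVE_TOL * 10**9 + 0.5):
            num += w
    p = float(Fraction(num, total))
    # odds-ratio style statistic is conventional but the p carries the inference
    stat = float(a * d - b * c)
    return TestResult(stat, min(p, 1.0), "fisher_exact", n=table.n)


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence for a 2x2 table (df = 1)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise DegenerateDataError("chi-square undefined: a margin is zero")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    stat = n * delta**2 / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(stat, 1)) if stat > 0 else 1.0
    return TestResult(
        float(stat), max(min(p, 1.0), np.nextafter(0, 1)),
        "chi_square_yates" if yates else "chi_square", df=1, n=n,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_counts(ranks: list[int]) -> np.ndarray:
    """Null distribution of W+ (counts over 0..sum(ranks)) by the
    generating-function expansion of all 2^n sign assignments."""
    total = sum(ranks)
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(differences, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded. With at most ``exact_max_n``
    non-zero differences the exact two-sided p-value is computed from
    the full sign-assignment distribution on mid-ranks
    (``p = min(1, 2 min(P(W+ <= w), P(W+ >= w)))``); for larger
    samples mid-ranks with the tie-corrected normal approximation are
    used (no continuity correction).
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise DegenerateDataError("no paired differences supplied")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", n=0, flags=("all_zero",))
    mags = np.abs(d)
    order = np.argsort(mags, kind="mergesort")
    sorted_mags = mags[order]
    # mid-ranks
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_mags[j + 1] == sorted_mags[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # doubled mid-ranks are integers, so the generating-function
        # enumeration stays exact even with tied magnitudes
        int_ranks = [int(round(2 * r)) for r in ranks]
        counts = _signed_rank_counts(int_ranks)
        total = 2**n
        w = int(round(2 * w_plus))
        p_le = int(counts[: w + 1].sum())
        p_ge = int(counts[w:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge) / total)
        return TestResult(w_plus, p, "wilcoxon_exact", n=n)
    mean = n * (n + 1) / 4.0
    _, tie_sizes = np.unique(mags, return_counts=True)
    tie_term = float(np.sum(tie_sizes**3 - tie_sizes)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon_normal", n=n, flags=("zero_variance",))
    z = (w_plus - mean) / math.sqrt(var)
    p = float(2.0 * _norm_dist.sf(abs(z)))
    return TestResult(w_plus, max(min(p, 1.0), np.nextafter(0, 1)), "wilcoxon_normal", n=n)


# ---------------------------------------------------------------------------
# survival


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DegenerateDataError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and event flags differ in length")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise RangeError("survival times must be finite and > 0")
    return t, e


def km_estimate(times, event_flags) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time ``t_i`` with ``d_i`` events out of
    ``n_i`` subjects still at risk, ``S`` is multiplied by
    ``1 - d_i/n_i``. Subjects censored at ``t_i`` leave the risk set
    after ``t_i`` (events precede censorings at tied times).
    """
    t, e = _check_surv(times, event_flags)
    order = np.lexsort((~e, t))
    t, e = t[order], e[order]
    n = t.size
    event_times, n_at_risk, n_events, surv = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        ti = t[i]
        at_risk = n - i
        d = 0
        j = i
        while j < n and t[j] == ti:
            d += int(e[j])
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            event_times.append(ti)
            n_at_risk.append(at_risk)
            n_events.append(d)
            surv.append(s)
        i = j
    return KMCurve(
        np.asarray(event_times),
        np.asarray(n_at_risk, dtype=int),
        np.asarray(n_events, dtype=int),
        np.asarray(surv),
    )


def km_median_survival(curve: KMCurve) -> float:
    """Smallest time at which S(t) drops to 0.5 or below; NaN if never."""
    for t, s in zip(curve.event_times, curve.survival_prob):
        if s <= 0.5:
            return float(t)
    return float("nan")


def logrank_test(group_labels, times, event_flags) -> TestResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group 1 are
    compared with the hypergeometric expectation given the pooled
    risk set (ties pooled); the statistic ``(sum O - sum E)^2 / sum V``
    is referred to chi-square with one degree of freedom.
    """
    t, e = _check_surv(times, event_flags)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("group labels must match times in length")
    levels = np.unique(g)
    if levels.size != 2:
        raise DegenerateDataError(f"log-rank needs exactly 2 groups, got {levels.size}")
    in1 = g == levels[0]
    if in1.all() or not in1.any():
        raise DegenerateDataError("one group has zero subjects")
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e]):
        at_risk = t >= ti
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        died = e & (t == ti)
        d_tot = int(died.sum())
        d1 = int((died & in1).sum())
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += (
                d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var <= 0:
        return TestResult(0.0, 1.0, "logrank", df=1, n=t.size, flags=("no_information",))
    stat = o_minus_e**2 / var
    p = float(_chi2_dist.sf(stat, 1))
    return TestResult(float(stat), max(min(p, 1.0), np.nextafter(0, 1)), "logrank", df=1, n=t.size)


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate, Breslow ties)


def _cox_loglik_derivs(beta: float, t, e, x):
    """Breslow log partial likelihood with first and second derivatives."""
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    ts, es, xs = t[order], e[order], x[order]
    ll = grad = info = 0.0
    s0 = s1 = s2 = 0.0  # running risk-set sums of exp(bx), x exp(bx), x^2 exp(bx)
    i = 0
    n = ts.size
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            w = math.exp(beta * xs[j])
            s0 += w
            s1 += xs[j] * w
            s2 += xs[j] ** 2 * w
            j += 1
        ev = es[i:j]
        if ev.any():
            d = int(ev.sum())
            xsum = float(xs[i:j][ev].sum())
            ll += beta * xsum - d * math.log(s0)
            grad += xsum - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        i = j
    return ll, grad, info


def cox_score_test(times, event_flags, covariate) -> TestResult:
    """Score test of beta = 0 in the univariate Cox model.

    On a tie-free binary covariate this equals the log-rank statistic.
    """
    t, e = _check_surv(times, event_flags)
    x = np.asarray(covariate, dtype=float)
    _, u, i0 = _cox_loglik_derivs(0.0, t, e, x)
    if i0 <= 0:
        raise DegenerateDataError("no information in the covariate (flat likelihood)")
    stat = u**2 / i0
    p = float(_chi2_dist.sf(stat, 1))
    return TestResult(float(stat), max(min(p, 1.0), np.nextafter(0, 1)), "cox_score", df=1, n=t.size)


def cox_univariate(
    times,
    event_flags,
    covariate,
    alpha: float = 0.05,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta_bound: float = 15.0,
) -> CoxResult:
    """Fit a one-covariate Cox proportional-hazards model.

    Newton iteration on the Breslow partial likelihood, safeguarded by
    step halving. Monotone likelihood (perfect separation) is detected
    when the coefficient runs away past ``beta_bound``; an infinite
    hazard-ratio sentinel is returned with ``converged=False``.
    """
    t, e = _check_surv(times, event_flags)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate must match times in length")
    n_events = int(e.sum())
    if n_events < 2:
        raise DegenerateDataError("Cox fit needs at least 2 events")
    if np.all(x == x[0]):
        raise DegenerateDataError("covariate is constant (flat likelihood)")
    # scale for numerical conditioning of continuous covariates
    beta = 0.0
    ll, grad, info = _cox_loglik_derivs(beta, t, e, x)
    if info <= 0:
        raise DegenerateDataError("no information in the covariate (flat likelihood)")
    converged = False
    flags: list[str] = []
    for _ in range(max_iter):
        step = grad / info
        new_beta = beta + step
        # safeguard: halve until the likelihood does not decrease
        for _ in range(30):
            new_ll, new_grad, new_info = _cox_loglik_derivs(new_beta, t, e, x)
            if new_ll >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > beta_bound:
            flags.append("monotone_likelihood")
            hr = math.inf if beta > 0 else 0.0
            return CoxResult(
                coef=math.copysign(math.inf, beta), hazard_ratio=hr, se=math.inf,
                ci_low=0.0, ci_high=math.inf, z=math.copysign(math.inf, beta),
                p_value=1.0, n_events=n_events, converged=False, flags=tuple(flags),
            )
        if abs(grad) < tol * max(1.0, abs(ll)):
            converged = True
            break
    if not converged:
        flags.append("max_iter")
    se = 1.0 / math.sqrt(info)
    z = beta / se
    zcrit = float(_norm_dist.ppf(1 - alpha / 2))
    p = float(2.0 * _norm_dist.sf(abs(z)))
    return CoxResult(
        coef=beta,
        hazard_ratio=math.exp(beta),
        se=se,
        ci_low=math.exp(beta - zcrit * se),
        ci_high=math.exp(beta + zcrit * se),
        z=z,
        p_value=max(min(p, 1.0), np.nextafter(0, 1)),
        n_events=n_events,
        converged=converged,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# dichotomization and reporting


def median_split(values) -> np.ndarray:
    """Label each value LOW (<= cohort median) or HIGH (> median).

    The median uses the midpoint-of-order-statistics convention; values
    tied with the median fall in LOW. Missing values stay missing
    (returned as None in an object array).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() == 0:
        raise DegenerateDataError("all values missing")
    if finite.sum() < 2:
        raise DegenerateDataError("median split needs at least 2 non-missing values")
    med = float(np.median(v[finite]))
    if np.unique(v[finite]).size == 1:
        warnings.warn("all values identical: every label is LOW")
    out = np.empty(v.shape, dtype=object)
    out[:] = None
    out[finite & (v > med)] = "HIGH"
    out[finite & (v <= med)] = "LOW"
    return out


def truncate_p(p: float, digits: int = 2) -> float:
    """Truncate (floor) a p-value to ``digits`` decimals for reporting.

    ``p = 1`` is reported as 1. A p of 0.0173 becomes 0.01; 0.5692
    becomes 0.56 (truncation, not rounding).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p == 1.0:
        return 1.0
    scale = 10**digits
    # tiny relative guard so 0.01-like values representable just below
    # their decimal do not floor one bin too low
    return math.floor(p * scale * (1 + 1e-12)) / scale
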