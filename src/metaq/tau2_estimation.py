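"""Point and interval estimators of the between-study variance tau^2.

Point estimators: DerSimonian-Laird (DL), restricted maximum likelihood
(REML), Mandel-Paule (MP), Jackson (J), Welch-type (WT, MD only), corrected
DL (CDL, MD only) and Kulinskaya-Dollinger-Bjorkestol (KDB, SMD only).

Interval estimators: Q-profile (QP), profile likelihood (PL),
Biggerstaff-Jackson (BJ), Jackson (J), WT and KDB.

All Q-profile-type equations are solved by bracketed root finding on tau^2;
Q(tau^2) is continuous, strictly decreasing and convex, so roots are unique.
Negative moment solutions are truncated at zero but the untruncated value is
retained for bias studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .effect_measures import MD, SMD, EffectRecord
from .q_moments import (
    InsufficientStudiesError,
    QMoments,
    chisq_mix_cdf,
    cochran_q,
    generalized_q,
    kdb_expected_q,
    welch_gamma_terms,
    welch_null_moments,
)

__all__ = [
    "Tau2Result",
    "IntervalResult",
    "tau2_dl",
    "tau2_reml",
    "tau2_mp",
    "tau2_jackson",
    "tau2_wt",
    "tau2_cdl",
    "tau2_kdb",
    "ci_q_profile",
    "ci_profile_likelihood",
    "ci_bj",
    "ci_jackson",
    "ci_wt",
    "ci_kdb",
    "tau2_estimate",
    "tau2_interval",
    "POINT_METHODS",
    "INTERVAL_METHODS",
]

_XTOL = 1e-10
_MAX_ITER = 200


@dataclass(frozen=True)
class Tau2Result:
    """A tau^2 point estimate with truncation and convergence bookkeeping."""

    method: str
    estimate: float
    untruncated: float
    converged: bool = True
    iterations: int = 0


@dataclass(frozen=True)
class IntervalResult:
    """A confidence interval for tau^2."""

    lower: float
    upper: float
    level: float
    method: str
    boundary_note: str = "none"


def _check(records: Sequence[EffectRecord]) -> None:
    k = len(records)
    if k < 2:
        raise InsufficientStudiesError("tau^2 estimation needs at least two studies")
    if k == 2:
        warnings.warn(
            "only two studies: tau^2 inference is extremely imprecise and "
            "intervals may be unbounded above",
            RuntimeWarning,
        )


def _arrays(records):
    y = np.array([r.estimate for r in records], float)
    v2 = np.array([r.variance for r in records], float)
    return y, v2


def _bracket_root(f, lo: float = 0.0, hi0: float = 1.0, grow: float = 4.0,
                  max_grow: int = 60):
    """Find the root of a decreasing function of tau^2 by growing the bracket."""
    flo = f(lo)
    if flo <= 0:
        return lo, True
    hi = hi0
    for _ in range(max_grow):
        if f(hi) < 0:
            return optimize.brentq(f, lo, hi, xtol=_XTOL), True
        hi *= grow
    return hi, False


def tau2_dl(records: Sequence[EffectRecord]) -> Tau2Result:
    """DerSimonian-Laird moment estimator.

    tau^2 = max{ (Q(0) - (K-1)) / (W - W2/W), 0 } with w_i = 1/v_i^2.
    """
    _check(records)
    y, v2 = _arrays(records)
    k = len(records)
    w = 1.0 / v2
    denom = w.sum() - (w**2).sum() / w.sum()
    raw = (cochran_q(records, 0.0) - (k - 1)) / denom
    return Tau2Result("DL", max(raw, 0.0), raw)


def tau2_reml(records: Sequence[EffectRecord]) -> Tau2Result:
    """Restricted maximum likelihood estimator via Fisher-scoring fixed point."""
    _check(records)
    y, v2 = _arrays(records)
    tau2 = max(tau2_dl(records).estimate, 0.0)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        w = 1.0 / (v2 + tau2)
        mu = np.sum(w * y) / w.sum()
        num = np.sum(w**2 * ((y - mu) ** 2 - v2)) + np.sum(w**2) / np.sum(w)
        new = max(num / np.sum(w**2), 0.0)
        if abs(new - tau2) <= _XTOL * (1.0 + tau2):
            tau2 = new
            converged = True
            break
        tau2 = new
    if not converged:
        warnings.warn("REML did not converge; returning last iterate", RuntimeWarning)
    return Tau2Result("REML", tau2, tau2, converged, it)


def tau2_mp(records: Sequence[EffectRecord]) -> Tau2Result:
    """Mandel-Paule estimator: the root of Q(tau^2) = K - 1."""
    _check(records)
    k = len(records)
    f = lambda t: cochran_q(records, t) - (k - 1)
    root, ok = _bracket_root(f)
    return Tau2Result("MP", max(root, 0.0), root, ok)


_JACKSON_POWER = 0.5  # weights a_i = 1/v_i (reciprocal standard error)


def _jackson_weights(v2: np.ndarray) -> np.ndarray:
    return v2 ** (-_JACKSON_POWER)


def tau2_jackson(records: Sequence[EffectRecord]) -> Tau2Result:
    """Jackson's moment estimator with reciprocal-standard-error weights.

    Matches the generalized Q statistic Q_a = sum a_i (y_i - ybar_a)^2,
    a_i = 1/v_i, to its expectation under the random-effects model, which is
    linear in tau^2; the solution is truncated at zero.
    """
    _check(records)
    y, v2 = _arrays(records)
    a = _jackson_weights(v2)
    asum = a.sum()
    q_a = generalized_q(y, a)
    e_null = np.sum(a * v2) - np.sum(a**2 * v2) / asum
    slope = asum - np.sum(a**2) / asum
    raw = (q_a - e_null) / slope
    return Tau2Result("J", max(raw, 0.0), raw)


def _wt_expected_q(records, tau2: float) -> QMoments:
    terms = welch_gamma_terms(records, tau2)
    return welch_null_moments(terms, len(records))


def tau2_wt(records: Sequence[EffectRecord]) -> Tau2Result:
    """Welch-type estimator for MD: solves Q(tau^2) = E_WT(Q)(tau^2).

    The corrected expected value is re-evaluated at the current tau^2 (the
    weights and p_i depend on it); the outer fixed point iterates an MP-type
    solve until successive tau^2 values agree.
    """
    _check(records)
    tau2 = tau2_mp(records).estimate
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        target = _wt_expected_q(records, tau2).kappa1
        f = lambda t: cochran_q(records, t) - target
        new, _ = _bracket_root(f)
        new = max(new, 0.0)
        if abs(new - tau2) <= _XTOL * (1.0 + tau2):
            tau2 = new
            converged = True
            break
        tau2 = new
    if not converged:
        warnings.warn("WT iteration did not converge; returning last iterate", RuntimeWarning)
    return Tau2Result("WT", tau2, tau2, converged, it)


def tau2_cdl(records: Sequence[EffectRecord]) -> Tau2Result:
    """Corrected DerSimonian-Laird estimator for MD.

    Replaces K - 1 in the DL numerator with the corrected null mean of Q
    evaluated at tau^2 = 0: kappa1 = K - 1 + 2 sum w_i^2 gamma_i p_i^2.
    """
    _check(records)
    y, v2 = _arrays(records)
    w = 1.0 / v2
    kappa1 = _wt_expected_q(records, 0.0).kappa1
    denom = w.sum() - (w**2).sum() / w.sum()
    raw = (cochran_q(records, 0.0) - kappa1) / denom
    return Tau2Result("CDL", max(raw, 0.0), raw)


def tau2_kdb(records: Sequence[EffectRecord]) -> Tau2Result:
    """Corrected-moment estimator for SMD: root of Q(tau^2) = kappa1.

    kappa1 is the corrected null mean of Q from :func:`kdb_expected_q`; the
    deflation of E[Q] below K - 1 for SMD pushes the estimate above MP's.
    """
    _check(records)
    target = kdb_expected_q(records).kappa1
    f = lambda t: cochran_q(records, t) - target
    root, ok = _bracket_root(f)
    return Tau2Result("KDB", max(root, 0.0), root, ok)


# ---------------------------------------------------------------------------
# Interval estimators
# ---------------------------------------------------------------------------

def _profile_invert(records, q_lo: float, q_hi: float, method: str, level: float):
    """Invert Q(tau^2) against lower/upper reference quantiles."""
    note = "none"
    f_lo = lambda t: cochran_q(records, t) - q_lo
    f_hi = lambda t: cochran_q(records, t) - q_hi
    if f_lo(0.0) <= 0:
        lower = 0.0
        note = "truncated_at_zero"
    else:
        lower, _ = _bracket_root(f_lo)
    if f_hi(0.0) <= 0:
        upper = 0.0
        note = "degenerate_zero"
    else:
        upper, ok = _bracket_root(f_hi)
        if not ok:
            warnings.warn("upper profile limit did not bracket; returning last bound",
                          RuntimeWarning)
    return IntervalResult(lower, upper, level, method, note)


def ci_q_profile(records: Sequence[EffectRecord], level: float = 0.95) -> IntervalResult:
    """Q-profile interval: Q(tau_L^2) = chi2_{K-1;1-a/2}, Q(tau_U^2) = chi2_{K-1;a/2}."""
    _check(records)
    k = len(records)
    alpha = 1.0 - level
    return _profile_invert(
        records,
        stats.chi2.ppf(1 - alpha / 2, k - 1),
        stats.chi2.ppf(alpha / 2, k - 1),
        "QP",
        level,
    )


def _restricted_ll(y, v2, tau2: float) -> float:
    w = 1.0 / (v2 + tau2)
    mu = np.sum(w * y) / w.sum()
    return -0.5 * (
        np.sum(np.log(v2 + tau2)) + np.sum(w * (y - mu) ** 2) + math.log(w.sum())
    )


def _ordinary_pll(y, v2, tau2: float) -> float:
    w = 1.0 / (v2 + tau2)
    mu = np.sum(w * y) / w.sum()
    return -0.5 * (np.sum(np.log(v2 + tau2)) + np.sum(w * (y - mu) ** 2))


def ci_profile_likelihood(
    records: Sequence[EffectRecord],
    level: float = 0.95,
    likelihood: str = "restricted",
) -> IntervalResult:
    """Profile-likelihood interval for tau^2.

    Inverts 2[l(tau_hat^2) - l(tau^2)] <= chi2_{1;level} where l profiles out
    the overall effect at each tau^2.  By default the *restricted* likelihood
    is profiled (the variant that pairs with the REML point estimate);
    ``likelihood="ordinary"`` uses the ordinary profile log-likelihood.
    """
    _check(records)
    y, v2 = _arrays(records)
    ll = _restricted_ll if likelihood == "restricted" else _ordinary_pll
    obj = lambda t: -ll(y, v2, t)
    hi = 4.0 * float(np.max(v2)) * len(records)
    while obj(hi) < obj(hi * 4):  # ensure the maximiser is interior to [0, hi]
        hi *= 4
        if hi > 1e8:
            break
    res = optimize.minimize_scalar(obj, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-12})
    t_hat = float(res.x)
    if obj(0.0) < obj(t_hat):
        t_hat = 0.0
    crit = ll(y, v2, t_hat) - 0.5 * stats.chi2.ppf(level, 1)
    f = lambda t: ll(y, v2, t) - crit
    note = "none"
    if f(0.0) >= 0:
        lower = 0.0
        note = "truncated_at_zero"
    else:
        lower = optimize.brentq(f, 0.0, t_hat, xtol=_XTOL)
    upper_hi = max(t_hat, 1.0)
    for _ in range(60):
        if f(upper_hi) < 0:
            break
        upper_hi *= 4
    else:
        warnings.warn("flat likelihood: upper PL limit not bracketed", RuntimeWarning)
    upper = optimize.brentq(f, t_hat, upper_hi, xtol=_XTOL)
    return IntervalResult(lower, upper, level, "PL", note)


def _gen_q_lambdas(v2: np.ndarray, a: np.ndarray, tau2: float) -> np.ndarray:
    """Eigenvalues of the weighted centring form under the RE model.

    Q_a = y' (diag(a) - a a'/A) y with y ~ N(mu 1, diag(v^2 + tau^2)) is
    distributed as sum lambda_j chi2_1 with lambda_j the nonzero eigenvalues
    of S M S, S = diag(sqrt(v^2 + tau^2)).
    """
    mat = np.diag(a) - np.outer(a, a) / a.sum()
    s = np.sqrt(v2 + tau2)
    lam = np.linalg.eigvalsh(mat * np.outer(s, s))
    return lam[lam > 1e-12 * lam.max()]


def _invert_mixture(records, a: np.ndarray, q_obs: float, level: float, method: str):
    y, v2 = _arrays(records)
    alpha = 1.0 - level

    def cdf_at(tau2: float) -> float:
        return chisq_mix_cdf(_gen_q_lambdas(v2, a, tau2), None, q_obs)

    note = "none"
    f_lo = lambda t: cdf_at(t) - (1 - alpha / 2)
    f_hi = lambda t: cdf_at(t) - alpha / 2
    # cdf_at decreases in tau^2
    if f_lo(0.0) <= 0:
        lower = 0.0
        note = "truncated_at_zero"
    else:
        lower, _ = _bracket_root(f_lo)
    if f_hi(0.0) <= 0:
        upper = 0.0
        note = "degenerate_zero"
    else:
        upper, ok = _bracket_root(f_hi)
        if not ok:
            raise RuntimeError(
                f"{method} interval: mixture CDF root not bracketed for the upper limit"
            )
    return IntervalResult(lower, upper, level, method, note)


def ci_bj(records: Sequence[EffectRecord], level: float = 0.95) -> IntervalResult:
    """Biggerstaff-Jackson interval: inverts the exact distribution of Q(0).

    Under the random-effects model with fixed inverse-variance weights, Q(0)
    is a positive linear combination of chi-square(1) variables whose
    coefficients depend on tau^2; the interval collects tau^2 values for
    which the observed Q is not extreme.
    """
    _check(records)
    y, v2 = _arrays(records)
    a = 1.0 / v2
    return _invert_mixture(records, a, generalized_q(y, a), level, "BJ")


def ci_jackson(records: Sequence[EffectRecord], level: float = 0.95) -> IntervalResult:
    """Jackson's interval: same inversion applied to the generalized Q with a=1/v."""
    _check(records)
    y, v2 = _arrays(records)
    a = _jackson_weights(v2)
    return _invert_mixture(records, a, generalized_q(y, a), level, "J")


def ci_wt(records: Sequence[EffectRecord], level: float = 0.95) -> IntervalResult:
    """Welch-type interval for MD: Q-profile with scaled-F quantiles.

    The matched (c, f2) are re-evaluated at every candidate tau^2, because the
    weights entering the corrected moments depend on tau^2.
    """
    _check(records)
    k = len(records)
    alpha = 1.0 - level
    note = "none"

    def f_gen(p):
        def f(t):
            qm = _wt_expected_q(records, t)
            return cochran_q(records, t) - qm.ppf(p, k)
        return f

    f_lo = f_gen(1 - alpha / 2)
    f_hi = f_gen(alpha / 2)
    if f_lo(0.0) <= 0:
        lower = 0.0
        note = "truncated_at_zero"
    else:
        lower, _ = _bracket_root(f_lo)
    if f_hi(0.0) <= 0:
        upper = 0.0
        note = "degenerate_zero"
    else:
        upper, _ = _bracket_root(f_hi)
    return IntervalResult(lower, upper, level, "WT", note)


def ci_kdb(records: Sequence[EffectRecord], level: float = 0.95) -> IntervalResult:
    """Corrected-moment interval for SMD: Q-profile with scaled chi-square quantiles.

    Uses the moment-matched scaled chi-square from :func:`kdb_expected_q`
    (mean kappa1, variance kappa2) in place of the chi-square with K - 1
    degrees of freedom.  Because kappa2 is well below 2(K-1) for small
    studies, the interval is narrower than the Q-profile interval.
    """
    _check(records)
    k = len(records)
    qm = kdb_expected_q(records)
    alpha = 1.0 - level
    return _profile_invert(
        records, qm.ppf(1 - alpha / 2, k), qm.ppf(alpha / 2, k), "KDB", level
    )


# ---------------------------------------------------------------------------
# Name-based dispatch (used by the CLI and the simulation grid)
# ---------------------------------------------------------------------------

POINT_METHODS = {
    "DL": tau2_dl,
    "REML": tau2_reml,
    "MP": tau2_mp,
    "J": tau2_jackson,
    "WT": tau2_wt,
    "CDL": tau2_cdl,
    "KDB": tau2_kdb,
}

INTERVAL_METHODS = {
    "QP": ci_q_profile,
    "PL": ci_profile_likelihood,
    "BJ": ci_bj,
    "J": ci_jackson,
    "WT": ci_wt,
    "KDB": ci_kdb,
}

_MEASURE_ONLY = {"WT": MD, "CDL": MD, "KDB": SMD}


def _dispatch(table, name: str, records, **kw):
    try:
        fn = table[name]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(table)}") from None
    required = _MEASURE_ONLY.get(name)
    if required is not None and any(r.measure != required for r in records):
        raise ValueError(f"method {name} is defined only for {required} records")
    return fn(records, **kw)


def tau2_estimate(records: Sequence[EffectRecord], method: str) -> Tau2Result:
    """Point estimate of tau^2 by method name (DL, REML, MP, J, WT, CDL, KDB)."""
    return _dispatch(POINT_METHODS, method, records)


def tau2_interval(
    records: Sequence[EffectRecord], method: str, level: float = 0.95
) -> IntervalResult:
    """Confidence interval for tau^2 by method name (QP, PL, BJ, J, WT, KDB)."""
    return _dispatch(INTERVAL_METHODS, method, records, level=level)
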