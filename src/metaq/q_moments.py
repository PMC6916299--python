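"""Cochran's Q, corrected moments of Q, and chi-square mixture CDFs.

Classically Q is referred to a chi-square with K - 1 degrees of freedom, which
treats the estimated within-study variances as known.  For small studies that
approximation fails in measure-specific ways:

* MD — the estimated variances are independent of the estimates, and the null
  moments of Q acquire positive corrections driven by the sampling variance of
  the v_i^2 (Welch-type approximation; a scaled F distribution with matched
  moments replaces the chi-square).
* SMD — Hedges's g and its variance estimator are functionally dependent
  (v^2 = a + b g^2), which *deflates* the null moments of Q.  The corrected
  first two moments are obtained here from a fourth-order expansion of Q in
  the effect estimates with exact noncentral-t moments, and the distribution
  of Q is approximated by a moment-matched scaled chi-square.

The module also provides the CDF of a positive linear combination of
chi-square variables (Ruben's series with an Imhof-integration fallback),
which the Biggerstaff–Jackson and Jackson intervals invert.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, special

from .effect_measures import MD, SMD, EffectRecord, hedges_j

__all__ = [
    "QMoments",
    "GammaTerms",
    "InsufficientStudiesError",
    "cochran_q",
    "generalized_q",
    "welch_gamma_terms",
    "welch_null_moments",
    "match_scaled_f",
    "kdb_expected_q",
    "chisq_mix_cdf",
]

SCALED_F = "SCALED_F"
CHISQ_MOMENT = "CHISQ_MOMENT"
CLASSICAL = "CLASSICAL"


class InsufficientStudiesError(ValueError):
    """Q-based methods need at least two studies."""


@dataclass(frozen=True)
class QMoments:
    """Corrected null moments of Q and the matched approximating distribution.

    ``kappa1``/``kappa2`` are the corrected mean and variance of Q.  For the
    SCALED_F family the approximation is scale_c * F(K-1, df2); for
    CHISQ_MOMENT it is scale_c * chi-square(df2) with scale_c * df2 = kappa1.
    """

    kappa1: float
    kappa2: float
    scale_c: float
    df2: float
    family: str

    def ppf(self, p: float, k: int) -> float:
        """Quantile of the approximating null distribution of Q (K = k studies)."""
        from scipy import stats

        if self.family == SCALED_F:
            return self.scale_c * stats.f.ppf(p, k - 1, self.df2)
        if self.family == CHISQ_MOMENT:
            return self.scale_c * stats.chi2.ppf(p, self.df2)
        return stats.chi2.ppf(p, k - 1)


@dataclass(frozen=True)
class GammaTerms:
    """Per-study ingredients of the Welch-type corrected moments for MD.

    ``gamma`` holds gamma_i = s_T^4/(n_T^2 f_T) + s_C^4/(n_C^2 f_C) (half the
    sampling variance of v_i^2), ``weights`` the w_i at the requested tau^2,
    and ``p`` the complements 1 - w_i/W.
    """

    gamma: np.ndarray
    weights: np.ndarray
    p: np.ndarray


def _as_arrays(records: Sequence[EffectRecord]):
    y = np.array([r.estimate for r in records], dtype=float)
    v2 = np.array([r.variance for r in records], dtype=float)
    return y, v2


def cochran_q(records: Sequence[EffectRecord], tau2: float = 0.0) -> float:
    """Generalized Cochran's Q at a candidate between-study variance.

    Q(tau^2) = sum w_i (y_i - ybar_w)^2 with w_i = 1/(v_i^2 + tau^2) and the
    weighted mean taken with the same weights.  tau^2 = 0 gives the classical
    Q statistic.
    """
    if len(records) < 2:
        raise InsufficientStudiesError("Q needs at least two studies")
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    y, v2 = _as_arrays(records)
    w = 1.0 / (v2 + tau2)
    return generalized_q(y, w)


def generalized_q(estimates: np.ndarray, weights: np.ndarray) -> float:
    """Weighted sum of squared deviations from the weighted mean."""
    estimates = np.asarray(estimates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ybar = np.sum(weights * estimates) / np.sum(weights)
    return float(np.sum(weights * (estimates - ybar) ** 2))


# ---------------------------------------------------------------------------
# Welch-type corrected moments for MD
# ---------------------------------------------------------------------------

def welch_gamma_terms(records: Sequence[EffectRecord], tau2: float = 0.0) -> GammaTerms:
    """gamma_i, w_i(tau^2) and p_i = 1 - w_i/W for MD records.

    gamma_i is evaluated with the sample SDs substituted for the unknown
    population SDs, so records must carry both arm SDs.
    """
    if len(records) < 2:
        raise InsufficientStudiesError("need at least two studies")
    gam = np.empty(len(records))
    for i, r in enumerate(records):
        if r.measure != MD:
            raise ValueError(f"Welch-type moments are defined for MD; study {i} is {r.measure}")
        if not r.has_arm_sds:
            raise ValueError(
                f"study {i} lacks arm SDs; the Welch-type gamma_i cannot be formed"
            )
        f_t, f_c = r.n_treat - 1, r.n_control - 1
        gam[i] = (
            r.arm_sd_treat**4 / (r.n_treat**2 * f_t)
            + r.arm_sd_control**4 / (r.n_control**2 * f_c)
        )
    _, v2 = _as_arrays(records)
    w = 1.0 / (v2 + tau2)
    p = 1.0 - w / w.sum()
    return GammaTerms(gamma=gam, weights=w, p=p)


def welch_null_moments(terms: GammaTerms, k: int) -> QMoments:
    """Corrected null mean and variance of Q for MD, with the matched scaled F.

    kappa1 = K - 1 + 2 sum w_i^2 gamma_i p_i^2
    kappa2 = 2(K - 1) + 14 sum w_i^2 gamma_i p_i^2

    Both corrections share the summand w_i^2 gamma_i p_i^2 and vanish as the
    arm sizes grow, recovering the classical chi-square moments.
    """
    if k < 2:
        raise InsufficientStudiesError("need at least two studies")
    s = float(np.sum(terms.weights**2 * terms.gamma * terms.p**2))
    kappa1 = k - 1 + 2.0 * s
    kappa2 = 2.0 * (k - 1) + 14.0 * s
    c, df2, ok = match_scaled_f(kappa1, kappa2, k)
    if ok:
        return QMoments(kappa1=kappa1, kappa2=kappa2, scale_c=c, df2=df2, family=SCALED_F)
    warnings.warn(
        "no scaled-F solution with df2 > 4; falling back to a chi-square with "
        "df equal to the corrected first moment",
        RuntimeWarning,
    )
    return QMoments(kappa1=kappa1, kappa2=kappa2, scale_c=1.0, df2=kappa1, family=CHISQ_MOMENT)


def match_scaled_f(kappa1: float, kappa2: float, k: int):
    """Solve E[c F(K-1, f2)] = kappa1, Var[c F(K-1, f2)] = kappa2 in closed form.

    The relative variance of an F variable does not involve the scale, so f2
    solves a linear equation; c follows from the mean.  Returns (c, f2, ok);
    ok is False when no solution with f2 > 4 (finite variance) exists.
    """
    if kappa1 <= 0 or kappa2 <= 0:
        raise ValueError("moments must be positive")
    d1 = k - 1
    r = kappa2 / kappa1**2
    denom = r * d1 - 2.0
    if denom <= 0:
        # variance no larger than a chi-square's: effectively infinite df2
        return kappa1, math.inf, False
    f2 = (2.0 * (d1 - 2.0) + 4.0 * r * d1) / denom
    if f2 <= 4.0:
        return kappa1, f2, False
    c = kappa1 * (f2 - 2.0) / f2
    return c, f2, True


# ---------------------------------------------------------------------------
# KDB-style corrected moments for SMD
# ---------------------------------------------------------------------------

_NORMAL_EVEN = (1.0, 0.0, 1.0, 0.0, 3.0, 0.0, 15.0, 0.0, 105.0)  # E[Z^k]


def _nct_raw_moments(m: float, lam: float, kmax: int) -> list[float]:
    """Raw moments E[T^k] of a noncentral t with m df and noncentrality lam."""
    out = []
    for k in range(1, kmax + 1):
        if m <= k:
            raise ValueError(f"moment of order {k} needs m > {k}")
        mz = sum(
            special.comb(k, j) * lam ** (k - j) * _NORMAL_EVEN[j] for j in range(0, k + 1)
        )
        scale = (m / 2.0) ** (k / 2.0) * math.exp(
            special.gammaln((m - k) / 2.0) - special.gammaln(m / 2.0)
        )
        out.append(scale * mz)
    return out


def _g_central_moments(m: float, ntilde: float, delta: float, kmax: int = 6) -> np.ndarray:
    """Central moments mu_2..mu_kmax of Hedges's g at a true effect delta.

    g = J(m) T / sqrt(ntilde) with T noncentral t(m, sqrt(ntilde) delta);
    g is exactly unbiased for delta.  When m is too small for an exact moment
    (m <= order), a normal-theory surrogate built from the lower moments is
    substituted with a warning.
    """
    lam = math.sqrt(ntilde) * delta
    s = hedges_j(m) / math.sqrt(ntilde)
    kavail = min(kmax, int(math.ceil(m)) - 1)
    raw = [s ** (k + 1) * r for k, r in enumerate(_nct_raw_moments(m, lam, kavail))]
    e1 = raw[0]
    mus = {}
    for k in range(2, kavail + 1):
        c = sum(
            special.comb(k, j) * raw[j - 1] * (-e1) ** (k - j) for j in range(1, k + 1)
        ) + (-e1) ** k
        mus[k] = float(c)
    if kavail < kmax:
        warnings.warn(
            f"study with m={m} too small for exact O(1/n) moment terms; using "
            "normal-theory surrogates for the missing orders",
            RuntimeWarning,
        )
        mu2 = mus[2]
        mu3 = mus.get(3, 0.0)
        defaults = {3: 0.0, 4: 3 * mu2**2, 5: 10 * mu2 * mu3, 6: 15 * mu2**3}
        for k in range(max(3, kavail + 1), kmax + 1):
            mus[k] = defaults[k]
    return np.array([mus[k] for k in range(2, kmax + 1)])


def _q_taylor_tensors(g0: np.ndarray, a: np.ndarray, b: np.ndarray, h: float = 0.02):
    """Finite-difference derivative tensors of Q(g) at the point g0.

    Q uses the SMD variance function: w_i(g) = 1/(a_i + b_i g^2).  Returns the
    diagonal and mixed second/third/fourth derivatives needed by the truncated
    moment sums.  Evaluation is batched; cost is O(K^3) Q evaluations.
    """
    k = len(g0)

    def q_batch(gm: np.ndarray) -> np.ndarray:
        w = 1.0 / (a + b * gm**2)
        gb = (w * gm).sum(axis=-1) / w.sum(axis=-1)
        return (w * (gm - gb[..., None]) ** 2).sum(axis=-1)

    base = float(q_batch(g0[None, :])[0])

    # one-coordinate stencils
    pts = np.repeat(g0[None, :], 4 * k, axis=0)
    for i in range(k):
        for jdx, s in enumerate((-2, -1, 1, 2)):
            pts[4 * i + jdx, i] += s * h
    vals = q_batch(pts).reshape(k, 4)
    f_2, f_1, f1, f2 = vals.T
    h_d = (-f2 + 16 * f1 - 30 * base + 16 * f_1 - f_2) / (12 * h**2)
    t_d = (f2 - 2 * f1 + 2 * f_1 - f_2) / (2 * h**3)
    f_d = (f2 - 4 * f1 + 6 * base - 4 * f_1 + f_2) / h**4

    # two-coordinate stencils
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    npair = len(pairs)
    pts = np.repeat(g0[None, :], 12 * npair, axis=0)
    row = 0
    for (i, j) in pairs:
        for si in (-1, 1):
            for sj in (-1, 1):
                pts[row, i] += si * h
                pts[row, j] += sj * h
                row += 1
        for si in (-2, 2):
            for sj in (-1, 1):
                pts[row, i] += si * h
                pts[row, j] += sj * h
                row += 1
        for si in (-1, 1):
            for sj in (-2, 2):
                pts[row, i] += si * h
                pts[row, j] += sj * h
                row += 1
    pv = q_batch(pts).reshape(npair, 12)

    h_od = np.zeros((k, k))
    t_ssr = np.zeros((k, k))  # [s, r] = d^3 Q / dg_s^2 dg_r
    f_ssrr = np.zeros((k, k))
    f_sssr = np.zeros((k, k))  # [s, r] = d^4 Q / dg_s^3 dg_r
    for idx, (i, j) in enumerate(pairs):
        fmm, fmp, fpm, fpp = pv[idx, 0], pv[idx, 1], pv[idx, 2], pv[idx, 3]
        f2mjm, f2mjp, f2pjm, f2pjp = pv[idx, 4], pv[idx, 5], pv[idx, 6], pv[idx, 7]
        fi2mm, fi2mp, fi2pm, fi2pp = pv[idx, 8], pv[idx, 9], pv[idx, 10], pv[idx, 11]
        h_od[i, j] = h_od[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        d2i_jp = (fpp - 2 * f1[j] + fmp) / h**2
        d2i_jm = (fpm - 2 * f_1[j] + fmm) / h**2
        t_ssr[i, j] = (d2i_jp - d2i_jm) / (2 * h)
        d2j_ip = (fpp - 2 * f1[i] + fpm) / h**2
        d2j_im = (fmp - 2 * f_1[i] + fmm) / h**2
        t_ssr[j, i] = (d2j_ip - d2j_im) / (2 * h)
        f_ssrr[i, j] = f_ssrr[j, i] = (
            fpp + fpm + fmp + fmm - 2 * (f1[i] + f_1[i] + f1[j] + f_1[j]) + 4 * base
        ) / h**4
        d3i_jp = (f2pjp - 2 * fpp + 2 * fmp - f2mjp) / (2 * h**3)
        d3i_jm = (f2pjm - 2 * fpm + 2 * fmm - f2mjm) / (2 * h**3)
        f_sssr[i, j] = (d3i_jp - d3i_jm) / (2 * h)
        d3j_ip = (fi2pp - 2 * fpp + 2 * fpm - fi2pm) / (2 * h**3)
        d3j_im = (fi2mp - 2 * fmp + 2 * fmm - fi2mm) / (2 * h**3)
        f_sssr[j, i] = (d3j_ip - d3j_im) / (2 * h)

    # three-coordinate stencils: T_stu and F_{s r u u}
    triples = [
        (i, j, l) for i in range(k) for j in range(i + 1, k) for l in range(j + 1, k)
    ]
    t_stu = np.zeros((k, k, k))
    f_sruu = np.zeros((k, k, k))  # [s, r, u] = d^4 Q / dg_s dg_r dg_u^2, s<r, u distinct
    if triples:
        ntr = len(triples)
        pts = np.repeat(g0[None, :], 8 * ntr, axis=0)
        row = 0
        for (i, j, l) in triples:
            for si in (-1, 1):
                for sj in (-1, 1):
                    for sl in (-1, 1):
                        pts[row, i] += si * h
                        pts[row, j] += sj * h
                        pts[row, l] += sl * h
                        row += 1
        tv = q_batch(pts).reshape(ntr, 2, 2, 2)
        for idx, (i, j, l) in enumerate(triples):
            v = tv[idx]

            def val(sig_i, sig_j, sig_l, v=v):
                return v[(sig_i + 1) // 2, (sig_j + 1) // 2, (sig_l + 1) // 2]

            t3 = (
                val(1, 1, 1) - val(1, 1, -1) - val(1, -1, 1) - val(-1, 1, 1)
                + val(1, -1, -1) + val(-1, 1, -1) + val(-1, -1, 1) - val(-1, -1, -1)
            ) / (8 * h**3)
            for (x, y, z) in ((i, j, l), (i, l, j), (j, l, i), (j, i, l), (l, i, j), (l, j, i)):
                t_stu[x, y, z] = t3
            for (s, r, u) in ((i, j, l), (i, l, j), (j, l, i)):
                def vv(a1, a2, a3, s=s, r=r, u=u):
                    sg = {s: a1, r: a2, u: a3}
                    return val(sg[i], sg[j], sg[l])

                dp = (vv(1, 1, 1) - vv(1, -1, 1) - vv(-1, 1, 1) + vv(-1, -1, 1)) / (4 * h**2)
                dm = (vv(1, 1, -1) - vv(1, -1, -1) - vv(-1, 1, -1) + vv(-1, -1, -1)) / (4 * h**2)
                f4 = (dp - 2 * h_od[s, r] + dm) / h**2
                f_sruu[s, r, u] = f_sruu[r, s, u] = f4
    return {
        "Hd": h_d, "Hod": h_od, "Td": t_d, "Fd": f_d,
        "Tssr": t_ssr, "Fssrr": f_ssrr, "Fsssr": f_sssr,
        "Tstu": t_stu, "Fsruu": f_sruu, "triples": triples,
    }


def _truncated_q_moments(g0, a, b, mu, h: float = 0.02):
    """Truncated mean and variance of Q from the derivative tensors.

    ``mu`` is a (K, 5) array of central moments mu_2..mu_6 per study.  The mean
    keeps every expectation term of the fourth-order Taylor polynomial; the
    variance keeps Var(Q2) + 2Cov(Q2,Q3) + 2Cov(Q2,Q4) + Var(Q3) with moment
    products up to the same order (the O(1/n) family).
    """
    k = len(g0)
    t = _q_taylor_tensors(np.asarray(g0, float), np.asarray(a, float), np.asarray(b, float), h)
    h_d, h_od, t_d, f_d = t["Hd"], t["Hod"], t["Td"], t["Fd"]
    t_ssr, f_ssrr, f_sssr = t["Tssr"], t["Fssrr"], t["Fsssr"]
    t_stu, f_sruu = t["Tstu"], t["Fsruu"]
    mu2, mu3, mu4, mu5, mu6 = np.asarray(mu, float).T

    kappa1 = (
        0.5 * np.sum(h_d * mu2)
        + np.sum(t_d * mu3) / 6.0
        + np.sum(f_d * mu4) / 24.0
        + 0.25 * sum(
            f_ssrr[i, j] * mu2[i] * mu2[j] for i in range(k) for j in range(i + 1, k)
        )
    )

    # Var(Q2)
    kappa2 = 0.25 * np.sum(h_d**2 * (mu4 - mu2**2))
    off = h_od**2 * np.outer(mu2, mu2)
    kappa2 += 0.5 * (off.sum() - np.trace(off))

    # 2 Cov(Q2, Q3)
    c23 = np.sum(h_d * t_d * (mu5 - mu2 * mu3))
    for s in range(k):
        for r in range(k):
            if r == s:
                continue
            c23 += 3.0 * h_d[s] * t_ssr[r, s] * mu3[s] * mu2[r]
            c23 += 6.0 * h_od[s, r] * t_ssr[s, r] * mu3[s] * mu2[r]
    kappa2 += c23 / 6.0

    # 2 Cov(Q2, Q4)
    c24 = np.sum(h_d * f_d * (mu6 - mu2 * mu4))
    for s in range(k):
        for r in range(k):
            if r == s:
                continue
            c24 += h_d[s] * (
                6.0 * f_ssrr[s, r] * (mu4[s] - mu2[s] ** 2) * mu2[r]
                + 4.0 * f_sssr[r, s] * mu3[s] * mu3[r]
            )
            c24 += h_od[s, r] * (
                4.0 * f_sssr[r, s] * mu2[s] * mu4[r]
                + 4.0 * f_sssr[s, r] * mu4[s] * mu2[r]
                + 6.0 * f_ssrr[s, r] * mu3[s] * mu3[r]
            )
    for (i, j, l) in t["triples"]:
        for (s, r, u) in ((i, j, l), (i, l, j), (j, l, i)):
            c24 += 2.0 * 12.0 * h_od[s, r] * f_sruu[s, r, u] * mu2[s] * mu2[r] * mu2[u]
    kappa2 += c24 / 24.0

    # Var(Q3)
    v33 = np.sum(t_d**2 * (mu6 - mu3**2))
    for s in range(k):
        for r in range(k):
            if r == s:
                continue
            v33 += 6.0 * t_d[s] * t_ssr[r, s] * mu4[s] * mu2[r]
            v33 += 9.0 * t_ssr[s, r] ** 2 * mu4[s] * mu2[r]
            v33 += 9.0 * t_ssr[s, r] * t_ssr[r, s] * mu3[s] * mu3[r]
    for ai in range(k):
        for bi in range(k):
            if bi == ai:
                continue
            for ci in range(k):
                if ci == ai or ci == bi:
                    continue
                v33 += 9.0 * t_ssr[ai, ci] * t_ssr[bi, ci] * mu2[ai] * mu2[bi] * mu2[ci]
    for (i, j, l) in t["triples"]:
        v33 += 36.0 * t_stu[i, j, l] ** 2 * mu2[i] * mu2[j] * mu2[l]
    kappa2 += v33 / 36.0

    return float(kappa1), float(kappa2)


def kdb_expected_q(
    records: Sequence[EffectRecord], delta: Optional[float] = None
) -> QMoments:
    """Corrected null moments of Q for SMD with a matched scaled chi-square.

    The null model sets a common true effect delta (estimated by the
    inverse-variance weighted mean unless supplied) and treats each g_i as a
    scaled noncentral t variable whose variance estimator is the deterministic
    function v^2(g) = a + b g^2 of the estimate itself.  The corrected mean
    kappa1 and variance kappa2 of Q then follow from a fourth-order expansion
    of Q about the homogeneous point; both corrections are negative for
    nontrivial delta, which is why the classical chi-square overstates E[Q]
    for SMD and the DerSimonian-Laird estimator underestimates tau^2.
    """
    if len(records) < 2:
        raise InsufficientStudiesError("need at least two studies")
    k = len(records)
    for r in records:
        if r.measure != SMD:
            raise ValueError("KDB corrected moments are defined for SMD records")
    y, v2 = _as_arrays(records)
    if delta is None:
        w = 1.0 / v2
        delta = float(np.sum(w * y) / w.sum())
    n_t = np.array([r.n_treat for r in records], float)
    n_c = np.array([r.n_control for r in records], float)
    ntilde = n_t * n_c / (n_t + n_c)
    m = n_t + n_c - 2.0
    j = np.array([hedges_j(mi) for mi in m])
    a = 1.0 / ntilde
    b = 1.0 - (m - 2.0) / (m * j**2)
    mu = np.array([_g_central_moments(m[i], ntilde[i], delta) for i in range(k)])
    g0 = np.full(k, delta)
    kappa1, kappa2 = _truncated_q_moments(g0, a, b, mu)
    if kappa1 <= 0 or kappa2 <= 0:
        warnings.warn(
            "corrected moments of Q degenerate (very small studies); "
            "falling back to the classical chi-square moments",
            RuntimeWarning,
        )
        return QMoments(float(k - 1), 2.0 * (k - 1), 1.0, float(k - 1), CLASSICAL)
    c = kappa2 / (2.0 * kappa1)
    df = 2.0 * kappa1**2 / kappa2
    return QMoments(kappa1=kappa1, kappa2=kappa2, scale_c=c, df2=df, family=CHISQ_MOMENT)


# ---------------------------------------------------------------------------
# CDF of positive linear combinations of chi-squares
# ---------------------------------------------------------------------------

def _ruben_cdf(coeffs: np.ndarray, dfs: np.ndarray, x: float, maxit: int = 5000,
               eps: float = 1e-11) -> Optional[float]:
    """Ruben's chi-square series for P(sum lambda_j chi2_{nu_j} <= x).

    Expands the distribution in central chi-square CDFs with a common scale
    beta; returns None if the series fails to converge within ``maxit`` terms.
    """
    from scipy import stats

    lam = np.asarray(coeffs, float)
    nu = np.asarray(dfs, float)
    n = nu.sum()
    lmin, lmax = lam.min(), lam.max()
    beta = 2.0 * lmin * lmax / (lmin + lmax)
    r = 1.0 - beta / lam
    # mixing coefficients a_k via the standard recursion
    d = np.empty(maxit)
    a = np.empty(maxit)
    a[0] = math.exp(0.5 * np.sum(nu * np.log(beta / lam)))
    if a[0] == 0.0:
        return None
    total = a[0] * stats.chi2.cdf(x / beta, n)
    partial = a[0]
    for k in range(1, maxit):
        d[k - 1] = 0.5 * np.sum(nu * r**k)
        a[k] = np.sum(d[:k][::-1] * a[:k]) / k
        term = a[k] * stats.chi2.cdf(x / beta, n + 2 * k)
        total += term
        partial += a[k]
        if 1.0 - partial < eps and term < eps:
            return float(min(max(total, 0.0), 1.0))
    return None


def _imhof_cdf(coeffs: np.ndarray, dfs: np.ndarray, x: float) -> float:
    """Imhof's integral for P(sum lambda_j chi2_{nu_j} <= x)."""
    lam = np.asarray(coeffs, float)
    nu = np.asarray(dfs, float)

    def integrand(u):
        theta = 0.5 * np.sum(nu * np.arctan(lam * u)) - 0.5 * x * u
        rho = math.exp(0.25 * np.sum(nu * np.log1p((lam * u) ** 2)))
        return math.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        # the oscillatory tail triggers benign slow-convergence warnings
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=2000,
                                epsabs=1e-12, epsrel=1e-10)
    return float(min(max(0.5 - val / math.pi, 0.0), 1.0))


def chisq_mix_cdf(coeffs, dfs=None, x: float = 0.0, method: str = "auto") -> float:
    """P(sum_j lambda_j chi2_{nu_j} <= x) for positive coefficients.

    Ruben's series is tried first (absolute accuracy ~1e-10 when it
    converges); Imhof's oscillatory integral is the fallback.  ``dfs``
    defaults to all ones.
    """
    lam = np.asarray(coeffs, dtype=float)
    if dfs is None:
        dfs = np.ones_like(lam)
    nu = np.asarray(dfs, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("all coefficients must be positive")
    if x <= 0:
        return 0.0
    if method == "imhof":
        return _imhof_cdf(lam, nu, x)
    res = _ruben_cdf(lam, nu, x)
    if method == "ruben":
        if res is None:
            raise RuntimeError("Ruben series failed to converge")
        return res
    return res if res is not None else _imhof_cdf(lam, nu, x)
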