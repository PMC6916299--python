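"""Cochran's Q, corrected moments (Welch-type and SMD), chi-square mixtures."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from metaq import (
    EffectRecord,
    chisq_mix_cdf,
    cochran_q,
    hedges_j,
    kdb_expected_q,
    match_scaled_f,
    welch_gamma_terms,
    welch_null_moments,
)
from metaq.q_moments import (
    InsufficientStudiesError,
    _g_central_moments,
    _q_taylor_tensors,
    _truncated_q_moments,
)


def _md(y, v, n_t=20, n_c=20, sd_t=1.0, sd_c=1.0):
    return EffectRecord(y, v, n_t, n_c, "MD", sd_t, sd_c)


def _smd(y, v, n_t=20, n_c=20):
    return EffectRecord(y, v, n_t, n_c, "SMD")


class TestCochranQ:
    def test_degenerate_equal_estimates(self):
        recs = [_md(1.0, v) for v in (0.1, 0.2, 0.3)]
        assert cochran_q(recs) == pytest.approx(0.0, abs=1e-12)

    def test_two_study_closed_form(self):
        r1, r2 = _md(1.2, 0.3), _md(0.1, 0.5)
        for tau2 in (0.0, 0.4):
            w1, w2 = 1 / (0.3 + tau2), 1 / (0.5 + tau2)
            expected = (1.2 - 0.1) ** 2 * w1 * w2 / (w1 + w2)
            assert cochran_q([r1, r2], tau2) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_on_example(self, ocd_records):
        qs = [cochran_q(ocd_records, t) for t in np.arange(0.0, 1.01, 0.1)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_shift_invariance_and_scaling(self, md_records):
        q0 = cochran_q(md_records, 0.2)
        shifted = [
            EffectRecord(r.estimate + 3.0, r.variance, r.n_treat, r.n_control, "MD",
                         r.arm_sd_treat, r.arm_sd_control)
            for r in md_records
        ]
        assert cochran_q(shifted, 0.2) == pytest.approx(q0, rel=1e-12)
        c = 2.5
        scaled = [
            EffectRecord(c * r.estimate, c**2 * r.variance, r.n_treat, r.n_control, "MD",
                         r.arm_sd_treat, r.arm_sd_control)
            for r in md_records
        ]
        assert cochran_q(scaled, c**2 * 0.2) == pytest.approx(q0, rel=1e-12)

    def test_insufficient_studies(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([_md(1.0, 0.1)])


class TestWelchGamma:
    def test_symmetric_closed_form(self):
        # equal arms of size m with unit SDs: gamma = 2 / (m^2 (m-1))
        m = 25
        rec = _md(0.0, 2.0 / m, n_t=m, n_c=m, sd_t=1.0, sd_c=1.0)
        terms = welch_gamma_terms([rec, rec])
        assert terms.gamma[0] == pytest.approx(2.0 / (m**2 * (m - 1)), abs=1e-15)

    def test_positive_and_vanishing(self):
        small = welch_gamma_terms([_md(0, 0.1, 10, 10), _md(0, 0.1, 10, 10)])
        big = welch_gamma_terms([_md(0, 0.1, 10**5, 10**5), _md(0, 0.1, 10**5, 10**5)])
        assert np.all(small.gamma > 0)
        assert np.all(big.gamma < 1e-12)

    def test_against_direct_formula(self, md_records):
        terms = welch_gamma_terms(md_records, tau2=0.15)
        for i, r in enumerate(md_records):
            direct = (
                r.arm_sd_treat**4 / (r.n_treat**2 * (r.n_treat - 1))
                + r.arm_sd_control**4 / (r.n_control**2 * (r.n_control - 1))
            )
            assert terms.gamma[i] == pytest.approx(direct, abs=1e-14)
            assert terms.weights[i] == pytest.approx(1 / (r.variance + 0.15), abs=1e-14)
        assert np.sum(1 - terms.p) == pytest.approx(1.0, abs=1e-12)

    def test_requires_arm_sds(self):
        bare = EffectRecord(0.3, 0.2, 15, 15, "MD")
        with pytest.raises(ValueError, match="arm SD"):
            welch_gamma_terms([bare, bare])


class TestWelchNullMoments:
    def test_classical_limit(self, big_md_records):
        terms = welch_gamma_terms(big_md_records)
        qm = welch_null_moments(terms, len(big_md_records))
        k = len(big_md_records)
        assert qm.kappa1 == pytest.approx(k - 1, abs=1e-6)
        assert qm.kappa2 == pytest.approx(2 * (k - 1), abs=1e-6)

    def test_corrections_positive(self, md_records):
        terms = welch_gamma_terms(md_records)
        qm = welch_null_moments(terms, len(md_records))
        k = len(md_records)
        assert qm.kappa1 > k - 1
        assert qm.kappa2 > 2 * (k - 1)

    def test_moments_match_null_simulation(self):
        """Transcription guard: kappa1/kappa2 vs 200k null MD simulations."""
        rng = np.random.default_rng(99)
        n_t = np.array([8, 12, 6])
        n_c = np.array([10, 6, 9])
        s2_t = np.array([1.0, 2.0, 1.5])
        s2_c = np.array([1.5, 1.0, 0.5])
        reps = 200_000
        st_ = s2_t * rng.chisquare(n_t - 1, (reps, 3)) / (n_t - 1)
        sc_ = s2_c * rng.chisquare(n_c - 1, (reps, 3)) / (n_c - 1)
        y = rng.normal(0.0, np.sqrt(s2_t / n_t + s2_c / n_c), (reps, 3))
        v2 = st_ / n_t + sc_ / n_c
        w = 1 / v2
        ybar = (w * y).sum(1) / w.sum(1)
        q = (w * (y - ybar[:, None]) ** 2).sum(1)

        # corrected moments evaluated at the true variances
        w0 = 1 / (s2_t / n_t + s2_c / n_c)
        gamma = s2_t**2 / (n_t**2 * (n_t - 1)) + s2_c**2 / (n_c**2 * (n_c - 1))
        p = 1 - w0 / w0.sum()
        s = float(np.sum(w0**2 * gamma * p**2))
        kappa1 = 2 + 2 * s
        kappa2 = 4 + 14 * s
        se_mean = q.std() / math.sqrt(reps)
        assert abs(q.mean() - kappa1) < 3 * se_mean
        se_var = math.sqrt((np.mean((q - q.mean()) ** 4) - q.var() ** 2) / reps)
        # the variance correction is O(1/n); allow Monte-Carlo noise plus a
        # small higher-order remainder
        assert abs(q.var() - kappa2) < 3 * se_var + 0.05 * kappa2
        # and the corrected moments must beat the classical chi-square moments
        assert abs(q.mean() - kappa1) < abs(q.mean() - 2)
        assert abs(q.var() - kappa2) < abs(q.var() - 4)


class TestMatchScaledF:
    def test_round_trip(self):
        # kappa2 must exceed 2 kappa1^2/(K-1) (the chi-square relative
        # variance) for a proper scaled-F solution to exist
        c, f2, ok = match_scaled_f(12.3, 40.0, 10)
        assert ok
        mean = c * f2 / (f2 - 2)
        var = (
            c**2 * 2 * f2**2 * (9 + f2 - 2) / (9 * (f2 - 2) ** 2 * (f2 - 4))
        )
        assert mean == pytest.approx(12.3, abs=1e-8)
        assert var == pytest.approx(40.0, abs=1e-8)

    def test_no_solution_flagged(self):
        _, _, ok = match_scaled_f(12.3, 31.0, 10)  # below the chi-square ratio
        assert not ok

    def test_classical_limit_quantiles(self):
        k = 10
        c, f2, ok = match_scaled_f(k - 1 + 1e-9, 2 * (k - 1) + 1e-8, k)
        for p in (0.025, 0.5, 0.975):
            fq = c * stats.f.ppf(p, k - 1, f2) if ok else stats.chi2.ppf(p, k - 1)
            assert fq == pytest.approx(stats.chi2.ppf(p, k - 1), rel=0.01)

    def test_null_quantile_beats_chi2(self):
        """Empirical 97.5% point of Q (K=5, n=20) is nearer the scaled-F value."""
        rng = np.random.default_rng(7)
        k, n_t, n_c = 5, 5, 15
        s2_t, s2_c = 2.0, 1.0
        reps = 200_000
        st_ = s2_t * rng.chisquare(n_t - 1, (reps, k)) / (n_t - 1)
        sc_ = s2_c * rng.chisquare(n_c - 1, (reps, k)) / (n_c - 1)
        y = rng.normal(0, math.sqrt(s2_t / n_t + s2_c / n_c), (reps, k))
        v2 = st_ / n_t + sc_ / n_c
        w = 1 / v2
        ybar = (w * y).sum(1) / w.sum(1)
        q = (w * (y - ybar[:, None]) ** 2).sum(1)
        emp = np.quantile(q, 0.975)
        w0 = np.full(k, 1 / (s2_t / n_t + s2_c / n_c))
        gamma = np.full(k, s2_t**2 / (n_t**2 * (n_t - 1)) + s2_c**2 / (n_c**2 * (n_c - 1)))
        p = 1 - w0 / w0.sum()
        s = float(np.sum(w0**2 * gamma * p**2))
        c, f2, ok = match_scaled_f(k - 1 + 2 * s, 2 * (k - 1) + 14 * s, k)
        assert ok
        f_q = c * stats.f.ppf(0.975, k - 1, f2)
        chi_q = stats.chi2.ppf(0.975, k - 1)
        assert abs(emp - f_q) < abs(emp - chi_q)


class TestKdbMoments:
    def test_asymptotic_classical_limit(self):
        recs = [_smd(0.5, 2.05e-5, 10**5, 10**5) for _ in range(6)]
        qm = kdb_expected_q(recs, delta=0.5)
        assert qm.kappa1 == pytest.approx(5.0, abs=2e-3)
        # kappa2 combines O(K^3) finite-difference terms, so its numerical
        # floor is looser than kappa1's
        assert qm.kappa2 == pytest.approx(10.0, abs=0.25)

    def test_corrections_negative_for_small_studies(self, ocd_records):
        qm = kdb_expected_q(ocd_records)
        k = len(ocd_records)
        assert qm.kappa1 < k - 1
        assert qm.kappa2 < 2 * (k - 1)
        assert qm.scale_c * qm.df2 == pytest.approx(qm.kappa1, rel=1e-10)

    def test_moments_beat_classical_against_null_simulation(self):
        """MC guard: corrected (kappa1, kappa2) closer to the truth than the
        classical chi-square moments under the exact nct generative model."""
        rng = np.random.default_rng(31)
        k, n, delta = 5, 100, 0.5
        n_t = n_c = n // 2
        m = n - 2
        ntilde = n_t * n_c / (n_t + n_c)
        j = hedges_j(m)
        reps = 200_000
        z = rng.standard_normal((reps, k))
        chi2 = rng.chisquare(m, (reps, k))
        t_nc = (z + math.sqrt(ntilde) * delta) / np.sqrt(chi2 / m)
        g = j * t_nc / math.sqrt(ntilde)
        b = 1 - (m - 2) / (m * j**2)
        v2 = 1 / ntilde + b * g**2
        w = 1 / v2
        gbar = (w * g).sum(1) / w.sum(1)
        q = (w * (g - gbar[:, None]) ** 2).sum(1)
        recs = [_smd(delta, 1 / ntilde + b * delta**2, n_t, n_c) for _ in range(k)]
        qm = kdb_expected_q(recs, delta=delta)
        assert abs(q.mean() - qm.kappa1) < abs(q.mean() - (k - 1))
        assert abs(q.var() - qm.kappa2) < abs(q.var() - 2 * (k - 1))
        # and kappa1 agrees with the simulated mean within MC noise plus a
        # higher-order remainder at n=100
        assert abs(q.mean() - qm.kappa1) < 3 * q.std() / math.sqrt(reps) + 20.0 / n**2 * k

    def test_requires_smd(self, md_records):
        with pytest.raises(ValueError, match="SMD"):
            kdb_expected_q(md_records)

    def test_truncated_moment_patterns_match_symbolic_expansion(self):
        """The pattern sums equal the exact moments of a generic quartic."""
        sp = pytest.importorskip("sympy")
        import metaq.q_moments as qmod

        k = 3
        rng = np.random.default_rng(7)
        h = rng.normal(size=(k, k))
        h = h + h.T
        t3 = rng.normal(size=(k, k, k))
        t3 = sum(t3.transpose(p) for p in itertools.permutations(range(3))) / 6
        f4 = rng.normal(size=(k, k, k, k))
        f4 = sum(f4.transpose(p) for p in itertools.permutations(range(4))) / 24

        eps = sp.symbols("e0 e1 e2")
        q2 = sum(sp.Rational(1, 2) * h[i, j] * eps[i] * eps[j]
                 for i in range(k) for j in range(k))
        q3 = sum(sp.Rational(1, 6) * t3[i, j, l] * eps[i] * eps[j] * eps[l]
                 for i in range(k) for j in range(k) for l in range(k))
        q4 = sum(sp.Rational(1, 24) * f4[i, j, l, o] * eps[i] * eps[j] * eps[l] * eps[o]
                 for i in range(k) for j in range(k) for l in range(k) for o in range(k))
        mu = {(p, i): sp.Symbol(f"mu{p}_{i}") for p in range(2, 9) for i in range(k)}

        def expect(poly):
            out = 0
            for term in sp.Add.make_args(sp.expand(poly)):
                pol = sp.Poly(term, *eps)
                mono, coeff = pol.monoms()[0], pol.coeffs()[0]
                if any(p == 1 for p in mono):
                    continue
                f = coeff
                for i, p in enumerate(mono):
                    if p >= 2:
                        f *= mu[(p, i)]
                out += f
            return sp.expand(out)

        e_sym = expect(q2 + q3 + q4)
        var_sym = sp.expand(
            expect(q2 * q2) - expect(q2) ** 2
            + 2 * (expect(q2 * q3) - expect(q2) * expect(q3))
            + 2 * (expect(q2 * q4) - expect(q2) * expect(q4))
            + expect(q3 * q3) - expect(q3) ** 2
        )
        subs = {s: float(rng.uniform(0.5, 1.5)) for s in mu.values()}

        tensors = {
            "Hd": np.diag(h).copy(),
            "Hod": h - np.diag(np.diag(h)),
            "Td": np.array([t3[i, i, i] for i in range(k)]),
            "Fd": np.array([f4[i, i, i, i] for i in range(k)]),
            "Tssr": np.array([[t3[s, s, r] for r in range(k)] for s in range(k)]),
            "Fssrr": np.array([[f4[s, s, r, r] for r in range(k)] for s in range(k)]),
            "Fsssr": np.array([[f4[s, s, s, r] for r in range(k)] for s in range(k)]),
            "Tstu": t3,
            "Fsruu": np.array(
                [[[f4[s, r, u, u] for u in range(k)] for r in range(k)] for s in range(k)]
            ),
            "triples": [(0, 1, 2)],
        }
        orig = qmod._q_taylor_tensors
        qmod._q_taylor_tensors = lambda *a, **kw: tensors
        try:
            mu_arr = np.array([[subs[mu[(p, i)]] for p in range(2, 7)] for i in range(k)])
            k1, k2 = _truncated_q_moments(np.zeros(k), np.ones(k), np.ones(k), mu_arr)
        finally:
            qmod._q_taylor_tensors = orig
        assert k1 == pytest.approx(float(e_sym.subs(subs)), abs=1e-10)
        assert k2 == pytest.approx(float(var_sym.subs(subs)), abs=1e-10)

    def test_finite_difference_tensors_match_sympy(self):
        sp = pytest.importorskip("sympy")
        k = 3
        rng = np.random.default_rng(11)
        a = rng.uniform(0.1, 0.3, k)
        b = rng.uniform(0.02, 0.06, k)
        g0 = rng.uniform(0.5, 1.2, k)
        gsym = sp.symbols("g0 g1 g2")
        w = [1 / (a[i] + b[i] * gsym[i] ** 2) for i in range(k)]
        gb = sum(wi * gi for wi, gi in zip(w, gsym)) / sum(w)
        q = sum(wi * (gi - gb) ** 2 for wi, gi in zip(w, gsym))
        pt = {gsym[i]: float(g0[i]) for i in range(k)}

        def deriv(*order):
            e = q
            for i in order:
                e = sp.diff(e, gsym[i])
            return float(e.subs(pt))

        td = _q_taylor_tensors(g0, a, b, h=0.01)
        assert td["Hd"][0] == pytest.approx(deriv(0, 0), abs=1e-5)
        assert td["Hod"][0, 1] == pytest.approx(deriv(0, 1), abs=1e-4)
        assert td["Td"][1] == pytest.approx(deriv(1, 1, 1), abs=1e-3)
        assert td["Fd"][2] == pytest.approx(deriv(2, 2, 2, 2), abs=1e-3)
        assert td["Tssr"][0, 2] == pytest.approx(deriv(0, 0, 2), abs=1e-3)
        assert td["Fsssr"][1, 0] == pytest.approx(deriv(1, 1, 1, 0), abs=1e-3)
        assert td["Tstu"][0, 1, 2] == pytest.approx(deriv(0, 1, 2), abs=1e-3)
        assert td["Fsruu"][0, 2, 1] == pytest.approx(deriv(0, 2, 1, 1), abs=1e-3)

    def test_g_moments_match_scipy_nct(self):
        m, ntilde, delta = 18, 5.0, 0.8
        j = hedges_j(m)
        dist = stats.nct(m, math.sqrt(ntilde) * delta, scale=j / math.sqrt(ntilde))
        mu = _g_central_moments(m, ntilde, delta, kmax=4)
        mean = dist.mean()
        assert mu[0] == pytest.approx(dist.var(), rel=1e-9)
        assert mu[1] == pytest.approx(dist.expect(lambda x: (x - mean) ** 3), rel=1e-6)
        assert mu[2] == pytest.approx(dist.expect(lambda x: (x - mean) ** 4), rel=1e-6)


class TestChisqMixCdf:
    def test_single_term_reduces_to_chi2(self):
        for df in (1, 4):
            for x in (1.0, 5.0, 10.0):
                assert chisq_mix_cdf([1.0], [df], x) == pytest.approx(
                    stats.chi2.cdf(x, df), abs=1e-10
                )

    def test_equal_coefficients_scaling_identity(self):
        lam = 0.7
        got = chisq_mix_cdf([lam, lam, lam], [2, 3, 1], 4.0)
        assert got == pytest.approx(stats.chi2.cdf(4.0 / lam, 6), abs=1e-10)

    def test_mixed_case_against_monte_carlo(self):
        rng = np.random.default_rng(1)
        reps = 10**6
        draws = 0.5 * rng.chisquare(2, reps) + 1.5 * rng.chisquare(3, reps)
        for x in (1.0, 2.5, 4.0, 7.0, 12.0):
            p = chisq_mix_cdf([0.5, 1.5], [2, 3], x)
            emp = np.mean(draws <= x)
            se = math.sqrt(emp * (1 - emp) / reps)
            assert abs(p - emp) < 3 * se

    def test_ruben_and_imhof_agree(self):
        lam = [0.3, 0.9, 2.2, 5.0]
        dfs = [1, 1, 2, 1]
        for x in (2.0, 8.0, 20.0):
            assert chisq_mix_cdf(lam, dfs, x, method="ruben") == pytest.approx(
                chisq_mix_cdf(lam, dfs, x, method="imhof"), abs=1e-8
            )

    def test_monotone_and_tails(self):
        lam = [0.4, 1.1, 3.0]
        xs = np.linspace(0.01, 60, 40)
        vals = [chisq_mix_cdf(lam, None, x) for x in xs]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        assert chisq_mix_cdf(lam, None, 1e-6) < 1e-4
        assert chisq_mix_cdf(lam, None, 1e3) > 1 - 1e-8

    def test_rejects_nonpositive_coefficients(self):
        with pytest.raises(ValueError):
            chisq_mix_cdf([0.5, -1.0], [1, 1], 2.0)
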