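"""Growth module: allometry and VBGF fitting, derivative curves, and the
closed-form life-history quantities."""

import math

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

import lenassess as la
from lenassess.errors import DomainError, InsufficientDataError

from conftest import make_records


# ---------------------------------------------------------------------------
# length-weight allometry
# ---------------------------------------------------------------------------

class TestLengthWeight:
    def test_noiseless_power_law_recovered_to_machine_precision(self):
        L = np.arange(50.0, 401.0, 50.0)
        lw = la.fit_length_weight(make_records(L, 1.0e-5 * L ** 3))
        assert lw.a == pytest.approx(1.0e-5, rel=1e-12)
        assert lw.b == pytest.approx(3.0, abs=1e-12)
        assert lw.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_matches_grid_search_oracle(self):
        # truth a=2e-5, b=2.97, multiplicative lognormal noise CV 10%, n=2000
        rng = np.random.default_rng(11)
        L = rng.uniform(50.0, 400.0, 2000)
        sigma = math.sqrt(math.log1p(0.10 ** 2))
        W = 2.0e-5 * L ** 2.97 * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, 2000))
        lw = la.fit_length_weight(make_records(L, W))
        assert abs(lw.b - 2.97) < 0.05

        # independent coarse grid search minimising the same log10 loss
        x, y = np.log10(L), np.log10(W)
        bs = np.linspace(2.8, 3.2, 81)
        log_as = np.linspace(-5.2, -4.2, 81)
        rss = np.array([[np.sum((y - (la_ + b * x)) ** 2) for b in bs]
                        for la_ in log_as])
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        assert abs(lw.b - bs[j]) <= (bs[1] - bs[0])
        assert abs(math.log10(lw.a) - log_as[i]) <= (log_as[1] - log_as[0])

    def test_published_exponents_are_isometric(self, tributaries):
        # all four tributaries report b within 0.08 of 3
        for b in tributaries["b"]:
            assert abs(b - 3.0) < 0.08
            assert la.LengthWeightParams(a=1e-5, b=b, n=0, r_squared=1.0,
                                         se_b=1.0).isometric()

    def test_nls_method_agrees_on_clean_data(self):
        L = np.arange(60.0, 361.0, 30.0)
        rec = make_records(L, 1.5e-5 * L ** 2.95)
        log_fit = la.fit_length_weight(rec)
        nls_fit = la.fit_length_weight(rec, method="nls")
        assert nls_fit.b == pytest.approx(log_fit.b, abs=1e-6)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(InsufficientDataError):
            la.fit_length_weight(make_records([100.0, 100.0, 100.0], [10, 10, 10]))
        bad = make_records([100.0, 200.0, -5.0], [10.0, 80.0, 1.0])
        with pytest.raises(la.ValidationError, match="row 2"):
            la.fit_length_weight(bad)


# ---------------------------------------------------------------------------
# VBGF fitting
# ---------------------------------------------------------------------------

class TestVBGFFit:
    def test_noiseless_data_recovered_exactly(self):
        ages = np.arange(0, 14)
        L = 414.5 * (1.0 - np.exp(-0.154 * (ages + 0.556)))
        fit = la.fit_vbgf_length(make_records(L, np.ones_like(L), ages=ages))
        assert fit.L_inf == pytest.approx(414.5, rel=1e-6)
        assert fit.k == pytest.approx(0.154, rel=1e-6)
        assert fit.t0 == pytest.approx(-0.556, rel=1e-6)

    def test_noisy_synthetic_recovery_within_tolerance(self):
        # truth (400, 0.16, -0.5), n=3000, length CV 8%
        cfg = la.SimulationConfig(n=3000, seed=42)
        pop = la.simulate_population(cfg)
        fit = la.fit_vbgf_length(pop)
        assert abs(fit.L_inf / 400.0 - 1.0) < 0.03
        assert abs(fit.k / 0.16 - 1.0) < 0.10

    def test_age_class_means_option(self):
        ages = np.repeat(np.arange(0, 10), 5)
        L = 350.0 * (1.0 - np.exp(-0.2 * (ages + 0.4)))
        fit = la.fit_vbgf_length(make_records(L, np.ones_like(L), ages=ages),
                                 use_age_means=True)
        assert fit.L_inf == pytest.approx(350.0, rel=1e-6)

    def test_published_L_inf_from_rate_coefficient(self, tributaries):
        # dL/dt leading coefficient / k recovers the reported 414.5 mm
        assert tributaries.loc["Duoxiong Zangbo", "L_inf_mm"] == pytest.approx(
            414.5, abs=0.05)

    def test_too_few_ages_rejected(self):
        rec = make_records([100, 150, 180.0], [10, 30, 50.0], ages=[1, 2, 3])
        with pytest.raises(InsufficientDataError):
            la.fit_vbgf_length(rec)


# ---------------------------------------------------------------------------
# derived weight growth and curve evaluation
# ---------------------------------------------------------------------------

class TestWeightGrowth:
    def test_direct_arithmetic(self):
        vb = la.VBGFParams(L_inf=100.0, k=0.2, t0=0.0)
        lw = la.LengthWeightParams(a=1e-5, b=3.0, n=0, r_squared=1.0, se_b=0.0)
        wg = la.derive_weight_growth(vb, lw)
        assert wg.W_inf == pytest.approx(10.0)
        assert (wg.k, wg.t0, wg.b) == (0.2, 0.0, 3.0)

    @pytest.mark.parametrize("river,coeff", [
        ("Duoxiong Zangbo", 540.037),
        ("Lhasa River", 565.268),
    ])
    def test_weight_rate_coefficient_recombines(self, tributaries, river, coeff):
        # W_inf k b must reproduce the published dW/dt leading coefficient
        p = tributaries.loc[river]
        vb = la.tributary_vbgf(river)
        a = (coeff / (p["k"] * p["b"])) / vb.L_inf ** p["b"]
        lw = la.LengthWeightParams(a=a, b=p["b"], n=0, r_squared=1.0, se_b=0.0)
        wg = la.derive_weight_growth(vb, lw)
        assert wg.W_inf * wg.k * wg.b == pytest.approx(coeff, rel=1e-3)

    def test_length_curve_boundary_and_asymptote(self, dx_vbgf):
        assert float(la.length_at_age(dx_vbgf, dx_vbgf.t0)) == pytest.approx(0.0)
        t = np.linspace(dx_vbgf.t0, 200.0, 500)
        L = la.length_at_age(dx_vbgf, t)
        assert np.all(np.diff(L) > 0)
        assert np.all(L < dx_vbgf.L_inf)
        assert L[-1] == pytest.approx(dx_vbgf.L_inf, rel=1e-9)

    def test_length_at_inflection_age(self, dx_vbgf):
        # published parameters give ~274.9 mm at the inflection age
        t_i = la.inflection_age(2.9689, dx_vbgf.k, dx_vbgf.t0)
        assert float(la.length_at_age(dx_vbgf, t_i)) == pytest.approx(274.9, abs=0.1)

    def test_age_below_t0_is_rejected(self, dx_vbgf):
        with pytest.raises(DomainError):
            la.length_at_age(dx_vbgf, dx_vbgf.t0 - 0.1)
        wg = la.WeightGrowthParams(W_inf=1000.0, b=3.0, k=0.154, t0=-0.556)
        with pytest.raises(DomainError):
            la.growth_rate_weight(wg, -1.0)


class TestDerivativeCurves:
    def test_published_leading_coefficients(self, dx_vbgf):
        # dL/dt at t0 is L_inf*k; d2L/dt2 at t0 is -L_inf*k^2
        assert float(la.growth_rate_length(dx_vbgf, dx_vbgf.t0)) == pytest.approx(
            63.838, abs=1e-3)
        assert float(la.growth_accel_length(dx_vbgf, dx_vbgf.t0)) == pytest.approx(
            -9.831, abs=1e-3)

    def test_length_rate_positive_and_decreasing(self, dx_vbgf):
        t = np.linspace(dx_vbgf.t0, 60.0, 2000)
        r = la.growth_rate_length(dx_vbgf, t)
        assert np.all(r > 0)
        assert np.all(np.diff(r) < 0)
        assert np.all(la.growth_accel_length(dx_vbgf, t) < 0)

    def test_weight_rate_peaks_at_inflection_age(self, dx_vbgf):
        wg = la.WeightGrowthParams(W_inf=1181.2, b=2.9689, k=dx_vbgf.k, t0=dx_vbgf.t0)
        t = np.arange(dx_vbgf.t0 + 1e-3, 40.0, 1e-3)
        rate = la.growth_rate_weight(wg, t)
        t_peak = t[np.argmax(rate)]
        t_i = la.inflection_age(wg.b, wg.k, wg.t0)
        assert t_peak == pytest.approx(t_i, abs=1.5e-3)

    def test_weight_accel_changes_sign_once_at_t_i(self, dx_vbgf):
        wg = la.WeightGrowthParams(W_inf=1181.2, b=2.9689, k=dx_vbgf.k, t0=dx_vbgf.t0)
        t = np.arange(dx_vbgf.t0 + 1e-3, 40.0, 1e-3)
        acc = la.growth_accel_weight(wg, t)
        signs = np.sign(acc)
        changes = np.nonzero(np.diff(signs))[0]
        assert changes.size == 1
        assert t[changes[0]] == pytest.approx(
            la.inflection_age(wg.b, wg.k, wg.t0), abs=2e-3)


# ---------------------------------------------------------------------------
# closed-form life-history quantities
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_inflection_age_forced_value(self):
        assert la.inflection_age(math.e, 1.0, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("river,expected", [
        ("Duoxiong Zangbo", 6.51), ("Lhasa River", 5.60)])
    def test_inflection_age_published(self, tributaries, river, expected):
        p = tributaries.loc[river]
        assert round(la.inflection_age(p["b"], p["k"], p["t0"]), 2) == expected

    def test_no_inflection_for_b_below_one(self):
        with pytest.raises(DomainError):
            la.inflection_age(0.9, 0.2, 0.0)

    @pytest.mark.parametrize("river,expected", [
        ("Duoxiong Zangbo", 5.32), ("Nianchu River", 5.13)])
    def test_critical_age_published(self, tributaries, river, expected):
        p = tributaries.loc[river]
        assert round(la.critical_age(p["k"], p["t0"], p["b"], p["M"]), 2) == expected

    def test_critical_age_algebraic_simplification(self):
        # M = b k and t0 = 0 collapse to ln(2)/k
        b, k = 2.5, 0.3
        assert la.critical_age(k, 0.0, b, b * k) == pytest.approx(math.log(2) / k)

    def test_critical_age_rejects_nonpositive_M(self):
        with pytest.raises(DomainError):
            la.critical_age(0.2, 0.0, 3.0, 0.0)

    def test_phi_log_identity_and_published(self, tributaries):
        assert la.growth_performance_index(1.0, 1.0) == 0.0
        p = tributaries.loc["Duoxiong Zangbo"]
        assert round(la.growth_performance_index(p["k"], p["L_inf_mm"]), 2) == 4.42
        p = tributaries.loc["Niyang River"]
        assert round(la.growth_performance_index(p["k"], p["L_inf_mm"]), 2) == 4.43

    @given(st.floats(0.05, 1.0), st.floats(100.0, 600.0), st.floats(0.1, 10.0))
    def test_phi_rescaling_shift(self, k, L_inf, c):
        # rescaling L_inf by c shifts phi by exactly 2*log10(c)
        shift = (la.growth_performance_index(k, L_inf * c)
                 - la.growth_performance_index(k, L_inf))
        assert shift == pytest.approx(2.0 * math.log10(c), abs=1e-9)

    def test_phi_monotone_in_k_and_L_inf(self):
        assert (la.growth_performance_index(0.2, 400.0)
                > la.growth_performance_index(0.15, 400.0))
        assert (la.growth_performance_index(0.2, 420.0)
                > la.growth_performance_index(0.2, 400.0))

    def test_closed_forms_against_50_digit_arithmetic(self, tributaries):
        # independent high-precision evaluation agrees to >= 10 significant digits
        for river, p in tributaries.iterrows():
            k, t0, b, M = (sympy.Float(p[c], 50) for c in ("k", "t0", "b", "M"))
            L_inf = sympy.Float(p["rate_coeff"], 50) / k
            ti_hp = float(sympy.N(sympy.log(b) / k + t0, 50))
            tc_hp = float(sympy.N((k * t0 - sympy.log(M) + sympy.log(b * k + M)) / k, 50))
            phi_hp = float(sympy.N(sympy.log(k, 10) + 2 * sympy.log(L_inf, 10), 50))
            assert la.inflection_age(p["b"], p["k"], p["t0"]) == pytest.approx(
                ti_hp, rel=1e-10)
            assert la.critical_age(p["k"], p["t0"], p["b"], p["M"]) == pytest.approx(
                tc_hp, rel=1e-10)
            assert la.growth_performance_index(p["k"], p["L_inf_mm"]) == pytest.approx(
                phi_hp, rel=1e-10)
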