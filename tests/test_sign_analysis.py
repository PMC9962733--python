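import math

import numpy as np
import pytest

from pnpiv.expansion import boundary_layer_difference, expansion_at_EN
from pnpiv.flux import SpeciesPair
from pnpiv.geometry import cylindrical_channel
from pnpiv.sign_analysis import (ThresholdUndefinedError, _quad_coeff_of_I1d,
                                 alpha_star, alpha_thresholds, beta1,
                                 classify_region, critical_potentials,
                                 discriminant, ell, g2, g4, lemma_shape)


class TestShapeFunction:
    def test_enhancing_branch_positive(self):
        # sigma + rho > 2 with sigma > 1
        assert ell(1.5, 1.1, 0.95) > 0.0
        assert lemma_shape(1.5, 1.1, 0.95).branch == "i"

    def test_neutral_is_identically_zero(self):
        for t in (1.2, 2.0, 7.0):
            assert ell(t, 1.0, 1.0) == 0.0

    def test_mixed_branch_has_root(self):
        res = lemma_shape(1.5, 1.01, 0.9)  # sigma + rho < 2 with sigma > 1
        assert res.branch == "iii"
        t_star = res.t_star
        assert ell(t_star, 1.01, 0.9) == pytest.approx(0.0, abs=1e-12)
        assert ell(t_star * 0.99, 1.01, 0.9) < 0.0 < ell(t_star * 1.01, 1.01, 0.9)

    def test_out_of_hypothesis(self):
        assert lemma_shape(0.8, 1.1, 0.9).branch == "out-of-hypothesis"
        assert lemma_shape(1.5, 0.9, 1.1).branch == "out-of-hypothesis"


class TestAlphaThresholds:
    def test_reference_alpha1(self):
        a1, a3, a4, _ = alpha_thresholds(1.5)
        assert a1 == pytest.approx((1.5 - math.sqrt(1.5)) / 0.5, rel=1e-14)
        assert a1 == pytest.approx(0.550510, abs=1e-6)

    def test_roots_satisfy_quadratic(self):
        _, a3, a4, _ = alpha_thresholds(1.5)
        assert g2(a3, 1.5) == pytest.approx(0.0, abs=1e-12)
        assert g2(a4, 1.5) == pytest.approx(0.0, abs=1e-12)
        assert 0.0 < a3 < 0.550511 < a4 < 1.0

    @pytest.mark.parametrize("t", [1.1, 1.3, 1.5, 1.7, 1.9])
    def test_ordering(self, t):
        a1, a3, a4, _ = alpha_thresholds(t)
        assert 0.0 < a3 < a1 < a4 < 1.0

    @pytest.mark.parametrize("t", [1.05, 1.25, 1.5, 1.75, 1.95])
    def test_closed_form_cross_check(self, t):
        """Quadratic roots equal the surd closed form with sqrt(p(t))."""
        a1, a3, a4, p_t = alpha_thresholds(t)
        lt = math.log(t)
        num = -3 * (1 - t) ** 2 - t * lt**2 + 4 * t * (t - 1) * lt
        den = 4 * (t - 1) ** 2 * lt
        assert a3 == pytest.approx((num - math.sqrt(p_t)) / den, rel=1e-10)
        assert a4 == pytest.approx((num + math.sqrt(p_t)) / den, rel=1e-10)

    def test_limit_toward_uniform_concentrations(self):
        a1, _, _, _ = alpha_thresholds(1 + 1e-6)
        assert a1 == pytest.approx(0.5, abs=1e-6)

    def test_requires_concentration_contrast(self):
        with pytest.raises(ValueError):
            alpha_thresholds(0.9)


class TestBeta1:
    def test_exists_above_alpha1(self, species):
        a1, _, a4, _ = alpha_thresholds(1.5)
        alpha = a1 + 0.01
        b1 = beta1(1.5, alpha, species)
        assert alpha < b1 < 1.0
        f = lambda b: _quad_coeff_of_I1d(1.5, alpha, b, 1.01, 0.99, species)
        assert f(b1) == pytest.approx(0.0, abs=1e-14)
        assert np.sign(f(0.5 * (alpha + b1))) != np.sign(f(0.5 * (b1 + 1.0)))

    def test_quad_coeff_vanishes_as_window_shrinks(self, species):
        a1, _, _, _ = alpha_thresholds(1.5)
        alpha = a1 + 0.01
        vals = [abs(_quad_coeff_of_I1d(1.5, alpha, alpha + h, 1.01, 0.99,
                                       species)) for h in (1e-3, 1e-5, 1e-7)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-8

    def test_out_of_hypothesis_refused(self, species):
        _, a3, _, _ = alpha_thresholds(1.5)
        with pytest.raises(ValueError):
            beta1(1.5, 0.5 * a3, species)


class TestG4:
    def test_matches_discriminant_limit(self, species):
        """g4 equals the beta->alpha limit of the scaled-discriminant
        curvature for every probed alpha (dual-path identity)."""
        t = 1.5
        lnt = math.log(t)
        sigma, rho = 1.1, 0.94
        for alpha in (0.2, 0.35, 0.5, 0.62, 0.8):
            h = 1e-5

            def delta1(beta):
                from pnpiv.sign_analysis import _FrameGeom
                exp = expansion_at_EN(species, t, 1.0,
                                      _FrameGeom(alpha, beta))
                c0, c1, c2 = boundary_layer_difference(
                    exp, sigma, rho).I1d_coeffs
                return (c1**2 - 4 * c0 * c2) * 4 * lnt**2

            d2 = lambda hh: 2.0 * delta1(alpha + hh) / hh**2
            dual = 2.0 * d2(h / 2) - d2(h)  # Richardson in h
            w = (1 - alpha) * t + alpha
            pref = (2 * (t - 1) ** 2 * (sigma - rho) ** 2 / (4 * w**6 * lnt**4))
            assert g4(t, alpha, species) == pytest.approx(dual / pref,
                                                          rel=1e-5)

    def test_alpha_star_reference(self, species):
        a_star, roots = alpha_star(1.5, species)
        assert g4(1.5, a_star, species) == pytest.approx(0.0, abs=1e-10)
        assert g4(1.5, a_star - 1e-3, species) > 0.0
        assert g4(1.5, a_star + 1e-3, species) < 0.0
        a1, a3, _, _ = alpha_thresholds(1.5)
        assert a3 < a_star < a1  # the ordering the sign theory assumes

    def test_domain_restriction(self, species):
        with pytest.raises(ValueError):
            alpha_star(2.5, species)


class TestDiscriminant:
    def test_neutral_point_vanishes(self, species, geom):
        exp = expansion_at_EN(species, 12.0, 8.0, geom)
        delta, parts = discriminant(exp, 1.0, 1.0)
        assert delta == 0.0
        assert all(p == 0.0 for p in parts)

    def test_parts_sum_to_polynomial_discriminant(self, rng):
        """Five-part decomposition vs c1^2 - 4 c0 c2, randomized."""
        from conftest import random_parameter_set
        for _ in range(50):
            sp, bs, g = random_parameter_set(rng)
            sigma = float(rng.uniform(0.8, 1.25))
            rho = float(rng.uniform(0.8, 1.25))
            exp = expansion_at_EN(sp, bs.L1, bs.R1, g)
            delta, parts = discriminant(exp, sigma, rho)
            c0, c1, c2 = boundary_layer_difference(exp, sigma, rho).I1d_coeffs
            disc = c1 * c1 - 4.0 * c0 * c2
            assert np.sign(delta) == np.sign(disc)
            assert delta == pytest.approx(disc, rel=1e-9, abs=1e-300)

    def test_sign_predicts_root_count(self, rng):
        from conftest import random_parameter_set
        for _ in range(50):
            sp, bs, g = random_parameter_set(rng)
            sigma = float(rng.uniform(0.8, 1.25))
            rho = float(rng.uniform(0.8, 1.25))
            exp = expansion_at_EN(sp, bs.L1, bs.R1, g)
            delta, _ = discriminant(exp, sigma, rho)
            c0, c1, c2 = boundary_layer_difference(exp, sigma, rho).I1d_coeffs
            if c2 == 0.0:
                continue
            roots = np.roots([c2, c1, c0])
            n_real = int(np.sum(np.abs(roots.imag) < 1e-12))
            assert (delta < 0.0) == (n_real == 0)


class TestCriticalPotentials:
    def test_reference_relaxation(self, species, geom):
        exp = expansion_at_EN(species, 12.0, 8.0, geom)
        cp = critical_potentials(exp, 1.2, 0.9)
        bld = boundary_layer_difference(exp, 1.2, 0.9)
        assert cp.V0d_label == "V01d"  # increasing branch
        assert bld.I0d(cp.V0d) == pytest.approx(0.0, abs=1e-12)
        # vertex is a stationary point of I1d
        c0, c1, c2 = bld.I1d_coeffs
        assert c1 + 2 * c2 * cp.V1c == pytest.approx(0.0, abs=1e-12)
        # zeroth-order reversal shifts right when layers appear
        assert cp.V01EN == pytest.approx(-0.0840804, abs=1e-6)
        assert cp.V01EN < cp.V01bd

    def test_side_swap_symmetry(self, rng):
        """(sigma, L1) <-> (rho, R1) with mirrored geometry and V -> -V
        maps the zero of I0d to its negative (1:1 electrolyte)."""
        for _ in range(20):
            D1, D2 = rng.uniform(0.3, 3.0, size=2)
            sp = SpeciesPair(1, -1, D1, D2)
            L1 = float(rng.uniform(5, 20))
            R1 = L1 * float(rng.uniform(0.4, 0.9))
            sigma = float(rng.uniform(1.0, 1.2))
            rho = float(rng.uniform(0.85, 1.0))
            a = float(rng.uniform(0.1, 0.5))
            b = float(rng.uniform(a + 0.05, 0.9))
            g_fwd = cylindrical_channel(a, b, 0.5)
            g_rev = cylindrical_channel(1 - b, 1 - a, 0.5)
            e_fwd = expansion_at_EN(sp, L1, R1, g_fwd)
            e_rev = expansion_at_EN(sp, R1, L1, g_rev)
            b_fwd = boundary_layer_difference(e_fwd, sigma, rho)
            b_rev = boundary_layer_difference(e_rev, rho, sigma)
            V0_fwd = -b_fwd.I0d_coeffs[0] / b_fwd.I0d_coeffs[1]
            V0_rev = -b_rev.I0d_coeffs[0] / b_rev.I0d_coeffs[1]
            assert V0_rev == pytest.approx(-V0_fwd, rel=1e-8)


class TestClassifier:
    def test_reference_setup(self, species, geom):
        out = classify_region(1.5, geom.alpha, geom.beta, 1.2, 0.9, species)
        assert out["monotonicity_I0d"].startswith("(i1)")
        # alpha = 0.3989 lies in [alpha3, alpha1): concave-down branch
        assert out["monotonicity_I1d"].startswith("(ii)")
        # and above alpha*: no real zeros of the linearized I1d
        assert out["sign_I1d"].startswith("(iii)")
        assert out["ordering_ok"]

    def test_beta1_branch(self, species):
        out = classify_region(1.5, 0.60, 0.65, 1.05, 0.97, species)
        assert out["monotonicity_I1d"].startswith("(iii)")
        assert "beta1" in out

    def test_electroneutral_degenerate(self, species):
        out = classify_region(1.5, 0.4, 0.5, 1.0, 1.0, species)
        assert out["label"] == "electroneutral"
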