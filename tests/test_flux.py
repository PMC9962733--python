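import math

import numpy as np
import pytest

from pnpiv.flux import (BoundaryState, SpeciesPair, electroneutral_limits,
                        flux_expansion, gamma)


class TestGamma:
    def test_midpoint_and_sample(self):
        assert gamma(1.0) == 0.5
        # direct evaluation of (t ln t - t + 1)/((t-1) ln t) at t = 1.5
        assert gamma(1.5) == pytest.approx(0.5336965376235683, rel=1e-12)

    def test_exact_deficit_identity(self):
        # gamma(t) = 1 - 1/ln t + 1/(t - 1) identically
        for t in (1e-9, 0.03, 0.7, 1.3, 17.0, 1e7):
            assert gamma(t) == pytest.approx(
                1.0 - 1.0 / math.log(t) + 1.0 / (t - 1.0), abs=1e-12)

    def test_bounds_monotone_and_symmetry(self):
        ts = np.logspace(-6, 6, 2001)
        vals = np.array([gamma(t) for t in ts])
        assert np.all((vals > 0.0) & (vals < 1.0))
        assert np.all(np.diff(vals) > 0.0)
        sym = np.array([gamma(t) + gamma(1.0 / t) for t in ts])
        assert np.max(np.abs(sym - 1.0)) < 1e-12

    def test_taylor_branch_continuity(self):
        # series and closed-form branches agree across the guard band
        for sgn in (+1, -1):
            t_closed = 1 + sgn * 1.02e-5   # closed-form side
            t_series = 1 + sgn * 0.98e-5   # series side
            assert gamma(t_series) == pytest.approx(gamma(t_closed), abs=5e-7)
            # and the series matches the closed form evaluated just outside
            lt = math.log(t_closed)
            closed = (t_closed * lt - t_closed + 1.0) / ((t_closed - 1.0) * lt)
            assert gamma(t_closed) == pytest.approx(closed, rel=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gamma(0.0)
        with pytest.raises(ValueError):
            gamma(-2.0)


class TestElectroneutralLimits:
    def test_neutral_boundaries_are_transparent(self, species, geom):
        bs = BoundaryState(V=0.7, L1=12, R1=8)
        lim = electroneutral_limits(species, bs, geom)
        assert lim.c1L == pytest.approx(12.0, rel=1e-14)
        assert lim.c1R == pytest.approx(8.0, rel=1e-14)
        assert lim.phiL == pytest.approx(0.7, abs=1e-14)
        assert lim.phiR == pytest.approx(0.0, abs=1e-14)

    def test_relaxation_scales_concentration(self, species, geom):
        # c1L = sigma^{z1/(z1-z2)} L1 = sqrt(1.21) * 12 for z1 = -z2 = 1
        bs = BoundaryState(V=0.0, L1=12, R1=8, sigma=1.21, rho=1.0)
        lim = electroneutral_limits(species, bs, geom)
        assert lim.c1L == pytest.approx(13.2, rel=1e-12)

    def test_interior_interpolation(self, species, geom):
        bs = BoundaryState(V=0.0, L1=12, R1=8)
        lim = electroneutral_limits(species, bs, geom)
        assert lim.c10a == pytest.approx(12 + geom.alpha * (8 - 12), rel=1e-13)
        assert lim.c10b == pytest.approx(12 + geom.beta * (8 - 12), rel=1e-13)

    def test_bulk_neutrality_invariant(self, rng):
        from conftest import random_parameter_set
        for _ in range(25):
            sp, bs, g = random_parameter_set(rng)
            lim = electroneutral_limits(sp, bs, g)
            assert sp.z1 * lim.c1L == pytest.approx(-sp.z2 * lim.c2L, rel=1e-12)
            assert sp.z1 * lim.c1R == pytest.approx(-sp.z2 * lim.c2R, rel=1e-12)


class TestFluxExpansion:
    def test_equilibrium_is_exactly_zero(self, species, geom):
        fx = flux_expansion(species, BoundaryState(V=0.0, L1=9, R1=9), geom)
        assert fx.J10 == fx.J20 == fx.J11 == fx.J21 == 0.0

    def test_reference_A_B(self, species, geom):
        bs = BoundaryState(V=0.3, L1=12, R1=8)
        fx = flux_expansion(species, bs, geom)
        # direct evaluation with c10a, c10b from the geometry's alpha, beta
        wa = 12 + geom.alpha * (8 - 12)
        wb = 12 + geom.beta * (8 - 12)
        lnt = math.log(1.5)
        A_ref = (12 - 8) * (wb - wa) / (wa * wb * lnt)
        assert fx.A == pytest.approx(A_ref, rel=1e-13)
        assert fx.B == pytest.approx(math.log(wb / wa) / A_ref, rel=1e-13)
        assert fx.A == pytest.approx(-0.0554018, abs=1e-6)
        assert fx.B == pytest.approx(1.0250036, abs=1e-6)

    def test_scaled_fluxes(self, species, geom):
        bs = BoundaryState(V=-0.4, L1=12, R1=8, sigma=1.1, rho=0.95)
        fx = flux_expansion(species, bs, geom)
        s10, s20, s11, s21 = fx.scaled(species)
        assert s10 == species.D1 * fx.J10
        assert s21 == species.D2 * fx.J21

    def test_antisymmetry_under_side_swap(self, rng):
        """Swapping (L1, sigma) with (R1, rho) and V -> -V negates J10 (1:1)."""
        from pnpiv.geometry import cylindrical_channel
        for _ in range(50):
            D1, D2 = rng.uniform(0.3, 3.0, size=2)
            sp = SpeciesPair(1, -1, D1, D2)
            L1, R1 = rng.uniform(2.0, 20.0, size=2)
            sigma, rho = rng.uniform(0.6, 1.6, size=2)
            V = rng.uniform(-2.0, 2.0)
            a = rng.uniform(0.1, 0.5)
            b = rng.uniform(a + 0.05, 0.9)
            # mirror geometry so alpha, beta swap to 1-beta, 1-alpha
            g_fwd = cylindrical_channel(a, b, 0.5)
            g_rev = cylindrical_channel(1 - b, 1 - a, 0.5)
            f_fwd = flux_expansion(sp, BoundaryState(V, L1, R1, sigma, rho),
                                   g_fwd)
            f_rev = flux_expansion(sp, BoundaryState(-V, R1, L1, rho, sigma),
                                   g_rev)
            assert f_rev.J10 == pytest.approx(-f_fwd.J10, rel=1e-9)

    def test_degenerate_branch_continuity(self, species, geom):
        """Both sides of the guard band agree where they meet."""
        V = 0.8
        base = None
        for ratio in (1 + 2e-8, 1 + 5e-9):  # just outside / inside the guard
            bs = BoundaryState(V=V, L1=10.0 * ratio, R1=10.0)
            fx = flux_expansion(species, bs, geom)
            if base is None:
                base = fx
            else:
                assert fx.J10 == pytest.approx(base.J10, rel=1e-7)
                assert fx.J11 == pytest.approx(base.J11, rel=1e-6)

    def test_all_outputs_finite(self, rng):
        from conftest import random_parameter_set
        for _ in range(50):
            sp, bs, g = random_parameter_set(rng)
            fx = flux_expansion(sp, bs, g)
            for v in (fx.J10, fx.J20, fx.J11, fx.J21):
                assert math.isfinite(v)
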