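"""Zeroth- and first-order ionic fluxes in the small permanent-charge expansion.

For two oppositely charged species (valences ``z1 > 0 > z2``) the individual
flux of species ``k`` expands in the permanent-charge amplitude ``Q0`` as

    J_k(V; Q0) = J_k0(V) + J_k1(V) Q0 + o(Q0),

with the zeroth order carrying the Goldman-Hodgkin-Katz-like structure and
the first order governed by three functionals: the slope

    lam = (phi_L - phi_R) / (ln c1_L - ln c1_R)

of the electric potential against log-concentration, and the geometry-weighted
functionals ``A`` and ``B`` built from the interior concentrations at the
charge-window edges.  Boundary layers enter through the effective
("electroneutral-limit") boundary values of potential and concentration,
parameterized by the neutrality-relaxation factors sigma and rho.

All quantities are dimensionless: potentials in units of kT/e, concentrations
in units of a characteristic number density, fluxes per unit diffusion
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import ChannelGeometry

__all__ = ["SpeciesPair", "BoundaryState", "ElectroneutralLimits",
           "FluxExpansion", "gamma", "electroneutral_limits", "flux_expansion"]

# below this value of |theta| = |ln c1L - ln c1R| the formulas switch to the
# removable-singularity branch (two-sided evaluation)
_THETA_TINY = 1e-8


@dataclass(frozen=True)
class SpeciesPair:
    """Valences and diffusion coefficients of the cation/anion pair."""

    z1: int
    z2: int
    D1: float
    D2: float

    def __post_init__(self) -> None:
        if not (self.z1 > 0 > self.z2):
            raise ValueError(f"need z1 > 0 > z2, got z1={self.z1}, z2={self.z2}")
        if self.D1 <= 0 or self.D2 <= 0:
            raise ValueError("diffusion coefficients must be positive")


@dataclass(frozen=True)
class BoundaryState:
    """Boundary data: potential, species-1 concentrations, neutrality factors.

    The species-2 concentrations follow from the relaxation factors:
    ``-z2 L2 = sigma z1 L1`` and ``-z2 R2 = rho z1 R1``; ``sigma = rho = 1``
    is exact electroneutrality at both reservoirs.
    """

    V: float
    L1: float
    R1: float
    sigma: float = 1.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if min(self.L1, self.R1, self.sigma, self.rho) <= 0:
            raise ValueError("L1, R1, sigma, rho must all be positive")

    def species2_concentrations(self, sp: SpeciesPair) -> tuple[float, float]:
        """(L2, R2) implied by the neutrality factors for the given valences."""
        L2 = self.sigma * sp.z1 * self.L1 / (-sp.z2)
        R2 = self.rho * sp.z1 * self.R1 / (-sp.z2)
        return L2, R2


@dataclass(frozen=True)
class ElectroneutralLimits:
    """Boundary-layer limiting values of potential and concentration.

    ``phiL``/``phiR`` are the potentials just inside the layers; ``c1L`` etc.
    the limiting concentrations satisfying bulk neutrality
    ``z1 c1 = -z2 c2``; ``c10a``/``c10b`` the zeroth-order species-1
    concentrations at the charge-window edges.
    """

    phiL: float
    phiR: float
    c1L: float
    c1R: float
    c2L: float
    c2R: float
    c10a: float
    c10b: float


@dataclass(frozen=True)
class FluxExpansion:
    """Fluxes to first order in Q0 together with their building blocks."""

    lam: float
    A: float
    B: float
    J10: float
    J20: float
    J11: float
    J21: float

    def scaled(self, sp: SpeciesPair) -> tuple[float, float, float, float]:
        """Number fluxes D_k J_k for both species and both orders."""
        return (sp.D1 * self.J10, sp.D2 * self.J20,
                sp.D1 * self.J11, sp.D2 * self.J21)

    def current(self, sp: SpeciesPair, Q0: float = 0.0) -> float:
        """I = z1 D1 (J10 + Q0 J11) + z2 D2 (J20 + Q0 J21)."""
        return (sp.z1 * sp.D1 * (self.J10 + Q0 * self.J11)
                + sp.z2 * sp.D2 * (self.J20 + Q0 * self.J21))


def gamma(t: float) -> float:
    """The monotone weight ``gamma(t) = (t ln t - t + 1)/((t - 1) ln t)``.

    Continuously extended by ``gamma(1) = 1/2``; maps ``(0, inf)`` onto
    ``(0, 1)`` increasingly, with limits 0 at 0+ and 1 at infinity.
    """
    if t <= 0:
        raise ValueError(f"gamma requires t > 0, got {t}")
    u = t - 1.0
    if abs(u) < 1e-5:
        # gamma(1+u) = 1/2 + u/12 - u^2/24 + ... (series of the closed form)
        return 0.5 + u / 12.0 - u * u / 24.0
    lt = math.log(t)
    return (t * lt - t + 1.0) / (u * lt)


def electroneutral_limits(sp: SpeciesPair, bs: BoundaryState,
                          geom: ChannelGeometry) -> ElectroneutralLimits:
    """Effective boundary values seen by the channel interior.

    The boundary layers (present when sigma or rho differ from 1) relax the
    imposed reservoir values to electroneutral limits:

        z1 c1L = -z2 c2L = (z1 L1)^(-z2/(z1-z2)) (-z2 L2)^(z1/(z1-z2)),
        phiL   = V - ln(-z2 L2 / (z1 L1)) / (z1 - z2),

    and mirror formulas on the right with V replaced by 0.  The interior
    zeroth-order concentration is linear in the resistance coordinate, giving
    ``c10a = c1L + alpha (c1R - c1L)`` and likewise at ``b``.
    """
    z1, z2 = sp.z1, sp.z2
    L2, R2 = bs.species2_concentrations(sp)
    q = z1 / (z1 - z2)
    # with Eq (5) substituted these reduce to c1L = sigma^q L1, c1R = rho^q R1
    c1L = (z1 * bs.L1) ** (-z2 / (z1 - z2)) * (-z2 * L2) ** q / z1
    c1R = (z1 * bs.R1) ** (-z2 / (z1 - z2)) * (-z2 * R2) ** q / z1
    c2L = z1 * c1L / (-z2)
    c2R = z1 * c1R / (-z2)
    phiL = bs.V - math.log(-z2 * L2 / (z1 * bs.L1)) / (z1 - z2)
    phiR = -math.log(-z2 * R2 / (z1 * bs.R1)) / (z1 - z2)
    c10a = c1L + geom.alpha * (c1R - c1L)
    c10b = c1L + geom.beta * (c1R - c1L)
    return ElectroneutralLimits(phiL=phiL, phiR=phiR, c1L=c1L, c1R=c1R,
                                c2L=c2L, c2R=c2R, c10a=c10a, c10b=c10b)


def _flux_from_limits(sp: SpeciesPair, bs: BoundaryState, geom: ChannelGeometry,
                      lim: ElectroneutralLimits) -> FluxExpansion:
    """Direct evaluation; requires ln(c1L/c1R) bounded away from zero.

    Differences are routed through a shared factor ``u = c1L - c1R`` and
    ``log1p`` so that the removable singularity at u -> 0 loses no precision
    until far inside the guard band (1 - B is an O(u) cancellation of two
    O(u) quantities and is formed from correlated terms).
    """
    z1, z2 = sp.z1, sp.z2
    al, be = geom.alpha, geom.beta
    H1 = geom.H_total
    L2, R2 = bs.species2_concentrations(sp)
    u = lim.c1L - lim.c1R
    d = u / lim.c1R
    th1 = math.log1p(d) if abs(d) < 0.5 else math.log(lim.c1L / lim.c1R)
    c10a = lim.c1L - al * u
    c10b = lim.c1L - be * u
    J10 = u * (z1 * bs.V + math.log(bs.L1 / bs.R1)) / (H1 * th1)
    J20 = ((lim.c2L - lim.c2R) * (z2 * bs.V + math.log(L2 / R2))
           / (H1 * th1))  # ln(c2L/c2R) = ln(c1L/c1R) by bulk neutrality
    lam = (lim.phiL - lim.phiR) / th1
    A = (al - be) * u * u / (c10a * c10b * th1)
    lnr = math.log1p((al - be) * u / c10a)   # ln(c10b / c10a)
    B = lnr / A
    oneB = (A - lnr) / A                      # 1 - B without cancellation
    J11 = A * (z2 * oneB * lam + 1.0) * (z1 * lam + 1.0) / ((z1 - z2) * H1)
    J21 = A * (z1 * oneB * lam + 1.0) * (z2 * lam + 1.0) / ((z2 - z1) * H1)
    for name, v in (("J10", J10), ("J20", J20), ("J11", J11), ("J21", J21)):
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite flux {name}")
    return FluxExpansion(lam=lam, A=A, B=B, J10=J10, J20=J20, J11=J11, J21=J21)


def flux_expansion(sp: SpeciesPair, bs: BoundaryState,
                   geom: ChannelGeometry) -> FluxExpansion:
    """Zeroth- and first-order fluxes for the given boundary state.

    The formulas have a removable singularity at ``c1L = c1R`` (equal
    effective concentrations).  Inside a narrow guard band the value is taken
    as the mean of two evaluations at symmetrically displaced log-ratios,
    which reproduces the analytic limit to second order in the displacement.
    """
    lim = electroneutral_limits(sp, bs, geom)
    th = math.log(lim.c1L) - math.log(lim.c1R)
    if abs(th) >= _THETA_TINY:
        return _flux_from_limits(sp, bs, geom, lim)
    if bs.V == 0.0 and th == 0.0 and bs.sigma == bs.rho and bs.L1 == bs.R1:
        # true equilibrium: all gradients vanish identically
        return FluxExpansion(lam=math.nan, A=0.0, B=math.nan,
                             J10=0.0, J20=0.0, J11=0.0, J21=0.0)
    delta = 1e-5
    vals = []
    for sgn in (+1.0, -1.0):
        c1L = lim.c1R * math.exp(sgn * delta)
        shifted = ElectroneutralLimits(
            phiL=lim.phiL, phiR=lim.phiR, c1L=c1L, c1R=lim.c1R,
            c2L=sp.z1 * c1L / (-sp.z2), c2R=lim.c2R,
            c10a=c1L + geom.alpha * (lim.c1R - c1L),
            c10b=c1L + geom.beta * (lim.c1R - c1L))
        vals.append(_flux_from_limits(sp, bs, geom, shifted))
    mean = lambda f: 0.5 * (getattr(vals[0], f) + getattr(vals[1], f))
    return FluxExpansion(lam=mean("lam"), A=mean("A"), B=mean("B"),
                         J10=mean("J10"), J20=mean("J20"),
                         J11=mean("J11"), J21=mean("J21"))
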