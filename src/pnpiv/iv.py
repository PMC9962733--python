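"""Exact current-voltage relation in the neutrality-relaxation parameters.

With the species-2 boundary concentrations tied to species 1 through the
relaxation factors (sigma, rho), the current to first order in the
permanent-charge amplitude Q0 is

    I(V; Q0) = I0(V) + I1(V) Q0 + o(Q0),
    I0(V) = P00 + P01 V,
    I1(V) = P10 + P11 V + P12 V^2,

where the five P-coefficients are explicit functions of (sigma, rho) built
from

    theta(sigma, rho) = z1/(z1 - z2) (ln sigma - ln rho) + ln L1 - ln R1,
    omega(x; sigma, rho) = (1 - x) sigma^q L1 + x rho^q R1,   q = z1/(z1-z2),

and the flux functionals lam, A, B re-expressed in these variables.  This
module evaluates those closed forms; the flux module provides the independent
second path used for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .flux import BoundaryState, SpeciesPair
from .geometry import ChannelGeometry

__all__ = ["SigmaRhoIntermediates", "PCoefficients", "IVExpansion",
           "sigma_rho_intermediates", "p_coefficients", "iv_exact"]

_THETA_TINY = 1e-8


@dataclass(frozen=True)
class SigmaRhoIntermediates:
    theta: float
    omega_alpha: float
    omega_beta: float
    lam: float
    A: float
    B: float
    degenerate: bool = False  # theta fell inside the guard band


@dataclass(frozen=True)
class PCoefficients:
    """I0 = P00 + P01 V (linear); I1 = P10 + P11 V + P12 V^2 (quadratic)."""

    P00: float
    P01: float
    P10: float
    P11: float
    P12: float

    def I0(self, V):
        return self.P00 + self.P01 * V

    def I1(self, V):
        return self.P10 + (self.P11 + self.P12 * V) * V

    def I(self, V, Q0):
        return self.I0(V) + Q0 * self.I1(V)


@dataclass(frozen=True)
class IVExpansion:
    """Polynomial representation of the I-V relation at fixed (sigma, rho)."""

    coeffs: PCoefficients
    sigma: float
    rho: float

    @property
    def I0_coeffs(self) -> tuple[float, float]:
        return (self.coeffs.P00, self.coeffs.P01)

    @property
    def I1_coeffs(self) -> tuple[float, float, float]:
        return (self.coeffs.P10, self.coeffs.P11, self.coeffs.P12)

    def reversal_potential_order0(self) -> float:
        """Zero of the zeroth-order relation, V = -P00/P01."""
        return -self.coeffs.P00 / self.coeffs.P01


def _omega(x: float, sq: float, rq: float, L1: float, R1: float) -> float:
    return (1.0 - x) * sq * L1 + x * rq * R1


def sigma_rho_intermediates(sp: SpeciesPair, bs: BoundaryState,
                            geom: ChannelGeometry) -> SigmaRhoIntermediates:
    """theta, omega(alpha), omega(beta), lam, A, B at the given (sigma, rho).

    Dual path to the flux module: here everything is expressed directly in
    (sigma, rho), whereas the flux module goes through the electroneutral
    boundary limits.  Both must agree to rounding error.
    """
    z1, z2 = sp.z1, sp.z2
    q = z1 / (z1 - z2)
    s = math.log(bs.sigma) - math.log(bs.rho)
    sq, rq = bs.sigma**q, bs.rho**q
    theta = q * s + math.log(bs.L1) - math.log(bs.R1)
    wa = _omega(geom.alpha, sq, rq, bs.L1, bs.R1)
    wb = _omega(geom.beta, sq, rq, bs.L1, bs.R1)
    degenerate = abs(theta) < _THETA_TINY
    if degenerate:
        th_eval = math.copysign(_THETA_TINY, theta if theta != 0 else 1.0)
    else:
        th_eval = theta
    lam = (bs.V - s / (z1 - z2)) / th_eval
    diff = sq * bs.L1 - rq * bs.R1
    A = (geom.alpha - geom.beta) * diff**2 / (th_eval * wb * wa)
    if A != 0.0:
        B = th_eval * wa * wb * math.log(wb / wa) / ((geom.alpha - geom.beta) * diff**2)
    else:
        B = math.nan
    return SigmaRhoIntermediates(theta=theta, omega_alpha=wa, omega_beta=wb,
                                 lam=lam, A=A, B=B, degenerate=degenerate)


def p_coefficients(sp: SpeciesPair, bs: BoundaryState,
                   geom: ChannelGeometry) -> PCoefficients:
    """The five P-coefficients at (sigma, rho); V in ``bs`` is ignored."""
    z1, z2 = sp.z1, sp.z2
    D1, D2 = sp.D1, sp.D2
    H1 = geom.H_total
    zz = z1 - z2
    q = z1 / zz
    s = math.log(bs.sigma) - math.log(bs.rho)
    lnt = math.log(bs.L1) - math.log(bs.R1)
    inter = sigma_rho_intermediates(sp, bs, geom)
    th = inter.theta if not inter.degenerate else math.copysign(_THETA_TINY, 1.0)
    diff = bs.sigma**q * bs.L1 - bs.rho**q * bs.R1
    A, B = inter.A, inter.B
    if not math.isfinite(B):
        B = 1.0  # A = 0 limit; the products A*(1-B) below vanish anyway
    P00 = z1 * diff * ((D1 - D2) * lnt - D2 * s) / (H1 * th)
    P01 = z1 * (z1 * D1 - z2 * D2) * diff / (H1 * th)
    K = z1 * z2 * (D1 - D2) * (1.0 - B) + z1**2 * D1 - z2**2 * D2
    P10 = A / (zz * H1) * (
        z1 * z2 * (z1 * D1 - z2 * D2) * (1.0 - B) * s**2 / (zz**2 * th**2)
        - K * s / (zz * th) + z1 * D1 - z2 * D2)
    P11 = A / (zz * H1) * (
        -2.0 * z1 * z2 * (z1 * D1 - z2 * D2) * (1.0 - B) * s / (zz * th**2)
        + K / th)
    P12 = z1 * z2 * (z1 * D1 - z2 * D2) * (1.0 - B) * A / (zz * H1 * th**2)
    return PCoefficients(P00=P00, P01=P01, P10=P10, P11=P11, P12=P12)


def iv_exact(sp: SpeciesPair, bs: BoundaryState, geom: ChannelGeometry,
             V: float | None = None, Q0: float = 0.0
             ) -> tuple[float, float, float]:
    """(I0, I1, I) at potential ``V`` (defaults to ``bs.V``)."""
    if V is None:
        V = bs.V
    pc = p_coefficients(sp, bs, geom)
    I0 = pc.I0(V)
    I1 = pc.I1(V)
    return I0, I1, I0 + Q0 * I1


def iv_expansion(sp: SpeciesPair, bs: BoundaryState,
                 geom: ChannelGeometry) -> IVExpansion:
    """Polynomial I-V representation at the boundary state's (sigma, rho)."""
    return IVExpansion(coeffs=p_coefficients(sp, bs, geom),
                      sigma=bs.sigma, rho=bs.rho)
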