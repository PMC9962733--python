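"""Sign analysis of the boundary-layer difference currents and their zeros.

The boundary-layer terms I0d (linear in V) and I1d (quadratic in V) change
sign at critical potentials that depend on the concentration ratio
``t = L1/R1``, the charge-window position ``alpha = H(a)/H(1)`` in resistance
coordinates, and the direction of the neutrality relaxation (sigma vs rho).
This module implements the threshold apparatus governing those signs:

* ``ell(t)`` — the shape function whose sign gives the slope of I0d, with a
  unique interior root ``t*`` in the mixed regime;
* ``alpha1 = (t - sqrt(t))/(t - 1)`` and the roots ``alpha3 < alpha4`` of the
  concave quadratic ``g2``, which organize the monotonicity of I1d;
* ``beta1`` — the window-end threshold where the V^2 coefficient of I1d
  changes sign when ``alpha`` lies between ``alpha1`` and ``alpha4``;
* ``g4`` and its zero ``alpha*`` — the discriminant kernel deciding whether
  I1d has real zeros as the charge window shrinks (``beta -> alpha``);
* the discriminant ``Delta`` of I1d with its five-part decomposition, and all
  critical potentials (zeros of I0d, I1d, vertex of I1d, and the reversal
  potentials of the full relations with and without boundary layers).

``g4`` is evaluated from the exact beta->alpha limit of the discriminant's
second derivative (a closed-form quadratic form); the equivalent textbook-
style expanded polynomial is unwieldy and numerically no better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .expansion import ExpansionAtEN, boundary_layer_difference, expansion_at_EN
from .flux import BoundaryState, SpeciesPair
from .iv import p_coefficients

__all__ = ["ell", "lemma_shape", "ShapeClassification", "alpha_thresholds",
           "beta1", "g4", "alpha_star", "discriminant", "critical_potentials",
           "CriticalPotentials", "classify_region"]


class ThresholdUndefinedError(ValueError):
    """A threshold does not exist (complex roots / no sign change)."""


@dataclass(frozen=True)
class _FrameGeom:
    """Minimal geometry stand-in: only (alpha, beta, H(1)) enter the theory."""

    alpha: float
    beta: float
    H_total: float = 1.0


# ---------------------------------------------------------------------------
# slope of I0d: the shape function ell(t)
# ---------------------------------------------------------------------------

def ell(t: float, sigma: float, rho: float) -> float:
    """Shape function (sigma-1) t ln t + (1-rho) ln t + (rho-sigma)(t-1).

    The slope of I0d in V is a positive multiple of ``ell(t)``.
    """
    lt = math.log(t)
    return (sigma - 1.0) * t * lt + (1.0 - rho) * lt + (rho - sigma) * (t - 1.0)


@dataclass(frozen=True)
class ShapeClassification:
    branch: str               # "i", "ii", "iii" or "out-of-hypothesis"
    sign_at_t: int            # sign of ell(t) at the supplied t
    t_star: float | None      # root of ell, branch iii only


def lemma_shape(t: float, sigma: float, rho: float) -> ShapeClassification:
    """Classify the sign of ell(t) for t > 1, sigma > rho.

    Branch (i): sigma + rho > 2 with sigma > 1 — ell > 0 for all t > 1.
    Branch (ii): sigma + rho < 2 with sigma < 1 — ell < 0.
    Branch (iii): sigma + rho < 2 with sigma > 1 — a unique root t* > 1
    separates ell < 0 (t < t*) from ell > 0 (t > t*).
    """
    val = ell(t, sigma, rho)
    sgn = int(math.copysign(1.0, val)) if val != 0.0 else 0
    if not (t > 1.0 and sigma > rho):
        return ShapeClassification("out-of-hypothesis", sgn, None)
    if sigma + rho > 2.0 and sigma > 1.0:
        return ShapeClassification("i", sgn, None)
    if sigma + rho < 2.0 and sigma < 1.0:
        return ShapeClassification("ii", sgn, None)
    if sigma + rho < 2.0 and sigma > 1.0:
        lo = 1.0 + 1e-9
        hi = 2.0
        while ell(hi, sigma, rho) < 0.0:
            hi *= 2.0
            if hi > 1e9:
                raise ThresholdUndefinedError(
                    "no sign change of ell on (1, 1e9)")
        t_star = brentq(ell, lo, hi, args=(sigma, rho), xtol=1e-14, rtol=1e-15)
        return ShapeClassification("iii", sgn, t_star)
    return ShapeClassification("out-of-hypothesis", sgn, None)


# ---------------------------------------------------------------------------
# alpha thresholds from the quadratic g2
# ---------------------------------------------------------------------------

def _omega1(alpha: float, t: float) -> float:
    return (1.0 - alpha) * t + alpha


def g2(alpha: float, t: float) -> float:
    """Concave-down quadratic in alpha controlling d(g1)/dbeta at beta=alpha."""
    lt = math.log(t)
    w = _omega1(alpha, t)
    return ((1.0 - t) * (2.0 * t * lt + 3.0 * (1.0 - t) * w)
            + t * w * lt**2 - 2.0 * (t - 1.0) * w**2 * lt)


def alpha_thresholds(t: float) -> tuple[float, float, float, float]:
    """(alpha1, alpha3, alpha4, p_t) for t > 1.

    ``alpha3 < alpha4`` are the roots of ``g2``; computed from the expanded
    quadratic coefficients (primary) and cross-checked against the closed
    form involving ``sqrt(p(t))`` with
    ``p(t) = 9(t-1)^4 + t^2 ln^4 t - 10 t (t-1)^2 ln^2 t``.
    """
    if t <= 1.0:
        raise ValueError(f"alpha thresholds require t > 1, got t={t}")
    lt = math.log(t)
    alpha1 = (t - math.sqrt(t)) / (t - 1.0)
    # expand g2 in alpha: coefficients via omega1 = t - (t-1) alpha
    a = -2.0 * (t - 1.0) ** 3 * lt
    b = (t - 1.0) * (-3.0 * (t - 1.0) ** 2 - t * lt**2
                     + 4.0 * t * (t - 1.0) * lt)
    c = t * (3.0 * (t - 1.0) ** 2 + t * lt**2
             - 2.0 * (t - 1.0) * (1.0 + t) * lt)
    disc = b * b - 4.0 * a * c
    p_t = 9.0 * (t - 1.0) ** 4 + t**2 * lt**4 - 10.0 * t * (t - 1.0) ** 2 * lt**2
    if disc < 0.0:
        raise ThresholdUndefinedError(
            f"g2 has complex roots at t={t} (p(t)={p_t})")
    r1 = (-b - math.sqrt(disc)) / (2.0 * a)
    r2 = (-b + math.sqrt(disc)) / (2.0 * a)
    alpha3, alpha4 = min(r1, r2), max(r1, r2)
    return alpha1, alpha3, alpha4, p_t


# ---------------------------------------------------------------------------
# g(beta): the V^2 coefficient of I1d as the window end moves
# ---------------------------------------------------------------------------

def _quad_coeff_of_I1d(t: float, alpha: float, beta: float, sigma: float,
                       rho: float, sp: SpeciesPair) -> float:
    """g(beta) = dP12/dsigma (sigma-1) + dP12/drho (rho-1), in t-units."""
    exp = expansion_at_EN(sp, t, 1.0, _FrameGeom(alpha, beta))
    return (exp.dP_dsigma["P12"] * (sigma - 1.0)
            + exp.dP_drho["P12"] * (rho - 1.0))


def beta1(t: float, alpha: float, sp: SpeciesPair,
          sigma: float = 1.01, rho: float = 0.99) -> float:
    """Unique root of g(beta) in (alpha, 1) when alpha in [alpha1, alpha4).

    In that window the V^2 coefficient of I1d is negative for
    beta in (alpha, beta1) and positive beyond.
    """
    a1, a3, a4, _ = alpha_thresholds(t)
    if not (a1 <= alpha < a4):
        raise ValueError(
            f"beta1 requires alpha in [alpha1, alpha4) = [{a1:.6f}, {a4:.6f}),"
            f" got {alpha}")
    f = lambda b: _quad_coeff_of_I1d(t, alpha, b, sigma, rho, sp)
    grid = np.linspace(alpha + 1e-9, 1.0 - 1e-9, 10_000)
    vals = np.array([f(b) for b in grid])
    sign_flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_flips) == 0:
        raise ThresholdUndefinedError(
            f"no sign change of g(beta) on ({alpha}, 1) at t={t}")
    i = sign_flips[0]
    return brentq(f, grid[i], grid[i + 1], xtol=1e-13)


# ---------------------------------------------------------------------------
# g4 and alpha*: the shrinking-window discriminant kernel
# ---------------------------------------------------------------------------

def g4(t: float, alpha: float, sp: SpeciesPair) -> float:
    """Discriminant kernel: sign of Delta as the charge window shrinks.

    Defined through the limit of the second beta-derivative of the scaled
    discriminant Delta1 at beta = alpha:

        lim_{beta->alpha} Delta1'' = 2 z1^2 (t-1)^2 (sigma-rho)^2
                                     / ((z1-z2)^2 omega1(alpha)^6 ln^4 t) g4,

    which collapses to a (sigma, rho)-independent quadratic form in the limit
    derivatives of the expansion functionals A and B.
    """
    z1, z2, D1, D2 = sp.z1, sp.z2, sp.D1, sp.D2
    lnt = math.log(t)
    f0 = (t - 1.0) / lnt
    w = _omega1(alpha, t)
    q = z1 / (z1 - z2)
    # beta->alpha limit derivatives (per unit (beta - alpha) and (sigma - rho))
    Aa = -(t - 1.0) * f0 / w**2
    brs = 2.0 * t - f0 - 2.0 * (1.0 - alpha) * t * (t - 1.0) / w
    Xa = -q * f0 / w**2 * brs                      # d/dbeta of dA increments
    Ya = Aa * q * (t - w * brs) / ((t - 1.0) * f0)  # d/dbeta of A * dB incr.
    Za = q * Aa / lnt
    oneB = 1.0 - w / f0                             # lim (1 - B) / ln t * ln t
    P = z1 * z2
    E = P * (D1 - D2)
    F = z1 * D1 - z2 * D2
    Fp = z1**2 * D1 - z2**2 * D2
    Mb = (P * oneB * (8.0 * P * D1 * D2
                      - 2.0 * (z1**2 * D1 + z2**2 * D2) * (D1 + D2))
          + Fp**2 + E**2 * oneB**2)
    W = Fp + z2 * oneB * (2.0 * z2 * D2 - z1 * D1 - z1 * D2)
    C13 = -z1**2 * z2 * (D1 - D2) ** 2 * oneB + Fp * (z1 * D1 + z1 * D2
                                                      - 2.0 * z2 * D2)
    C14 = 2.0 * F**2 - P * (D1 - D2) ** 2 * oneB - (D1 - D2) * Fp
    Q2 = (Mb * Xa * (Xa - 2.0 * Za) + W**2 * Za**2 + E**2 * Ya**2
          - 2.0 * z2 * C13 * Ya * Za + 2.0 * P * C14 * Xa * Ya)
    return Q2 * (z1 - z2) ** 2 * w**6 * lnt**4 / (z1**2 * (t - 1.0) ** 2)


def alpha_star(t: float, sp: SpeciesPair) -> tuple[float, list[float]]:
    """(alpha*, all_sign_changes) — zeros of g4(alpha) on (0, 1) for t in (1, 2).

    ``alpha*`` is the sign change located inside (alpha3, alpha1), the window
    assumed by the shrinking-window classification; the full list of sign
    changes on (0, 1) is returned alongside because the root count of g4 is
    sensitive to t.
    """
    if not (1.0 < t < 2.0):
        raise ValueError(f"alpha_star requires t in (1, 2), got t={t}")
    f = lambda a: g4(t, a, sp)
    grid = np.linspace(0.01, 0.99, 10_000)
    vals = np.array([f(a) for a in grid])
    flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    roots = [brentq(f, grid[i], grid[i + 1], xtol=1e-13) for i in flips]
    _, a3, _, _ = alpha_thresholds(t)
    a1 = alpha_thresholds(t)[0]
    in_window = [r for r in roots if a3 < r < a1]
    if len(in_window) != 1:
        raise ThresholdUndefinedError(
            f"expected one zero of g4 in (alpha3, alpha1), found {len(in_window)}"
            f" (all sign changes: {roots})")
    return in_window[0], roots


# ---------------------------------------------------------------------------
# discriminant of I1d with its five-part decomposition
# ---------------------------------------------------------------------------

def discriminant(exp: ExpansionAtEN, sigma: float, rho: float
                 ) -> tuple[float, tuple[float, float, float, float, float]]:
    """(Delta, (Delta10..Delta14)) for I1d at the given (sigma, rho).

    Delta equals the polynomial discriminant c1^2 - 4 c0 c2 of I1d; the parts
    sum to Delta1 = Delta * (z1-z2)^2 H(1)^2 (ln L1 - ln R1)^2.  The
    decomposition is written in the increments

        X = dA/dsigma (sigma-1) + dA/drho (rho-1),
        Y = A(1,1) [dB/dsigma (sigma-1) + dB/drho (rho-1)],
        Z = z1 (sigma-rho) A(1,1) / ((z1-z2)(ln L1 - ln R1)).
    """
    sp = exp.sp
    z1, z2, D1, D2 = sp.z1, sp.z2, sp.D1, sp.D2
    zz = z1 - z2
    lnt = math.log(exp.L1) - math.log(exp.R1)
    ds, dr = sigma - 1.0, rho - 1.0
    X = exp.dA_dsigma * ds + exp.dA_drho * dr
    Y = exp.A11 * (exp.dB_dsigma * ds + exp.dB_drho * dr)
    Z = z1 * (sigma - rho) * exp.A11 / (zz * lnt)
    B = exp.B11
    P = z1 * z2
    E = P * (D1 - D2)
    F = z1 * D1 - z2 * D2
    Fp = z1**2 * D1 - z2**2 * D2
    oneB = 1.0 - B
    Mb = (P * oneB * (8.0 * P * D1 * D2
                      - 2.0 * (z1**2 * D1 + z2**2 * D2) * (D1 + D2))
          + Fp**2 + E**2 * oneB**2)
    W = Fp + z2 * oneB * (2.0 * z2 * D2 - z1 * D1 - z1 * D2)
    C13 = -z1**2 * z2 * (D1 - D2) ** 2 * oneB + Fp * (z1 * D1 + z1 * D2
                                                      - 2.0 * z2 * D2)
    C14 = 2.0 * F**2 - P * (D1 - D2) ** 2 * oneB - (D1 - D2) * Fp
    D10 = Mb * X * (X - 2.0 * Z)
    D11 = W**2 * Z**2
    D12 = E**2 * Y**2
    D13 = -2.0 * z2 * C13 * Y * Z
    D14 = 2.0 * P * C14 * Y * X
    delta1 = D10 + D11 + D12 + D13 + D14
    delta = delta1 / (zz**2 * exp.H1**2 * lnt**2)
    return delta, (D10, D11, D12, D13, D14)


# ---------------------------------------------------------------------------
# critical potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriticalPotentials:
    """Zeros and vertex of the difference terms plus full-relation zeros.

    ``V0d`` is the unique zero of I0d, labelled ``V01d`` when I0d is
    increasing (enhancement above the zero) and ``V02d`` when decreasing.
    ``V1d_pair`` holds the real zeros of I1d when the discriminant is
    positive, labelled V11d < V12d (concave-up branch) or V13d < V14d.
    ``V1c`` is the vertex (extremum) of I1d.  The EN/bd entries are zeros of
    the exact zeroth/first-order relations under electroneutral and relaxed
    boundary conditions respectively.
    """

    V0d: float | None
    V0d_label: str
    V1c: float | None
    V1d_pair: tuple[float, float] | None
    V1d_labels: tuple[str, str] | None
    delta: float
    V01EN: float
    V01bd: float
    V1EN_pair: tuple[float, float] | None
    V1bd_pair: tuple[float, float] | None
    notes: list[str] = field(default_factory=list)


def _real_quad_roots(c0: float, c1: float, c2: float
                     ) -> tuple[float, float] | None:
    """Stable real roots of c2 V^2 + c1 V + c0, ascending, or None."""
    if c2 == 0.0:
        if c1 == 0.0:
            return None
        r = -c0 / c1
        return (r, r)
    disc = c1 * c1 - 4.0 * c0 * c2
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    qq = -0.5 * (c1 + math.copysign(sq, c1))
    r1 = qq / c2
    r2 = c0 / qq if qq != 0.0 else -c1 / c2 - r1
    return (min(r1, r2), max(r1, r2))


def _polished(roots, c0, c1, c2):
    """Re-verify quadratic-formula roots by bisection on the polynomial."""
    if roots is None:
        return None
    f = lambda v: c0 + (c1 + c2 * v) * v
    out = []
    for r in roots:
        w = max(1e-6, 1e-6 * abs(r))
        lo, hi = r - w, r + w
        k = 0
        while f(lo) * f(hi) > 0.0 and k < 60:
            w *= 4.0
            lo, hi = r - w, r + w
            k += 1
        out.append(brentq(f, lo, hi, xtol=1e-13) if f(lo) * f(hi) <= 0.0 else r)
    return (min(out), max(out))


def critical_potentials(exp: ExpansionAtEN, sigma: float, rho: float
                        ) -> CriticalPotentials:
    """All critical potentials for the given neutrality relaxation."""
    notes: list[str] = []
    bld = boundary_layer_difference(exp, sigma, rho)
    a0, a1c = bld.I0d_coeffs
    c0, c1, c2 = bld.I1d_coeffs
    if a1c != 0.0:
        V0d = -a0 / a1c
        V0d_label = "V01d" if a1c > 0.0 else "V02d"
    else:
        V0d, V0d_label = None, "undefined (zero slope)"
        notes.append("I0d has zero slope; no unique zero")
    V1c = -c1 / (2.0 * c2) if c2 != 0.0 else None
    delta, _ = discriminant(exp, sigma, rho)
    pair = _polished(_real_quad_roots(c0, c1, c2), c0, c1, c2) \
        if delta >= 0.0 else None
    if pair is not None:
        labels = ("V11d", "V12d") if c2 > 0.0 else ("V13d", "V14d")
    else:
        labels = None

    # zeros of the exact relations, with (EN) and without (bd) neutrality
    geom = _FrameGeom(exp.alpha, exp.beta, exp.H1)
    pc_en = p_coefficients(exp.sp, BoundaryState(0.0, exp.L1, exp.R1), geom)
    pc_bd = p_coefficients(exp.sp,
                           BoundaryState(0.0, exp.L1, exp.R1, sigma, rho), geom)
    V01EN = -pc_en.P00 / pc_en.P01
    V01bd = -pc_bd.P00 / pc_bd.P01
    en_pair = _polished(_real_quad_roots(pc_en.P10, pc_en.P11, pc_en.P12),
                        pc_en.P10, pc_en.P11, pc_en.P12)
    bd_pair = _polished(_real_quad_roots(pc_bd.P10, pc_bd.P11, pc_bd.P12),
                        pc_bd.P10, pc_bd.P11, pc_bd.P12)
    return CriticalPotentials(V0d=V0d, V0d_label=V0d_label, V1c=V1c,
                              V1d_pair=pair, V1d_labels=labels, delta=delta,
                              V01EN=V01EN, V01bd=V01bd,
                              V1EN_pair=en_pair, V1bd_pair=bd_pair,
                              notes=notes)


# ---------------------------------------------------------------------------
# theorem-branch classification
# ---------------------------------------------------------------------------

def classify_region(t: float, alpha: float, beta: float, sigma: float,
                    rho: float, sp: SpeciesPair) -> dict:
    """Branch labels for the monotonicity/sign statements of I0d and I1d.

    Returns a dict with keys ``monotonicity_I0d``, ``monotonicity_I1d`` and
    ``sign_I1d`` plus the thresholds used.  Hypotheses: t > 1, sigma > rho,
    (sigma, rho) within 0.25 of (1, 1); otherwise the corresponding label is
    "unclassified" (degenerate sigma = rho returns "electroneutral").
    """
    out: dict = {"t": t, "alpha": alpha, "beta": beta,
                 "sigma": sigma, "rho": rho}
    if sigma == rho == 1.0:
        out["label"] = "electroneutral"
        return out
    if max(abs(sigma - 1.0), abs(rho - 1.0)) > 0.25:
        out["warning"] = "(sigma, rho) far from (1, 1); expansion unreliable"
    if not (t > 1.0 and sigma > rho):
        out["label"] = "unclassified"
        out["reason"] = "requires t > 1 and sigma > rho"
        return out

    shape = lemma_shape(t, sigma, rho)
    if shape.branch == "i":
        out["monotonicity_I0d"] = "(i1) increasing; unique zero V01d"
    elif shape.branch == "ii":
        out["monotonicity_I0d"] = "(ii1) decreasing; unique zero V02d"
    elif shape.branch == "iii":
        assert shape.t_star is not None
        out["t_star"] = shape.t_star
        if t > shape.t_star:
            out["monotonicity_I0d"] = "(i2) increasing; unique zero V01d"
        else:
            out["monotonicity_I0d"] = "(ii2) decreasing; unique zero V02d"
    else:
        out["monotonicity_I0d"] = "unclassified"

    a1, a3, a4, _ = alpha_thresholds(t)
    out["alpha1"], out["alpha3"], out["alpha4"] = a1, a3, a4
    if alpha < a3:
        out["monotonicity_I1d"] = "(i) concave up: increasing for V > V1c"
    elif alpha < a1:
        out["monotonicity_I1d"] = "(ii) concave down: increasing for V < V1c"
    elif alpha < a4:
        try:
            b1 = beta1(t, alpha, sp, sigma, rho)
            out["beta1"] = b1
            side = "decreasing in V" if beta < b1 else "increasing in V"
            out["monotonicity_I1d"] = f"(iii) beta1 governs: {side}"
        except ThresholdUndefinedError as e:
            out["monotonicity_I1d"] = f"(iii) beta1 not found: {e}"
    else:
        out["monotonicity_I1d"] = "(iv) increasing in V"

    if 1.0 < t < 2.0:
        try:
            a_star, all_roots = alpha_star(t, sp)
            out["alpha_star"] = a_star
            out["g4_sign_changes"] = all_roots
            ordering_ok = a3 < a_star < a1 < a4
            out["ordering_ok"] = ordering_ok
            if ordering_ok:
                if alpha < a3:
                    out["sign_I1d"] = ("(i) Delta > 0: two zeros V11d < V12d, "
                                       "negative between them")
                elif alpha < a_star:
                    out["sign_I1d"] = ("(ii) Delta > 0: two zeros V13d < V14d, "
                                       "positive between them")
                elif alpha < a1:
                    out["sign_I1d"] = "(iii) Delta < 0: I1d < 0 for all V"
                elif alpha < a4:
                    out["sign_I1d"] = "(iv) beta1 governs the sign"
                else:
                    out["sign_I1d"] = "(v) I1d > 0 for all V"
            else:
                out["sign_I1d"] = "unclassified (threshold ordering violated)"
        except (ThresholdUndefinedError, ValueError) as e:
            out["sign_I1d"] = f"unclassified ({e})"
    else:
        out["sign_I1d"] = "unclassified (t outside (1, 2))"
    return out
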