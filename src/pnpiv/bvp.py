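"""Collocation solver for the full singularly perturbed steady-state system.

The rescaled steady-state Poisson-Nernst-Planck equations on x in [0, 1],

    eps phi' = u,
    eps (h u)' = -h (z1 c1 + z2 c2 + Q(x)),
    eps c_k'  = -z_k c_k u - eps J_k / h(x),      J_k' = 0,   k = 1, 2,

with Dirichlet data phi(0)=V, phi(1)=0, c_k(0)=L_k, c_k(1)=R_k, develop
boundary layers of width O(eps) at both ends (when electroneutrality is
relaxed) and internal layers at the permanent-charge jumps a and b.

The solver works on the three sub-intervals [0,a], [a,b], [b,1] mapped onto a
common collocation coordinate, stacking the four state variables per segment
plus the two global flux unknowns into one 14-component first-order system
for :func:`scipy.integrate.solve_bvp`.  Q is constant on each segment, so no
smoothing of the discontinuity is needed; continuity of (phi, h u, c1, c2) is
imposed at the interfaces.  The second Poisson equation is integrated in the
variable w = h u, avoiding derivatives of h at the (continuous but kinked)
junctions.  A geometric continuation in eps, warm-starting each solve from
the previous solution, carries the solution from the mildly stiff eps = 0.1
down to the target.

Sign convention: the current I = z1 D1 J1 + z2 D2 J2 is positive when net
positive charge flows from x = 0 towards x = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_bvp
from scipy.optimize import brentq

from .flux import BoundaryState, SpeciesPair, electroneutral_limits
from .geometry import ChannelGeometry
from .iv import p_coefficients

__all__ = ["PNPProblem", "BVPSolution", "solve_pnp_bvp", "iv_curve_numeric",
           "numeric_critical_potentials", "compare_numeric_analytic"]

_EPS_START = 0.1
_EPS_FACTOR = 0.7
_EPS_MIN = 1e-3


class SolverError(RuntimeError):
    """Collocation failed to converge or produced an inadmissible solution."""


@dataclass(frozen=True)
class PNPProblem:
    sp: SpeciesPair
    bs: BoundaryState
    geom: ChannelGeometry
    eps: float

    def __post_init__(self) -> None:
        if self.eps < _EPS_MIN:
            raise ValueError(
                f"eps below {_EPS_MIN} requires continuation beyond the "
                f"supported range, got {self.eps}")


@dataclass
class BVPSolution:
    mesh: np.ndarray
    phi: np.ndarray
    u: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    J1: float
    J2: float
    residual_max: float
    current: float
    _raw: object = None  # scipy result, kept for warm starts


def _segments(geom: ChannelGeometry):
    a, b = geom.a, geom.b
    return [(0.0, a, 0.0), (a, b, geom.Q0), (b, 1.0, 0.0)]


def _interior_guess(prob: PNPProblem, s: np.ndarray):
    """Outer (eps -> 0) profiles used as the continuation starting point."""
    sp, bs, geom = prob.sp, prob.bs, prob.geom
    lim = electroneutral_limits(sp, bs, geom)
    H1 = geom.H_total
    th = math.log(lim.c1L) - math.log(lim.c1R)
    lam = (lim.phiL - lim.phiR) / th if abs(th) > 1e-12 else 0.0
    y = np.zeros((14, s.size))
    for i, (x0, x1, _q) in enumerate(_segments(geom)):
        x = x0 + (x1 - x0) * s
        Hx = geom.H(x) / H1
        c1 = lim.c1L + Hx * (lim.c1R - lim.c1L)
        c1 = np.clip(c1, 1e-12, None)
        phi = lim.phiL + lam * (np.log(c1) - math.log(lim.c1L))
        y[4 * i + 0] = phi
        y[4 * i + 1] = 0.0
        y[4 * i + 2] = c1
        y[4 * i + 3] = sp.z1 * c1 / (-sp.z2)
    # outer fluxes from the zeroth-order theory
    if abs(th) > 1e-12:
        L2, R2 = bs.species2_concentrations(sp)
        y[12] = (lim.c1L - lim.c1R) * (sp.z1 * bs.V
                                       + math.log(bs.L1 / bs.R1)) / (H1 * th)
        y[13] = (lim.c2L - lim.c2R) * (sp.z2 * bs.V
                                       + math.log(L2 / R2)) / (H1 * th)
    return y


def _make_rhs_bc(prob: PNPProblem, eps: float):
    sp, bs, geom = prob.sp, prob.bs, prob.geom
    z1, z2 = sp.z1, sp.z2
    L2, R2 = bs.species2_concentrations(sp)
    segs = _segments(geom)

    def rhs(s, y):
        dy = np.empty_like(y)
        J1, J2 = y[12], y[13]
        for i, (x0, x1, q) in enumerate(segs):
            ell = x1 - x0
            x = x0 + ell * s
            h = geom.h(x)
            phi, w, c1, c2 = y[4 * i], y[4 * i + 1], y[4 * i + 2], y[4 * i + 3]
            u = w / h
            dy[4 * i + 0] = ell * u / eps
            dy[4 * i + 1] = -ell * h * (z1 * c1 + z2 * c2 + q) / eps
            dy[4 * i + 2] = ell * (-z1 * c1 * u / eps - J1 / h)
            dy[4 * i + 3] = ell * (-z2 * c2 * u / eps - J2 / h)
        dy[12] = 0.0
        dy[13] = 0.0
        return dy

    def bc(ya, yb):
        res = np.empty(14)
        # outer boundary data
        res[0] = ya[0] - bs.V
        res[1] = ya[2] - bs.L1
        res[2] = ya[3] - L2
        res[3] = yb[8]
        res[4] = yb[10] - bs.R1
        res[5] = yb[11] - R2
        # continuity of (phi, w, c1, c2) at the two interfaces
        res[6:10] = yb[0:4] - ya[4:8]
        res[10:14] = yb[4:8] - ya[8:12]
        return res

    return rhs, bc


def _solve_at_eps(prob: PNPProblem, eps: float, guess, s_mesh,
                  tol: float, max_nodes: int):
    rhs, bc = _make_rhs_bc(prob, eps)
    sol = solve_bvp(rhs, bc, s_mesh, guess, tol=tol, max_nodes=max_nodes,
                    verbose=0)
    if sol.status != 0:
        raise SolverError(
            f"collocation failed at eps={eps:g}: {sol.message} "
            f"(max residual {np.max(sol.rms_residuals):.3g})")
    return sol


def _layer_mesh(n: int) -> np.ndarray:
    """Collocation nodes on [0,1] clustered at both ends (layer regions)."""
    t = np.linspace(-1.0, 1.0, n)
    s = 0.5 * (1.0 + np.tanh(2.2 * t) / math.tanh(2.2))
    s[0], s[-1] = 0.0, 1.0
    return s


def solve_pnp_bvp(prob: PNPProblem, tol: float = 1e-8, max_nodes: int = 5000,
                  warm_start: BVPSolution | None = None) -> BVPSolution:
    """Solve the full system at ``prob.eps`` with continuation in eps.

    ``warm_start`` (a solution of a nearby problem, e.g. the previous point
    of a voltage sweep) skips the continuation and starts directly at the
    target eps.
    """
    sp, geom = prob.sp, prob.geom
    if warm_start is not None and warm_start._raw is not None:
        raw = warm_start._raw
        try:
            sol = _solve_at_eps(prob, prob.eps, raw.y, raw.x, tol, max_nodes)
            return _package(prob, sol)
        except SolverError:
            pass  # fall back to full continuation
    s_mesh = _layer_mesh(41)
    guess = _interior_guess(prob, s_mesh)
    eps = max(_EPS_START, prob.eps)
    sol = None
    while True:
        try:
            sol = _solve_at_eps(prob, eps, guess, s_mesh, tol, max_nodes)
        except SolverError:
            if sol is None:
                raise
            # refine continuation step
            eps_prev = eps / _EPS_FACTOR
            eps = eps_prev * math.sqrt(_EPS_FACTOR)
            guess, s_mesh = sol.y, sol.x
            sol = _solve_at_eps(prob, eps, guess, s_mesh, tol, max_nodes)
        guess, s_mesh = sol.y, sol.x
        if eps <= prob.eps * (1.0 + 1e-12):
            break
        eps = max(prob.eps, eps * _EPS_FACTOR)
    return _package(prob, sol)


def _package(prob: PNPProblem, sol) -> BVPSolution:
    sp, geom = prob.sp, prob.geom
    segs = _segments(geom)
    xs, phis, us, c1s, c2s = [], [], [], [], []
    for i, (x0, x1, _q) in enumerate(segs):
        x = x0 + (x1 - x0) * sol.x
        h = geom.h(x)
        sl = slice(None, -1) if i < 2 else slice(None)
        xs.append(x[sl])
        phis.append(sol.y[4 * i][sl])
        us.append((sol.y[4 * i + 1] / h)[sl])
        c1s.append(sol.y[4 * i + 2][sl])
        c2s.append(sol.y[4 * i + 3][sl])
    mesh = np.concatenate(xs)
    c1 = np.concatenate(c1s)
    c2 = np.concatenate(c2s)
    if np.any(c1 <= 0.0) or np.any(c2 <= 0.0):
        raise SolverError("converged solution has non-positive concentration")
    J1, J2 = float(sol.y[12, 0]), float(sol.y[13, 0])
    current = sp.z1 * sp.D1 * J1 + sp.z2 * sp.D2 * J2
    return BVPSolution(mesh=mesh, phi=np.concatenate(phis),
                       u=np.concatenate(us), c1=c1, c2=c2, J1=J1, J2=J2,
                       residual_max=float(np.max(sol.rms_residuals)),
                       current=current, _raw=sol)


# ---------------------------------------------------------------------------
# I-V curves and numeric critical potentials
# ---------------------------------------------------------------------------

def _with(prob: PNPProblem, V: float | None = None,
          Q0: float | None = None) -> PNPProblem:
    bs = prob.bs if V is None else replace(prob.bs, V=V)
    geom = prob.geom
    if Q0 is not None and Q0 != geom.Q0:
        geom = replace(geom, Q0=Q0)
    return PNPProblem(sp=prob.sp, bs=bs, geom=geom, eps=prob.eps)


def iv_curve_numeric(prob: PNPProblem, V_grid, mode: str = "order0",
                     Q0: float | None = None, tol: float = 1e-8) -> dict:
    """Numeric I-V table.

    mode "order0": current at Q0 = 0 (zeroth order in the permanent charge).
    mode "order1": centered difference (I(+Q0) - I(-Q0)) / (2 Q0), the
    numeric analogue of the first-order coefficient I1(V).

    Returns a dict with arrays V, I and per-point status flags; failed points
    carry NaN and the error message.
    """
    if mode not in ("order0", "order1"):
        raise ValueError(f"unknown mode {mode!r}")
    if Q0 is None:
        Q0 = prob.geom.Q0
    V_grid = np.atleast_1d(np.asarray(V_grid, dtype=float))
    if V_grid.size == 0:
        raise ValueError("V grid is empty")
    I = np.full(V_grid.shape, np.nan)
    flags = []
    warm_p = warm_m = None
    for j, V in enumerate(V_grid):
        try:
            if mode == "order0":
                s0 = solve_pnp_bvp(_with(prob, V=V, Q0=0.0), tol=tol,
                                   warm_start=warm_p)
                warm_p = s0
                I[j] = s0.current
            else:
                sp_ = solve_pnp_bvp(_with(prob, V=V, Q0=+Q0), tol=tol,
                                    warm_start=warm_p)
                sm_ = solve_pnp_bvp(_with(prob, V=V, Q0=-Q0), tol=tol,
                                    warm_start=warm_m)
                warm_p, warm_m = sp_, sm_
                I[j] = (sp_.current - sm_.current) / (2.0 * Q0)
            flags.append("ok")
        except SolverError as e:
            flags.append(str(e))
    return {"V": V_grid, "I": I, "flags": flags, "mode": mode, "Q0": Q0,
            "eps": prob.eps, "sigma": prob.bs.sigma, "rho": prob.bs.rho}


def _curve_fun(prob: PNPProblem, mode: str, Q0: float, tol: float):
    cache: dict = {}

    def f(V: float) -> float:
        if V not in cache:
            cache[V] = float(iv_curve_numeric(prob, [V], mode=mode, Q0=Q0,
                                              tol=tol)["I"][0])
        return cache[V]

    return f


def numeric_critical_potentials(prob: PNPProblem, mode: str,
                                V_window: tuple[float, float],
                                Q0: float | None = None, n_scan: int = 9,
                                tol: float = 1e-8,
                                xtol: float = 1e-4) -> list[float]:
    """Zeros of the numeric order0/order1 curve inside ``V_window``.

    Scans ``n_scan`` points, brackets every sign change and polishes each by
    bisection, re-solving the boundary-value problem per iterate.
    """
    f = _curve_fun(prob, mode, Q0 if Q0 is not None else prob.geom.Q0, tol)
    Vs = np.linspace(*V_window, n_scan)
    vals = np.array([f(V) for V in Vs])
    good = np.isfinite(vals)
    Vs, vals = Vs[good], vals[good]
    roots = []
    for i in range(len(Vs) - 1):
        if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            roots.append(brentq(f, Vs[i], Vs[i + 1], xtol=xtol))
    return roots


def compare_numeric_analytic(prob: PNPProblem, V_grid, tol: float = 1e-8
                             ) -> dict:
    """Error table |I_bvp - (I0 + Q0 I1)| / scale on the V grid.

    The analytic value is the eps -> 0, first-order-in-Q0 prediction; the gap
    is dominated by the finite eps of the numeric solve.
    """
    V_grid = np.atleast_1d(np.asarray(V_grid, dtype=float))
    Q0 = prob.geom.Q0
    pc = p_coefficients(prob.sp, prob.bs, prob.geom)
    rows = []
    warm = None
    for V in V_grid:
        sol = solve_pnp_bvp(_with(prob, V=V), tol=tol, warm_start=warm)
        warm = sol
        I_an = pc.I(V, Q0)
        scale = max(abs(I_an), 1e-12)
        rows.append({"V": float(V), "I_bvp": sol.current, "I_analytic": I_an,
                     "rel_err": abs(sol.current - I_an) / scale})
    errs = [r["rel_err"] for r in rows]
    return {"rows": rows, "max_rel_err": max(errs),
            "median_rel_err": float(np.median(errs)), "eps": prob.eps,
            "Q0": Q0, "sigma": prob.bs.sigma, "rho": prob.bs.rho}
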