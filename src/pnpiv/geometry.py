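"""Channel geometry: cross-section profile, permanent charge and resistance integral.

The channel is treated as a quasi-one-dimensional pore on the normalized axis
``x ∈ [0, 1]`` with cross-section area profile ``h(x) > 0``.  Two derived
quantities drive the whole current-voltage theory:

* the resistance integral ``H(x) = ∫_0^x ds / h(s)``, and
* the normalized positions ``alpha = H(a)/H(1)`` and ``beta = H(b)/H(1)`` of
  the permanent-charge window ``(a, b)`` in resistance coordinates.

The permanent charge ``Q(x)`` is piecewise constant: ``Q0`` on ``(a, b)`` and
zero in the reservoir-facing segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = ["ChannelGeometry", "cylindrical_channel", "resistance_profile",
           "permanent_charge"]


class InvalidGeometryError(ValueError):
    """Raised when jump locations or profile values are inadmissible."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel shape and permanent-charge layout.

    Parameters
    ----------
    a, b
        Jump locations of the permanent charge, ``0 < a < b < 1``.
    r0
        Neck radius of the cylinder-like profile (dimensionless length).
        ``None`` for a user-supplied profile.
    Q0
        Permanent-charge amplitude on the window ``(a, b)``.
    h
        Positive cross-section area profile on ``[0, 1]``.
    """

    a: float
    b: float
    r0: float | None
    Q0: float
    h: Callable[[float], float]
    H_total: float = field(init=False)
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.a < self.b < 1.0):
            raise InvalidGeometryError(
                f"need 0 < a < b < 1, got a={self.a}, b={self.b}")
        if self.r0 is not None and self.r0 <= 0:
            raise InvalidGeometryError(f"need r0 > 0, got {self.r0}")
        Ha = self._H(self.a)
        Hb = self._H(self.b)
        H1 = self._H(1.0)
        object.__setattr__(self, "H_total", H1)
        object.__setattr__(self, "alpha", Ha / H1)
        object.__setattr__(self, "beta", Hb / H1)

    # -- resistance integral -------------------------------------------------

    def _H(self, x: float) -> float:
        if self.r0 is not None:
            return self._H_closed(x)
        val, _ = quad(lambda s: 1.0 / self.h(s), 0.0, x,
                      points=[p for p in (self.a, self.b) if p < x],
                      epsabs=1e-12, epsrel=1e-12, limit=200)
        return val

    def _H_closed(self, x: float) -> float:
        """Piecewise antiderivative of 1/h for the cylinder-like profile."""
        a, b, r0 = self.a, self.b, self.r0
        pi = np.pi
        # segment [0, a): h = pi (r0 + a - x)^2, antiderivative 1/(pi (r0+a-x))
        seg1 = lambda u: (1.0 / (r0 + a - u)) / pi
        Ha = seg1(min(x, a)) - seg1(0.0)
        if x <= a:
            return Ha
        # segment [a, b): h = pi r0^2
        Hb = (min(x, b) - a) / (pi * r0**2)
        if x <= b:
            return Ha + Hb
        # segment [b, 1]: h = pi (x + r0 - b)^2
        seg3 = lambda u: (-1.0 / (u + r0 - b)) / pi
        return Ha + Hb + seg3(x) - seg3(b)

    def H(self, x):
        """Accumulated resistance ``H(x)`` (vectorized)."""
        xs = np.asarray(x, dtype=float)
        if np.any(xs < 0) or np.any(xs > 1):
            raise ValueError("x must lie in [0, 1]")
        out = np.vectorize(self._H)(xs)
        return float(out) if np.isscalar(x) or xs.ndim == 0 else out

    def Q(self, x):
        """Permanent charge density ``Q(x)`` (vectorized).

        The closed window ``[a, b]`` carries ``Q0``; the convention at the
        measure-zero endpoints is irrelevant to every integral quantity.
        """
        xs = np.asarray(x, dtype=float)
        if np.any(xs < 0) or np.any(xs > 1):
            raise ValueError("x must lie in [0, 1]")
        out = np.where((xs >= self.a) & (xs <= self.b), self.Q0, 0.0)
        return float(out) if np.isscalar(x) or xs.ndim == 0 else out


def cylindrical_channel(a: float = 0.4, b: float = 0.48, r0: float = 0.5,
                        Q0: float = 0.0) -> ChannelGeometry:
    """Cylinder-like channel with a narrow neck carrying the permanent charge.

    The area profile is ``pi (r0 + a - x)^2`` on ``[0, a)`` (tapering cone),
    ``pi r0^2`` on ``[a, b)`` (the neck) and ``pi (x + r0 - b)^2`` on
    ``[b, 1]`` (widening cone); it is continuous at both junctions with value
    ``pi r0^2``.
    """
    if not (0.0 < a < b < 1.0):
        raise InvalidGeometryError(f"need 0 < a < b < 1, got a={a}, b={b}")
    if r0 <= 0:
        raise InvalidGeometryError(f"need r0 > 0, got {r0}")

    def h(x):
        xs = np.asarray(x, dtype=float)
        out = np.where(xs < a, np.pi * (r0 + a - xs) ** 2,
                       np.where(xs < b, np.pi * r0**2,
                                np.pi * (xs + r0 - b) ** 2))
        return float(out) if np.isscalar(x) or xs.ndim == 0 else out

    return ChannelGeometry(a=a, b=b, r0=r0, Q0=Q0, h=h)


def resistance_profile(geom: ChannelGeometry, x) -> float:
    """Accumulated resistance ``H(x) = ∫_0^x ds/h(s)``."""
    return geom.H(x)


def permanent_charge(geom: ChannelGeometry, x) -> float:
    """Permanent charge density ``Q(x)``."""
    return geom.Q(x)
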