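"""Run configuration: schema, defaults and the reference parameter set.

The default configuration reproduces the simulation setup of the study this
package models: a 1:1 electrolyte (z1 = -z2 = 1) with D1 = 2.032,
D2 = 1.334 (potassium/chloride-like mobilities), boundary concentrations
L1 = 12, R1 = 8, a cylinder-like channel with neck on (0.4, 0.48), neck
radius r0 = 0.5, permanent-charge amplitude Q0 = 0.008 and eps = 0.01.
The neutrality-relaxation factors default to (sigma, rho) = (1.2, 0.9),
which puts the boundary-layer term I0d in its increasing branch
(sigma > rho, sigma > 1, sigma + rho > 2).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .flux import BoundaryState, SpeciesPair
from .geometry import ChannelGeometry, cylindrical_channel

__all__ = ["RunConfig", "reference_preset", "load_config"]


@dataclass
class RunConfig:
    """Validated run parameters; defaults are the reference preset."""

    # species
    z1: int = 1
    z2: int = -1
    D1: float = 2.032
    D2: float = 1.334
    # boundary
    V: float = 0.0
    V_grid: list[float] = field(
        default_factory=lambda: list(np.linspace(-1.0, 1.0, 21)))
    L1: float = 12.0
    R1: float = 8.0
    sigma: float = 1.2
    rho: float = 0.9
    # geometry
    a: float = 0.4
    b: float = 0.48
    r0: float = 0.5
    Q0: float = 0.008
    h_table: list[list[float]] | None = None  # optional [[x, h(x)], ...]
    # numerics
    eps: float = 0.01
    bvp_tol: float = 1e-8
    seed: int = 0
    # output
    out_dir: str = "pnpiv-out"
    float_digits: int = 17

    def __post_init__(self) -> None:
        if not (self.z1 > 0 > self.z2):
            raise ValueError("species: need z1 > 0 > z2")
        for key in ("D1", "D2", "L1", "R1", "sigma", "rho", "r0", "eps"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if not (0.0 < self.a < self.b < 1.0):
            raise ValueError("geometry: need 0 < a < b < 1")

    # -- object builders -----------------------------------------------------

    def species(self) -> SpeciesPair:
        return SpeciesPair(self.z1, self.z2, self.D1, self.D2)

    def boundary(self, V: float | None = None) -> BoundaryState:
        return BoundaryState(V=self.V if V is None else V, L1=self.L1,
                             R1=self.R1, sigma=self.sigma, rho=self.rho)

    def geometry(self) -> ChannelGeometry:
        if self.h_table is not None:
            from scipy.interpolate import PchipInterpolator
            tab = np.asarray(self.h_table, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2 or np.any(tab[:, 1] <= 0):
                raise ValueError("h_table must be [[x, h], ...] with h > 0")
            interp = PchipInterpolator(tab[:, 0], tab[:, 1])
            return ChannelGeometry(a=self.a, b=self.b, r0=None, Q0=self.Q0,
                                   h=lambda x: float(interp(x)))
        return cylindrical_channel(self.a, self.b, self.r0, self.Q0)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def reference_preset() -> RunConfig:
    """The reference parameter set (see module docstring)."""
    return RunConfig()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML or JSON config file; ``None`` gives the reference preset.

    Block-style files (sections ``species``, ``boundary``, ``geometry``,
    ``numerics``, ``output``) and flat key-value files are both accepted.
    """
    if path is None:
        return reference_preset()
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib
        raw = tomllib.loads(text)
    else:
        raw = json.loads(text)
    flat: dict = {}
    for k, v in raw.items():
        if isinstance(v, dict):
            flat.update(v)
        else:
            flat[k] = v
    return RunConfig.from_dict(flat)
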