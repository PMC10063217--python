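"""Dimensionless parameter groups, physical scales and shared numerics.

The swimmer is fully parameterized by four dimensionless groups:

* ``S``       -- viscous/elastic ratio, ``S = L (mu / (Ed * tau_d))**(1/4)``
* ``rho``     -- proximal/distal bending-stiffness ratio ``Ep / Ed``
* ``M``       -- active/elastic ratio, ``M = L**2 * mc / Ed``
* ``kappa_c`` -- critical curvature threshold of the switching law

together with the geometric constants (taper fraction ``d``, active fraction
``ell`` and the ellipsoidal head semi-axes) and the numerical settings of the
discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

#: semi-axes of the ellipsoidal head, in flagellar lengths
DEFAULT_HEAD_SEMI_AXES = (0.04, 0.032, 0.02)

#: fraction of the flagellum that actively bends (distal end piece is passive)
ELL_DEFAULT = 0.95


@dataclass(frozen=True)
class PhysicalScales:
    """Dimensional scales of a cell, used to form the dimensionless groups.

    Attributes
    ----------
    L : float
        Flagellum length (m).
    mc : float
        Preferred active moment density of a fully engaged section (N).
    mu : float
        Dynamic viscosity of the medium (Pa s).
    tau_d : float
        Characteristic bending-switching time (s).
    Ed, Ep : float
        Distal and proximal bending stiffness (N m^2).
    """

    L: float
    mc: float
    mu: float
    tau_d: float
    Ed: float
    Ep: float

    def __post_init__(self) -> None:
        for name in ("L", "mc", "mu", "tau_d", "Ed", "Ep"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"physical scale {name} must be positive and finite, got {v!r}")


@dataclass
class DimensionlessParameters:
    """The four dimensionless groups plus geometry and numerics.

    Geometry and physics defaults follow the reference human-sperm values
    (head semi-axes 0.04/0.032/0.02 flagellar lengths, active fraction 0.95).
    """

    S: float = 18.0
    rho: float = 36.4
    M: float = 900.0
    kappa_c: float = 1.5

    # geometry
    d: float = 1.0                 # taper fraction of the stiffness profile
    ell: float = ELL_DEFAULT       # active fraction (end piece is passive)
    head_semi_axes: tuple = DEFAULT_HEAD_SEMI_AXES

    # discretization
    N: int = 40                    # flagellar segments (N+1 angle nodes)
    epsilon: float | None = None   # regularization length; None -> 0.25*h
    head_Q: int = 16               # coarse (traction) head nodes
    head_refinement: int = 4       # fine quadrature nodes per coarse node

    # switching-law numerics
    delta_smooth: float = 1e-2     # smoothing width of sgn/Heaviside
    m0: float = 1.0                # initial uniform active moment density

    # repulsion (self-intersection regularization)
    repulsion_A: float = 100.0
    repulsion_B: float | None = None       # None -> 4 / epsilon
    repulsion_delta_excl: float | None = None  # None -> 2*h
    repulsion_cutoff: float | None = None      # None -> 4 * epsilon

    # head-flagellum junction
    clamp_offset: float = 0.0      # head angle = theta(0) + clamp_offset

    # time integration / steady-beat protocol
    rtol: float = 1e-5
    atol: float = 1e-7
    reporting_cadence: float = 200.0   # dense-output samples per unit time
    max_time: float = 400.0
    steady_rtol: float = 1e-2          # rel. L2 change of per-beat |kappa| profile
    no_beat_atol: float = 1e-3         # amplitude floor on theta(0,t) (rad)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S <= 0 or self.M < 0:
            raise ValueError("require S > 0 and M >= 0")
        if self.rho < 1:
            raise ValueError("proximal/distal stiffness ratio rho must be >= 1")
        if self.kappa_c <= 0:
            raise ValueError("critical curvature kappa_c must be positive")
        if not (0 < self.ell <= 1):
            raise ValueError("active fraction ell must lie in (0, 1]")
        if not (0 < self.d <= 1):
            raise ValueError("taper fraction d must lie in (0, 1]")
        if self.N < 4:
            raise ValueError("need at least 4 flagellar segments")

    # -- derived quantities -------------------------------------------------

    @property
    def h(self) -> float:
        """Flagellar segment length (dimensionless)."""
        return 1.0 / self.N

    @property
    def eps(self) -> float:
        """Effective regularization length (0.25 h unless set explicitly)."""
        return 0.25 * self.h if self.epsilon is None else self.epsilon

    @property
    def rep_B(self) -> float:
        return 4.0 / self.eps if self.repulsion_B is None else self.repulsion_B

    @property
    def rep_delta_excl(self) -> float:
        return 2.0 * self.h if self.repulsion_delta_excl is None else self.repulsion_delta_excl

    @property
    def rep_cutoff(self) -> float:
        return 4.0 * self.eps if self.repulsion_cutoff is None else self.repulsion_cutoff

    @property
    def cell_length(self) -> float:
        """Head length plus flagellum length, the velocity normalization."""
        return 1.0 + 2.0 * self.head_semi_axes[0]

    @property
    def s_nodes(self) -> np.ndarray:
        """Joint (segment endpoint) arclength grid, [0, 1]."""
        return np.linspace(0.0, 1.0, self.N + 1)

    @property
    def n_active(self) -> int:
        """Number of interior joints carrying active moment (arclength <= ell)."""
        return min(self.N - 1, int(np.floor(self.ell * self.N + 1e-9)))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_semi_axes"] = list(self.head_semi_axes)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "DimensionlessParameters":
        data = dict(data)
        if "head_semi_axes" in data:
            data["head_semi_axes"] = tuple(data["head_semi_axes"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "DimensionlessParameters":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    def with_(self, **kwargs) -> "DimensionlessParameters":
        """Copy with some fields replaced."""
        return replace(self, **kwargs)


def nondimensionalize(scales: PhysicalScales, **kwargs) -> DimensionlessParameters:
    """Form the dimensionless groups from dimensional cell/fluid scales.

    ``S = L (mu/(Ed tau_d))**(1/4)``, ``M = L^2 mc / Ed``, ``rho = Ep / Ed``.
    Additional keyword arguments (e.g. ``kappa_c``, numerics) are forwarded.
    """
    S = scales.L * (scales.mu / (scales.Ed * scales.tau_d)) ** 0.25
    M = scales.L**2 * scales.mc / scales.Ed
    rho = scales.Ep / scales.Ed
    return DimensionlessParameters(S=S, rho=rho, M=M, **kwargs)


def redimensionalize(params: DimensionlessParameters, L: float, tau_d: float) -> dict:
    """Convert dimensionless velocity/frequency scales back to SI units.

    Returns conversion factors: multiply a dimensionless velocity
    (flagellar lengths per unit time) by ``velocity`` to get m/s, and a
    dimensionless frequency by ``frequency`` to get Hz.
    """
    if L <= 0 or tau_d <= 0:
        raise ValueError("L and tau_d must be positive")
    return {"velocity": L / tau_d, "frequency": 1.0 / tau_d, "length": L, "time": tau_d}
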