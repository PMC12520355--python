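"""Domain types and the constitutive (tube) law for the 1D blood-flow model.

The 1D pulse-wave model evolves cross-sectional area ``A(x,t)`` (cm^2) and
volumetric flow ``q(x,t)`` (mL/s) on each vessel of a small rooted binary
network. Pressure is recovered algebraically from area through the linear
elastic tube law

    p(x,t) = (4/3) (Eh/r0) (sqrt(A/A0) - 1),

with the vessel stiffness following the empirical exponential law
``Eh/r0 = k1 exp(-k2 r0) + k3``. All public interfaces use clinical units
(pressure in mmHg, flow in mL/s); the solver works internally in CGS with
pressure in dyn/cm^2 (1 mmHg = 1333.22 dyn/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_CGS",
    "HemoDomainError",
    "BloodProperties",
    "WallParams",
    "Vessel",
    "VesselNetwork",
    "ParameterVector",
    "WK_PARAM_NAMES",
    "ST_PARAM_NAMES",
    "stiffness",
    "tube_law_pressure",
    "tube_law_area",
    "wave_speed",
]

#: dyn/cm^2 per mmHg
MMHG_TO_CGS = 1333.22


class HemoDomainError(ValueError):
    """Raised when a physical quantity leaves its admissible domain."""


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties.

    Parameters
    ----------
    density : float
        Blood density rho (g/cm^3).
    viscosity : float
        Dynamic viscosity mu (g/(cm s)).
    gamma : float
        Velocity-profile power-law exponent; gamma = 9 gives the nearly flat
        profile observed in vivo.
    """

    density: float = 1.055
    viscosity: float = 0.049
    gamma: float = 9.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise HemoDomainError("density must be positive")
        if self.viscosity <= 0:
            raise HemoDomainError("viscosity must be positive")
        if self.gamma < 2:
            raise HemoDomainError("gamma must be >= 2")

    @property
    def advective_coefficient(self) -> float:
        """Momentum-flux coefficient (gamma+2)/(gamma+1)."""
        return (self.gamma + 2.0) / (self.gamma + 1.0)

    @property
    def friction_coefficient(self) -> float:
        """Viscous source coefficient 2 pi mu (gamma+2) / rho (CGS)."""
        return 2.0 * np.pi * self.viscosity * (self.gamma + 2.0) / self.density


@dataclass(frozen=True)
class WallParams:
    """Exponential wall-stiffness law Eh/r0 = k1 exp(-k2 r0) + k3.

    k1 and k3 are in mmHg, k2 in 1/cm.
    """

    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        if self.k3 <= 0:
            raise HemoDomainError("k3 must be positive")
        if self.k1 < 0 or self.k2 < 0:
            raise HemoDomainError("k1 and k2 must be non-negative")


def stiffness(r0, wall: WallParams):
    """Wall stiffness Eh/r0 (mmHg) at reference radius ``r0`` (cm)."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise HemoDomainError("reference radius must be positive")
    out = wall.k1 * np.exp(-wall.k2 * r0) + wall.k3
    return out if out.ndim else float(out)


def tube_law_pressure(A, A0, stiff):
    """Transmural pressure p (mmHg) from area via the sqrt tube law.

    p = (4/3) * stiff * (sqrt(A/A0) - 1); p(A0) = 0 and p is strictly
    increasing in A.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0):
        raise HemoDomainError("areas must be positive")
    out = (4.0 / 3.0) * stiff * (np.sqrt(A / A0) - 1.0)
    return out if out.ndim else float(out)


def tube_law_area(p, A0, stiff):
    """Exact inverse of :func:`tube_law_pressure`.

    Requires p > -(4/3)*stiff (area positivity / collapse bound).
    """
    p = np.asarray(p, dtype=float)
    bound = -(4.0 / 3.0) * stiff
    if np.any(p <= bound):
        raise HemoDomainError("pressure at or below the collapse bound")
    out = A0 * (1.0 + 3.0 * p / (4.0 * stiff)) ** 2
    return out if out.ndim else float(out)


def wave_speed(A, A0, stiff, density: float = 1.055):
    """Local pulse-wave speed c (cm/s).

    c = sqrt((A/rho) dp/dA) for the sqrt tube law reduces to
    sqrt(2 s_cgs / (3 rho)) * (A/A0)**(1/4) with s_cgs the stiffness in
    dyn/cm^2 (``stiff`` is given in mmHg).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise HemoDomainError("area must be positive")
    s_cgs = np.asarray(stiff) * MMHG_TO_CGS
    out = np.sqrt(2.0 * s_cgs / (3.0 * density)) * (A / A0) ** 0.25
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Vessel:
    """One untapered vessel segment of the network."""

    name: str
    length: float  # cm
    radius: float  # cm, reference radius r0
    daughters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise HemoDomainError(f"vessel {self.name}: length must be positive")
        if self.radius <= 0:
            raise HemoDomainError(f"vessel {self.name}: radius must be positive")
        if len(self.daughters) not in (0, 2):
            raise HemoDomainError(
                f"vessel {self.name}: junctions must have exactly 2 daughters"
            )
        object.__setattr__(self, "daughters", tuple(self.daughters))

    @property
    def area(self) -> float:
        """Reference cross-sectional area A0 = pi r0^2 (cm^2)."""
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class VesselNetwork:
    """A rooted binary tree of vessels.

    Every non-terminal vessel has exactly two daughters; terminal vessels
    carry the outflow boundary conditions.
    """

    vessels: tuple[Vessel, ...]
    root: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessels", tuple(self.vessels))
        names = [v.name for v in self.vessels]
        if len(set(names)) != len(names):
            raise HemoDomainError("duplicate vessel names")
        if self.root not in names:
            raise HemoDomainError(f"root vessel {self.root!r} not in network")
        parents: dict[str, str] = {}
        for v in self.vessels:
            for d in v.daughters:
                if d not in names:
                    raise HemoDomainError(f"unknown daughter vessel {d!r}")
                if d in parents:
                    raise HemoDomainError(f"vessel {d!r} has two parents")
                parents[d] = v.name
        if self.root in parents:
            raise HemoDomainError("root vessel must not have a parent")
        for v in self.vessels:
            if v.name != self.root and v.name not in parents:
                raise HemoDomainError(f"vessel {v.name!r} is disconnected")

    def __getitem__(self, name: str) -> Vessel:
        for v in self.vessels:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.vessels]

    @property
    def terminals(self) -> list[str]:
        """Terminal vessel names, in network order."""
        return [v.name for v in self.vessels if not v.daughters]

    @property
    def junctions(self) -> list[tuple[str, str, str]]:
        """(parent, daughter1, daughter2) triples."""
        return [(v.name, *v.daughters) for v in self.vessels if v.daughters]

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "vessels": [
                {
                    "name": v.name,
                    "length_cm": v.length,
                    "radius_cm": v.radius,
                    "daughters": list(v.daughters),
                }
                for v in self.vessels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselNetwork":
        vessels = tuple(
            Vessel(
                name=v["name"],
                length=v["length_cm"],
                radius=v["radius_cm"],
                daughters=tuple(v.get("daughters", ())),
            )
            for v in d["vessels"]
        )
        return cls(vessels=vessels, root=d["root"])


WK_PARAM_NAMES = ("k1", "k2", "k3", "Rp1", "Rp2", "Rd1", "Rd2", "CT1", "CT2")
ST_PARAM_NAMES = ("k1", "k2", "k3", "alpha", "beta", "lrr", "rmin")


@dataclass(frozen=True)
class ParameterVector:
    """Named, ordered parameter vector for one boundary-condition variant.

    variant "wk": {k1,k2,k3,Rp1,Rp2,Rd1,Rd2,CT1,CT2} (9 values; resistances in
    mmHg s/mL, compliances in mL/mmHg). variant "st":
    {k1,k2,k3,alpha,beta,lrr,rmin} (7 values; alpha/beta/lrr dimensionless,
    rmin in cm) with 0 < beta <= alpha < 1 shared by both terminals.
    """

    variant: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.names_for(self.variant)
        missing = set(names) - set(self.values)
        extra = set(self.values) - set(names)
        if missing or extra:
            raise HemoDomainError(
                f"parameter set mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
            )
        object.__setattr__(
            self, "values", {n: float(self.values[n]) for n in names}
        )
        if any(v <= 0 for v in self.values.values()):
            raise HemoDomainError("all parameters must be positive")
        if self.variant == "st":
            a, b = self.values["alpha"], self.values["beta"]
            if not (0 < b <= a < 1):
                raise HemoDomainError("require 0 < beta <= alpha < 1")

    @staticmethod
    def names_for(variant: str) -> tuple[str, ...]:
        if variant == "wk":
            return WK_PARAM_NAMES
        if variant == "st":
            return ST_PARAM_NAMES
        raise HemoDomainError(f"unknown variant {variant!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return self.names_for(self.variant)

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, variant: str, arr) -> "ParameterVector":
        names = cls.names_for(variant)
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(names),):
            raise HemoDomainError(f"expected {len(names)} values, got {arr.shape}")
        return cls(variant=variant, values=dict(zip(names, arr)))

    def wall(self) -> WallParams:
        return WallParams(self.values["k1"], self.values["k2"], self.values["k3"])

    def replace(self, **updates: float) -> "ParameterVector":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterVector(self.variant, vals)

    def to_dict(self) -> dict:
        return {"variant": self.variant, **self.values}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterVector":
        d = dict(d)
        variant = d.pop("variant")
        return cls(variant=variant, values=d)
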