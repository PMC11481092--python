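"""Optimization design spaces for flow-reactor campaigns.

A :class:`DesignSpace` is an ordered collection of bounded continuous
variables in physical units (reactor temperatures, pump flow rates, reagent
ratios, feed concentrations, residence times).  Campaigns work internally on
the unit hypercube ``[0, 1]^n``; :meth:`DesignSpace.to_unit` and
:meth:`DesignSpace.from_unit` provide the affine maps between the two
representations.

Initial conditions for a campaign come from a seeded Latin hypercube design
of ``2n + 1`` points (one point per stratum per dimension), the conventional
sizing for small self-optimization campaigns: 7 points for a 3-variable
single-step space, 9 for the 4-variable telescoped space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "BoundsError",
    "VariableSpec",
    "DesignSpace",
    "lhs_design",
]

#: Canonical unit strings accepted for each variable role.
ROLE_UNITS: dict[str, tuple[str, ...]] = {
    "temperature": ("degC", "°C"),
    "liquid_flow": ("mL/min", "mL·min⁻¹"),
    "flow_ratio": ("", "ratio", "dimensionless"),
    "concentration": ("mol/L", "mol·L⁻¹"),
    "residence_time": ("min",),
}


class BoundsError(ValueError):
    """A condition value falls outside its variable's bounds."""


@dataclass(frozen=True)
class VariableSpec:
    """One bounded optimization variable.

    Parameters
    ----------
    name
        Identifier used in condition mappings (e.g. ``"T1"``).
    unit
        Physical unit; must be consistent with ``role`` (see ``ROLE_UNITS``).
    lower, upper
        Inclusive bounds in physical units; ``lower < upper``.
    role
        One of ``temperature``, ``liquid_flow``, ``flow_ratio``,
        ``concentration``, ``residence_time``.
    """

    name: str
    unit: str
    lower: float
    upper: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLE_UNITS:
            raise ValueError(
                f"unknown role {self.role!r} for variable {self.name!r}; "
                f"expected one of {sorted(ROLE_UNITS)}"
            )
        if self.unit not in ROLE_UNITS[self.role]:
            raise ValueError(
                f"unit {self.unit!r} inconsistent with role {self.role!r} "
                f"for variable {self.name!r}"
            )
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError(f"non-finite bounds for variable {self.name!r}")
        if not self.lower < self.upper:
            raise BoundsError(
                f"variable {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


class DesignSpace:
    """Ordered collection of :class:`VariableSpec` with unique names."""

    def __init__(self, variables: Iterable[VariableSpec]):
        variables = tuple(variables)
        if len(variables) < 1:
            raise ValueError("a design space needs at least one variable")
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate variable names in design space: {names}")
        self.variables: tuple[VariableSpec, ...] = variables

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def lower(self) -> np.ndarray:
        return np.array([v.lower for v in self.variables], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([v.upper for v in self.variables], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        vs = ", ".join(f"{v.name}[{v.lower}, {v.upper}]" for v in self.variables)
        return f"DesignSpace({vs})"

    # -- unit scaling -----------------------------------------------------

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Affine map from physical units to ``[0, 1]^n``.

        Raises :class:`BoundsError` naming the offending variable if any
        coordinate lies outside its bounds (beyond a 1e-12 relative slack).
        """
        x = np.asarray(x, dtype=float)
        lo, up = self.lower, self.upper
        tol = 1e-12 * np.maximum(1.0, np.abs(up))
        x2 = np.atleast_2d(x)
        bad = (x2 < lo - tol) | (x2 > up + tol)
        if bad.any():
            j = int(np.argmax(bad.any(axis=0)))
            v = self.variables[j]
            val = float(x2[bad[:, j], j][0])
            raise BoundsError(
                f"variable {v.name!r}: value {val:g} outside bounds "
                f"[{v.lower:g}, {v.upper:g}]"
            )
        return np.clip((x - lo) / (up - lo), 0.0, 1.0)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_unit`."""
        u = np.asarray(u, dtype=float)
        return self.lower + u * (self.upper - self.lower)

    def midpoint(self) -> np.ndarray:
        """Center of the design space, used as the monitoring standard."""
        return 0.5 * (self.lower + self.upper)

    # -- condition helpers ------------------------------------------------

    def as_dict(self, x: Sequence[float]) -> dict[str, float]:
        """Map an ordered condition vector to a name -> value mapping."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected a length-{self.n} condition vector")
        return dict(zip(self.names, (float(v) for v in x)))

    def from_dict(self, cond: Mapping[str, float]) -> np.ndarray:
        return np.array([float(cond[name]) for name in self.names])


def lhs_design(space: DesignSpace, seed: int, m: int | None = None) -> np.ndarray:
    """Seeded Latin hypercube design in physical units.

    Returns ``m`` points (default ``2n + 1``) of shape ``(m, n)``.  In each
    dimension the unit-scaled coordinates occupy the ``m`` distinct
    equal-width strata of ``[0, 1]``, i.e. a permutation design with
    within-stratum jitter.  Identical seeds give identical designs.
    """
    if m is None:
        m = 2 * space.n + 1
    sampler = qmc.LatinHypercube(d=space.n, seed=int(seed))
    u = sampler.random(m)
    return space.from_unit(u)
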