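"""Quasi-static (small-angle) bending of a conical whisker under a point force.

Closed-form Euler-Bernoulli solution for a cone clamped at the base
(``y(L) = y'(L) = 0``) and loaded by a transverse point force ``F`` at
``x = c``.  On ``[c, L]`` the deflection is cubic in ``1/x``; on
``[trunc, c]`` the beam is moment-free and the deflection continues as the
tangent line through the contact point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .geometry import ContactConfig, WhiskerGeometry

__all__ = [
    "StaticSolution",
    "StaticLoads",
    "static_deflection",
    "static_moment_and_shear",
    "axial_lateral_ratio",
]


@dataclass(frozen=True)
class StaticSolution:
    """Quasi-static bending solution ``y_s`` for a unit-scaled point force.

    ``deflection``/``slope`` evaluate the solution for the stored force ``F``;
    ``ytilde``/``ytilde_slope`` give the per-unit-force factorized form used by
    the modal dynamics (``y_s(x, t) = F(t) * ytilde(x)``).
    """

    geom: WhiskerGeometry
    contact: ContactConfig
    F: float

    def _prefactor(self) -> float:
        g = self.geom
        return 2.0 / (3.0 * math.pi * g.E * g.xi**4)

    def ytilde(self, x):
        """Per-unit-force deflection (m/N) on [trunc, L]."""
        g, c, L = self.geom, self.contact.c, self.geom.L
        x = np.asarray(x, dtype=float)
        pre = self._prefactor()
        # cubic-in-1/x branch, valid for c <= x <= L
        right = pre * ((3.0 * x - c) / x**2 + ((3.0 * L - 2.0 * c) * x + 3.0 * L * (c - 2.0 * L)) / L**3)
        yc = 2.0 * pre * (L - c) ** 3 / (c * L**3)
        ypc = pre * (3.0 * L * c**2 - L**3 - 2.0 * c**3) / (c**2 * L**3)
        left = ypc * (x - c) + yc
        out = np.where(x >= c, right, left)
        return out if out.ndim else float(out)

    def ytilde_slope(self, x):
        """Per-unit-force slope (1/N)."""
        g, c, L = self.geom, self.contact.c, self.geom.L
        x = np.asarray(x, dtype=float)
        pre = self._prefactor()
        right = pre * ((2.0 * c - 3.0 * x) / x**3 + (3.0 * L - 2.0 * c) / L**3)
        ypc = pre * (3.0 * L * c**2 - L**3 - 2.0 * c**3) / (c**2 * L**3)
        out = np.where(x >= c, right, ypc)
        return out if out.ndim else float(out)

    def deflection(self, x):
        """Deflection y_s(x) (m) for the stored force."""
        return self.F * self.contact.F_sign * self.ytilde(x)

    def slope(self, x):
        """Slope y_s'(x) for the stored force."""
        return self.F * self.contact.F_sign * self.ytilde_slope(x)

    def moment(self, x):
        """Bending moment profile M(x) = (x - c) F for x >= c, else 0 (N m)."""
        c = self.contact.c
        x = np.asarray(x, dtype=float)
        out = np.where(x >= c, (x - c) * self.F * self.contact.F_sign, 0.0)
        return out if out.ndim else float(out)


class StaticLoads(NamedTuple):
    moment: Callable
    base_moment: float
    base_shear: float


def _validate(geom: WhiskerGeometry, contact: ContactConfig, F: float) -> None:
    contact.validate(geom)
    if not math.isfinite(F):
        raise ValueError(f"force must be finite, got {F}")


def static_deflection(geom: WhiskerGeometry, contact: ContactConfig, F: float) -> StaticSolution:
    """Closed-form quasi-static deflection under a point force ``F`` (N) at ``c``.

    Satisfies the clamped-base conditions ``y(L) = y'(L) = 0`` exactly and is
    C1-continuous at the contact point.
    """
    _validate(geom, contact, F)
    return StaticSolution(geom=geom, contact=contact, F=F)


def static_moment_and_shear(geom: WhiskerGeometry, contact: ContactConfig, F: float) -> StaticLoads:
    """Static internal loads: moment profile, base moment F (L - c), base shear F."""
    _validate(geom, contact, F)
    sol = StaticSolution(geom=geom, contact=contact, F=F)
    Fs = F * contact.F_sign
    return StaticLoads(moment=sol.moment, base_moment=Fs * (geom.L - contact.c), base_shear=Fs)


def axial_lateral_ratio(geom: WhiskerGeometry, contact: ContactConfig, F: float = 1.0) -> float:
    """Axial-to-lateral force ratio, tan of the base-to-contact slope difference.

    The applied force is normal to the whisker at the contact point while the
    base direction is fixed by the clamp (zero slope), so the angle between
    the force and the base axis is ``arctan(|y_s'(c)|)`` in the small-angle
    solution.  The ratio of the axial to the lateral force component at the
    follicle is then ``tan`` of that angle, i.e. ``|y_s'(c)| * F`` per se.
    Monotone increasing in the push force for fixed contact position.
    """
    _validate(geom, contact, F)
    sol = StaticSolution(geom=geom, contact=contact, F=abs(F))
    return abs(sol.ytilde_slope(contact.c)) * abs(F)
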