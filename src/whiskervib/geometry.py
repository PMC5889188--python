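"""Physical description of a truncated conical whisker and the contact configuration.

The whisker is modeled as a linearly tapered elastic cone.  The axial
coordinate ``x`` runs from the extrapolated virtual tip (``x = 0``) to the
base at ``x = L``; the real (possibly trimmed) tip sits at ``x = trunc``.
All quantities are SI internally.  User-facing reports may also give
"distance from follicle" = ``L - x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class WhiskerGeometry:
    """Geometry and material parameters of a truncated conical whisker.

    Parameters
    ----------
    L : float
        Extrapolated length from virtual tip to base (m).
    R : float
        Whisker radius at the base (m).
    trunc : float
        Truncation length ``l``: axial position of the real tip (m).
        ``trunc = 0`` describes a full-length cone.
    rho : float
        Volume density (kg/m^3).
    E : float
        Young's modulus (Pa).
    alpha : float
        Frequency-independent viscous damping constant (rad/s).
    """

    L: float
    R: float
    trunc: float = 0.0
    rho: float = 1000.0
    E: float = 3.0e9
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (self.L > 0 and math.isfinite(self.L)):
            raise ValueError(f"L must be positive and finite, got {self.L}")
        if not (self.R > 0 and math.isfinite(self.R)):
            raise ValueError(f"R must be positive and finite, got {self.R}")
        if not (0.0 <= self.trunc < self.L):
            raise ValueError(f"trunc must satisfy 0 <= trunc < L, got {self.trunc}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.E <= 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")

    @property
    def xi(self) -> float:
        """Taper ratio xi = R/L (dimensionless)."""
        return self.R / self.L

    @property
    def ell_ratio(self) -> float:
        """Relative truncation l/L."""
        return self.trunc / self.L

    @property
    def I0(self) -> float:
        """Area moment of inertia at the base, I(L) = (pi/4) R^4 (m^4)."""
        return math.pi / 4.0 * self.R**4

    def radius(self, x):
        """Local radius r(x) = xi * x (m)."""
        return self.xi * x

    def area_moment(self, x):
        """Area moment of inertia I(x) = (pi/4) xi^4 x^4 (m^4)."""
        return math.pi / 4.0 * self.xi**4 * x**4

    def linear_density(self, x):
        """Mass per unit length mu(x) = rho * pi * xi^2 * x^2 (kg/m)."""
        return self.rho * math.pi * self.xi**2 * x**2

    def wave_speed_factor(self) -> float:
        """sqrt(E/rho) (m/s), the material factor in the eigenfrequency relation."""
        return math.sqrt(self.E / self.rho)


@dataclass(frozen=True)
class ContactConfig:
    """Pole contact configuration.

    ``c`` is the axial coordinate of the contact point measured from the
    virtual tip (m); ``F_sign`` fixes the direction convention of positive
    force (+1 = positive-y, i.e. "upwards").
    """

    c: float
    F_sign: int = +1

    def __post_init__(self) -> None:
        if self.c <= 0 or not math.isfinite(self.c):
            raise ValueError(f"contact position must be positive and finite, got {self.c}")
        if self.F_sign not in (+1, -1):
            raise ValueError("F_sign must be +1 or -1")

    def validate(self, geom: WhiskerGeometry) -> None:
        """Raise if the contact point does not lie strictly between tip and base."""
        if not (geom.trunc < self.c < geom.L):
            raise ValueError(
                f"contact point c={self.c} must lie in (trunc, L)=({geom.trunc}, {geom.L})"
            )

    @classmethod
    def from_relative(cls, geom: WhiskerGeometry, c_ratio: float, F_sign: int = +1) -> "ContactConfig":
        """Build a contact at relative position c/L for a given whisker."""
        contact = cls(c=c_ratio * geom.L, F_sign=F_sign)
        contact.validate(geom)
        return contact


def standard_whisker(alpha: float = 430.0) -> WhiskerGeometry:
    """The standard modeling whisker: 5%-trimmed cone, L = 18 mm, R = 37 um,
    rho = 1.0 g/cm^3, E = 3.0 GPa, alpha = 430 rad/s."""
    return WhiskerGeometry(L=18e-3, R=37e-6, trunc=0.05 * 18e-3, rho=1000.0, E=3.0e9, alpha=alpha)


def measured_c2_whisker() -> WhiskerGeometry:
    """Dimensions of the measured C2 whisker used for the modulus estimate:
    L = 17.14 mm, R = 37.15 um, rho = 1.0 g/cm^3 (E set to the inferred 3.04 GPa)."""
    return WhiskerGeometry(L=17.14e-3, R=37.15e-6, trunc=0.0, rho=1000.0, E=3.04e9, alpha=430.0)
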