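"""Time-dependent applied-force profiles with two continuous derivatives.

The touch force is the upper part of a truncated Gaussian active on
``0 <= t <= t_f``, preceded on ``[0, tau]`` by a smooth cubic-quartic onset
that makes the force and its first two time derivatives vanish at contact
onset and join the Gaussian continuously at ``t = tau``.  A linear ramp,
``F = s t``, is also provided for wave-propagation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

__all__ = ["ForceKind", "ForceProfile", "solve_gaussian_params"]


class ForceKind(Enum):
    GAUSSIAN_SMOOTH = "gaussian-smooth"
    RAMP = "ramp"


@dataclass(frozen=True)
class ForceProfile:
    """Piecewise force time course F(t) with analytic first two derivatives.

    GAUSSIAN_SMOOTH: ``F = F_s(t)`` on [0, tau] (quartic onset), the truncated
    Gaussian ``F_G(t) = F_max/(1-C) [exp(-((t-a)/b)^2) - C]`` on [tau, t_f],
    and 0 afterwards.  ``a`` and ``b`` are solved so that ``F_G(t_f) = 0`` and
    ``F_s(tau) = F_G(tau)``; the peak value ``F_max`` is attained at ``t = a``.

    RAMP: ``F = s t`` for t >= 0 (never detaches).
    """

    kind: ForceKind
    F_max: float = 0.0
    t_f: float = math.inf
    tau: float = 0.0
    C: float = 0.5
    a: float = 0.0
    b: float = 1.0
    s: float = 0.0

    # -- Gaussian branch internals -------------------------------------------------
    def _gauss(self, t, deriv: int):
        g = np.exp(-(((t - self.a) / self.b) ** 2))
        amp = self.F_max / (1.0 - self.C)
        if deriv == 0:
            return amp * (g - self.C)
        if deriv == 1:
            return amp * (-2.0 / self.b) * ((t - self.a) / self.b) * g
        if deriv == 2:
            return amp * (2.0 / self.b**2) * (2.0 * ((t - self.a) / self.b) ** 2 - 1.0) * g
        raise ValueError("derivative must be 0, 1 or 2")

    def _onset(self, t, deriv: int):
        tau = self.tau
        Fd1 = float(self._gauss(np.asarray(tau), 1))
        Fd2 = float(self._gauss(np.asarray(tau), 2))
        p3 = 3.0 * Fd1 - tau * Fd2
        p4 = tau * Fd2 - 2.0 * Fd1
        u = t / tau
        if deriv == 0:
            return (tau / 3.0) * p3 * u**3 + (tau / 4.0) * p4 * u**4
        if deriv == 1:
            return p3 * u**2 + p4 * u**3
        if deriv == 2:
            return (2.0 / tau) * p3 * u + (3.0 / tau) * p4 * u**2
        raise ValueError("derivative must be 0, 1 or 2")

    def __call__(self, t, deriv: int = 0):
        """Evaluate F (deriv=0), dF/dt (1) or d2F/dt2 (2) at time(s) t (s)."""
        t = np.asarray(t, dtype=float)
        if self.kind == ForceKind.RAMP:
            if deriv == 0:
                out = np.where(t >= 0.0, self.s * t, 0.0)
            elif deriv == 1:
                out = np.where(t >= 0.0, self.s, 0.0)
            elif deriv == 2:
                out = np.zeros_like(t)
            else:
                raise ValueError("derivative must be 0, 1 or 2")
            return out if out.ndim else float(out)
        out = np.zeros_like(t)
        m_on = (t >= 0.0) & (t < self.tau)
        m_g = (t >= self.tau) & (t <= self.t_f)
        if np.any(m_on):
            out[m_on] = self._onset(t[m_on], deriv)
        if np.any(m_g):
            out[m_g] = self._gauss(t[m_g], deriv)
        return out if out.ndim else float(out)

    # -- constructors ---------------------------------------------------------------
    @classmethod
    def ramp(cls, s: float) -> "ForceProfile":
        """Linear ramp F = s t (N/s)."""
        return cls(kind=ForceKind.RAMP, s=s)

    @classmethod
    def gaussian_smooth(
        cls, F_max: float, t_f: float = 10e-3, tau: float = 0.1e-3, C: float = 0.5,
    ) -> "ForceProfile":
        """Standard touch profile (defaults: t_f = 10 ms, tau = 0.1 ms, C = 0.5)."""
        return solve_gaussian_params(F_max, t_f, tau, C)

    @classmethod
    def from_touch_duration(cls, F_max: float, t_d: float) -> "ForceProfile":
        """Canonical profile for a touch of half-duration ``t_d``.

        The slip-fit convention (half-Gaussian with C = 0.5, center 2 t_d,
        width 1.2011 t_d) implies a total contact duration t_f ~= 3 t_d via
        the cutoff condition; those literal center/width values are not
        compatible with a smooth (C^2) onset, so only the implied duration is
        kept and the center is re-solved from the continuity conditions.
        """
        t_f = 2.0 * t_d + 1.2011 * t_d * math.sqrt(math.log(2.0))
        return solve_gaussian_params(F_max, t_f, tau=t_f / 100.0, C=0.5)


def solve_gaussian_params(
    F_max: float, t_f: float, tau: float, C: float, a_init: float | None = None
) -> ForceProfile:
    """Solve the Gaussian center/width from the cutoff and continuity conditions.

    ``b = (t_f - a)/sqrt(ln(1/C))`` enforces ``F_G(t_f) = 0``; ``a`` is then the
    root of the implicit continuity equation ``F_s(tau) = F_G(tau)`` with
    ``F_s(tau) = (tau/2) Fdot_G(tau) - (tau^2/12) Fddot_G(tau)``.
    """
    if not (0.0 < C < 1.0):
        raise ValueError(f"cutoff must satisfy 0 < C < 1, got {C}")
    if not (0.0 < tau <= t_f / 10.0):
        raise ValueError(f"onset duration must satisfy 0 < tau <= t_f/10, got tau={tau}")
    if not (F_max != 0.0 and math.isfinite(F_max)):
        raise ValueError(f"F_max must be finite and nonzero, got {F_max}")

    ln_inv_c = math.sqrt(math.log(1.0 / C))

    def residual(a: float) -> float:
        b = (t_f - a) / ln_inv_c
        p = ForceProfile(kind=ForceKind.GAUSSIAN_SMOOTH, F_max=F_max, t_f=t_f,
                         tau=tau, C=C, a=a, b=b)
        tau_arr = np.asarray(tau)
        f_g = float(p._gauss(tau_arr, 0))
        f_s = 0.5 * tau * float(p._gauss(tau_arr, 1)) - tau**2 / 12.0 * float(p._gauss(tau_arr, 2))
        return (f_g - f_s) / F_max

    lo = tau * (1.0 + 1e-9)
    hi = t_f * (1.0 - 1e-9)
    grid = np.linspace(lo, hi, 400)
    if a_init is not None:
        grid = np.sort(np.append(grid, a_init))
    vals = np.array([residual(a) for a in grid])
    sgn = np.sign(vals)
    idx = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
    if idx.size == 0:
        raise ValueError(
            f"no Gaussian center a in (tau, t_f) satisfies continuity for "
            f"t_f={t_f}, tau={tau}, C={C}"
        )
    i = idx[0]
    a = brentq(residual, grid[i], grid[i + 1], xtol=1e-18, rtol=8.9e-16)
    b = (t_f - a) / ln_inv_c
    prof = ForceProfile(kind=ForceKind.GAUSSIAN_SMOOTH, F_max=F_max, t_f=t_f,
                        tau=tau, C=C, a=a, b=b)
    if abs(residual(a)) > 1e-12:
        raise ValueError("Gaussian parameterization did not converge")
    return prof
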