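"""Closed-form eigenmodes of a vibrating conical whisker.

The transverse eigenmode equation of a linearly tapered cone,
``(x^4 X'')'' = q^2 x^2 X`` with ``q^2 = 4 rho omega^2 / (E xi^2)``,
reduces in the dimensionless variable ``z = q x`` to
``(z^4 chi'')'' = z^2 chi``, whose general solution is a combination of

    J2(2 sqrt z)/z,  Y2(2 sqrt z)/z,  I2(2 sqrt z)/z,  K2(2 sqrt z)/z.

Four boundary cases are supported: a freely vibrating full-length or
truncated cone (clamped base, free tip), and the same two cones with a
simple support at the pole contact point ``x = c`` (zero deflection,
continuous slope and bending moment).  Each case yields a characteristic
determinant whose positive roots ``beta_j = q_j L`` are the dimensionless
eigenfrequencies; the corresponding coefficient vectors are null vectors of
the boundary matrix.

The modified Bessel terms grow like ``exp(2 sqrt z)``, so all boundary
matrices are assembled from exponentially scaled ``I`` and ``K`` with
column-wise positive scale factors: root locations and null spaces are
unchanged while the entries stay O(1) up to arbitrarily high modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, ive, jv, kve, yv

from .geometry import WhiskerGeometry
from .quadrature import cone_grid

__all__ = [
    "BoundaryCase",
    "Eigenmode",
    "char_determinant",
    "find_eigenvalues",
    "build_eigenmode",
    "build_modes",
    "omega_from_beta",
    "beta_from_omega",
    "young_modulus_from_frequency",
    "orthogonality_matrix",
    "free_full_beta1",
]


class BoundaryCase(Enum):
    FREE_FULL = "free-full"
    FREE_TRUNCATED = "free-truncated"
    CONTACT_FULL = "contact-full"
    CONTACT_TRUNCATED = "contact-truncated"

    @property
    def is_contact(self) -> bool:
        return self in (BoundaryCase.CONTACT_FULL, BoundaryCase.CONTACT_TRUNCATED)

    @property
    def is_truncated(self) -> bool:
        return self in (BoundaryCase.FREE_TRUNCATED, BoundaryCase.CONTACT_TRUNCATED)


_SMALL_Z = 1e-8


def _series_ratio(nu: int, z, signed: bool):
    """Small-argument series of J_nu(2 sqrt z)/z^(nu/2) (signed) or the I analogue."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    sgn = 1.0
    for k in range(3):
        coef = math.exp(-gammaln(k + 1) - gammaln(nu + k + 1))
        out = out + sgn * coef * z**k
        sgn = -sgn if signed else sgn
    return out


def _basis(deriv: int, z, ref_I: float, ref_K: float, with_YK: bool = True):
    """Scaled basis values [J, Y, I, K] of chi^(deriv) at z (common z-power removed
    per row is NOT done here: the full z^{-(2+d)/2} factor is included).

    I entries carry the column scale exp(-ref_I), K entries exp(+ref_K); the
    scales are folded in through the exponentially scaled Bessel routines.
    """
    nu = 2 + deriv
    sgn = -1.0 if deriv % 2 else 1.0
    z = np.asarray(z, dtype=float)
    x = 2.0 * np.sqrt(np.maximum(z, 0.0))
    small = z < _SMALL_Z
    zp = np.where(small, 1.0, z) ** (nu / 2.0)

    termJ = np.where(small, sgn * _series_ratio(nu, z, signed=True),
                     sgn * jv(nu, x) / zp)
    # exp(x - ref_I) <= 1 on the region since ref_I is the maximal argument
    expI = np.exp(np.maximum(x - ref_I, -745.0))
    termI = np.where(small, _series_ratio(nu, z, signed=False) * np.exp(np.maximum(-np.asarray(ref_I, dtype=float), -745.0)),
                     ive(nu, x) * expI / zp)
    if not with_YK:
        return termJ, termI
    termY = sgn * yv(nu, x) / zp
    termK = sgn * kve(nu, x) * np.exp(ref_K - x) / zp
    return termJ, termY, termI, termK


def _row(kind: str, z, ref_I: float, ref_K: float, with_YK: bool = True):
    """One boundary-condition row over the region basis.

    kinds: 'val' chi = 0; 'slope' chi' = 0; 'mom' chi'' = 0 (bending moment,
    z != 0); 'shear' d/dz(z^4 chi'') = 0, which by the Bessel recurrences is
    proportional to [J3, Y3, I3, -K3](2 sqrt z).
    """
    if kind == "val":
        return np.stack(_basis(0, z, ref_I, ref_K, with_YK), axis=-1)
    if kind == "slope":
        return np.stack(_basis(1, z, ref_I, ref_K, with_YK), axis=-1)
    if kind == "mom":
        return np.stack(_basis(2, z, ref_I, ref_K, with_YK), axis=-1)
    if kind == "shear":
        # signs of the order-3 shear row differ from chi''' : [+J3, +Y3, +I3, -K3]
        terms = _basis(1, z, ref_I, ref_K, with_YK)
        if with_YK:
            tJ, tY, tI, tK = terms
            return np.stack([-tJ, -tY, tI, tK], axis=-1)
        tJ, tI = terms
        return np.stack([-tJ, tI], axis=-1)
    raise ValueError(kind)


def _shape_check(case: BoundaryCase, ell_ratio: float, c_ratio: float | None) -> None:
    if case.is_truncated:
        if not (0.0 < ell_ratio < 1.0):
            raise ValueError(f"truncated case requires 0 < l/L < 1, got {ell_ratio}")
    else:
        if ell_ratio != 0.0:
            raise ValueError(f"full-length case requires l/L = 0, got {ell_ratio}")
    if case.is_contact:
        if c_ratio is None or not (ell_ratio < c_ratio < 1.0):
            raise ValueError(f"contact case requires l/L < c/L < 1, got c/L={c_ratio}")
    elif c_ratio is not None:
        raise ValueError("free case forbids a contact position")


def _boundary_matrices(case: BoundaryCase, betas, ell_ratio: float, c_ratio: float | None):
    """Batch of scaled boundary matrices, shape (n, k, k) for an array of betas."""
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    gam = betas * ell_ratio
    sb = 2.0 * np.sqrt(betas)

    if case == BoundaryCase.FREE_FULL:
        ref_I = sb
        M = np.zeros(betas.shape + (2, 2))
        M[..., 0, :] = _row("val", betas, ref_I, 0.0, with_YK=False)
        M[..., 1, :] = _row("slope", betas, ref_I, 0.0, with_YK=False)
        return M

    if case == BoundaryCase.FREE_TRUNCATED:
        ref_I, ref_K = sb, 2.0 * np.sqrt(gam)
        M = np.zeros(betas.shape + (4, 4))
        M[..., 0, :] = _row("val", betas, ref_I, ref_K)
        M[..., 1, :] = _row("slope", betas, ref_I, ref_K)
        M[..., 2, :] = _row("mom", gam, ref_I, ref_K)
        M[..., 3, :] = _row("shear", gam, ref_I, ref_K)
        return M

    eta = betas * c_ratio
    se = 2.0 * np.sqrt(eta)

    if case == BoundaryCase.CONTACT_FULL:
        refI_L = se
        refI_R, refK_R = sb, se
        M = np.zeros(betas.shape + (6, 6))
        M[..., 0, 2:] = _row("val", betas, refI_R, refK_R)
        M[..., 1, 2:] = _row("slope", betas, refI_R, refK_R)
        M[..., 2, :2] = _row("val", eta, refI_L, 0.0, with_YK=False)
        M[..., 3, 2:] = _row("val", eta, refI_R, refK_R)
        M[..., 4, :2] = _row("slope", eta, refI_L, 0.0, with_YK=False)
        M[..., 4, 2:] = -_row("slope", eta, refI_R, refK_R)
        M[..., 5, :2] = _row("mom", eta, refI_L, 0.0, with_YK=False)
        M[..., 5, 2:] = -_row("mom", eta, refI_R, refK_R)
        return M

    if case == BoundaryCase.CONTACT_TRUNCATED:
        sg = 2.0 * np.sqrt(gam)
        refI_L, refK_L = se, sg
        refI_R, refK_R = sb, se
        M = np.zeros(betas.shape + (8, 8))
        M[..., 0, 4:] = _row("val", betas, refI_R, refK_R)
        M[..., 1, 4:] = _row("slope", betas, refI_R, refK_R)
        M[..., 2, :4] = _row("val", eta, refI_L, refK_L)
        M[..., 3, 4:] = _row("val", eta, refI_R, refK_R)
        M[..., 4, :4] = _row("slope", eta, refI_L, refK_L)
        M[..., 4, 4:] = -_row("slope", eta, refI_R, refK_R)
        M[..., 5, :4] = _row("mom", eta, refI_L, refK_L)
        M[..., 5, 4:] = -_row("mom", eta, refI_R, refK_R)
        M[..., 6, :4] = _row("mom", gam, refI_L, refK_L)
        M[..., 7, :4] = _row("shear", gam, refI_L, refK_L)
        return M

    raise ValueError(case)


def char_determinant(
    case: BoundaryCase,
    beta,
    ell_ratio: float = 0.0,
    c_ratio: float | None = None,
):
    """Rescaled characteristic determinant of the boundary matrix at ``beta``.

    Returns a signed scalar (or array) whose zeros and sign pattern coincide
    with those of the true determinant; the positive rescaling keeps the
    exponentially growing modified-Bessel terms bounded for arbitrarily large
    ``beta``.  For FREE_FULL this is the reduced 2x2 form
    ``J2 I1 - J1 I2`` evaluated at ``2 sqrt(beta)`` with scaled ``I``.
    """
    _shape_check(case, ell_ratio, c_ratio)
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("beta must be positive")
    if case == BoundaryCase.FREE_FULL:
        x = 2.0 * np.sqrt(b)
        d = jv(2, x) * ive(1, x) - jv(1, x) * ive(2, x)
        return d if d.ndim else float(d)
    M = _boundary_matrices(case, b, ell_ratio, c_ratio)
    d = np.linalg.det(M)
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("boundary determinant overflowed despite scaling")
    return d if np.ndim(beta) else float(d[0])


def _scan_roots(case, ell_ratio, c_ratio, s_lo, s_hi, step):
    """Sign-change brackets of det(s^2) on a uniform grid in s = sqrt(beta)."""
    n = max(8, int(np.ceil((s_hi - s_lo) / step)) + 1)
    s = np.linspace(s_lo, s_hi, n)
    d = np.asarray(char_determinant(case, s**2, ell_ratio, c_ratio))
    idx = np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]
    return [(s[i], s[i + 1]) for i in idx]


def find_eigenvalues(
    case: BoundaryCase,
    n_modes: int,
    ell_ratio: float = 0.0,
    c_ratio: float | None = None,
    beta_max: float | None = None,
) -> np.ndarray:
    """The ``n_modes`` smallest positive roots of the characteristic equation.

    Roots are located by a bracketed scan uniform in ``sqrt(beta)`` (where
    the asymptotic root spacing is constant), cross-checked at half the scan
    step to guard against closely spaced roots, and polished to relative
    tolerance 1e-12.  The trivial root at ``beta = 0`` is excluded by
    starting the scan at ``beta = 0.25``.
    """
    _shape_check(case, ell_ratio, c_ratio)
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    s_lo = 0.5
    # asymptotic spacing in s is ~ pi/2 / (1 - sqrt(l/L)); generous ceiling
    density = 2.0 * (1.0 - math.sqrt(ell_ratio)) / math.pi + (0.7 if case.is_contact else 0.0)
    s_hi = s_lo + 1.5 * (n_modes + 4) / max(density, 0.2)
    if beta_max is not None:
        s_hi = min(s_hi, math.sqrt(beta_max))

    step = 0.05
    for _ in range(12):
        brackets = _scan_roots(case, ell_ratio, c_ratio, s_lo, s_hi, step)
        finer = _scan_roots(case, ell_ratio, c_ratio, s_lo, s_hi, step / 2.0)
        if len(finer) == len(brackets):
            brackets = finer
            break
        step /= 2.0
    else:
        brackets = finer

    while len(brackets) < n_modes:
        if beta_max is not None and s_hi >= math.sqrt(beta_max):
            raise RuntimeError(
                f"found only {len(brackets)} roots below beta_max={beta_max}; "
                f"requested {n_modes}"
            )
        new_hi = s_hi * 1.5
        brackets += _scan_roots(case, ell_ratio, c_ratio, s_hi, new_hi, step)
        s_hi = new_hi

    roots = []
    for a, b in brackets[:n_modes]:
        s_root = brentq(
            lambda s: char_determinant(case, s * s, ell_ratio, c_ratio),
            a, b, xtol=1e-13, rtol=8.9e-16,
        )
        roots.append(s_root**2)
    return np.array(roots)


@lru_cache(maxsize=None)
def free_full_beta1() -> float:
    """First dimensionless root of the free full-length cone (computed, cached)."""
    return float(find_eigenvalues(BoundaryCase.FREE_FULL, 1)[0])


@dataclass(frozen=True)
class _Region:
    """One closed-form segment of a mode: coefficients over the scaled basis."""
    z_lo: float
    z_hi: float
    coeffs: np.ndarray  # length 2 (J, I) or 4 (J, Y, I, K), scaled convention
    ref_I: float
    ref_K: float

    @property
    def with_YK(self) -> bool:
        return self.coeffs.size == 4

    def eval(self, z, deriv: int):
        terms = _basis(deriv, z, self.ref_I, self.ref_K, with_YK=self.with_YK)
        out = 0.0
        for c, t in zip(self.coeffs, terms):
            out = out + c * t
        return out


@dataclass(frozen=True)
class Eigenmode:
    """One normalized closed-form eigenmode.

    ``eval(xhat, deriv)`` returns the dimensionless mode shape (or its
    derivatives with respect to ``xhat = x/L``) normalized so that
    ``int_{l/L}^{1} xhat^2 X(xhat)^2 dxhat = 1``.  Dimensional values follow
    from ``X(x) = X(x/L) L^{-3/2}`` and one factor ``1/L`` per derivative.
    """

    case: BoundaryCase
    j: int
    beta: float
    ell_ratio: float
    c_ratio: float | None
    regions: tuple
    singular_values: tuple = field(default=(), compare=False)

    @property
    def gamma(self) -> float:
        return self.beta * self.ell_ratio

    @property
    def eta(self) -> float | None:
        return None if self.c_ratio is None else self.beta * self.c_ratio

    def eval(self, xhat, deriv: int = 0):
        """Dimensionless mode shape; derivatives are with respect to xhat."""
        xhat = np.asarray(xhat, dtype=float)
        z = self.beta * xhat
        if len(self.regions) == 1:
            out = self.regions[0].eval(z, deriv)
        else:
            left, right = self.regions
            zc = np.clip(z, None, left.z_hi)
            out = np.where(z <= left.z_hi, left.eval(zc, deriv),
                           right.eval(np.clip(z, right.z_lo, None), deriv))
        out = out * self.beta**deriv
        return out if out.ndim else float(out)

    def eval_dim(self, geom: WhiskerGeometry, x, deriv: int = 0):
        """Dimensional mode value at x (m); normalized so int x^2 X^2 dx = 1."""
        scale = geom.L ** (-1.5 - deriv)
        return self.eval(np.asarray(x, dtype=float) / geom.L, deriv) * scale

    def omega(self, geom: WhiskerGeometry) -> float:
        """Angular eigenfrequency for a particular whisker (rad/s)."""
        return omega_from_beta(geom, self.beta)

    def q(self, geom: WhiskerGeometry) -> float:
        """Dimensional wavenumber q = beta / L (1/m)."""
        return self.beta / geom.L


def omega_from_beta(geom: WhiskerGeometry, beta) -> float:
    """omega = (beta/2) (xi/L) sqrt(E/rho) = (beta/2) (R/L^2) sqrt(E/rho)."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    out = 0.5 * beta * geom.xi / geom.L * geom.wave_speed_factor()
    return out if out.ndim else float(out)


def beta_from_omega(geom: WhiskerGeometry, omega) -> float:
    """Inverse of :func:`omega_from_beta`."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    out = 2.0 * omega * geom.L / (geom.xi * geom.wave_speed_factor())
    return out if out.ndim else float(out)


def young_modulus_from_frequency(
    L: float, R: float, rho: float, omega_measured: float, beta1: float | None = None
) -> float:
    """Young's modulus from a measured fundamental frequency (Pa).

    Inverts the conical-beam eigenfrequency relation:
    ``E = rho (2 omega L^2 / (beta1 R))^2``.  By default ``beta1`` is the
    first root of the free full-length cone.
    """
    if min(L, R, rho, omega_measured) <= 0:
        raise ValueError("all inputs must be positive")
    if beta1 is None:
        beta1 = free_full_beta1()
    return rho * (2.0 * omega_measured * L**2 / (beta1 * R)) ** 2


def build_eigenmode(
    case: BoundaryCase,
    beta: float,
    ell_ratio: float = 0.0,
    c_ratio: float | None = None,
    j: int = 0,
) -> Eigenmode:
    """Construct the normalized eigenmode for a verified root ``beta``.

    The coefficient vector is the right singular vector of the boundary
    matrix belonging to its smallest singular value; a degenerate (rank
    deficiency > 1) root is rejected.  The normalization integral uses the
    oscillation-resolving composite Gauss grid, and the sign is fixed so the
    mode is positive at its largest-amplitude point closest to the tip.
    """
    _shape_check(case, ell_ratio, c_ratio)
    M = _boundary_matrices(case, np.array([beta]), ell_ratio, c_ratio)[0]
    U, s, Vt = np.linalg.svd(M)
    if s[0] > 0 and s[-1] / s[0] > 1e-6:
        raise ValueError(f"beta={beta} is not a root of the {case.name} determinant")
    if s.size > 1 and s[-2] / s[0] < 1e-8:
        raise ValueError(f"degenerate root beta={beta}: null space dimension > 1")
    v = Vt[-1]

    gam = beta * ell_ratio
    eta = None if c_ratio is None else beta * c_ratio
    sb, sg = 2.0 * math.sqrt(beta), 2.0 * math.sqrt(gam) if gam > 0 else 0.0

    if case == BoundaryCase.FREE_FULL:
        regions = (_Region(0.0, beta, np.array([v[0], v[1]]), sb, 0.0),)
    elif case == BoundaryCase.FREE_TRUNCATED:
        regions = (_Region(gam, beta, v.copy(), sb, sg),)
    elif case == BoundaryCase.CONTACT_FULL:
        se = 2.0 * math.sqrt(eta)
        regions = (
            _Region(0.0, eta, v[:2].copy(), se, 0.0),
            _Region(eta, beta, v[2:].copy(), sb, se),
        )
    else:  # CONTACT_TRUNCATED
        se = 2.0 * math.sqrt(eta)
        regions = (
            _Region(gam, eta, v[:4].copy(), se, sg),
            _Region(eta, beta, v[4:].copy(), sb, se),
        )

    mode = Eigenmode(
        case=case, j=j, beta=float(beta), ell_ratio=ell_ratio, c_ratio=c_ratio,
        regions=regions, singular_values=tuple(s),
    )
    # normalize: int xhat^2 X^2 dxhat = 1
    xh, w = cone_grid(ell_ratio, c_ratio, beta_max=beta)
    vals = mode.eval(xh)
    nrm = math.sqrt(float(np.sum(w * xh**2 * vals**2)))
    if nrm == 0.0 or not math.isfinite(nrm):
        raise FloatingPointError("mode normalization failed")
    # deterministic sign: positive at the max-|X| point closest to the tip
    a = np.abs(vals)
    near_max = np.nonzero(a >= (1.0 - 1e-9) * a.max())[0]
    sign = 1.0 if vals[near_max[0]] > 0 else -1.0
    scale = sign / nrm
    regions = tuple(
        _Region(r.z_lo, r.z_hi, r.coeffs * scale, r.ref_I, r.ref_K) for r in mode.regions
    )
    return Eigenmode(
        case=case, j=j, beta=float(beta), ell_ratio=ell_ratio, c_ratio=c_ratio,
        regions=regions, singular_values=tuple(s),
    )


def build_modes(
    case: BoundaryCase,
    n_modes: int,
    ell_ratio: float = 0.0,
    c_ratio: float | None = None,
) -> list[Eigenmode]:
    """Find the first ``n_modes`` roots and build their normalized modes."""
    betas = find_eigenvalues(case, n_modes, ell_ratio, c_ratio)
    return [
        build_eigenmode(case, b, ell_ratio, c_ratio, j=i + 1) for i, b in enumerate(betas)
    ]


def orthogonality_matrix(modes: Sequence[Eigenmode]) -> np.ndarray:
    """Gram matrix ``int xhat^2 X_i X_j dxhat`` of a family of modes.

    For exact eigenmodes of a common boundary case this is the identity.
    """
    if not modes:
        raise ValueError("need at least one mode")
    m0 = modes[0]
    for m in modes[1:]:
        if m.case != m0.case or m.ell_ratio != m0.ell_ratio or m.c_ratio != m0.c_ratio:
            raise ValueError("all modes must share boundary case and shape ratios")
    beta_max = max(m.beta for m in modes)
    xh, w = cone_grid(m0.ell_ratio, m0.c_ratio, beta_max=beta_max)
    Phi = np.stack([m.eval(xh) for m in modes], axis=0)
    return (Phi * (w * xh**2)) @ Phi.T
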