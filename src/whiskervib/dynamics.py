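"""Damped modal time evolution of a whisker touching and releasing a pole.

During contact the displacement splits exactly into a quasi-static part that
tracks the instantaneous force, ``y_s(x, t) = F(t) ytilde(x)``, and a
vibrational part expanded in the contact-constrained eigenmodes,
``y_e(x, t) = sum_j phi_j(t) X_j(x)``.  Each modal coefficient obeys the
damped oscillator equation

    phidot2_j + alpha phidot_j + omega_j^2 phi_j = -[Fddot + alpha Fdot] P_j,

with ``P_j`` the x^2-weighted overlap of the unit static deflection with the
mode.  The primary engine propagates this equation exactly over each step of
a fine time grid assuming the drive is linear within the step (exact
exponential/trigonometric update, unconditionally stable); the explicit
Duhamel convolution is retained as a cross-check oracle.

At detachment the whisker state is projected onto the free-vibration modes
``Z_j`` and evolves in closed form as damped sinusoids.  The bending moment
and shear force at the follicle follow from the second and third spatial
derivatives of the modes at the base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .eigen import BoundaryCase, Eigenmode, build_modes, omega_from_beta
from .forcing import ForceKind, ForceProfile
from .geometry import ContactConfig, WhiskerGeometry
from .quadrature import cone_grid
from .statics import StaticSolution, static_deflection

__all__ = [
    "ModalEvolution",
    "DisplacementField",
    "FollicleSignal",
    "modal_projection",
    "contact_coefficients",
    "contact_coefficients_duhamel",
    "detach_and_free",
    "displacement_field",
    "follicle_signal",
    "simulate_touch",
]


def _require_contact_modes(modes: Sequence[Eigenmode], static: StaticSolution) -> None:
    c_ratio = static.contact.c / static.geom.L
    ell_ratio = static.geom.ell_ratio
    for m in modes:
        if not m.case.is_contact:
            raise ValueError("modes must be contact-constrained (CONTACT_* case)")
        if abs((m.c_ratio or 0.0) - c_ratio) > 1e-12 or abs(m.ell_ratio - ell_ratio) > 1e-12:
            raise ValueError("mode shape ratios do not match the static solution")


def modal_projection(static: StaticSolution, modes: Sequence[Eigenmode]) -> np.ndarray:
    """Projection coefficients P_j = int ytilde(x) x^2 X_j(x) dx (per unit force).

    Quadrature uses the oscillation-resolving composite Gauss grid with a
    forced panel break at the contact point, where ``ytilde`` has a slope kink.
    """
    _require_contact_modes(modes, static)
    geom = static.geom
    c_ratio = static.contact.c / geom.L
    beta_max = max(m.beta for m in modes)
    xh, w = cone_grid(geom.ell_ratio, c_ratio, beta_max=beta_max)
    yt = static.ytilde(xh * geom.L)  # m/N
    Phi = np.stack([m.eval(xh) for m in modes], axis=0)  # dimensionless
    # dimensional: int ytilde x^2 X dx = L^3 * L^{-3/2} * int ytilde(xh L) xh^2 X(xh) dxh
    return geom.L**1.5 * (Phi @ (w * xh**2 * yt))


def _nigam_jennings(
    omega: np.ndarray, alpha: float, g: np.ndarray, t: np.ndarray,
    y0: np.ndarray | None = None, yd0: np.ndarray | None = None,
):
    """Exact stepping of y'' + alpha y' + omega^2 y = g(t), g piecewise linear on t.

    Returns (y, ydot) with shape (n_modes, len(t)).
    """
    n_modes, nt = omega.size, t.size
    a = alpha / 2.0
    om_t = np.sqrt(omega**2 - a**2)
    y = np.zeros((n_modes, nt))
    yd = np.zeros((n_modes, nt))
    if y0 is not None:
        y[:, 0] = y0
    if yd0 is not None:
        yd[:, 0] = yd0
    w2 = omega**2
    w4 = w2**2
    for i in range(nt - 1):
        h = t[i + 1] - t[i]
        gi = g[:, i]
        dg = (g[:, i + 1] - gi) / h
        # particular solution for linear drive: y_p = (gi + dg s)/w^2 - dg*alpha/w^4
        A = y[:, i] - gi / w2 + dg * alpha / w4
        B = (yd[:, i] + a * A - dg / w2) / om_t
        e = np.exp(-a * h)
        cs, sn = np.cos(om_t * h), np.sin(om_t * h)
        y[:, i + 1] = e * (A * cs + B * sn) + (gi + dg * h) / w2 - dg * alpha / w4
        yd[:, i + 1] = e * ((om_t * B - a * A) * cs - (om_t * A + a * B) * sn) + dg / w2
    return y, yd


def _contact_time_grid(profile: ForceProfile, t_eval: np.ndarray, t_end: float) -> np.ndarray:
    """Fine integration grid: dense over the onset, fine over the rest."""
    pieces = [np.asarray(t_eval, dtype=float)]
    if np.isfinite(profile.tau) and profile.tau > 0:
        pieces.append(np.linspace(0.0, profile.tau, 8001))
        pieces.append(np.linspace(profile.tau, t_end, 40001))
    else:
        pieces.append(np.linspace(0.0, t_end, 40001))
    grid = np.unique(np.concatenate([np.array([0.0, t_end])] + pieces))
    return grid[(grid >= 0.0) & (grid <= t_end * (1 + 1e-12))]


@dataclass
class ModalEvolution:
    """Modal state of a touch: contact-phase and free-phase coefficients."""

    geom: WhiskerGeometry
    contact: ContactConfig
    profile: ForceProfile
    static: StaticSolution
    contact_modes: list
    free_modes: list
    P: np.ndarray                      # projections of ytilde on contact modes
    t_contact: np.ndarray              # evaluation times in [0, t_f]
    phi: np.ndarray                    # (n_contact_modes, nt)
    phi_dot: np.ndarray
    phi_f: np.ndarray = field(default=None)      # free-mode coefficients at t_f
    phi_f_dot: np.ndarray = field(default=None)
    continuity_residual: float = field(default=float("nan"))

    @property
    def t_f(self) -> float:
        return self.profile.t_f

    def contact_omegas(self) -> np.ndarray:
        return np.array([omega_from_beta(self.geom, m.beta) for m in self.contact_modes])

    def free_omegas(self) -> np.ndarray:
        return np.array([omega_from_beta(self.geom, m.beta) for m in self.free_modes])


def contact_coefficients(
    modes: Sequence[Eigenmode],
    P: np.ndarray,
    profile: ForceProfile,
    t_eval: np.ndarray,
    geom: WhiskerGeometry,
):
    """Contact-phase coefficients phi_j(t) and rates on the requested times.

    The modal oscillator is driven by ``-[Fddot + alpha Fdot] P_j`` starting
    from rest; an underdamped spectrum (omega_j > alpha/2) is required.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    omega = np.array([omega_from_beta(geom, m.beta) for m in modes])
    alpha = geom.alpha
    if np.any(omega <= alpha / 2.0):
        raise ValueError("over/critically damped mode encountered: omega_j <= alpha/2")
    t_end = float(min(t_eval.max() if t_eval.size else profile.t_f, profile.t_f))
    grid = _contact_time_grid(profile, t_eval, t_end)
    g = -np.outer(P, np.ones_like(grid)) * (profile(grid, 2) + alpha * profile(grid, 1))
    yd0 = None
    if profile.kind == ForceKind.RAMP:
        # Fddot = s delta(t): the impulse sets the initial modal velocity,
        # leaving the smooth drive -alpha Fdot P_j for t > 0
        yd0 = -np.asarray(P, dtype=float) * profile.s
    y, yd = _nigam_jennings(omega, alpha, g, grid, yd0=yd0)
    idx = np.searchsorted(grid, t_eval)
    idx = np.clip(idx, 0, grid.size - 1)
    return y[:, idx], yd[:, idx]


def contact_coefficients_duhamel(
    modes: Sequence[Eigenmode],
    P: np.ndarray,
    profile: ForceProfile,
    t_eval: np.ndarray,
    geom: WhiskerGeometry,
):
    """Direct adaptive quadrature of the Duhamel convolution (cross-check oracle).

    phi_j(t) = -(P_j/om~_j) int_0^t [Fddot + alpha Fdot] e^{-alpha(t-t')/2}
               sin(om~_j (t-t')) dt'.
    """
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    omega = np.array([omega_from_beta(geom, m.beta) for m in modes])
    alpha = geom.alpha
    a = alpha / 2.0
    om_t = np.sqrt(omega**2 - a**2)
    phi = np.zeros((omega.size, t_eval.size))
    phid = np.zeros_like(phi)
    for j, wj in enumerate(om_t):
        for k, t in enumerate(t_eval):
            if t <= 0:
                continue
            if profile.kind == ForceKind.RAMP:
                # impulse part of Fddot = s delta(t)
                e = math.exp(-a * t)
                phi[j, k] = -P[j] * profile.s / wj * e * math.sin(wj * t)
                phid[j, k] = -P[j] * profile.s * e * (
                    math.cos(wj * t) - a / wj * math.sin(wj * t)
                )

            def drive(tp):
                return profile(tp, 2) + alpha * profile(tp, 1)

            def f_sin(tp):
                return drive(tp) * math.exp(-a * (t - tp)) * math.sin(wj * (t - tp))

            def f_cos(tp):
                return drive(tp) * math.exp(-a * (t - tp)) * math.cos(wj * (t - tp))

            pts = [p for p in (profile.tau, profile.a) if 0 < p < t]
            kw = dict(points=pts or None, limit=400, epsabs=1e-14, epsrel=1e-11)
            Is, _ = quad(f_sin, 0.0, t, **kw)
            Ic, _ = quad(f_cos, 0.0, t, **kw)
            phi[j, k] += -P[j] / wj * Is
            phid[j, k] += -P[j] * (Ic - a / wj * Is)
    return phi, phid


def detach_and_free(evol: ModalEvolution, t_grid: np.ndarray):
    """Free-phase coefficients varphi_j(t) for t >= t_f by continuity matching.

    Projects the whisker displacement and velocity at detachment onto the
    free modes and evaluates the closed-form damped-sinusoid evolution.
    Records the relative continuity residual of the re-expanded displacement.
    """
    geom = evol.geom
    c_ratio = evol.contact.c / geom.L
    free = evol.free_modes
    beta_max = max(max(m.beta for m in free), max(m.beta for m in evol.contact_modes))
    xh, w = cone_grid(geom.ell_ratio, c_ratio, beta_max=beta_max)
    wx2 = w * xh**2

    Z = np.stack([m.eval(xh) for m in free], axis=0)
    X = np.stack([m.eval(xh) for m in evol.contact_modes], axis=0)
    yt = evol.static.ytilde(xh * geom.L)  # m/N

    t_f = evol.t_f
    i_f = int(np.argmin(np.abs(evol.t_contact - t_f)))
    phi_tf = evol.phi[:, i_f]
    phid_tf = evol.phi_dot[:, i_f]
    F_tf = float(evol.profile(t_f))
    Fd_tf = float(evol.profile(t_f, 1))

    # work in scaled shape units yhat = y * L^{3/2}, in which the free-mode
    # projection is simply the dimensionless weighted inner product
    y_tf = F_tf * yt * geom.L**1.5 + phi_tf @ X
    yd_tf = Fd_tf * yt * geom.L**1.5 + phid_tf @ X

    vphi_f = Z @ (wx2 * y_tf)
    vphid_f = Z @ (wx2 * yd_tf)

    recon = vphi_f @ Z
    peak = np.abs(y_tf).max()
    resid = float(np.abs(recon - y_tf).max() / peak) if peak > 0 else 0.0

    evol.phi_f = vphi_f
    evol.phi_f_dot = vphid_f
    evol.continuity_residual = resid

    return free_coefficients(evol, t_grid)


def free_coefficients(evol: ModalEvolution, t_grid: np.ndarray):
    """Closed-form damped free evolution from the matched detachment state."""
    if evol.phi_f is None:
        raise ValueError("detachment state not computed; call detach_and_free first")
    t_grid = np.asarray(t_grid, dtype=float)
    s = t_grid[None, :] - evol.t_f
    alpha = evol.geom.alpha
    a = alpha / 2.0
    varpi = evol.free_omegas()[:, None]
    varpi_t = np.sqrt(varpi**2 - a**2)
    p0 = evol.phi_f[:, None]
    v0 = evol.phi_f_dot[:, None]
    e = np.exp(-a * s)
    cs, sn = np.cos(varpi_t * s), np.sin(varpi_t * s)
    vphi = e * (p0 * (a / varpi_t * sn + cs) + v0 / varpi_t * sn)
    vphid = e * (v0 * cs - (varpi**2 * p0 + a * v0) / varpi_t * sn)
    return vphi, vphid


@dataclass
class DisplacementField:
    """Sampled whisker displacement on an (x, t) grid.

    During contact ``y = y_static + y_vib`` (the decomposition is exact);
    after detachment only the total free motion ``u`` is defined and it is
    stored in ``y_total`` with the static component zero.
    """

    x: np.ndarray
    t: np.ndarray
    y_static: np.ndarray   # (nt, nx)
    y_vib: np.ndarray      # (nt, nx)

    @property
    def y_total(self) -> np.ndarray:
        return self.y_static + self.y_vib


def displacement_field(
    evol: ModalEvolution, x_grid: np.ndarray, t_grid: np.ndarray
) -> DisplacementField:
    """Whisker displacement over the full length, including beyond the contact.

    For t <= t_f:  y(x,t) = F(t) ytilde(x) + sum_j phi_j(t) X_j(x);
    for t > t_f:   u(x,t) = sum_j varphi_j(t) Z_j(x) (reported as vibrational).
    """
    geom = evol.geom
    x_grid = np.asarray(x_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    xh = x_grid / geom.L
    scale = geom.L ** (-1.5)

    X = np.stack([m.eval(xh) for m in evol.contact_modes], axis=0) * scale
    Z = np.stack([m.eval(xh) for m in evol.free_modes], axis=0) * scale
    yt = evol.static.ytilde(x_grid)

    y_static = np.zeros((t_grid.size, x_grid.size))
    y_vib = np.zeros_like(y_static)

    in_contact = t_grid <= evol.t_f
    if np.any(in_contact):
        tc = t_grid[in_contact]
        phi, _ = contact_coefficients(evol.contact_modes, evol.P, evol.profile, tc, geom)
        F = np.atleast_1d(evol.profile(tc))
        y_static[in_contact] = np.outer(F, yt)
        y_vib[in_contact] = phi.T @ X
    if np.any(~in_contact):
        tf_grid = t_grid[~in_contact]
        vphi, _ = free_coefficients(evol, tf_grid)
        y_vib[~in_contact] = vphi.T @ Z
    return DisplacementField(x=x_grid, t=t_grid, y_static=y_static, y_vib=y_vib)


@dataclass
class FollicleSignal:
    """Bending moment and shear force at the base, split into components.

    ``M_static = F(t)(L - c)``, ``V_static = F(t)`` during contact (zero
    after detachment); the vibrational parts come from the modal expansion
    evaluated at the base.
    """

    t: np.ndarray
    M_static: np.ndarray
    M_vib: np.ndarray
    V_static: np.ndarray
    V_vib: np.ndarray

    @property
    def M_total(self) -> np.ndarray:
        return self.M_static + self.M_vib

    @property
    def V_total(self) -> np.ndarray:
        return self.V_static + self.V_vib


def _base_load_factors(modes: Sequence[Eigenmode], geom: WhiskerGeometry):
    """(EI0 X_j''(L), EI0 [4 X_j''(L)/L + X_j'''(L)]) for each mode."""
    EI0 = geom.E * geom.I0
    d2 = np.array([m.eval_dim(geom, geom.L, 2) for m in modes])
    d3 = np.array([m.eval_dim(geom, geom.L, 3) for m in modes])
    return EI0 * d2, EI0 * (4.0 / geom.L * d2 + d3)


def follicle_signal(evol: ModalEvolution, t_grid: np.ndarray) -> FollicleSignal:
    """Base bending moment M(L;t) and shear V(L;t), static + vibrational parts."""
    geom = evol.geom
    t_grid = np.asarray(t_grid, dtype=float)
    mom_X, shr_X = _base_load_factors(evol.contact_modes, geom)
    mom_Z, shr_Z = _base_load_factors(evol.free_modes, geom)

    M_static = np.zeros_like(t_grid)
    M_vib = np.zeros_like(t_grid)
    V_static = np.zeros_like(t_grid)
    V_vib = np.zeros_like(t_grid)

    in_contact = t_grid <= evol.t_f
    if np.any(in_contact):
        tc = t_grid[in_contact]
        phi, _ = contact_coefficients(evol.contact_modes, evol.P, evol.profile, tc, geom)
        F = np.atleast_1d(evol.profile(tc))
        M_static[in_contact] = F * (geom.L - evol.contact.c)
        V_static[in_contact] = F
        M_vib[in_contact] = mom_X @ phi
        V_vib[in_contact] = shr_X @ phi
    if np.any(~in_contact):
        vphi, _ = free_coefficients(evol, t_grid[~in_contact])
        M_vib[~in_contact] = mom_Z @ vphi
        V_vib[~in_contact] = shr_Z @ vphi
    return FollicleSignal(t=t_grid, M_static=M_static, M_vib=M_vib,
                          V_static=V_static, V_vib=V_vib)


def simulate_touch(
    geom: WhiskerGeometry,
    contact: ContactConfig,
    profile: ForceProfile,
    n_modes: int = 100,
    n_free_modes: int | None = None,
    t_grid: np.ndarray | None = None,
) -> ModalEvolution:
    """Full modal solution of a touch: eigenmodes, projections, both phases.

    By default the time grid is 10 us steps over [0, 2 t_f] and the free-mode
    count equals the contact-mode count.
    """
    contact.validate(geom)
    c_ratio = contact.c / geom.L
    case = (
        BoundaryCase.CONTACT_TRUNCATED if geom.trunc > 0 else BoundaryCase.CONTACT_FULL
    )
    free_case = (
        BoundaryCase.FREE_TRUNCATED if geom.trunc > 0 else BoundaryCase.FREE_FULL
    )
    contact_modes = build_modes(case, n_modes, geom.ell_ratio, c_ratio)
    free_modes = build_modes(free_case, n_free_modes or n_modes, geom.ell_ratio)

    static = static_deflection(geom, contact, 1.0)
    P = modal_projection(static, contact_modes)

    if t_grid is None:
        t_grid = np.arange(0.0, 2.0 * profile.t_f + 5e-6, 10e-6)
    t_grid = np.asarray(t_grid, dtype=float)
    tc = np.unique(np.append(t_grid[t_grid <= profile.t_f], profile.t_f))
    phi, phi_dot = contact_coefficients(contact_modes, P, profile, tc, geom)

    evol = ModalEvolution(
        geom=geom, contact=contact, profile=profile, static=static,
        contact_modes=contact_modes, free_modes=free_modes, P=P,
        t_contact=tc, phi=phi, phi_dot=phi_dot,
    )
    detach_and_free(evol, np.array([profile.t_f]))
    return evol
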