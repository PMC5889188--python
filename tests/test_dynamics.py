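"""Modal dynamics: projections, time stepping vs Duhamel, detachment, oracles."""

from types import SimpleNamespace

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from whiskervib import (
    BoundaryCase,
    ContactConfig,
    ForceProfile,
    build_modes,
    contact_coefficients,
    contact_coefficients_duhamel,
    follicle_signal,
    modal_projection,
    omega_from_beta,
    simulate_touch,
    standard_whisker,
    static_deflection,
)
from whiskervib.dynamics import displacement_field, free_coefficients


# ---------------------------------------------------------------- projections

def test_projection_of_a_mode_is_kronecker_delta(geom, contact06):
    modes = build_modes(BoundaryCase.CONTACT_TRUNCATED, 5, 0.05, 0.6)
    k = 2
    fake = SimpleNamespace(
        geom=geom, contact=contact06,
        ytilde=lambda x: modes[k].eval_dim(geom, x),
    )
    P = modal_projection(fake, modes)
    expect = np.zeros(5)
    expect[k] = 1.0
    np.testing.assert_allclose(P, expect, atol=1e-9)


def test_projection_against_dense_trapezoid_oracle(geom, contact06, touch_small):
    st = static_deflection(geom, contact06, 1.0)
    modes = touch_small.contact_modes
    P = modal_projection(st, modes)
    # dense trapezoid with a node exactly at the contact kink
    x = np.unique(np.concatenate([
        np.linspace(geom.trunc, contact06.c, 120001),
        np.linspace(contact06.c, geom.L, 120001),
    ]))
    yt = st.ytilde(x)
    for j in [0, 4, 9, 19]:
        X = modes[j].eval_dim(geom, x)
        oracle = np.trapezoid(yt * x**2 * X, x)
        assert P[j] == pytest.approx(oracle, rel=2e-6, abs=1e-6 * np.abs(P).max())


def test_projection_amplitudes_decay(touch_small):
    P = np.abs(touch_small.P)
    assert P[0] == P.max()
    assert np.abs(touch_small.P[9:]).max() < 0.2 * P[0]


# ------------------------------------------------------------- time evolution

def test_no_drive_no_response(geom, contact06):
    modes = build_modes(BoundaryCase.CONTACT_TRUNCATED, 3, 0.05, 0.6)
    st = static_deflection(geom, contact06, 1.0)
    P = modal_projection(st, modes)
    phi, phid = contact_coefficients(modes, P, ForceProfile.ramp(0.0),
                                     np.linspace(0, 5e-3, 11), geom)
    assert np.all(phi == 0.0) and np.all(phid == 0.0)


def test_engine_matches_duhamel_quadrature(geom, contact06, profile):
    modes = build_modes(BoundaryCase.CONTACT_TRUNCATED, 4, 0.05, 0.6)
    st = static_deflection(geom, contact06, 1.0)
    P = modal_projection(st, modes)
    tt = np.array([1e-3, 5e-3, 9e-3])
    phi_e, phid_e = contact_coefficients(modes, P, profile, tt, geom)
    phi_d, phid_d = contact_coefficients_duhamel(modes, P, profile, tt, geom)
    assert np.abs((phi_e - phi_d) / phi_d).max() < 1e-6
    assert np.abs((phid_e - phid_d) / phid_d).max() < 1e-6


def test_ramp_closed_form_undamped(geom_undamped):
    """With alpha = 0 a ramp excites each mode as -(s P_j / omega_j) sin(omega_j t)."""
    geom = geom_undamped
    contact = ContactConfig.from_relative(geom, 0.6)
    modes = build_modes(BoundaryCase.CONTACT_TRUNCATED, 4, 0.05, 0.6)
    st = static_deflection(geom, contact, 1.0)
    P = modal_projection(st, modes)
    ramp = ForceProfile.ramp(1e-3)
    tt = np.linspace(1e-4, 3e-3, 7)
    phi, _ = contact_coefficients(modes, P, ramp, tt, geom)
    om = np.array([omega_from_beta(geom, m.beta) for m in modes])
    closed = -(ramp.s * P[:, None] / om[:, None]) * np.sin(om[:, None] * tt[None, :])
    np.testing.assert_allclose(phi, closed, atol=1e-10 * np.abs(closed).max())


def test_underdamped_guard():
    geom = standard_whisker(alpha=1e7)  # absurd damping: alpha/2 > omega_1
    contact = ContactConfig.from_relative(geom, 0.6)
    with pytest.raises(ValueError, match="damped"):
        simulate_touch(geom, contact, ForceProfile.gaussian_smooth(1e-6), n_modes=3)


# ------------------------------------------------------------------ detachment

def test_displacement_continuity_at_detachment(geom, touch06, profile):
    x = np.linspace(geom.trunc, geom.L, 200)
    eps = 1e-9
    fld = displacement_field(touch06, x, np.array([profile.t_f - eps, profile.t_f + eps]))
    peak_hist = displacement_field(touch06, x, np.linspace(0, profile.t_f, 21))
    peak = np.abs(peak_hist.y_total).max()
    jump = np.abs(fld.y_total[1] - fld.y_total[0]).max()
    assert jump < 1e-3 * peak
    assert touch06.continuity_residual < 1e-4


def test_free_phase_energy_conserved_undamped(geom_undamped):
    geom = geom_undamped
    contact = ContactConfig.from_relative(geom, 0.6)
    evol = simulate_touch(geom, contact, ForceProfile.gaussian_smooth(1e-6), n_modes=12)
    varpi = evol.free_omegas()
    t = evol.t_f + np.linspace(0.0, 20e-3, 9)
    vphi, vphid = free_coefficients(evol, t)
    energy = np.sum(vphid**2 + (varpi[:, None] * vphi) ** 2, axis=0)
    assert np.abs(energy / energy[0] - 1.0).max() < 1e-8


def test_free_phase_envelope_decays_at_half_alpha(geom, touch06):
    """log-envelope regression of each free coefficient recovers -alpha/2."""
    alpha = geom.alpha
    varpi = touch06.free_omegas()
    varpi_t = np.sqrt(varpi**2 - (alpha / 2) ** 2)
    t = touch06.t_f + np.linspace(0.0, 10e-3, 401)
    vphi, vphid = free_coefficients(touch06, t)
    for j in range(3):
        amp = np.sqrt(vphi[j] ** 2 + ((vphid[j] + alpha / 2 * vphi[j]) / varpi_t[j]) ** 2)
        slope = np.polyfit(t - touch06.t_f, np.log(amp), 1)[0]
        assert slope == pytest.approx(-alpha / 2.0, rel=0.01)


# ------------------------------------------------------------- field and loads

def test_rest_initial_condition_and_support_node(geom, touch_small, profile):
    x = np.linspace(geom.trunc, geom.L, 101)
    fld = displacement_field(touch_small, x, np.array([0.0, 3e-3]))
    assert np.abs(fld.y_total[0]).max() < 1e-9 * np.abs(fld.y_total[1]).max()
    # vibrational component vanishes at the pole for all contact times
    fld_c = displacement_field(touch_small, np.array([0.6 * geom.L]),
                               np.linspace(0.0, profile.t_f, 21))
    assert np.abs(fld_c.y_vib).max() < 1e-6 * np.abs(fld.y_vib[1]).max()


def test_onset_wave_travels_toward_base(geom, touch06):
    """Shortly after impact the peak of |y_e| moves from the pole to the base."""
    x = np.linspace(0.6 * geom.L, geom.L, 400)
    t_frames = np.array([0.05e-3, 0.1e-3, 0.15e-3, 0.2e-3])
    fld = displacement_field(touch06, x, t_frames)
    peaks = x[np.argmax(np.abs(fld.y_vib), axis=1)]
    assert np.all(np.diff(peaks) > 0)


def test_mode_count_convergence(geom, touch06):
    """Doubling retained modes 50 -> 100 moves peak |y_e| by < 0.1%."""
    x = np.linspace(geom.trunc, geom.L, 301)
    xh = x / geom.L
    X = np.stack([m.eval(xh) for m in touch06.contact_modes], axis=0) * geom.L**-1.5
    i_t = np.argmin(np.abs(touch06.t_contact - 1.0e-3))
    phi = touch06.phi[:, i_t]
    y50 = phi[:50] @ X[:50]
    y100 = phi @ X
    assert abs(np.abs(y100).max() - np.abs(y50).max()) < 1e-3 * np.abs(y100).max()


def test_follicle_signal_static_terms_and_ringdown(geom, touch06, profile):
    t = np.arange(0.0, 2 * profile.t_f, 10e-6)
    sig = follicle_signal(touch06, t)
    inc = t <= profile.t_f
    np.testing.assert_allclose(sig.V_static[inc], profile(t[inc]), rtol=1e-12)
    np.testing.assert_allclose(sig.M_static[inc],
                               profile(t[inc]) * (geom.L - 0.6 * geom.L), rtol=1e-12)
    assert np.all(sig.M_static[~inc] == 0.0)
    # vibrational part oscillates about zero during contact and rings down after
    crossings = np.sum(np.diff(np.sign(sig.M_vib[inc][50:])) != 0)
    assert crossings > 10
    late = np.abs(sig.M_vib[t > 1.8 * profile.t_f]).max()
    early_free = np.abs(sig.M_vib[(t > profile.t_f) & (t < 1.2 * profile.t_f)]).max()
    assert late < early_free  # damped ringdown


def test_adiabatic_limit_recovers_quasi_statics(geom, contact06):
    """A very slow force leaves only the quasi-static moment and shear."""
    slow = ForceProfile.gaussian_smooth(1e-6, t_f=1.0, tau=0.01)
    fast = ForceProfile.gaussian_smooth(1e-6)
    ratios = {}
    for name, prof in [("slow", slow), ("fast", fast)]:
        evol = simulate_touch(geom, contact06, prof, n_modes=10,
                              t_grid=np.linspace(0, prof.t_f, 201))
        sig = follicle_signal(evol, np.linspace(0.05 * prof.t_f, prof.t_f, 101))
        ratios[name] = np.abs(sig.V_vib).max() / np.abs(sig.V_static).max()
    assert ratios["slow"] < 1e-2
    assert ratios["slow"] < ratios["fast"] / 30.0


def test_linearity_in_force_amplitude(geom, contact06):
    t = np.linspace(0, 10e-3, 41)
    sigs = []
    for fmax in (1e-6, 2e-6):
        evol = simulate_touch(geom, contact06, ForceProfile.gaussian_smooth(fmax),
                              n_modes=10, t_grid=t)
        sigs.append(follicle_signal(evol, t))
    np.testing.assert_allclose(2 * sigs[0].M_vib[1:], sigs[1].M_vib[1:], rtol=1e-9)
    np.testing.assert_allclose(2 * sigs[0].V_total[1:], sigs[1].V_total[1:], rtol=1e-9)


# ------------------------------------------------------- method-of-lines oracle

def _newmark_vibrational_field(geom, contact, prof, snap_times, n_nodes=1500, dt=1e-6):
    """Independent finite-difference integration of the vibrational equation.

    Weak-form FD spatial operator with clamped base, free tip (natural) and a
    pinned contact node; Newmark average-acceleration stepping of
    mu ydd + alpha mu yd + (EI y'')'' = -mu (Fdd + alpha Fd) ytilde.
    """
    st = static_deflection(geom, contact, 1.0)
    cr, er = contact.c / geom.L, geom.ell_ratio
    n_left = int(round(n_nodes * (cr - er) / (1 - er)))
    xh = np.concatenate([np.linspace(er, cr, n_left + 1)[:-1],
                         np.linspace(cr, 1.0, n_nodes - n_left + 1)])
    x = xh * geom.L
    h = np.diff(x).mean()
    n = x.size
    rows, cols, vals = [], [], []
    for i in range(1, n - 1):
        for j, v in ((i - 1, 1.0), (i, -2.0), (i + 1, 1.0)):
            rows.append(i - 1); cols.append(j); vals.append(v / h**2)
    D2 = sp.csr_matrix((vals, (rows, cols)), shape=(n - 2, n))
    K = (D2.T @ sp.diags(geom.E * geom.area_moment(x[1:-1]) * h) @ D2).tocsc()
    M = sp.diags(geom.linear_density(x) * h).tocsc()
    ic = int(np.argmin(np.abs(xh - cr)))
    keep = np.setdiff1d(np.arange(n), [ic, n - 2, n - 1])
    K = K[np.ix_(keep, keep)]
    M = M[np.ix_(keep, keep)]
    C = geom.alpha * M
    yt = st.ytilde(x[keep])
    mu = geom.linear_density(x[keep])
    lu = splu((K + 2 / dt * C + 4 / dt**2 * M).tocsc())
    u = np.zeros(keep.size)
    v = np.zeros_like(u)
    acc = np.zeros_like(u)
    snaps = {}
    t = 0.0
    nt = int(round(max(snap_times) / dt))
    for _ in range(nt):
        t1 = t + dt
        f1 = -(mu * (prof(t1, 2) + geom.alpha * prof(t1, 1))) * yt * h
        rhs = f1 + M @ (4 / dt**2 * u + 4 / dt * v + acc) + C @ (2 / dt * u + v)
        u1 = lu.solve(rhs)
        acc1 = 4 / dt**2 * (u1 - u) - 4 / dt * v - acc
        v = v + dt / 2 * (acc + acc1)
        u, acc, t = u1, acc1, t1
        for stt in snap_times:
            if abs(t - stt) < dt / 2:
                snaps[stt] = u.copy()
    return x[keep], snaps


def test_method_of_lines_oracle(geom, contact06, profile, touch06):
    """Modal solution matches a direct FD integration to 2% of peak amplitude."""
    snap_times = [2e-3, 5e-3, 8e-3]
    x, snaps = _newmark_vibrational_field(geom, contact06, profile, snap_times)
    fld = displacement_field(touch06, x, np.array(snap_times))
    peak = np.abs(fld.y_vib).max()
    for i, stt in enumerate(snap_times):
        assert np.abs(fld.y_vib[i] - snaps[stt]).max() < 0.02 * peak
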