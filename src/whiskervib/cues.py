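"""Object-distance cue analyses built on the vibration solver.

Sweeps of contact position and truncation map out how the eigenfrequency
spectrum, the modal excitation pattern, and the vibrational-to-quasi-static
force ratios at the follicle depend on where along the whisker the pole is
touched — the two dynamic distance cues (frequency and relative vibration
magnitude), compared against the quasi-static axial-to-lateral force-angle
cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import follicle_signal, simulate_touch
from .eigen import BoundaryCase, find_eigenvalues, omega_from_beta
from .forcing import ForceProfile
from .geometry import ContactConfig, WhiskerGeometry
from .statics import axial_lateral_ratio, static_deflection

__all__ = [
    "SweepResult",
    "frequency_sweep",
    "truncation_sweep",
    "excitation_spectrum",
    "ratio_analysis",
    "rate_of_change_comparison",
]


@dataclass
class SweepResult:
    """Tidy sweep output: one row per grid point per mode/statistic."""

    sweep_variable: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path, **kw) -> None:
        self.data.to_csv(path, index=False, **kw)


def _contact_case(ell_ratio: float) -> BoundaryCase:
    return BoundaryCase.CONTACT_TRUNCATED if ell_ratio > 0 else BoundaryCase.CONTACT_FULL


def frequency_sweep(
    geom: WhiskerGeometry | None,
    c_grid: np.ndarray,
    n_modes: int = 5,
    ell_ratio: float | None = None,
) -> SweepResult:
    """Contact eigenfrequencies beta_j(c/L) over a grid of pole positions.

    The dimensionless curves depend only on the shape ratios l/L and c/L.
    If a geometry is supplied, dimensional angular frequencies are reported
    alongside.  The mode-1 curve is single-peaked; mode j has j peaks.
    """
    if ell_ratio is None:
        ell_ratio = geom.ell_ratio if geom is not None else 0.0
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(np.diff(c_grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    if np.any((c_grid <= ell_ratio) | (c_grid >= 1.0)):
        raise ValueError("contact grid must lie in (l/L, 1)")
    case = _contact_case(ell_ratio)
    rows = []
    for cr in c_grid:
        betas = find_eigenvalues(case, n_modes, ell_ratio, cr)
        for j, b in enumerate(betas, start=1):
            row = {"c_ratio": cr, "mode": j, "beta": b}
            if geom is not None:
                row["omega"] = omega_from_beta(geom, b)
            rows.append(row)
    meta = {"ell_ratio": ell_ratio, "case": case.value, "n_modes": n_modes}
    if geom is not None:
        meta["geometry"] = geom
    return SweepResult("c_ratio", pd.DataFrame(rows), meta)


def truncation_sweep(
    ell_grid: np.ndarray, c_ratio: float = 0.6, n_modes: int = 5
) -> SweepResult:
    """Contact eigenfrequencies beta_j(l/L) at fixed pole position.

    Truncation barely moves the first mode but increasingly shifts higher
    modes.  ``l/L = 0`` is solved as the full-length contact case.
    """
    ell_grid = np.asarray(ell_grid, dtype=float)
    if np.any(np.diff(ell_grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    if np.any((ell_grid < 0.0) | (ell_grid >= c_ratio)):
        raise ValueError("truncation grid must lie in [0, c/L)")
    rows = []
    for er in ell_grid:
        betas = find_eigenvalues(_contact_case(er), n_modes, er, c_ratio)
        for j, b in enumerate(betas, start=1):
            rows.append({"ell_ratio": er, "mode": j, "beta": b})
    return SweepResult("ell_ratio", pd.DataFrame(rows), {"c_ratio": c_ratio, "n_modes": n_modes})


def excitation_spectrum(
    geom: WhiskerGeometry,
    contact: ContactConfig,
    profile: ForceProfile,
    n_modes: int = 20,
    tau_values: np.ndarray | None = None,
    c_ratios: np.ndarray | None = None,
) -> SweepResult:
    """Peak modal excitation |phi_j| over the contact window, per mode.

    Optionally swept over the onset duration tau (at fixed contact) or over
    contact position (at fixed tau).  Amplitudes are reported raw and
    normalized to the strongest mode of each sweep point.
    """
    from .dynamics import contact_coefficients, modal_projection
    from .eigen import build_modes
    from .forcing import solve_gaussian_params

    rows = []
    mode_cache: dict = {}

    def one_point(cfg_contact, prof, label: dict):
        cr = cfg_contact.c / geom.L
        if cr not in mode_cache:
            modes = build_modes(_contact_case(geom.ell_ratio), n_modes, geom.ell_ratio, cr)
            P = modal_projection(static_deflection(geom, cfg_contact, 1.0), modes)
            mode_cache[cr] = (modes, P)
        modes, P = mode_cache[cr]
        # fine sampling so the peak of rapidly oscillating high modes is resolved
        t_fine = np.linspace(0.0, prof.t_f, 20001)
        phi, _ = contact_coefficients(modes, P, prof, t_fine, geom)
        amp = np.abs(phi).max(axis=1)
        ref = amp.max()
        for j, a in enumerate(amp, start=1):
            rows.append({**label, "mode": j, "amplitude": a, "normalized": a / ref})

    if tau_values is not None:
        for tau in np.asarray(tau_values, dtype=float):
            p = solve_gaussian_params(profile.F_max, profile.t_f, tau, profile.C)
            one_point(contact, p, {"tau": tau, "c_ratio": contact.c / geom.L})
        var = "tau"
    elif c_ratios is not None:
        for cr in np.asarray(c_ratios, dtype=float):
            one_point(ContactConfig.from_relative(geom, cr), profile,
                      {"tau": profile.tau, "c_ratio": cr})
        var = "c_ratio"
    else:
        one_point(contact, profile, {"tau": profile.tau, "c_ratio": contact.c / geom.L})
        var = "mode"
    return SweepResult(var, pd.DataFrame(rows), {"geometry": geom, "n_modes": n_modes})


def ratio_analysis(
    geom: WhiskerGeometry,
    profile: ForceProfile,
    c_grid: np.ndarray,
    n_modes: int = 100,
) -> SweepResult:
    """Vibrational-to-quasi-static force ratios at the follicle per contact point.

    "Average" is the time-average of |vibrational component| over the contact
    window divided by the time-average of |quasi-static component| (robust
    when the static part crosses zero); "maximum" is the ratio of the two
    peak magnitudes.  Both are force-amplitude invariant.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(np.diff(c_grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    rows = []
    for cr in c_grid:
        contact = ContactConfig.from_relative(geom, cr)
        evol = simulate_touch(geom, contact, profile, n_modes=n_modes)
        t_grid = np.arange(0.0, profile.t_f + 5e-6, 10e-6)
        sig = follicle_signal(evol, t_grid)
        rows.append({
            "c_ratio": cr,
            "shear_avg": np.mean(np.abs(sig.V_vib)) / np.mean(np.abs(sig.V_static)),
            "shear_max": np.max(np.abs(sig.V_vib)) / np.max(np.abs(sig.V_static)),
            "moment_avg": np.mean(np.abs(sig.M_vib)) / np.mean(np.abs(sig.M_static)),
            "moment_max": np.max(np.abs(sig.M_vib)) / np.max(np.abs(sig.M_static)),
        })
    meta = {"geometry": geom, "profile": profile, "n_modes": n_modes}
    return SweepResult("c_ratio", pd.DataFrame(rows), meta)


def rate_of_change_comparison(
    geom: WhiskerGeometry,
    c_grid: np.ndarray,
    ratio_normalization: str = "push_angle",
) -> SweepResult:
    """Relative rate of change (%/mm) of the two distance cues along the whisker.

    Compares the fundamental contact eigenfrequency omega_1(c) against the
    quasi-static axial-to-lateral force ratio, both as centered-difference
    percent change per millimeter of contact distance.

    ``ratio_normalization`` selects what is held fixed along the sweep for the
    force-ratio curve: ``"push_angle"`` (default) evaluates the force angle
    per unit base rotation toward the object, (L - c) |ytilde'(c)| / ytilde(c),
    which is how touches of equal push angle compare across distances;
    ``"unit_force"`` evaluates |ytilde'(c)| at equal applied force.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(np.diff(c_grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    if np.any((c_grid <= geom.trunc) | (c_grid >= geom.L)):
        raise ValueError("contact grid must lie inside (trunc, L)")
    case = _contact_case(geom.ell_ratio)
    omega1 = np.array([
        omega_from_beta(geom, find_eigenvalues(case, 1, geom.ell_ratio, c / geom.L)[0])
        for c in c_grid
    ])
    if ratio_normalization == "push_angle":
        fratio = np.empty_like(c_grid)
        for i, c in enumerate(c_grid):
            sol = static_deflection(geom, ContactConfig(c), 1.0)
            fratio[i] = (geom.L - c) * abs(sol.ytilde_slope(c)) / sol.ytilde(c)
    elif ratio_normalization == "unit_force":
        fratio = np.array([axial_lateral_ratio(geom, ContactConfig(c)) for c in c_grid])
    else:
        raise ValueError(f"unknown ratio_normalization: {ratio_normalization!r}")
    c_mm = c_grid * 1e3
    dom = np.gradient(omega1, c_mm)
    dfr = np.gradient(fratio, c_mm)
    df = pd.DataFrame({
        "c": c_grid,
        "distance_from_follicle_mm": (geom.L - c_grid) * 1e3,
        "omega1": omega1,
        "force_ratio": fratio,
        "freq_rate_pct_per_mm": 100.0 * np.abs(dom) / omega1,
        "force_ratio_rate_pct_per_mm": 100.0 * np.abs(dfr) / fratio,
    })
    return SweepResult("c", df, {"geometry": geom})
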