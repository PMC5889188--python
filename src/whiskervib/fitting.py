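"""Damped-oscillation fits of whisker vibration traces.

After a whisker slips off an object it rings down freely; the displacement
(or curvature change) at any fixed point follows

    f(t) = A sin( sqrt(omega^2 - (alpha/2)^2) t + phi ) exp(-alpha t / 2),

where ``omega`` is the undamped angular frequency of the dominant mode and
``alpha`` the viscous damping constant.  Fitting this model to slip-off
traces yields the material frequency and damping used throughout the
dynamics model, and — through the conical-beam eigenfrequency relation —
an estimate of the Young's modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import hilbert

from .eigen import young_modulus_from_frequency

__all__ = [
    "VibrationTrace",
    "DampedOscFit",
    "fit_damped_oscillation",
    "synth_vibration_trace",
    "estimate_modulus",
]


@dataclass
class VibrationTrace:
    """A sampled vibration trace: times (s) and displacement/curvature values."""

    t: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "VibrationTrace":
        df = pd.read_csv(path, comment="#")
        t, v = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
        return cls(t=t, v=v, meta={"source": str(path)})

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("time_s,displacement\n")
            for ti, vi in zip(self.t, self.v):
                fh.write(f"{ti:.9e},{vi:.9e}\n")


@dataclass
class DampedOscFit:
    """Fitted damped-sinusoid parameters with 0.95 confidence intervals."""

    A: float
    omega: float          # undamped angular frequency (rad/s)
    alpha: float          # damping constant (rad/s)
    phase: float          # phase at t = 0 (rad)
    ci: dict              # parameter -> (lo, hi), 0.95 level
    rss: float
    overdamped_flag: bool = False

    @property
    def omega_damped(self) -> float:
        return math.sqrt(max(self.omega**2 - (self.alpha / 2.0) ** 2, 0.0))

    @property
    def frequency_hz(self) -> float:
        return self.omega / (2.0 * math.pi)

    def model(self, t):
        t = np.asarray(t, dtype=float)
        return self.A * np.sin(self.omega_damped * t + self.phase) * np.exp(-self.alpha * t / 2.0)


def _model(t, A, om_t, alpha, phase):
    return A * np.sin(om_t * t + phase) * np.exp(-alpha * t / 2.0)


def _initial_guess(t, v):
    """Spectral peak for the frequency; log-envelope regression for damping."""
    dt = np.median(np.diff(t))
    tu = np.arange(t[0], t[-1], dt)
    vu = np.interp(tu, t, v)
    win = np.hanning(vu.size)
    spec = np.abs(np.fft.rfft(vu * win))
    freqs = np.fft.rfftfreq(vu.size, dt)
    k = int(np.argmax(spec[1:]) + 1)
    om_t = 2.0 * math.pi * freqs[k]
    env = np.abs(hilbert(vu))
    # discard edge artifacts of the analytic signal
    m = slice(vu.size // 10, -max(vu.size // 10, 1))
    good = env[m] > 1e-12 * env.max()
    x, y = tu[m][good], np.log(env[m][good])
    slope = np.polyfit(x, y, 1)[0] if x.size >= 2 else 0.0
    alpha0 = max(-2.0 * slope, 0.0)
    # amplitude/phase by linear projection at fixed (om_t, alpha)
    w = np.exp(-alpha0 * t / 2.0)
    B = np.column_stack([w * np.sin(om_t * t), w * np.cos(om_t * t)])
    p, q = np.linalg.lstsq(B, v, rcond=None)[0]
    A0 = math.hypot(p, q)
    phase0 = math.atan2(q, p)
    return A0, om_t, alpha0, phase0


def fit_damped_oscillation(
    trace: VibrationTrace, init: tuple | None = None
) -> DampedOscFit:
    """Least-squares fit of a damped sinusoid to a vibration trace.

    The internal parameterization is (A, omega_damped, alpha, phase); the
    reported undamped ``omega = sqrt(omega_damped^2 + (alpha/2)^2)`` with its
    confidence interval propagated by the delta method.  Confidence
    intervals are curvature-based (observed information at the optimum).
    """
    t, v = trace.t, trace.v
    if t.size < 16:
        raise ValueError("trace too short for a stable fit")
    if init is None:
        A0, om_t0, alpha0, phase0 = _initial_guess(t, v)
    else:
        A0, om0, alpha0, phase0 = init
        om_t0 = math.sqrt(max(om0**2 - (alpha0 / 2.0) ** 2, (0.1 * om0) ** 2))
    # sampling guard: >= 8 samples per expected period
    dt = np.max(np.diff(t))
    if om_t0 > 0 and dt > (2.0 * math.pi / om_t0) / 8.0:
        raise ValueError("sampling too sparse: need >= 8 samples per period")

    def resid(p):
        return _model(t, *p) - v

    res = least_squares(resid, x0=[A0, om_t0, alpha0, phase0], method="lm",
                        xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise RuntimeError(f"damped-oscillation fit did not converge: {res.message}")
    A, om_t, alpha, phase = res.x
    if A < 0:
        A, phase = -A, phase + math.pi
    phase = math.atan2(math.sin(phase), math.cos(phase))
    rss = float(2.0 * res.cost)

    ndat, npar = t.size, 4
    dof = max(ndat - npar, 1)
    s2 = rss / dof
    JTJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    zc = 1.959963984540054
    omega = math.sqrt(om_t**2 + (alpha / 2.0) ** 2)
    # delta method: omega = g(om_t, alpha)
    g = np.array([om_t / omega, alpha / (4.0 * omega)])
    sub = cov[np.ix_([1, 2], [1, 2])]
    se_omega = math.sqrt(max(g @ sub @ g, 0.0))
    ci = {
        "A": (A - zc * se[0], A + zc * se[0]),
        "omega": (omega - zc * se_omega, omega + zc * se_omega),
        "alpha": (alpha - zc * se[2], alpha + zc * se[2]),
        "phase": (phase - zc * se[3], phase + zc * se[3]),
    }
    return DampedOscFit(
        A=float(A), omega=float(omega), alpha=float(alpha), phase=float(phase),
        ci=ci, rss=rss, overdamped_flag=bool(omega <= alpha / 2.0),
    )


def synth_vibration_trace(
    A: float, omega: float, alpha: float, phase: float,
    duration: float, rate: float, noise_sd: float = 0.0, seed: int | None = None,
) -> VibrationTrace:
    """Synthetic damped-sinusoid trace with additive Gaussian noise.

    Deterministic for a given seed; provenance recorded in ``meta``.
    """
    if omega <= alpha / 2.0:
        raise ValueError("need an underdamped parameter set: omega > alpha/2")
    om_t = math.sqrt(omega**2 - (alpha / 2.0) ** 2)
    if rate < 8.0 * om_t / (2.0 * math.pi):
        raise ValueError("sampling rate below the 8-samples-per-period guard")
    t = np.arange(0.0, duration, 1.0 / rate)
    v = A * np.sin(om_t * t + phase) * np.exp(-alpha * t / 2.0)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=t.size)
    meta = {
        "provenance": "synthetic",
        "seed": seed,
        "params": {"A": A, "omega": omega, "alpha": alpha, "phase": phase},
        "noise_sd": noise_sd,
        "rate": rate,
    }
    return VibrationTrace(t=t, v=v, meta=meta)


def estimate_modulus(
    fit: DampedOscFit, L: float, R: float, rho: float, beta1: float | None = None
) -> dict:
    """Young's modulus from a fitted fundamental frequency.

    Delegates to the conical-beam eigenfrequency inversion (free full-length
    first root by default; pass the truncated-cone ``beta1`` to use that
    boundary case).  The CI on E follows from the quadratic map E ~ omega^2.
    """
    if fit.overdamped_flag:
        raise ValueError("fit is not underdamped; modulus estimate undefined")
    E = young_modulus_from_frequency(L, R, rho, fit.omega, beta1)
    lo, hi = fit.ci["omega"]
    ci_E = (
        young_modulus_from_frequency(L, R, rho, max(lo, 1e-12), beta1),
        young_modulus_from_frequency(L, R, rho, hi, beta1),
    )
    return {
        "E": E,
        "E_ci": ci_E,
        "frequency_hz": fit.frequency_hz,
        "omega": fit.omega,
    }
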