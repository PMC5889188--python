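"""Composite Gauss-Legendre quadrature on the whisker axis.

The closed-form eigenmodes oscillate with phase ``2*sqrt(beta * x/L)``, i.e.
uniformly in ``sqrt(x)``.  All mode integrals (normalization, orthogonality,
modal projections) therefore use a composite Gauss grid that is uniform in
``sqrt(x/L)``, with panel density set by the largest dimensionless root in
play and a forced panel break at the contact point, where the quasi-static
deflection has a slope kink.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cone_grid"]

_GAUSS_PTS = 10


def _panels(t_lo: float, t_hi: float, n: int) -> np.ndarray:
    return np.linspace(t_lo, t_hi, n + 1)


def cone_grid(
    ell_ratio: float,
    c_ratio: float | None,
    beta_max: float,
    min_panels: int = 24,
    phase_per_panel: float = 1.0,
):
    """Quadrature nodes/weights for integrals ``int_{l/L}^{1} f(xhat) dxhat``.

    Parameters
    ----------
    ell_ratio : float
        Relative truncation l/L (lower integration limit).
    c_ratio : float or None
        Relative contact position; if given, a panel edge is placed exactly
        at ``xhat = c_ratio``.
    beta_max : float
        Largest dimensionless eigenvalue whose mode must be resolved.
    """
    t_lo = np.sqrt(max(ell_ratio, 0.0))
    total_phase = 2.0 * np.sqrt(max(beta_max, 1.0)) * (1.0 - t_lo)
    n_total = max(min_panels, int(np.ceil(total_phase / phase_per_panel)))

    if c_ratio is not None and ell_ratio < c_ratio < 1.0:
        t_c = np.sqrt(c_ratio)
        frac = (t_c - t_lo) / (1.0 - t_lo)
        n_left = max(4, int(np.ceil(frac * n_total)))
        n_right = max(4, int(np.ceil((1.0 - frac) * n_total)))
        edges = np.concatenate([_panels(t_lo, t_c, n_left)[:-1], _panels(t_c, 1.0, n_right)])
    else:
        edges = _panels(t_lo, 1.0, n_total)

    gp, gw = np.polynomial.legendre.leggauss(_GAUSS_PTS)
    a = edges[:-1][:, None]
    b = edges[1:][:, None]
    t = (0.5 * (b - a) * gp[None, :] + 0.5 * (b + a)).ravel()
    wt = (0.5 * (b - a) * gw[None, :]).ravel()
    # substitution xhat = t^2 : dxhat = 2 t dt
    xhat = t**2
    w = 2.0 * t * wt
    return xhat, w
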