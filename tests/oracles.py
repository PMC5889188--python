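"""Independent numerical oracles shared by the test modules.

These deliberately avoid the package's scaled-Bessel machinery: the
high-precision oracle evaluates the unscaled boundary determinant with
40-digit arithmetic; the finite-difference oracle discretizes the weighted
eigenvalue problem directly.
"""

import mpmath as mp
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh


def mp_contact_truncated_det(beta, ell_ratio, c_ratio):
    """Unscaled 8x8 contact-case boundary determinant in 40-digit arithmetic."""
    mp.mp.dps = 40
    b = mp.mpf(beta)
    sqb = 2 * mp.sqrt(b)
    sqg = 2 * mp.sqrt(b * mp.mpf(ell_ratio))
    sqe = 2 * mp.sqrt(b * mp.mpf(c_ratio))

    def row(kind, x):
        J = lambda n: mp.besselj(n, x)
        Y = lambda n: mp.bessely(n, x)
        I = lambda n: mp.besseli(n, x)
        K = lambda n: mp.besselk(n, x)
        if kind == "val":
            return [J(2), Y(2), I(2), K(2)]
        if kind == "slope":
            return [-J(3), -Y(3), I(3), -K(3)]
        if kind == "mom":
            return [J(4), Y(4), I(4), K(4)]
        if kind == "shear":
            return [J(3), Y(3), I(3), -K(3)]
        raise ValueError(kind)

    Z = [mp.mpf(0)] * 4
    M = mp.matrix([
        Z + row("val", sqb),
        Z + row("slope", sqb),
        row("val", sqe) + Z,
        Z + row("val", sqe),
        row("slope", sqe) + [-v for v in row("slope", sqe)],
        row("mom", sqe) + [-v for v in row("mom", sqe)],
        row("mom", sqg) + Z,
        row("shear", sqg) + Z,
    ])
    return mp.det(M)


def mp_bisect_root(beta_lo, beta_hi, ell_ratio, c_ratio, tol=1e-10):
    """Bisection of the high-precision determinant to a verified root."""
    f_lo = mp_contact_truncated_det(beta_lo, ell_ratio, c_ratio)
    f_hi = mp_contact_truncated_det(beta_hi, ell_ratio, c_ratio)
    assert f_lo * f_hi < 0
    while beta_hi - beta_lo > tol * beta_lo:
        mid = 0.5 * (beta_lo + beta_hi)
        f_mid = mp_contact_truncated_det(mid, ell_ratio, c_ratio)
        if f_lo * f_mid <= 0:
            beta_hi = mid
        else:
            beta_lo, f_lo = mid, f_mid
    return 0.5 * (beta_lo + beta_hi)


def fd_contact_eigenvalues(ell_ratio, c_ratio, n_nodes=2000, k=5):
    """Finite-difference discretization of the weighted eigenproblem.

    Weak form of (x^4 X'')'' = lambda x^2 X on [l/L, 1] with clamped base,
    free tip (natural) and a simple support at c; returns lambda = beta^2.
    """
    n_left = int(round(n_nodes * (c_ratio - ell_ratio) / (1.0 - ell_ratio)))
    x = np.concatenate([
        np.linspace(ell_ratio, c_ratio, n_left + 1)[:-1],
        np.linspace(c_ratio, 1.0, n_nodes - n_left + 1),
    ])
    h = np.diff(x).mean()
    n = x.size
    rows, cols, vals = [], [], []
    for i in range(1, n - 1):
        for j, v in ((i - 1, 1.0), (i, -2.0), (i + 1, 1.0)):
            rows.append(i - 1); cols.append(j); vals.append(v / h**2)
    D2 = sp.csr_matrix((vals, (rows, cols)), shape=(n - 2, n))
    W = sp.diags(x[1:-1] ** 4 * h)
    K = (D2.T @ W @ D2).tocsc()
    M = sp.diags(x**2 * h).tocsc()
    ic = int(np.argmin(np.abs(x - c_ratio)))
    keep = np.setdiff1d(np.arange(n), [ic, n - 2, n - 1])
    K = K[np.ix_(keep, keep)]
    M = M[np.ix_(keep, keep)]
    vals = eigsh(K, k=k, M=M, sigma=0.0, which="LM", return_eigenvectors=False)
    return np.sort(vals)
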