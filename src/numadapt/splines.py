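"""Spherical-spline basis shared by channel interpolation and the surface
Laplacian.

Both operations rest on the same construction (Perrin-style spherical
splines): scalp potential is expanded in the kernel

    g(x) = 1/(4*pi) * sum_{n=1..N} (2n+1) / (n (n+1))**m * P_n(x)

evaluated at x = cos(angle between electrodes), with spline flexibility
``m`` and Legendre truncation ``N``.  The surface Laplacian uses the
companion kernel ``h`` with exponent ``m - 1``.  Fitting solves the
regularized interpolation system with the usual zero-sum constraint on the
spline coefficients, so a spatially constant potential maps to exactly zero
Laplacian.

Defaults: m = 4, regularization lambda = 1e-5, N = 50 Legendre terms.
Laplacian output is in arbitrary units (unit sphere radius; no head-radius
scaling), which is immaterial for the phase-based connectivity downstream.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

from .montage import Montage

__all__ = [
    "SplineParams",
    "g_kernel",
    "h_kernel",
    "laplacian_operator",
    "interpolation_weights",
]

# Spline constants (flexibility, ridge term, series truncation)
DEFAULT_M = 4
DEFAULT_LAMBDA = 1e-5
DEFAULT_NTERMS = 50


def _kernel(x: np.ndarray, exponent: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** exponent / (4 * np.pi)
    return legendre.legval(np.asarray(x, dtype=float), coeffs)


def g_kernel(x: np.ndarray, m: int = DEFAULT_M, n_terms: int = DEFAULT_NTERMS) -> np.ndarray:
    """Interpolation kernel g(cos angle)."""
    return _kernel(x, m, n_terms)


def h_kernel(x: np.ndarray, m: int = DEFAULT_M, n_terms: int = DEFAULT_NTERMS) -> np.ndarray:
    """Laplacian kernel h(cos angle) (exponent m - 1)."""
    return _kernel(x, m - 1, n_terms)


def _solve_operators(
    cosmat: np.ndarray, lam: float, m: int, n_terms: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (C_op, c0_op): spline coefficients c = C_op @ V, offset c0 = c0_op @ V.

    Solves the augmented system
        [[G + lam*I, 1], [1^T, 0]] [c; c0] = [V; 0]
    which enforces sum(c) = 0.
    """
    n = cosmat.shape[0]
    G = g_kernel(cosmat, m, n_terms)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate montage
        raise ValueError("singular spline system (degenerate electrode layout)") from err
    return Ainv[:n, :n], Ainv[n, :n]


def _check_positions(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    cosmat = np.clip(pos @ pos.T, -1.0, 1.0)
    off = cosmat[~np.eye(len(pos), dtype=bool)]
    if np.any(off > 1.0 - 1e-12):
        raise ValueError("duplicate sensor positions in montage")
    return cosmat


def laplacian_operator(
    montage: Montage,
    m: int = DEFAULT_M,
    lam: float = DEFAULT_LAMBDA,
    n_terms: int = DEFAULT_NTERMS,
) -> np.ndarray:
    """(n, n) matrix mapping channel data to its surface Laplacian.

    Linear in the input by construction; annihilates spatially constant
    fields exactly (the constant is absorbed by the constraint offset).
    """
    cosmat = _check_positions(montage.positions)
    C_op, _ = _solve_operators(cosmat, lam, m, n_terms)
    H = h_kernel(cosmat, m, n_terms)
    # CSD sign convention: sources (local maxima) positive.
    return -H @ C_op


def interpolation_weights(
    montage: Montage,
    good_idx: np.ndarray,
    bad_idx: np.ndarray,
    m: int = DEFAULT_M,
    lam: float = DEFAULT_LAMBDA,
    n_terms: int = DEFAULT_NTERMS,
) -> np.ndarray:
    """(n_bad, n_good) weights reconstructing bad channels from good ones."""
    good_idx = np.asarray(good_idx, dtype=int)
    bad_idx = np.asarray(bad_idx, dtype=int)
    pos = montage.positions
    cos_good = _check_positions(pos[good_idx])
    C_op, c0_op = _solve_operators(cos_good, lam, m, n_terms)
    cos_bad_good = np.clip(pos[bad_idx] @ pos[good_idx].T, -1.0, 1.0)
    G_bg = g_kernel(cos_bad_good, m, n_terms)
    return G_bg @ C_op + np.ones((len(bad_idx), 1)) * c0_op
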