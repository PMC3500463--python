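"""Spherical-spline surface Laplacian of scalp potentials.

Implements the classical spherical-spline estimate: the potential is
expanded in a spline basis g(cos gamma) built from a truncated Legendre
series, the expansion coefficients are obtained from a regularized linear
solve with a zero-sum constraint, and the surface Laplacian follows by
applying the Laplace-Beltrami operator degree-wise (each spherical-harmonic
degree l is an eigenfunction with eigenvalue -l(l+1)/r^2).

The returned quantity is the surface Laplacian of the potential in
uV/m^2 (note: current source density as usually plotted is its negative).
The transform is linear and reference-free: adding a constant to all
channels leaves the output unchanged, and a spatially constant potential
maps to zero.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import legval


class SingularGeometryError(ValueError):
    """Electrode geometry does not admit a spline solution."""


def _legendre_factors(stiffness: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    return (2 * n + 1) / (n * (n + 1)) ** stiffness / (4 * np.pi)


def _calc_g(cosang: np.ndarray, stiffness: int, n_terms: int) -> np.ndarray:
    return legval(cosang, np.concatenate([[0.0], _legendre_factors(stiffness, n_terms)]))


def _calc_h(cosang: np.ndarray, stiffness: int, n_terms: int) -> np.ndarray:
    # one power of l(l+1) fewer: the Laplace-Beltrami eigenvalues applied
    # degree-wise to the spline basis (up to the -1/r^2 factor)
    return legval(cosang, np.concatenate([[0.0], _legendre_factors(stiffness - 1, n_terms)]))


def laplacian_transform(
    positions: np.ndarray,
    stiffness: int = 4,
    lambda2: float = 1e-5,
    n_legendre: int = 50,
    head_radius_m: float = 0.095,
) -> np.ndarray:
    """Precompute the (n_channels, n_channels) linear map potential -> surface
    Laplacian for a fixed electrode set on the unit sphere.

    Parameters
    ----------
    positions : (n, 3) unit-norm electrode coordinates.
    stiffness : spline order m (4 is the common default).
    lambda2 : Tikhonov regularization added to the spline Gram matrix.
    n_legendre : truncation degree of the Legendre expansions.
    head_radius_m : physical sphere radius; output scales as 1/r^2.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be (n_channels, 3)")
    n = pos.shape[0]
    if n < 16:
        raise ValueError(f"need >= 16 electrodes for a stable spline fit, got {n}")
    norms = np.linalg.norm(pos, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("electrode positions must lie on the unit sphere")
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    off = cosang[~np.eye(n, dtype=bool)]
    if np.any(off > 1.0 - 1e-10):
        raise SingularGeometryError("duplicate electrode positions")

    G = _calc_g(cosang, stiffness, n_legendre)
    H = _calc_h(cosang, stiffness, n_legendre)
    G_reg = G + lambda2 * np.eye(n)
    G_inv = np.linalg.inv(G_reg)
    TC = G_inv.sum(axis=0)
    sgi = TC.sum()
    if abs(sgi) < 1e-300:
        raise SingularGeometryError("degenerate spline system (zero constraint norm)")
    # coefficient solve with the zero-sum constraint folded in:
    # c(v) = G_inv (v - 1 c0),  c0 = (TC . v)/sgi  =>  linear map C
    C = G_inv - np.outer(TC, TC) / sgi
    # surface Laplacian = -(1/r^2) * H C  (Laplace-Beltrami applied to the fit)
    return -(H @ C) / head_radius_m**2


def spline_laplacian(
    data: np.ndarray,
    positions: np.ndarray,
    stiffness: int = 4,
    lambda2: float = 1e-5,
    n_legendre: int = 50,
    head_radius_m: float = 0.095,
) -> np.ndarray:
    """Apply the spherical-spline surface Laplacian along the channel axis.

    ``data`` may be (n_channels, n_times) or (n_trials, n_channels,
    n_times); channels must match ``positions`` row order. Returns the same
    shape in uV/m^2 (for uV input and metres radius).
    """
    L = laplacian_transform(positions, stiffness, lambda2, n_legendre, head_radius_m)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        return L @ arr
    if arr.ndim == 3:
        return np.einsum("ij,tjk->tik", L, arr)
    raise ValueError("data must be 2-D or 3-D")
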