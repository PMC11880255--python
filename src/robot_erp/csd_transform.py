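"""Reference-free current-source-density (surface Laplacian) transform.

Spherical-spline formulation: scalp potential is fitted as
v(x) = c0 + sum_i c_i g(cos(x, x_i)) with
g(t) = (1/4pi) sum_n (2n+1) / (n (n+1))^m P_n(t),
and the CSD is the negated surface Laplacian of the fitted spline,
CSD(x) = sum_i c_i h(cos(x, x_i)) / r^2 with
h(t) = (1/4pi) sum_n (2n+1) / (n (n+1))^(m-1) P_n(t),
using the spherical harmonic identity Lap P_n = -n(n+1) P_n. Positive CSD
marks a current source (focal potential maximum), negative a sink.

Constants m=4, 50 Legendre terms, lambda=1e-5 regularization and unit head
radius are the de-facto standard defaults of the spline-Laplacian
literature; the physical head radius only scales the output, and all
downstream statistics and classifiers are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from robot_erp.montage_io import EpochSet, Montage


def g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spline kernel g evaluated at an array of cosines."""
    n = np.arange(1, n_terms + 1)
    w = (2 * n + 1) / (n * (n + 1.0)) ** m / (4 * np.pi)
    return _legendre_series(cosang, w)


def h_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Laplacian kernel h (g with stiffness m-1 weights)."""
    n = np.arange(1, n_terms + 1)
    w = (2 * n + 1) / (n * (n + 1.0)) ** (m - 1) / (4 * np.pi)
    return _legendre_series(cosang, w)


def _legendre_series(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for i, w in enumerate(weights, start=1):
        out += w * eval_legendre(i, x)
    return out


@dataclass
class SplineBasis:
    G: np.ndarray
    H: np.ndarray
    m: int
    n_terms: int
    lam: float
    head_radius: float
    channels: list[str]
    transform: np.ndarray  # precomputed CSD matrix: csd = transform @ v

    @property
    def n_channels(self) -> int:
        return self.G.shape[0]


def build_spline_basis(montage: Montage, m: int = 4, n_terms: int = 50,
                       lam: float = 1e-5,
                       head_radius: float = 1.0) -> SplineBasis:
    """Evaluate the g/h kernels on all electrode pairs and factorize the
    regularized, sum-to-zero-constrained spline system once.

    The per-sample solve [[G + lam I, 1], [1', 0]] [c; mu] = [v; 0] is
    linear, so the full CSD map is one precomputed matrix applied to every
    time sample; results are identical to per-sample solves.
    """
    if m < 2:
        raise ValueError("stiffness m must be >= 2")
    if n_terms < 20:
        raise ValueError("need at least 20 Legendre terms")
    cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    off = ~np.eye(montage.n_channels, dtype=bool)
    if np.any(cosang[off] > 1 - 1e-12):
        raise ValueError("coincident electrodes in montage")
    G = g_matrix(cosang, m=m, n_terms=n_terms)
    H = h_matrix(cosang, m=m, n_terms=n_terms)
    n = montage.n_channels
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular spline system (condition number {cond:.3g})"
        )
    Ainv = np.linalg.inv(A)
    # c = Ainv[:n, :n] @ v  (the rhs constant entry is zero)
    transform = (H @ Ainv[:n, :n]) / head_radius**2
    return SplineBasis(G=G, H=H, m=m, n_terms=n_terms, lam=lam,
                       head_radius=head_radius, channels=list(montage.labels),
                       transform=transform)


def csd_matrix_apply(basis: SplineBasis, data: np.ndarray) -> np.ndarray:
    """Apply the CSD transform along the channel axis (axis -2 of an
    (..., channels, time) array)."""
    return np.einsum("ij,...jt->...it", basis.transform, data)


def csd(epochs: EpochSet, basis: SplineBasis) -> EpochSet:
    """CSD-transform an epoch set of scalp potentials."""
    if epochs.unit != "potential_uV":
        raise ValueError("csd expects potential_uV input")
    if epochs.channels and list(epochs.channels) != list(basis.channels):
        raise ValueError("channel order does not match the spline basis")
    if epochs.n_channels != basis.n_channels:
        raise ValueError("channel count does not match the spline basis")
    return epochs.copy_with(data=csd_matrix_apply(basis, epochs.data),
                            unit="csd")


def csd_values(basis_montage: Montage, coefficients: np.ndarray,
               const: float, points: np.ndarray, m: int = 4,
               n_terms: int = 50) -> np.ndarray:
    """Evaluate the fitted spline potential at arbitrary unit-sphere points
    (used by validation oracles)."""
    cosang = np.clip(points @ basis_montage.positions.T, -1.0, 1.0)
    return g_matrix(cosang, m=m, n_terms=n_terms) @ coefficients + const


def fit_spline_coefficients(basis: SplineBasis,
                            v: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the constrained spline system for one potential vector,
    returning (coefficients, constant term)."""
    n = basis.n_channels
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = basis.G + basis.lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[:n] = v
    sol = np.linalg.solve(A, rhs)
    return sol[:n], float(sol[n])
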