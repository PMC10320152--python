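"""Matérn-family covariance kernels.

The stationary Matérn family with smoothness ``nu``, length scale ``kappa``
and variance ``sigma2`` covers the four closed-form subfamilies used in
practice: ``nu = 1/2`` (Exponential), ``3/2`` (Matern32), ``5/2`` (Matern52)
and the ``nu -> inf`` limit (RBF, also called squared-exponential). Only
these four are implemented; the general-``nu`` Bessel-function form is out
of scope.

The length scale is isotropic: distances are plain Euclidean norms on the
normalized unit-cube inputs, so a single ``kappa`` is shared across
dimensions. Hyperparameters are handled in log-space throughout the
package, hence gradients are reported with respect to ``log kappa`` and
``log sigma2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAMILIES",
    "KernelSpec",
    "kernel_value",
    "kernel_matrix",
    "kernel_gradients",
]

FAMILIES = ("Exponential", "Matern32", "Matern52", "RBF")

# below this distance the kernel is exactly sigma2; avoids 0*inf in the
# Matern32/52 forms and spurious negative values from cancellation
_U_FLOOR = 1e-12

_SQRT3 = np.sqrt(3.0)
_SQRT5 = np.sqrt(5.0)


@dataclass(frozen=True)
class KernelSpec:
    """One Matérn-subfamily prior: family name, length scale, variance."""

    family: str
    length_scale: float = 1.0
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (np.isfinite(self.length_scale) and self.length_scale > 0):
            raise ValueError(f"length_scale must be positive, got {self.length_scale}")
        if not (np.isfinite(self.variance) and self.variance > 0):
            raise ValueError(f"variance must be positive, got {self.variance}")


def _correlation(family: str, u: np.ndarray, kappa: float) -> np.ndarray:
    """Correlation k/sigma2 as a function of Euclidean distance u >= 0."""
    if family == "Exponential":
        return np.exp(-u / kappa)
    if family == "Matern32":
        a = _SQRT3 * u / kappa
        return (1.0 + a) * np.exp(-a)
    if family == "Matern52":
        a = _SQRT5 * u / kappa
        return (1.0 + a + a * a / 3.0) * np.exp(-a)
    # RBF
    return np.exp(-0.5 * (u / kappa) ** 2)


def _correlation_dlogkappa(family: str, u: np.ndarray, kappa: float) -> np.ndarray:
    """d(correlation)/d(log kappa), closed form per subfamily."""
    if family == "Exponential":
        a = u / kappa
        return a * np.exp(-a)
    if family == "Matern32":
        a = _SQRT3 * u / kappa
        return a * a * np.exp(-a)
    if family == "Matern52":
        a = _SQRT5 * u / kappa
        return (a * a * (1.0 + a) / 3.0) * np.exp(-a)
    a2 = (u / kappa) ** 2
    return a2 * np.exp(-0.5 * a2)


def _check_points(t: np.ndarray, t2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t.shape != t2.shape:
        raise ValueError(f"dimension mismatch: {t.shape} vs {t2.shape}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(t2))):
        raise ValueError("points must have finite coordinates")
    return t, t2


def kernel_value(spec: KernelSpec, t, t2) -> float:
    """Evaluate the kernel at a pair of points.

    Returns ``sigma2 * correlation(||t - t2||)``; at coincident points the
    value is exactly ``sigma2``.
    """
    t, t2 = _check_points(t, t2)
    u = float(np.linalg.norm(t - t2))
    if u < _U_FLOOR:
        return spec.variance
    return float(spec.variance * _correlation(spec.family, np.asarray(u), spec.length_scale))


def kernel_matrix(spec: KernelSpec, A, B) -> np.ndarray:
    """Cross-covariance matrix ``K[i, j] = k(A[i], B[j])``.

    ``kernel_matrix(spec, A, A)`` is symmetric positive semidefinite.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimension mismatch: points of dim {A.shape[1]} vs {B.shape[1]}"
        )
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("points must have finite coordinates")
    diff = A[:, None, :] - B[None, :, :]
    u = np.sqrt(np.maximum(np.einsum("ijk,ijk->ij", diff, diff), 0.0))
    K = spec.variance * _correlation(spec.family, u, spec.length_scale)
    K[u < _U_FLOOR] = spec.variance
    return K


def kernel_matrix_dlogkappa(spec: KernelSpec, A, B) -> np.ndarray:
    """Elementwise derivative of `kernel_matrix` w.r.t. ``log kappa``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    diff = A[:, None, :] - B[None, :, :]
    u = np.sqrt(np.maximum(np.einsum("ijk,ijk->ij", diff, diff), 0.0))
    G = spec.variance * _correlation_dlogkappa(spec.family, u, spec.length_scale)
    G[u < _U_FLOOR] = 0.0
    return G


def kernel_gradients(spec: KernelSpec, t, t2) -> tuple[float, float]:
    """Gradients of `kernel_value` w.r.t. ``(log kappa, log sigma2)``.

    Since the kernel is linear in ``sigma2``, the second component equals
    the kernel value itself. At coincident points the kappa-gradient is 0.
    """
    t, t2 = _check_points(t, t2)
    u = float(np.linalg.norm(t - t2))
    k = kernel_value(spec, t, t2)
    if u < _U_FLOOR:
        return 0.0, k
    dk_dlogkappa = float(
        spec.variance * _correlation_dlogkappa(spec.family, np.asarray(u), spec.length_scale)
    )
    return dk_dlogkappa, k
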