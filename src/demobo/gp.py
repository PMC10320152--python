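"""Zero-mean Gaussian-process regression.

Implements the standard exact-GP workflow used as the surrogate model in
Bayesian optimization:

* hyperparameters ``(kappa, sigma2, sigma_eps2)`` fitted by maximizing the
  log marginal likelihood with multi-start quasi-Newton ascent in
  log-space,
* a single Cholesky factorization of ``K + sigma_eps2*I`` (the O(n^3)
  step) reused for all predictions,
* closed-form posterior mean ``K_qt (K + sigma_eps2 I)^-1 y`` and variance
  ``k(q,q) - K_qt (K + sigma_eps2 I)^-1 K_tq``.

Observations are centered and scaled before fitting; the transform is
recorded on the fitted model and undone at prediction time. The prior mean
is fixed at zero on the standardized scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .kernels import (
    FAMILIES,
    KernelSpec,
    _correlation,
    _correlation_dlogkappa,
    kernel_matrix,
)

__all__ = [
    "NumericalError",
    "TrainingSet",
    "GPHyperparameters",
    "FittedGP",
    "PosteriorPrediction",
    "standardize_observations",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "factorize",
    "predict",
    "predict_batch",
]

# log-space box constraints for hyperparameter search (normalized inputs,
# standardized observations)
LOG_KAPPA_BOUNDS = (math.log(1e-3), math.log(1e3))
LOG_SIGMA2_BOUNDS = (math.log(1e-4), math.log(1e4))
LOG_NOISE_BOUNDS = (math.log(1e-8), math.log(1e-1))

_JITTER_START = 1e-8
_JITTER_MAX = 1e-2


class NumericalError(RuntimeError):
    """Raised when linear algebra fails beyond recoverable jitter."""


@dataclass(frozen=True)
class TrainingSet:
    """Evaluation inputs in the normalized unit cube with observed values."""

    inputs: np.ndarray
    observations: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        y = np.asarray(self.observations, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"{X.shape[0]} inputs but {y.shape[0]} observations"
            )
        if X.shape[0] < 1:
            raise ValueError("at least one training point is required")
        if not np.all(np.isfinite(X)):
            raise ValueError("training inputs must be finite")
        if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
            raise ValueError("training inputs must lie in the unit cube")
        if not np.all(np.isfinite(y)):
            raise ValueError("observations must be finite")
        object.__setattr__(self, "inputs", X)
        object.__setattr__(self, "observations", y)

    @property
    def n(self) -> int:
        return self.inputs.shape[0]

    @property
    def d(self) -> int:
        return self.inputs.shape[1]


@dataclass(frozen=True)
class GPHyperparameters:
    kernel: KernelSpec
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.noise_variance) and self.noise_variance >= 0):
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")


@dataclass(frozen=True)
class PosteriorPrediction:
    mean: float
    variance: float


@dataclass(frozen=True)
class FittedGP:
    """Training data plus the Cholesky machinery for posterior prediction."""

    training: TrainingSet
    hyper: GPHyperparameters
    chol: np.ndarray
    alpha: np.ndarray
    jitter: float
    standardization: tuple[float, float] = (0.0, 1.0)

    @property
    def n(self) -> int:
        return self.training.n

    @property
    def d(self) -> int:
        return self.training.d


def standardize_observations(y) -> tuple[np.ndarray, float, float]:
    """Center by the mean and scale by the sample standard deviation
    (ddof=1), so the output has unit sample SD when non-constant.

    Falls back to scale 1 for a single observation or (numerically)
    constant data, so the transform is always invertible.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least one observation")
    center = float(np.mean(y))
    if y.size == 1:
        return np.zeros(1), center, 1.0
    var = float(np.sum((y - center) ** 2) / (y.size - 1))
    if var < 1e-12:
        return np.zeros_like(y), center, 1.0
    scale = math.sqrt(var)
    return (y - center) / scale, center, scale


def _cholesky_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K, escalating diagonal jitter on failure."""
    mean_diag = float(np.mean(np.diag(K)))
    jitter = 0.0
    for _ in range(8):
        try:
            L = cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except LinAlgError:
            jitter = _JITTER_START * mean_diag if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX * mean_diag:
                break
    raise NumericalError(
        f"Cholesky factorization failed for n={K.shape[0]} even with jitter "
        f"{jitter:.2e} (mean diagonal {mean_diag:.3e})"
    )


def _gram(train: TrainingSet, hyper: GPHyperparameters) -> np.ndarray:
    K = kernel_matrix(hyper.kernel, train.inputs, train.inputs)
    return K + hyper.noise_variance * np.eye(train.n)


def log_marginal_likelihood(train: TrainingSet, hyper: GPHyperparameters) -> float:
    """log p(y) = -1/2 y^T (K + s2 I)^-1 y - 1/2 log|K + s2 I| - n/2 log 2pi."""
    y = train.observations
    L, _ = _cholesky_with_jitter(_gram(train, hyper))
    z = solve_triangular(L, y, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-0.5 * z @ z - 0.5 * logdet - 0.5 * train.n * math.log(2 * math.pi))


def _make_nll_and_grad(train: TrainingSet, family: str):
    """Build the negative-LML objective with gradients w.r.t. the
    log-hyperparameters, caching the pairwise distance matrix across
    evaluations (the training inputs do not change during one fit)."""
    X = train.inputs
    y = train.observations
    n = train.n
    diff = X[:, None, :] - X[None, :, :]
    u = np.sqrt(np.maximum(np.einsum("ijk,ijk->ij", diff, diff), 0.0))
    eye = np.eye(n)

    def nll_and_grad(x: np.ndarray):
        log_kappa, log_sigma2, log_noise = x
        kappa, sigma2, noise = math.exp(log_kappa), math.exp(log_sigma2), math.exp(log_noise)
        Kk = sigma2 * _correlation(family, u, kappa)
        L, _ = _cholesky_with_jitter(Kk + noise * eye)
        alpha = cho_solve((L, True), y)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        nll = 0.5 * float(y @ alpha) + 0.5 * logdet + 0.5 * n * math.log(2 * math.pi)
        # d(LML)/dtheta = 1/2 tr((alpha alpha^T - K^-1) dK/dtheta)
        Kinv = cho_solve((L, True), eye)
        W = np.outer(alpha, alpha) - Kinv
        dK_dlogkappa = sigma2 * _correlation_dlogkappa(family, u, kappa)
        g_kappa = 0.5 * float(np.sum(W * dK_dlogkappa))
        g_sigma2 = 0.5 * float(np.sum(W * Kk))
        g_noise = 0.5 * noise * float(np.trace(W))
        return nll, -np.array([g_kappa, g_sigma2, g_noise])

    return nll_and_grad


def fit_hyperparameters(
    train: TrainingSet,
    family: str,
    n_restarts: int = 10,
    rng: np.random.Generator | None = None,
) -> GPHyperparameters:
    """Maximize the log marginal likelihood with multiple restarts.

    One start is a fixed heuristic (length scale 0.3, unit variance, small
    noise); the remaining ``n_restarts`` starts are log-uniform in the
    search box. Returns the best outcome across all starts.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown kernel family {family!r}")
    if train.n < 2:
        raise ValueError("hyperparameter fitting requires n >= 2")
    rng = np.random.default_rng(0) if rng is None else rng

    bounds = [LOG_KAPPA_BOUNDS, LOG_SIGMA2_BOUNDS, LOG_NOISE_BOUNDS]
    starts = [np.array([math.log(0.3), 0.0, math.log(1e-4)])]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(n_restarts):
        starts.append(lo + rng.random(3) * (hi - lo))

    objective = _make_nll_and_grad(train, family)
    best_x, best_nll = None, np.inf
    n_failed = 0
    for x0 in starts:
        try:
            res = minimize(
                objective,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
            )
        except NumericalError:
            n_failed += 1
            continue
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_x = res.fun, res.x
    if best_x is None:
        raise NumericalError(
            f"all {len(starts)} hyperparameter restarts failed ({n_failed} "
            "factorization failures)"
        )
    return GPHyperparameters(
        kernel=KernelSpec(family, math.exp(best_x[0]), math.exp(best_x[1])),
        noise_variance=math.exp(best_x[2]),
    )


def factorize(
    train: TrainingSet,
    hyper: GPHyperparameters,
    standardization: tuple[float, float] = (0.0, 1.0),
) -> FittedGP:
    """Cholesky-factorize the Gram matrix and precompute the solve vector.

    The observations in ``train`` are taken as-is (callers standardize
    first); ``standardization`` records the (center, scale) transform so
    `predict` can report on the original observation scale.
    """
    L, jitter = _cholesky_with_jitter(_gram(train, hyper))
    alpha = cho_solve((L, True), train.observations)
    return FittedGP(
        training=train,
        hyper=hyper,
        chol=L,
        alpha=alpha,
        jitter=jitter,
        standardization=(float(standardization[0]), float(standardization[1])),
    )


def predict_batch(model: FittedGP, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at many query points (vectorized).

    Results are de-standardized: mean on the original observation scale,
    variance multiplied by scale^2. Variances are clipped at zero.
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != model.d:
        raise ValueError(
            f"query dimension {Q.shape[1]} does not match training dimension {model.d}"
        )
    spec = model.hyper.kernel
    Kqt = kernel_matrix(spec, Q, model.training.inputs)
    mean_std = Kqt @ model.alpha
    V = solve_triangular(model.chol, Kqt.T, lower=True)
    var_std = spec.variance - np.einsum("ij,ij->j", V, V)
    var_std = np.maximum(var_std, 0.0)
    center, scale = model.standardization
    return center + scale * mean_std, scale * scale * var_std


def predict(model: FittedGP, query) -> PosteriorPrediction:
    """Posterior mean/variance at a single query point."""
    mean, var = predict_batch(model, np.atleast_2d(np.asarray(query, dtype=float)))
    return PosteriorPrediction(mean=float(mean[0]), variance=float(var[0]))
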