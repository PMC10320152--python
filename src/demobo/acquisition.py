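"""Closed-form acquisition functions and their maximization.

All three acquisitions score a candidate point from the Gaussian posterior
``N(mu, sigma^2)`` of the surrogate at that point, relative to the
incumbent (lowest objective value observed so far):

* EI — expected improvement ``E[max(0, incumbent - f(t))]``,
* PI — probability of improvement ``P(f(t) < incumbent)``,
* LogEI — expected improvement computed under a log-transformed
  observation model: the surrogate predicts ``log y`` and the improvement
  expectation is taken over the implied lognormal, which rewards large
  multiplicative improvements of a positive objective.

Maximization uses a dense random candidate sweep followed by bounded
quasi-Newton refinement of the best candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

from .gp import FittedGP, NumericalError, predict_batch

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _normal_pdf(z: np.ndarray) -> np.ndarray:
    return _INV_SQRT_2PI * np.exp(-0.5 * z * z)

__all__ = [
    "AcquisitionKind",
    "AcquisitionContext",
    "expected_improvement",
    "probability_of_improvement",
    "log_ei",
    "maximize_acquisition",
    "OptimizerSettings",
]

_SIGMA_FLOOR = 1e-12
_DUPLICATE_TOL = 1e-9


class AcquisitionKind(str, Enum):
    EI = "EI"
    PI = "PI"
    LogEI = "LogEI"


@dataclass(frozen=True)
class AcquisitionContext:
    """Fitted surrogate plus the improvement reference.

    ``incumbent`` is the minimum of the raw evaluation history on the
    original objective scale. When ``log_transformed`` the surrogate was
    trained on ``log(y + log_shift)`` and LogEI is the valid acquisition;
    otherwise EI/PI apply.
    """

    surrogate: FittedGP
    incumbent: float
    log_transformed: bool = False
    log_shift: float = 0.0


@dataclass(frozen=True)
class OptimizerSettings:
    """Candidate-sweep size and number of quasi-Newton refinements."""

    n_candidates: int = 1000
    n_refine: int = 10


def _ei_values(mu: np.ndarray, var: np.ndarray, incumbent: float) -> np.ndarray:
    sigma = np.sqrt(var)
    gap = incumbent - mu
    out = np.maximum(gap, 0.0)
    ok = sigma >= _SIGMA_FLOOR
    z = np.divide(gap, sigma, out=np.zeros_like(sigma), where=ok)
    out_ok = gap * ndtr(z) + sigma * _normal_pdf(z)
    return np.where(ok, out_ok, out)


def _pi_values(mu: np.ndarray, var: np.ndarray, incumbent: float) -> np.ndarray:
    sigma = np.sqrt(var)
    ok = sigma >= _SIGMA_FLOOR
    z = np.divide(incumbent - mu, sigma, out=np.zeros_like(sigma), where=ok)
    return np.where(ok, ndtr(z), (mu < incumbent).astype(float))


def _logei_values(mu: np.ndarray, var: np.ndarray, c: float) -> np.ndarray:
    # E[max(0, c - e^G)] for G ~ N(mu, var): the lognormal partial moment
    #   c Phi((ln c - mu)/s) - exp(mu + s^2/2) Phi((ln c - mu)/s - s)
    if c <= 0:
        raise RuntimeError(
            f"shifted incumbent must be positive for LogEI, got {c}"
        )
    sigma = np.sqrt(var)
    lnc = math.log(c)
    ok = sigma >= _SIGMA_FLOOR
    z = np.divide(lnc - mu, sigma, out=np.zeros_like(sigma), where=ok)
    # second term computed in log space: exp(mu + var/2) can overflow while
    # the adjacent normal tail underflows to zero
    vals = c * ndtr(z) - np.exp(mu + var / 2.0 + log_ndtr(z - sigma))
    degenerate = np.maximum(c - np.exp(mu), 0.0)
    return np.maximum(np.where(ok, vals, degenerate), 0.0)


def _values(ctx: AcquisitionContext, kind: AcquisitionKind, points: np.ndarray) -> np.ndarray:
    mu, var = predict_batch(ctx.surrogate, points)
    if kind is AcquisitionKind.LogEI:
        if not ctx.log_transformed:
            raise RuntimeError("LogEI requires a log-transformed surrogate")
        return _logei_values(mu, var, ctx.incumbent + ctx.log_shift)
    if ctx.log_transformed:
        raise RuntimeError(f"{kind.value} requires an untransformed surrogate")
    if kind is AcquisitionKind.EI:
        return _ei_values(mu, var, ctx.incumbent)
    return _pi_values(mu, var, ctx.incumbent)


def expected_improvement(ctx: AcquisitionContext, t) -> float:
    """EI at one point; zero whenever no improvement is possible."""
    return float(_values(ctx, AcquisitionKind.EI, np.atleast_2d(np.asarray(t, float)))[0])


def probability_of_improvement(ctx: AcquisitionContext, t) -> float:
    """PI at one point, in [0, 1]."""
    return float(_values(ctx, AcquisitionKind.PI, np.atleast_2d(np.asarray(t, float)))[0])


def log_ei(ctx: AcquisitionContext, t) -> float:
    """LogEI at one point; bounded above by the shifted incumbent."""
    return float(_values(ctx, AcquisitionKind.LogEI, np.atleast_2d(np.asarray(t, float)))[0])


def acquisition_values(ctx: AcquisitionContext, kind: AcquisitionKind, points) -> np.ndarray:
    """Vectorized acquisition over a batch of normalized points."""
    return _values(ctx, kind, np.atleast_2d(np.asarray(points, dtype=float)))


def maximize_acquisition(
    ctx: AcquisitionContext,
    kind: AcquisitionKind,
    d: int,
    settings: OptimizerSettings | None = None,
    rng: np.random.Generator | None = None,
    avoid: np.ndarray | None = None,
) -> np.ndarray:
    """Maximize the acquisition over the unit cube.

    Draws ``n_candidates`` uniform points, refines the best ``n_refine`` by
    bounded L-BFGS-B, and returns the best point seen. Ties are broken by
    the lowest candidate index. If ``avoid`` is given and the winner lies
    within 1e-9 (inf-norm) of an already-evaluated point, the best
    non-duplicate candidate is returned instead (or a fresh uniform point
    if every candidate is a duplicate).
    """
    settings = settings or OptimizerSettings()
    rng = np.random.default_rng(0) if rng is None else rng
    cand = rng.random((settings.n_candidates, d))
    vals = _values(ctx, kind, cand)
    if not np.any(np.isfinite(vals)):
        raise NumericalError("acquisition is non-finite at every candidate")
    vals = np.where(np.isfinite(vals), vals, -np.inf)

    # stable argsort keeps lowest-index candidates first among ties
    order = np.argsort(-vals, kind="stable")
    best_x = cand[order[0]].copy()
    best_v = vals[order[0]]

    bounds = [(0.0, 1.0)] * d
    fd_step = 1e-6

    def neg_value_and_grad(x: np.ndarray):
        # value and central-difference gradient from one batched predict
        pts = np.vstack([x, x + fd_step * np.eye(d), x - fd_step * np.eye(d)])
        v = _values(ctx, kind, np.clip(pts, 0.0, 1.0))
        grad = (v[1 : d + 1] - v[d + 1 :]) / (2 * fd_step)
        return -float(v[0]), -grad

    for idx in order[: settings.n_refine]:
        res = minimize(
            neg_value_and_grad,
            cand[idx],
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 30},
        )
        if np.isfinite(res.fun) and -res.fun > best_v:
            best_v = -res.fun
            best_x = np.clip(res.x, 0.0, 1.0)

    if avoid is not None and len(avoid) > 0:
        avoid = np.atleast_2d(avoid)

        def is_dup(x: np.ndarray) -> bool:
            return bool(np.any(np.max(np.abs(avoid - x), axis=1) < _DUPLICATE_TOL))

        if is_dup(best_x):
            for idx in order:
                if not is_dup(cand[idx]):
                    return cand[idx].copy()
            return rng.random(d)
    return best_x
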