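"""The Bayesian-optimization loop and its pipeline variants.

A pipeline is the combination of an acquisition rule and a kernel-prior
rule:

* ``EI/PI/LogEI + <family>`` — fixed acquisition, fixed Matérn subfamily;
* ``PI/LogEI + Auto`` — the family is chosen once, by LOO-CV score on the
  initial design, among all four subfamilies;
* ``Ensemble`` — the family is chosen on the initial design between
  Matern52 and RBF only, and at every iteration a fair coin picks PI or
  LogEI as the acquisition.

Each run evaluates a random initial design of ``2d`` points (uniform on
the normalized domain, i.e. log-uniform in raw units for log-scaled
parameters), then repeats: refit the GP hyperparameters from scratch,
maximize the acquisition, evaluate the objective, append to the history.
The iteration budget counts objective evaluations including the initial
design. A bounded BFGS-family local search is available to polish the
incumbent after the loop.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .acquisition import (
    AcquisitionContext,
    AcquisitionKind,
    OptimizerSettings,
    maximize_acquisition,
)
from .gp import TrainingSet, factorize, fit_hyperparameters, standardize_observations
from .kernels import FAMILIES
from .prior_selection import select_prior
from .transforms import transform_for_logei

__all__ = [
    "Parameter",
    "SearchSpace",
    "PipelineConfig",
    "EvaluationRecord",
    "OptimizationResult",
    "normalize_point",
    "denormalize_point",
    "sample_initial_design",
    "transform_for_logei",
    "ensemble_step_choice",
    "run_bo",
    "local_polish",
]

_AUTO_CANDIDATES = ("Exponential", "Matern32", "Matern52", "RBF")
_ENSEMBLE_CANDIDATES = ("Matern52", "RBF")


@dataclass(frozen=True)
class Parameter:
    """One bounded search-space coordinate, optionally log-scaled."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires a positive lower bound")


class SearchSpace:
    """Bounded box of demographic parameters with per-parameter scaling."""

    def __init__(self, parameters: Sequence[Parameter]):
        if len(parameters) < 1:
            raise ValueError("search space needs at least one parameter")
        self.parameters = tuple(parameters)

    @property
    def d(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def bounds(self) -> list[tuple[float, float]]:
        return [(p.lower, p.upper) for p in self.parameters]

    def normalize(self, raw) -> np.ndarray:
        return normalize_point(self, raw)

    def denormalize(self, unit) -> np.ndarray:
        return denormalize_point(self, unit)

    def __repr__(self) -> str:
        inner = ", ".join(
            f"{p.name}[{p.lower:g},{p.upper:g},{p.scale}]" for p in self.parameters
        )
        return f"SearchSpace({inner})"


def normalize_point(space: SearchSpace, raw) -> np.ndarray:
    """Map raw parameters to the unit cube (log-interpolating log scales)."""
    raw = np.asarray(raw, dtype=float).ravel()
    if raw.shape != (space.d,):
        raise ValueError(f"expected {space.d} parameters, got {raw.shape}")
    out = np.empty(space.d)
    for j, p in enumerate(space.parameters):
        v = raw[j]
        if v < p.lower - 1e-12 or v > p.upper + 1e-12:
            raise ValueError(
                f"{p.name}={v} outside bounds [{p.lower}, {p.upper}]"
            )
        if p.scale == "log":
            out[j] = (math.log(v) - math.log(p.lower)) / (
                math.log(p.upper) - math.log(p.lower)
            )
        else:
            out[j] = (v - p.lower) / (p.upper - p.lower)
    return np.clip(out, 0.0, 1.0)


def denormalize_point(space: SearchSpace, unit) -> np.ndarray:
    """Inverse of `normalize_point`."""
    unit = np.asarray(unit, dtype=float).ravel()
    if unit.shape != (space.d,):
        raise ValueError(f"expected {space.d} coordinates, got {unit.shape}")
    out = np.empty(space.d)
    for j, p in enumerate(space.parameters):
        u = min(max(float(unit[j]), 0.0), 1.0)
        if p.scale == "log":
            out[j] = math.exp(
                math.log(p.lower) + u * (math.log(p.upper) - math.log(p.lower))
            )
        else:
            out[j] = p.lower + u * (p.upper - p.lower)
    return out


def sample_initial_design(
    space: SearchSpace, size: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. uniform sample on the normalized domain (size x d)."""
    if size < 1:
        raise ValueError("design size must be >= 1")
    return rng.random((size, space.d))


def ensemble_step_choice(rng: np.random.Generator) -> AcquisitionKind:
    """Fair coin between PI and LogEI for one ensemble iteration."""
    return AcquisitionKind.PI if rng.random() < 0.5 else AcquisitionKind.LogEI


@dataclass(frozen=True)
class PipelineConfig:
    """Which pipeline to run and with what budget.

    ``acquisition_mode`` is "EI", "PI", "LogEI" or "ensemble";
    ``prior_mode`` is "fixed" (with ``kernel``), "auto" (all four families)
    or "auto_restricted" (Matern52 and RBF only). The evaluation budget
    ``total_evaluations`` includes the initial design (default size 2d).
    """

    total_evaluations: int
    acquisition_mode: str = "ensemble"
    prior_mode: str = "auto_restricted"
    kernel: str | None = None
    initial_design_size: int | None = None
    seed: int = 0
    gp_restarts: int = 5
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)

    def __post_init__(self) -> None:
        if self.acquisition_mode not in ("EI", "PI", "LogEI", "ensemble"):
            raise ValueError(f"unknown acquisition mode {self.acquisition_mode!r}")
        if self.prior_mode not in ("fixed", "auto", "auto_restricted"):
            raise ValueError(f"unknown prior mode {self.prior_mode!r}")
        if self.prior_mode == "fixed":
            if self.kernel not in FAMILIES:
                raise ValueError(
                    f"fixed prior mode needs kernel in {FAMILIES}, got {self.kernel!r}"
                )
        if self.total_evaluations < 2:
            raise ValueError("total_evaluations must be at least 2")
        if self.total_evaluations > 1000:
            import logging

            logging.getLogger(__name__).warning(
                "budgets above 1000 evaluations are not recommended: the "
                "surrogate overhead grows cubically with the history size"
            )

    def design_size(self, d: int) -> int:
        size = 2 * d if self.initial_design_size is None else self.initial_design_size
        if size < 1:
            raise ValueError("initial design size must be >= 1")
        if self.total_evaluations <= size:
            raise ValueError(
                f"budget {self.total_evaluations} must exceed the initial design "
                f"size {size}"
            )
        return size

    @classmethod
    def from_string(cls, pipeline: str, total_evaluations: int, seed: int = 0, **kw):
        """Parse CLI-style names: "pi+matern52", "logei+auto", "ensemble"."""
        s = pipeline.strip().lower()
        if s == "ensemble":
            return cls(total_evaluations, "ensemble", "auto_restricted", seed=seed, **kw)
        if "+" not in s:
            raise ValueError(f"cannot parse pipeline name {pipeline!r}")
        acq_s, kern_s = s.split("+", 1)
        acq = {"ei": "EI", "pi": "PI", "logei": "LogEI"}.get(acq_s)
        if acq is None:
            raise ValueError(f"unknown acquisition {acq_s!r} in {pipeline!r}")
        if kern_s == "auto":
            return cls(total_evaluations, acq, "auto", seed=seed, **kw)
        kern = {f.lower(): f for f in FAMILIES}.get(kern_s)
        if kern is None:
            raise ValueError(f"unknown kernel {kern_s!r} in {pipeline!r}")
        return cls(total_evaluations, acq, "fixed", kernel=kern, seed=seed, **kw)


@dataclass(frozen=True)
class EvaluationRecord:
    index: int
    phase: str  # "initial" | "bo"
    raw: np.ndarray
    unit: np.ndarray
    y: float
    failed: bool = False
    acquisition: str | None = None
    wall_time: float = 0.0


@dataclass(frozen=True)
class OptimizationResult:
    history: tuple[EvaluationRecord, ...]
    incumbent_raw: np.ndarray
    incumbent_value: float
    selected_family: str
    coin_flips: tuple[str, ...]
    trace: np.ndarray
    config: PipelineConfig
    space: SearchSpace

    @property
    def cumulative_wall_time(self) -> np.ndarray:
        return np.cumsum([r.wall_time for r in self.history])


def _evaluate(objective, raw: np.ndarray) -> tuple[float, bool, float]:
    t0 = time.perf_counter()
    try:
        y = float(objective(raw))
        failed = not np.isfinite(y)
    except Exception:
        y, failed = math.nan, True
    return y, failed, time.perf_counter() - t0


def run_bo(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: PipelineConfig,
) -> OptimizationResult:
    """Run one seeded Bayesian-optimization pipeline to its budget.

    Failed objective evaluations (exceptions or non-finite values) are
    recorded with a failure flag and excluded from the surrogate; the run
    aborts if more than half of all evaluations have failed.
    """
    d = space.d
    n_init = config.design_size(d)
    ss = np.random.SeedSequence(config.seed)
    design_rng, coin_rng, fit_rng, acq_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    history: list[EvaluationRecord] = []
    coin_flips: list[str] = []

    def check_failures() -> None:
        n_failed = sum(r.failed for r in history)
        if len(history) >= 2 and n_failed * 2 > len(history):
            raise RuntimeError(
                f"{n_failed}/{len(history)} objective evaluations failed; aborting"
            )

    design = sample_initial_design(space, n_init, design_rng)
    for unit in design:
        raw = denormalize_point(space, unit)
        y, failed, dt = _evaluate(objective, raw)
        history.append(
            EvaluationRecord(
                index=len(history), phase="initial", raw=raw, unit=unit.copy(),
                y=y, failed=failed, wall_time=dt,
            )
        )
        check_failures()

    def successes() -> tuple[np.ndarray, np.ndarray]:
        ok = [r for r in history if not r.failed]
        return np.array([r.unit for r in ok]), np.array([r.y for r in ok])

    # prior choice: fixed, or LOO-CV on the initial design
    if config.prior_mode == "fixed":
        family = config.kernel
    else:
        candidates = (
            _AUTO_CANDIDATES if config.prior_mode == "auto" else _ENSEMBLE_CANDIDATES
        )
        X, y = successes()
        # the LogEI pipeline models log observations, so its prior is also
        # scored on the log scale; the ensemble mixes acquisitions and
        # scores on the untransformed scale
        log_cv = config.acquisition_mode == "LogEI"
        if len(y) >= 2:
            family = select_prior(
                TrainingSet(X, y),
                candidates,
                log_transform=log_cv,
                rng=fit_rng,
                n_restarts=config.gp_restarts,
            )
        else:
            family = candidates[0]

    while len(history) < config.total_evaluations:
        if config.acquisition_mode == "ensemble":
            kind = ensemble_step_choice(coin_rng)
            coin_flips.append(kind.value)
        else:
            kind = AcquisitionKind(config.acquisition_mode)

        X, y = successes()
        if len(y) >= 2:
            if kind is AcquisitionKind.LogEI:
                y_t, shift = transform_for_logei(y)
            else:
                y_t, shift = y, 0.0
            y_std, center, scale = standardize_observations(y_t)
            train = TrainingSet(X, y_std)
            hyper = fit_hyperparameters(
                train, family, n_restarts=config.gp_restarts, rng=fit_rng
            )
            gp = factorize(train, hyper, standardization=(center, scale))
            ctx = AcquisitionContext(
                surrogate=gp,
                incumbent=float(np.min(y)),
                log_transformed=kind is AcquisitionKind.LogEI,
                log_shift=shift,
            )
            unit = maximize_acquisition(
                ctx, kind, d, settings=config.optimizer, rng=acq_rng, avoid=X
            )
        else:
            # not enough successful evaluations to fit a surrogate yet
            unit = acq_rng.random(d)

        raw = denormalize_point(space, unit)
        y_val, failed, dt = _evaluate(objective, raw)
        history.append(
            EvaluationRecord(
                index=len(history), phase="bo", raw=raw, unit=unit,
                y=y_val, failed=failed, acquisition=kind.value, wall_time=dt,
            )
        )
        check_failures()

    finite = np.array([math.inf if r.failed else r.y for r in history])
    trace = np.minimum.accumulate(finite)
    best_idx = int(np.argmin(finite))
    return OptimizationResult(
        history=tuple(history),
        incumbent_raw=history[best_idx].raw,
        incumbent_value=float(finite[best_idx]),
        selected_family=family,
        coin_flips=tuple(coin_flips),
        trace=trace,
        config=config,
        space=space,
    )


def local_polish(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    start: np.ndarray,
    max_evals: int = 200,
) -> tuple[np.ndarray, float]:
    """Bounded quasi-Newton (L-BFGS-B) descent from the incumbent.

    Gradients are numerical; the returned value never exceeds the starting
    value and at most ``max_evals`` objective calls are spent. Any failure
    returns the start point unchanged.
    """
    start = np.asarray(start, dtype=float).ravel()
    best = {"x": start.copy(), "f": math.inf}
    calls = {"n": 0}

    def wrapped(x: np.ndarray) -> float:
        if calls["n"] >= max_evals:
            raise StopIteration
        calls["n"] += 1
        f = float(objective(np.asarray(x, dtype=float)))
        if math.isfinite(f) and f < best["f"]:
            best["x"], best["f"] = np.array(x, dtype=float), f
        return f

    try:
        f0 = wrapped(start)
    except Exception:
        return start, float("nan")
    try:
        minimize(
            wrapped,
            start,
            method="L-BFGS-B",
            bounds=space.bounds(),
            options={"maxfun": max(max_evals - 1, 1)},
        )
    except (StopIteration, Exception):
        pass
    if best["f"] <= f0:
        return best["x"], best["f"]
    return start, f0
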