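"""Synthetic expensive-to-evaluate objectives.

The optimizer in this package is aimed at demographic inference, where the
objective is the negative log-likelihood of a demographic model given an
observed site frequency spectrum (SFS). Real SFS likelihood engines are
deliberately not a dependency; instead this module provides

* a *toy* single-population SFS objective — an independent-Poisson
  composite negative log-likelihood over an unfolded spectrum whose
  expectation follows a three-parameter decay curve. It is a fixture, not
  a demographic model: it reproduces the features that matter to the
  optimizer (a log-scale amplitude parameter, monotone-ish decay, a
  likelihood surface with a sharp well) without claiming demographic
  meaning;
* the classic deterministic benchmark functions (sphere, Rosenbrock,
  Branin, Hartmann-6) with their known optima, standing in for expensive
  log-likelihoods at desk scale;
* read/write support for the single-population dadi/moments-style
  plain-text spectrum dialect.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import gammaln

from .pipeline import Parameter, SearchSpace

__all__ = [
    "ObjectiveFunction",
    "SiteFrequencySpectrum",
    "ToySFSModel",
    "SFSFormatError",
    "toy_sfs_expected",
    "sfs_poisson_nll",
    "simulate_sfs",
    "toy_sfs_space",
    "make_toy_sfs_objective",
    "benchmark_objective",
    "read_sfs",
    "write_sfs",
]


class SFSFormatError(ValueError):
    """Malformed spectrum file; the message carries the offending line."""


@dataclass(frozen=True)
class ObjectiveFunction:
    """A black-box function to minimize over a bounded search space."""

    fn: Callable[[np.ndarray], float]
    space: SearchSpace
    name: str = "objective"
    known_optimum: tuple[np.ndarray, float] | None = None
    artificial_delay: float = 0.0

    def __call__(self, raw: np.ndarray) -> float:
        if self.artificial_delay > 0:
            time.sleep(self.artificial_delay)
        return float(self.fn(np.asarray(raw, dtype=float)))


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Unfolded single-population SFS: counts of derived alleles seen
    ``i`` times among ``n_chrom`` sampled chromosomes, ``i = 1..n_chrom-1``.
    The monomorphic corner entries are not stored."""

    n_chrom: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.n_chrom < 3:
            raise ValueError(f"n_chrom must be >= 3, got {self.n_chrom}")
        counts = np.asarray(self.counts)
        if counts.shape != (self.n_chrom - 1,):
            raise ValueError(
                f"expected {self.n_chrom - 1} entries for n_chrom={self.n_chrom}, "
                f"got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("spectrum entries must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))


@dataclass(frozen=True)
class ToySFSModel:
    """Three-parameter expected-spectrum shape.

    ``theta`` sets the overall scale (log-uniform over orders of magnitude,
    like a population-scaled mutation rate), ``beta`` the power-law decay in
    allele frequency, ``gamma`` an extra exponential suppression of
    high-frequency alleles.
    """

    theta: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be positive, got {self.theta}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def toy_sfs_expected(model: ToySFSModel, n_chrom: int) -> np.ndarray:
    """Expected entries ``mu_i = theta * i^-beta * exp(-gamma (i-1)/(n-2))``."""
    if n_chrom < 3:
        raise ValueError(f"n_chrom must be >= 3, got {n_chrom}")
    i = np.arange(1, n_chrom, dtype=float)
    denom = max(n_chrom - 2, 1)
    return model.theta * i ** (-model.beta) * np.exp(-model.gamma * (i - 1.0) / denom)


def sfs_poisson_nll(sfs: SiteFrequencySpectrum, expected: np.ndarray) -> float:
    """Independent-Poisson composite negative log-likelihood.

    ``sum_i [mu_i - xi_i log mu_i + log(xi_i!)]`` — constants included so
    the value is a true NLL. log-factorials go through the log-gamma
    function for overflow safety.
    """
    mu = np.asarray(expected, dtype=float)
    xi = sfs.counts.astype(float)
    if mu.shape != xi.shape:
        raise ValueError(f"length mismatch: {xi.shape} counts vs {mu.shape} expected")
    if np.any(mu <= 0):
        raise ValueError("expected spectrum entries must be positive")
    return float(np.sum(mu - xi * np.log(mu) + gammaln(xi + 1.0)))


def simulate_sfs(
    model: ToySFSModel, n_chrom: int, rng: np.random.Generator
) -> SiteFrequencySpectrum:
    """Draw each spectrum entry independently Poisson(mu_i)."""
    mu = toy_sfs_expected(model, n_chrom)
    return SiteFrequencySpectrum(n_chrom=n_chrom, counts=rng.poisson(mu))


def toy_sfs_space(theta_hi: float = 1e5) -> SearchSpace:
    """Default bounded space for the toy model: theta log-scaled over
    [1, theta_hi], beta and gamma linear on [0, 3]."""
    return SearchSpace(
        [
            Parameter("theta", 1.0, theta_hi, scale="log"),
            Parameter("beta", 0.0, 3.0),
            Parameter("gamma", 0.0, 3.0),
        ]
    )


def make_toy_sfs_objective(
    observed: SiteFrequencySpectrum, space: SearchSpace | None = None
) -> ObjectiveFunction:
    """Poisson NLL of the observed spectrum as a function of (theta, beta, gamma)."""
    space = space if space is not None else toy_sfs_space()
    if space.d != 3:
        raise ValueError("toy SFS objective needs a 3-parameter space")

    def nll(raw: np.ndarray) -> float:
        model = ToySFSModel(theta=raw[0], beta=raw[1], gamma=raw[2])
        return sfs_poisson_nll(observed, toy_sfs_expected(model, observed.n_chrom))

    return ObjectiveFunction(fn=nll, space=space, name="toy_sfs")


# ---------------------------------------------------------------------------
# classic deterministic benchmarks

def _branin(x: np.ndarray) -> float:
    a, b, c = 1.0, 5.1 / (4 * np.pi**2), 5.0 / np.pi
    r, s, t = 6.0, 10.0, 1.0 / (8 * np.pi)
    return a * (x[1] - b * x[0] ** 2 + c * x[0] - r) ** 2 + s * (1 - t) * np.cos(x[0]) + s


def _hartmann6(x: np.ndarray) -> float:
    alpha = np.array([1.0, 1.2, 3.0, 3.2])
    A = np.array(
        [
            [10, 3, 17, 3.5, 1.7, 8],
            [0.05, 10, 17, 0.1, 8, 14],
            [3, 3.5, 1.7, 10, 17, 8],
            [17, 8, 0.05, 10, 0.1, 14],
        ]
    )
    P = 1e-4 * np.array(
        [
            [1312, 1696, 5569, 124, 8283, 5886],
            [2329, 4135, 8307, 3736, 1004, 9991],
            [2348, 1451, 3522, 2883, 3047, 6650],
            [4047, 8828, 8732, 5743, 1091, 381],
        ]
    )
    inner = np.sum(A * (x[None, :] - P) ** 2, axis=1)
    return -float(np.sum(alpha * np.exp(-inner)))


_BENCHMARKS: dict[str, dict] = {
    "sphere": dict(
        fn=lambda x: float(np.sum(x**2)),
        bounds=[(-5.12, 5.12)] * 2,
        optimum=(np.zeros(2), 0.0),
    ),
    "rosenbrock": dict(
        fn=lambda x: float(100.0 * (x[1] - x[0] ** 2) ** 2 + (1 - x[0]) ** 2),
        bounds=[(-5.0, 10.0)] * 2,
        optimum=(np.ones(2), 0.0),
    ),
    "branin": dict(
        fn=_branin,
        bounds=[(-5.0, 10.0), (0.0, 15.0)],
        optimum=(np.array([np.pi, 2.275]), 0.39788735772973816),
    ),
    "hartmann6": dict(
        fn=_hartmann6,
        bounds=[(0.0, 1.0)] * 6,
        optimum=(
            np.array([0.20169, 0.150011, 0.476874, 0.275332, 0.311652, 0.6573]),
            -3.32236801141551,
        ),
    ),
}


def benchmark_objective(name: str, artificial_delay: float = 0.0) -> ObjectiveFunction:
    """Standard test function with its standard domain and known optimum."""
    if name not in _BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; options: {sorted(_BENCHMARKS)}")
    entry = _BENCHMARKS[name]
    space = SearchSpace(
        [Parameter(f"x{i}", lo, hi) for i, (lo, hi) in enumerate(entry["bounds"])]
    )
    return ObjectiveFunction(
        fn=entry["fn"],
        space=space,
        name=name,
        known_optimum=entry["optimum"],
        artificial_delay=artificial_delay,
    )


# ---------------------------------------------------------------------------
# dadi/moments-style single-population spectrum text format

def write_sfs(sfs: SiteFrequencySpectrum, path) -> None:
    """Write the spectrum in the single-population unfolded text dialect.

    Line 1: ``<n_chrom+1> unfolded``; line 2: the n_chrom+1 entries with
    zeroed monomorphic corners; line 3: the corner mask (1 = masked).
    """
    m = sfs.n_chrom + 1
    entries = [0, *sfs.counts.tolist(), 0]
    mask = [1] + [0] * (m - 2) + [1]
    text = (
        f"{m} unfolded\n"
        + " ".join(str(v) for v in entries)
        + "\n"
        + " ".join(str(v) for v in mask)
        + "\n"
    )
    Path(path).write_text(text)


def read_sfs(path) -> SiteFrequencySpectrum:
    """Parse the dialect written by `write_sfs`; corners are ignored."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise SFSFormatError("line 1: file truncated, need header and data lines")
    header = lines[0].split()
    if len(header) != 2 or header[1] not in ("unfolded", "folded"):
        raise SFSFormatError(f"line 1: malformed header {lines[0]!r}")
    if header[1] == "folded":
        raise SFSFormatError("line 1: folded spectra are not supported")
    try:
        m = int(header[0])
    except ValueError:
        raise SFSFormatError(f"line 1: spectrum length {header[0]!r} is not an integer")
    if m < 4:
        raise SFSFormatError(f"line 1: spectrum length {m} implies n_chrom < 3")
    values = lines[1].split()
    if len(values) != m:
        raise SFSFormatError(f"line 2: expected {m} entries, found {len(values)}")
    try:
        counts = np.array([int(round(float(v))) for v in values])
    except ValueError:
        raise SFSFormatError("line 2: non-numeric spectrum entry")
    if np.any(counts[1:-1] < 0):
        raise SFSFormatError("line 2: negative spectrum entry")
    if len(lines) >= 3 and lines[2].strip():
        mask = lines[2].split()
        if len(mask) != m:
            raise SFSFormatError(f"line 3: expected {m} mask entries, found {len(mask)}")
        if mask[0] != "1" or mask[-1] != "1":
            raise SFSFormatError("line 3: monomorphic corners must be masked")
    return SiteFrequencySpectrum(n_chrom=m - 1, counts=counts[1:-1])
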