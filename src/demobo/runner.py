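"""Replication harness: repeated seeded runs, convergence aggregation, export.

Convergence of a stochastic optimizer is summarized the standard way:
many independent runs, and per evaluation index the median and first/third
quartiles of the best-so-far value across runs. Replicate seeds are
derived deterministically from ``(master_seed, replicate_index)``, so any
subset of replicates can be reproduced independently of the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import OptimizationResult, PipelineConfig, SearchSpace, run_bo

__all__ = [
    "ConvergenceTrace",
    "AggregatedConvergence",
    "replicate_seed",
    "run_replicates",
    "aggregate_convergence",
    "export_results",
]

QUANTILE_METHOD = "linear"  # interpolation between order statistics


@dataclass(frozen=True)
class ConvergenceTrace:
    best_so_far: np.ndarray
    cumulative_wall_time: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.best_so_far, dtype=float)
        w = np.asarray(self.cumulative_wall_time, dtype=float)
        if b.shape != w.shape:
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(b) > 1e-12):
            raise ValueError("best-so-far trace must be non-increasing")
        if np.any(np.diff(w) < -1e-9):
            raise ValueError("cumulative wall time must be non-decreasing")
        object.__setattr__(self, "best_so_far", b)
        object.__setattr__(self, "cumulative_wall_time", w)


@dataclass(frozen=True)
class AggregatedConvergence:
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    n_replicates: int
    quantile_method: str = QUANTILE_METHOD


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed, independent of other replicates."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))


def run_replicates(
    objective,
    space: SearchSpace,
    config: PipelineConfig,
    n_replicates: int,
    master_seed: int,
) -> list[OptimizationResult | None]:
    """Run ``n_replicates`` independent seeded copies of one pipeline.

    Each replicate uses its own substream from `replicate_seed`. A
    replicate that errors out is recorded as ``None``; the others proceed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    results: list[OptimizationResult | None] = []
    for r in range(n_replicates):
        seed = int(replicate_seed(master_seed, r).generate_state(1)[0] % (2**31))
        cfg = PipelineConfig(
            total_evaluations=config.total_evaluations,
            acquisition_mode=config.acquisition_mode,
            prior_mode=config.prior_mode,
            kernel=config.kernel,
            initial_design_size=config.initial_design_size,
            seed=seed,
            gp_restarts=config.gp_restarts,
            optimizer=config.optimizer,
        )
        try:
            results.append(run_bo(objective, space, cfg))
        except Exception:
            results.append(None)
    return results


def aggregate_convergence(traces: list[ConvergenceTrace]) -> AggregatedConvergence:
    """Median and quartiles of best-so-far per evaluation index."""
    if not traces:
        raise ValueError("need at least one trace")
    lengths = {len(t.best_so_far) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    M = np.stack([t.best_so_far for t in traces])
    q1, med, q3 = np.quantile(M, [0.25, 0.5, 0.75], axis=0, method=QUANTILE_METHOD)
    return AggregatedConvergence(
        median=med, q1=q1, q3=q3, n_replicates=len(traces)
    )


def result_trace(result: OptimizationResult) -> ConvergenceTrace:
    return ConvergenceTrace(
        best_so_far=result.trace,
        cumulative_wall_time=result.cumulative_wall_time,
    )


def export_results(results: list[OptimizationResult | None], out_dir) -> dict:
    """Write per-replicate trace CSVs and summary JSONs plus an aggregate CSV.

    Returns a manifest mapping replicate index to the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"replicates": {}, "aggregate": None}
    traces = []
    for r, res in enumerate(results):
        if res is None:
            manifest["replicates"][r] = None
            continue
        cum = res.cumulative_wall_time
        df = pd.DataFrame(
            {
                "index": [rec.index for rec in res.history],
                "phase": [rec.phase for rec in res.history],
                "acquisition": [rec.acquisition or "" for rec in res.history],
                "y": [rec.y for rec in res.history],
                "best_so_far": res.trace,
                "cum_wall_time": cum,
            }
        )
        trace_path = out / f"replicate_{r:03d}_trace.csv"
        df.to_csv(trace_path, index=False)
        summary = {
            "config": {
                "acquisition_mode": res.config.acquisition_mode,
                "prior_mode": res.config.prior_mode,
                "kernel": res.config.kernel,
                "total_evaluations": res.config.total_evaluations,
                "initial_design_size": res.config.design_size(res.space.d),
                "gp_restarts": res.config.gp_restarts,
            },
            "seed": res.config.seed,
            "space": [asdict(p) for p in res.space.parameters],
            "incumbent": {
                "parameters": dict(
                    zip(res.space.names, res.incumbent_raw.tolist())
                ),
                "value": res.incumbent_value,
            },
            "selected_prior": res.selected_family,
            "coin_flips": list(res.coin_flips),
            "quantile_method": QUANTILE_METHOD,
        }
        summary_path = out / f"replicate_{r:03d}_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["replicates"][r] = {
            "trace": trace_path.name,
            "summary": summary_path.name,
        }
        traces.append(result_trace(res))
    if traces:
        agg = aggregate_convergence(traces)
        adf = pd.DataFrame(
            {
                "index": np.arange(len(agg.median)),
                "median": agg.median,
                "q1": agg.q1,
                "q3": agg.q3,
            }
        )
        agg_path = out / "aggregated_convergence.csv"
        adf.to_csv(agg_path, index=False)
        manifest["aggregate"] = agg_path.name
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
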