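"""Replicated benchmark experiments: simulate, select with every method,
score against truth. This is the engine behind the ``bench`` CLI
subcommand and the reproduction scripts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import baselines
from .driver import run_mbrfs, run_single_mb_baseline
from .evaluate import (
    ConfusionCounts,
    EvaluationReport,
    evaluate_clustered,
    evaluate_flat,
    summarize_replicates,
)
from .search import SearchParams
from .simulate import ScenarioSpec, simulate_case_control_study

__all__ = ["BenchmarkConfig", "run_benchmark", "METHODS"]

METHODS = ("mbrfs", "bonferroni", "bh", "lasso", "dasso")


@dataclass
class BenchmarkConfig:
    """One benchmark: a scenario/scheme, the methods to compare, and scale."""

    scenario: ScenarioSpec
    methods: tuple[str, ...] = ("mbrfs", "bonferroni", "bh")
    n_replicates: int = 100
    seed: int = 0
    clustered: bool = False  # cluster-level scoring (causal SNPs inside LD blocks)
    search_params: SearchParams = field(default_factory=SearchParams)
    screen_alpha: float = 0.05
    stop_size: int = 2
    correction_alpha: float = 0.05
    lasso_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _select(method: str, data, cfg: BenchmarkConfig, trend_p):
    if method == "mbrfs":
        res = run_mbrfs(
            data, cfg.search_params, screen_alpha=cfg.screen_alpha,
            stop_size=cfg.stop_size,
        )
        return res.final_set
    if method == "dasso":
        res = run_single_mb_baseline(
            data, cfg.search_params, screen_alpha=cfg.screen_alpha
        )
        return res.final_set
    if method == "bonferroni":
        return baselines.bonferroni_select(trend_p, cfg.correction_alpha).selected
    if method == "bh":
        return baselines.bh_select(trend_p, cfg.correction_alpha).selected
    if method == "lasso":
        return baselines.lasso_select(data, seed=cfg.seed, **cfg.lasso_kwargs).selected
    raise ValueError(method)


def run_benchmark(cfg: BenchmarkConfig) -> dict[str, EvaluationReport]:
    """Run ``n_replicates`` simulated studies and score every method.

    Each replicate re-simulates the population and the case-control
    draw under a seed derived from ``cfg.seed``; trend-test p-values
    are computed once per replicate and shared by the multiple-testing
    baselines.
    """
    rng = np.random.default_rng(cfg.seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_replicates)
    counts: dict[str, list[ConfusionCounts]] = {m: [] for m in cfg.methods}
    selections: dict[str, list] = {m: [] for m in cfg.methods}
    n_markers = None
    for rep in range(cfg.n_replicates):
        spec = replace(cfg.scenario, seed=int(rep_seeds[rep]))
        data = simulate_case_control_study(spec)
        n_markers = data.n_markers
        needs_trend = {"bonferroni", "bh"} & set(cfg.methods)
        trend_p = baselines.trend_pvalues(data) if needs_trend else None
        for m in cfg.methods:
            sel = _select(m, data, cfg, trend_p)
            selections[m].append(sel)
            if cfg.clustered:
                counts[m].append(
                    evaluate_clustered(sel, data.truth, data.genotypes)
                )
            else:
                counts[m].append(evaluate_flat(sel, data.truth, n_markers))
    return {
        m: summarize_replicates(m, counts[m], selections[m], n_markers)
        for m in cfg.methods
    }
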