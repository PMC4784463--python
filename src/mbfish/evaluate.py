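"""Scoring selections against simulation truth: TDR, FDR, MCC and
per-marker discovery rates, flat (per SNP) or cluster-based (per LD
cluster, for scenarios where causal SNPs sit inside LD blocks)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "mcc",
    "evaluate_flat",
    "evaluate_clustered",
    "discovery_rate",
    "discovery_rates",
    "summarize_replicates",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts; in cluster mode TP and FP count clusters
    (TPC/FPC) rather than individual markers."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tdr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if self.tp + self.fp else 0.0


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def evaluate_flat(selected, truth, n_markers: int) -> ConfusionCounts:
    """SNP-level confusion counts of a selection against the truth set."""
    sel = set(int(s) for s in selected)
    tru = set(int(t) for t in truth)
    if not sel <= set(range(n_markers)):
        raise ValueError("selected indices out of range")
    tp = len(sel & tru)
    fp = len(sel - tru)
    fn = len(tru - sel)
    tn = n_markers - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def evaluate_clustered(
    selected,
    truth,
    genotypes: np.ndarray,
    window: int = 20,
    r2: float = 0.05,
    fp_gap: int = 10,
) -> ConfusionCounts:
    """Cluster-level scoring for causal SNPs embedded in LD blocks.

    A captured SNP within ``window`` positions of a true SNP and with
    genotype r² above ``r2`` with it counts toward that true SNP; all
    such captures for one true SNP form a single true-positive cluster
    (TPC). Captured SNPs explained by no true SNP are false positives,
    and runs of them no more than ``fp_gap`` positions apart merge into
    one false-positive cluster (FPC). TN is the number of markers
    participating in no cluster (an index-unit approximation).
    """
    sel = sorted(set(int(s) for s in selected))
    tru = sorted(set(int(t) for t in truth))
    n_markers = genotypes.shape[1]
    explained: set[int] = set()
    tpc = 0
    for t in tru:
        hits = []
        gt = genotypes[:, t].astype(float)
        for s in sel:
            if abs(s - t) > window:
                continue
            if s == t:
                hits.append(s)
                continue
            gs = genotypes[:, s].astype(float)
            if gt.std() == 0 or gs.std() == 0:
                continue
            r = float(np.corrcoef(gt, gs)[0, 1])
            if r * r > r2:
                hits.append(s)
        if hits:
            tpc += 1
            explained.update(hits)
    strays = [s for s in sel if s not in explained]
    fpc = 0
    prev = None
    for s in strays:
        if prev is None or s - prev > fp_gap:
            fpc += 1
        prev = s
    fn = len(tru) - tpc
    participating = len(explained) + len(strays)
    tn = n_markers - participating
    return ConfusionCounts(tpc, fpc, fn, tn)


def discovery_rate(per_replicate_selections, marker_j: int, n_reps: int | None = None) -> float:
    """Percentage of replicates in which marker ``marker_j`` was selected."""
    sels = list(per_replicate_selections)
    n = n_reps if n_reps is not None else len(sels)
    if n < 1:
        raise ValueError("need at least one replicate")
    hits = sum(1 for s in sels if int(marker_j) in set(int(x) for x in s))
    return 100.0 * hits / n


def discovery_rates(per_replicate_selections, n_markers: int) -> np.ndarray:
    """Per-marker discovery percentages over replicates."""
    sels = [set(int(x) for x in s) for s in per_replicate_selections]
    counts = np.zeros(n_markers)
    for s in sels:
        for j in s:
            counts[j] += 1
    return 100.0 * counts / len(sels)


@dataclass
class EvaluationReport:
    """Replicate-averaged performance of one method.

    ``tdr_overall``, ``fdr`` and ``mcc`` are arithmetic means of the
    per-replicate metrics (each replicate applies the 0/0 -> 0
    conventions locally before averaging).
    """

    method: str
    tdr_overall: float
    fdr: float
    mcc: float
    n_replicates: int
    per_marker_discovery: np.ndarray | None = None
    per_replicate: list[ConfusionCounts] = field(default_factory=list)


def summarize_replicates(
    method: str,
    per_replicate_counts: list[ConfusionCounts],
    per_replicate_selections=None,
    n_markers: int | None = None,
) -> EvaluationReport:
    """Aggregate per-replicate confusion counts into an EvaluationReport."""
    if not per_replicate_counts:
        raise ValueError("no replicates to summarize")
    tdrs = [c.tdr for c in per_replicate_counts]
    fdrs = [c.fdr for c in per_replicate_counts]
    mccs = [mcc(c) for c in per_replicate_counts]
    rates = None
    if per_replicate_selections is not None and n_markers is not None:
        rates = discovery_rates(per_replicate_selections, n_markers)
    return EvaluationReport(
        method=method,
        tdr_overall=float(np.mean(tdrs)),
        fdr=float(np.mean(fdrs)),
        mcc=float(np.mean(mccs)),
        n_replicates=len(per_replicate_counts),
        per_marker_discovery=rates,
        per_replicate=per_replicate_counts,
    )
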