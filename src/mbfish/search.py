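"""One fishing round: forward admission, LD pruning, backward pruning.

The search is a modified grow-shrink Markov-blanket construction. To
keep stratified contingency tables small, conditional-independence is
assessed under a *first-order* relaxation: a candidate is compared
against each current blanket member one at a time, and is considered
dependent on the phenotype only if every such single-conditioner test
rejects independence. The summary score of a candidate is its
worst-case (largest) p-value across those tests — the conservative
reading of selecting the candidate "with the minimal p-value".

After each admission, markers in strong LD with the admitted SNP
(r² above a threshold, within a window of neighbouring markers) are
removed from the candidate pool so a captured LD block contributes one
representative, and a backward pass re-tests each member against the
others and drops those no longer supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .citests import CITestResult, TableTooLargeError, conditional_g2, regression_ci_test
from .dataset import GenotypeDataset

__all__ = [
    "SearchParams",
    "Blanket",
    "first_order_dependent",
    "forward_step",
    "backward_prune",
    "ld_prune",
    "run_mb_round",
]


@dataclass(frozen=True)
class SearchParams:
    """Tuning knobs of one MB fishing round.

    ``alpha`` — admission/removal significance level; ``r2_threshold``
    and ``ld_window`` define the LD-pruning rule (markers within
    ``ld_window`` positions of an admitted SNP and with genotype r²
    above the threshold leave the pool); ``ci_backend`` picks the
    conditional-independence test; ``first_order=False`` restores the
    legacy full-conditioning behaviour (all blanket members at once),
    guarded by ``max_cells``.
    """

    alpha: float = 0.05
    r2_threshold: float = 0.05
    ld_window: int = 20
    ci_backend: str = "g2"
    first_order: bool = True
    max_cells: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.ld_window < 0:
            raise ValueError("ld_window must be >= 0")
        if self.ci_backend not in ("g2", "logistic", "linear"):
            raise ValueError(f"unknown ci_backend {self.ci_backend!r}")


@dataclass
class Blanket:
    """One round's selected markers with the evidence behind each admission."""

    members: list[int] = field(default_factory=list)
    admission_log: list[dict] = field(default_factory=list)
    removed_by_ld: dict[int, list[int]] = field(default_factory=dict)
    removed_by_backward: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _ci_test(
    data: GenotypeDataset, target: int, cond, params: SearchParams
) -> CITestResult:
    if params.ci_backend == "g2":
        try:
            return conditional_g2(data, target, cond, max_cells=params.max_cells)
        except TableTooLargeError as exc:
            return CITestResult(
                0.0, 0, 1.0, tuple(cond), "g2", reliable=False, reason=str(exc)
            )
    return regression_ci_test(data, target, cond, family=params.ci_backend)


def first_order_dependent(
    data: GenotypeDataset, candidate: int, members, params: SearchParams
) -> tuple[bool, float, list[CITestResult]]:
    """Is the candidate dependent on the phenotype given the blanket?

    With an empty blanket this is the marginal test. Otherwise one test
    per single member is run (or, in legacy full-conditioning mode, one
    test given all members); the candidate is dependent iff the worst
    (largest) reliable p-value is below ``params.alpha``. If every test
    is unreliable the candidate is treated as independent.

    Returns ``(is_dependent, worst_p, tests)``; ``worst_p`` is NaN when
    no test was reliable.
    """
    members = [m for m in members]
    if candidate in members:
        raise ValueError("candidate already in blanket")
    if not members:
        tests = [_ci_test(data, candidate, (), params)]
    elif params.first_order:
        tests = [_ci_test(data, candidate, (m,), params) for m in members]
    else:
        tests = [_ci_test(data, candidate, tuple(members), params)]
    ps = [t.p_value for t in tests if t.reliable]
    if not ps:
        return False, float("nan"), tests
    worst_p = max(ps)
    return worst_p < params.alpha, worst_p, tests


def forward_step(
    data: GenotypeDataset,
    pool,
    blanket: Blanket,
    params: SearchParams,
    marginal_p: dict[int, float] | None = None,
):
    """Examine the top-ranked remaining candidate and admit it if dependent.

    Candidates are ranked by marginal p-value (ties by lower marker
    index), the strongest single-marker association first. Only the
    best-ranked candidate is considered per step — if it fails the
    dependence criterion the forward phase ends, mirroring the
    grow-shrink convention that the phase stops once its top-scoring
    variable is conditionally independent of the target. Returns
    ``(marker, worst_p, tests)`` or ``None``.
    """
    ranked = sorted(
        (int(c) for c in pool),
        key=lambda c: (marginal_p.get(c, 1.0) if marginal_p else 1.0, c),
    )
    if not ranked:
        return None
    cand = ranked[0]
    dep, worst_p, tests = first_order_dependent(data, cand, blanket.members, params)
    if not dep:
        return None
    return cand, worst_p, tests


def backward_prune(
    data: GenotypeDataset, blanket: Blanket, params: SearchParams
) -> Blanket:
    """Remove members no longer dependent given the other members.

    Most-recently-admitted members are re-tested first; removal repeats
    until stable, so the operation is idempotent. Removed members are
    recorded in ``removed_by_backward`` and discarded (they do not
    return to the candidate pool).
    """
    changed = True
    while changed:
        changed = False
        for m in list(reversed(blanket.members)):
            others = [x for x in blanket.members if x != m]
            dep, _, _ = first_order_dependent(data, m, others, params)
            if not dep:
                pos = blanket.members.index(m)
                blanket.members.pop(pos)
                blanket.admission_log.pop(pos)
                blanket.removed_by_backward.append(m)
                changed = True
                break
    return blanket


def ld_prune(pool, admitted: int, genotypes: np.ndarray, params: SearchParams):
    """Drop pool markers in LD with the admitted one.

    A marker leaves the pool iff its position index is within
    ``ld_window`` of the admitted marker AND its genotype r² with it
    exceeds ``r2_threshold`` — both conditions are required. Returns
    ``(surviving_pool, removed)`` preserving pool order.
    """
    pool = [int(c) for c in pool]
    if admitted in pool:
        raise ValueError("admitted marker must already be out of the pool")
    if params.ld_window == 0 or not pool:
        return pool, []
    near = [c for c in pool if abs(c - admitted) <= params.ld_window]
    if not near:
        return pool, []
    a = genotypes[:, admitted].astype(float)
    removed = []
    for c in near:
        b = genotypes[:, c].astype(float)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r * r > params.r2_threshold:
            removed.append(c)
    surviving = [c for c in pool if c not in removed]
    return surviving, removed


def run_mb_round(
    data: GenotypeDataset,
    pool,
    params: SearchParams,
    marginal_p: dict[int, float] | None = None,
) -> tuple[Blanket, list[int], list[int]]:
    """One full fishing round over the candidate pool.

    Alternates forward admission, LD pruning of the pool around the
    admitted marker, and backward pruning of the blanket, until no
    further candidate is dependent. Returns ``(blanket,
    surviving_pool, pool_size_trace)`` where the trace records the pool
    size after each update.
    """
    pool = [int(c) for c in pool]
    blanket = Blanket()
    trace: list[int] = []
    while pool:
        step = forward_step(data, pool, blanket, params, marginal_p)
        if step is None:
            break
        admitted, worst_p, tests = step
        pool.remove(admitted)
        blanket.members.append(admitted)
        blanket.admission_log.append(
            {
                "marker": admitted,
                "worst_p": worst_p,
                "evidence": [
                    (t.conditioning_set, t.p_value, t.reliable) for t in tests
                ],
            }
        )
        pool, removed = ld_prune(pool, admitted, data.genotypes, params)
        if removed:
            blanket.removed_by_ld[admitted] = removed
        backward_prune(data, blanket, params)
        trace.append(len(pool))
    return blanket, pool, trace
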