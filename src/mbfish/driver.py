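"""The repeated-fishing loop: screen, fish, empty the net, re-fish.

A single Markov-blanket construction loses power as the blanket grows,
because every further admission must survive conditioning on the
members already caught. Repeated fishing removes each round's catch
from the candidate pool and rebuilds a fresh blanket from what remains:
weaker true signals that failed conditional tests in an earlier round
are admitted early in a later round, when the blanket is empty again.
The loop stops at the first round that catches no more than
``stop_size`` markers (or runs dry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .citests import ScreenResult, marginal_screen
from .dataset import GenotypeDataset
from .search import Blanket, SearchParams, run_mb_round

logger = logging.getLogger(__name__)

__all__ = ["MBRFSResult", "run_mbrfs", "run_single_mb_baseline"]


@dataclass
class MBRFSResult:
    """Outcome of a repeated-fishing run.

    ``rounds`` holds the reported blankets in fishing order (their
    member sets are pairwise disjoint); ``final_set`` is their sorted
    union; ``pool_trace`` records candidate-pool sizes after each
    update, starting with the screened pool.
    """

    rounds: list[Blanket] = field(default_factory=list)
    final_set: list[int] = field(default_factory=list)
    pool_trace: list[int] = field(default_factory=list)
    screen: ScreenResult | None = None
    params: SearchParams = field(default_factory=SearchParams)
    screen_alpha: float = 0.05
    stop_size: int = 2
    terminated_by: str = "pool_exhausted"

    @property
    def selected(self) -> list[int]:
        return self.final_set

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def run_mbrfs(
    data: GenotypeDataset,
    params: SearchParams | None = None,
    screen_alpha: float = 0.05,
    screen_test: str = "auto",
    stop_size: int = 2,
    include_terminal_round: bool = True,
    max_rounds: int = 50,
) -> MBRFSResult:
    """Run the full repeated-fishing selection on a dataset.

    The candidate pool is built by single-marker screening at
    ``screen_alpha``; rounds of MB construction then run until a round
    returns at most ``stop_size`` members (that terminal round is
    reported by default), an empty blanket, or an empty pool.
    ``max_rounds`` guards pathological inputs.
    """
    params = params or SearchParams()
    if data.n_markers < 2:
        return MBRFSResult(params=params, screen_alpha=screen_alpha,
                           stop_size=stop_size, terminated_by="degenerate_input")
    screen = marginal_screen(data, screen_alpha, test=screen_test)
    marginal_p = {int(j): float(p) for j, p in zip(screen.indices, screen.p_values)}
    pool = [int(j) for j in screen.indices]
    result = MBRFSResult(
        screen=screen, params=params, screen_alpha=screen_alpha, stop_size=stop_size
    )
    result.pool_trace.append(len(pool))
    terminated = "pool_exhausted"
    while pool:
        if len(result.rounds) >= max_rounds:
            logger.warning("run_mbrfs hit the %d-round cap", max_rounds)
            terminated = "round_cap"
            break
        blanket, pool, trace = run_mb_round(data, pool, params, marginal_p)
        result.pool_trace.extend(trace)
        if not blanket.members:
            terminated = "empty_blanket"
            break
        if len(blanket.members) <= stop_size:
            if include_terminal_round:
                result.rounds.append(blanket)
            terminated = "terminal_round"
            break
        result.rounds.append(blanket)
    result.terminated_by = terminated
    result.final_set = sorted({m for b in result.rounds for m in b.members})
    return result


def run_single_mb_baseline(
    data: GenotypeDataset,
    params: SearchParams | None = None,
    screen_alpha: float = 0.05,
    screen_test: str = "auto",
) -> MBRFSResult:
    """One blanket, no fishing loop — the legacy comparator.

    Runs exactly one MB construction round under full conditioning on
    all current members (the historical behaviour), so the stratified
    table grows exponentially with the blanket; tests whose projected
    table exceeds ``params.max_cells`` are refused and treated as
    uninformative, which is precisely the power pathology the fishing
    strategy avoids.
    """
    params = replace(params or SearchParams(), first_order=False)
    screen = marginal_screen(data, screen_alpha, test=screen_test)
    marginal_p = {int(j): float(p) for j, p in zip(screen.indices, screen.p_values)}
    pool = [int(j) for j in screen.indices]
    result = MBRFSResult(
        screen=screen, params=params, screen_alpha=screen_alpha, stop_size=0
    )
    result.pool_trace.append(len(pool))
    blanket, pool, trace = run_mb_round(data, pool, params, marginal_p)
    result.pool_trace.extend(trace)
    if blanket.members:
        result.rounds.append(blanket)
    refused = sum(
        1
        for log in blanket.admission_log
        for (_, _, reliable) in log["evidence"]
        if not reliable
    )
    if refused:
        logger.warning("single-MB baseline refused %d oversized tests", refused)
    result.terminated_by = "single_round"
    result.final_set = sorted(blanket.members)
    return result
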