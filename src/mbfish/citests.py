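"""Statistical test backends for the Markov-blanket search.

Three conditional-independence (CI) backends cover the data types met in
omics association studies:

* ``g2`` — likelihood-ratio chi-square G² = 2 Σ O ln(O/E) on stratified
  contingency tables, for categorical markers with a categorical
  phenotype (SNP dosages x case-control status). The degrees of freedom
  follow the product rule (Cat(A)−1)(Cat(B)−1)·∏Cat(Cᵢ), reduced for
  strata/margins with no data.
* ``logistic`` — Wald test of the target coefficient in a logistic
  model of a binary phenotype on the target plus conditioners
  (quantitative biomarkers, binary outcome).
* ``linear`` — the same for a quantitative phenotype via OLS.

Marginal screening (Cochran-Armitage trend or genotypic chi-square for
SNPs, the regression test otherwise) builds the initial candidate pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CITestResult",
    "TableTooLargeError",
    "DegenerateTableError",
    "g2_from_table",
    "conditional_g2",
    "regression_ci_test",
    "armitage_trend_test",
    "trend_test_all",
    "marginal_screen",
    "ScreenResult",
    "stratified_cell_count",
]


class TableTooLargeError(ValueError):
    """Projected stratified table exceeds the configured cell cap."""


class DegenerateTableError(ValueError):
    """No-test signal: the table carries no information (e.g. all zero)."""


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one (conditional) independence test.

    ``reliable`` is False when the test could not be trusted (too many
    near-empty expected cells, perfect separation, zero df); callers
    treat an unreliable test as uninformative, never as evidence of
    dependence.
    """

    statistic: float
    df: int
    p_value: float
    conditioning_set: tuple[int, ...] = ()
    method: str = "g2"
    reliable: bool = True
    reason: str | None = None


def stratified_cell_count(n_y_cats: int, n_target_cats: int, cond_cats) -> int:
    """Number of cells of the full stratified table Y x V | C₁..Cₙ."""
    cells = n_y_cats * n_target_cats
    for c in cond_cats:
        cells *= c
    return cells


def _g2_core(table: np.ndarray) -> tuple[float, int, np.ndarray]:
    """G², df and the expected-count array after dropping empty margins."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    t = t[np.ix_(rows, cols)]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0, np.empty((0, 0))
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    mask = t > 0  # O ln(O/E) := 0 when O = 0
    g2 = 2.0 * float(np.sum(t[mask] * np.log(t[mask] / expected[mask])))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return max(g2, 0.0), df, expected


def g2_from_table(observed) -> tuple[float, int]:
    """Likelihood-ratio G² statistic and df of a two-way count table.

    Rows/columns with zero margin are dropped and the df reduced
    accordingly; an all-zero table raises :class:`DegenerateTableError`
    (no test performed — distinct from a statistic of 0).
    """
    t = np.asarray(observed, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("observed must be at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t.sum() == 0:
        raise DegenerateTableError("all-zero table")
    g2, df, _ = _g2_core(t)
    return g2, df


def _codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Dense integer codes 0..k-1 and category count of a vector."""
    vals, codes = np.unique(x, return_inverse=True)
    return codes, len(vals)


def conditional_g2(
    data: GenotypeDataset,
    target_marker: int,
    conditioning_set=(),
    max_cells: int | None = None,
    min_expected_frac: float = 0.2,
) -> CITestResult:
    """Stratified G² test of phenotype vs one marker given other markers.

    The statistic sums per-stratum G² over the joint levels of the
    conditioning markers; df sums the per-stratum df after dropping
    empty margins (equal to the product rule when nothing is dropped).
    If more than ``min_expected_frac`` of the full table's cells have
    expected count below 1, the result is flagged unreliable — such a
    test has essentially no power and the caller should treat the pair
    as independent rather than trust its p-value.
    """
    cond = tuple(int(c) for c in conditioning_set)
    if target_marker in cond:
        raise ValueError("conditioning_set must not contain the target marker")
    y, n_y = _codes(data.phenotype)
    v, n_v = _codes(data.genotypes[:, target_marker])
    cond_counts = []
    strat = np.zeros(data.n_samples, dtype=np.int64)
    n_strata = 1
    for c in cond:
        cc, n_c = _codes(data.genotypes[:, c])
        cond_counts.append(n_c)
        strat = strat * n_c + cc
        n_strata *= n_c
    total_cells = stratified_cell_count(n_y, n_v, cond_counts)
    if max_cells is not None and total_cells > max_cells:
        raise TableTooLargeError(
            f"stratified table would have {total_cells} cells "
            f"(cap {max_cells}); conditioning on {len(cond)} markers"
        )
    # joint count cube: stratum x y x v
    code = (strat * n_y + y) * n_v + v
    counts = np.bincount(code, minlength=n_strata * n_y * n_v).reshape(
        n_strata, n_y, n_v
    )
    stat = 0.0
    df = 0
    n_ok_cells = 0
    for s in range(n_strata):
        g2_s, df_s, expected = _g2_core(counts[s])
        stat += g2_s
        df += df_s
        n_ok_cells += int((expected >= 1.0).sum())
    if df == 0:
        return CITestResult(
            0.0, 0, 1.0, cond, "g2", reliable=False, reason="no informative stratum"
        )
    frac_small = 1.0 - n_ok_cells / total_cells
    reliable = frac_small <= min_expected_frac
    p = float(stats.chi2.sf(stat, df))
    return CITestResult(
        stat,
        df,
        p,
        cond,
        "g2",
        reliable=reliable,
        reason=None if reliable else f"{frac_small:.0%} of expected cells < 1",
    )


def regression_ci_test(
    data: GenotypeDataset,
    target_marker: int,
    conditioning_set=(),
    family: str = "logistic",
) -> CITestResult:
    """Wald test of the target's coefficient given the conditioners.

    ``family='logistic'`` models a binary phenotype, ``'linear'`` a
    quantitative one; the statistic is the squared Wald z of the target
    coefficient (df 1). Perfect separation or collinearity yields an
    unreliable no-test result rather than an exception.
    """
    import statsmodels.api as sm

    cond = tuple(int(c) for c in conditioning_set)
    if target_marker in cond:
        raise ValueError("conditioning_set must not contain the target marker")
    y = np.asarray(data.phenotype, dtype=float)
    X = np.column_stack(
        [np.ones(data.n_samples)]
        + [data.genotypes[:, target_marker].astype(float)]
        + [data.genotypes[:, c].astype(float) for c in cond]
    )
    method = family
    try:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design (conditioner duplicates target?)")
        if family == "logistic":
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                raise ValueError("logistic fit did not converge")
        elif family == "linear":
            fit = sm.OLS(y, X).fit()
        else:
            raise ValueError(f"unknown family {family!r}")
        z = fit.params[1] / fit.bse[1]
        if not np.isfinite(z):
            raise ValueError("non-finite Wald statistic")
    except (ValueError, np.linalg.LinAlgError) as exc:
        if "unknown family" in str(exc):
            raise
        return CITestResult(
            0.0, 1, 1.0, cond, method, reliable=False, reason=str(exc)
        )
    stat = float(z * z)
    return CITestResult(stat, 1, float(stats.chi2.sf(stat, 1)), cond, method)


def armitage_trend_test(case_counts, control_counts) -> CITestResult:
    """Cochran-Armitage trend chi-square over genotype dosages 0/1/2.

    Scores are (0, 1, 2); one degree of freedom. Symmetric in the
    case/control labels.
    """
    r = np.asarray(case_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    if r.shape != (3,) or c.shape != (3,):
        raise ValueError("expected genotype count 3-vectors")
    n_i = r + c
    N = n_i.sum()
    if N == 0:
        raise DegenerateTableError("zero total count")
    R = r.sum()
    s = np.array([0.0, 1.0, 2.0])
    num = N * (s @ r) - R * (s @ n_i)
    den = R * (N - R) * (N * (s * s) @ n_i - (s @ n_i) ** 2)
    if den <= 0:
        return CITestResult(
            0.0, 1, 1.0, (), "trend", reliable=False, reason="zero trend variance"
        )
    stat = float(N * num * num / den)
    return CITestResult(stat, 1, float(stats.chi2.sf(stat, 1)), (), "trend")


def trend_test_all(genotypes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Armitage trend p-values for every marker column.

    Markers with zero trend variance (constant columns) get p = NaN.
    """
    y = np.asarray(y)
    g = np.asarray(genotypes)
    n, p = g.shape
    counts = np.zeros((2, 3, p))
    for yy in (0, 1):
        sub = g[y == yy]
        for gg in (0, 1, 2):
            counts[yy, gg] = (sub == gg).sum(axis=0)
    r, c = counts[1], counts[0]
    n_i = r + c
    N = n_i.sum(axis=0)
    R = r.sum(axis=0)
    s = np.array([0.0, 1.0, 2.0])[:, None]
    num = N * (s * r).sum(axis=0) - R * (s * n_i).sum(axis=0)
    den = R * (N - R) * (N * (s * s * n_i).sum(axis=0) - ((s * n_i).sum(axis=0)) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, N * num * num / np.maximum(den, 1e-300), np.nan)
    return np.where(np.isfinite(stat), stats.chi2.sf(stat, 1), np.nan)


@dataclass
class ScreenResult:
    """Candidate pool from marginal screening: indices ordered by ascending p."""

    indices: np.ndarray
    p_values: np.ndarray  # aligned with ``indices``
    alpha: float
    method: str
    skipped: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)

    def p_of(self, marker: int) -> float:
        pos = np.flatnonzero(self.indices == marker)
        return float(self.p_values[pos[0]]) if pos.size else 1.0


def marginal_screen(
    data: GenotypeDataset, alpha: float = 0.05, test: str = "auto"
) -> ScreenResult:
    """Single-marker screen: keep markers with unadjusted p < alpha.

    For integer-coded markers with a binary phenotype the default is the
    Armitage trend test (``test='genotypic'`` switches to the 2x3 G²);
    otherwise the appropriate regression test is used per marker.
    Constant markers are skipped with a log entry.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p = np.full(data.n_markers, np.nan)
    categorical = np.issubdtype(data.genotypes.dtype, np.integer)
    if test == "auto":
        test = "trend" if (categorical and data.is_binary_phenotype) else "regression"
    if test == "trend":
        p = trend_test_all(data.genotypes, data.phenotype)
        method = "trend"
    elif test == "genotypic":
        method = "g2"
        for j in range(data.n_markers):
            if np.unique(data.genotypes[:, j]).size < 2:
                continue
            res = conditional_g2(data, j)
            p[j] = res.p_value
    elif test == "regression":
        family = "logistic" if data.is_binary_phenotype else "linear"
        method = family
        for j in range(data.n_markers):
            if np.unique(data.genotypes[:, j]).size < 2:
                continue
            res = regression_ci_test(data, j, (), family)
            p[j] = res.p_value if res.reliable else np.nan
    else:
        raise ValueError(f"unknown screening test {test!r}")
    skipped = np.flatnonzero(~np.isfinite(p)).tolist()
    if skipped:
        logger.info("marginal_screen skipped %d constant/untestable markers", len(skipped))
    keep = np.flatnonzero(np.nan_to_num(p, nan=1.0) < alpha)
    order = keep[np.argsort(p[keep], kind="stable")]
    return ScreenResult(order, p[order], alpha, method, skipped)
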