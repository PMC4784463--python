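"""Synthetic GWAS-style data with block LD structure and a logistic disease model.

The generator emulates a miniature genome: 22 regions of 50 SNPs each
(configurable), with per-region linkage-disequilibrium regimes, and a
binary phenotype produced by a logistic model over a handful of causal
SNPs, from which a case-control study is sampled out of a large
population.

Genotypes are built from two latent-Gaussian haplotypes per individual.
High- and modest-LD regions use an exchangeable latent block (every
pair of markers at the calibrated r-squared, like a tight haplotype
block); low-LD regions use an AR(1)-style latent chain with decaying
long-range correlation. In both cases the latent correlation is
calibrated analytically (bivariate-normal orthant probability inverted
numerically) to hit the declared genotype r-squared, and summing two
independent haplotypes gives Hardy-Weinberg genotype frequencies by
construction.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special
from scipy.special import expit, ndtri

from .dataset import GenotypeDataset

__all__ = [
    "RegionSpec",
    "ScenarioSpec",
    "simulate_region",
    "simulate_phenotype",
    "sample_case_control",
    "make_scenario",
    "simulate_case_control_study",
    "scheme_defaults",
]

#: genotype r^2 targets for the named LD regimes (high/modest: every
#: pair in the block; low: adjacent pairs of the chain)
REGIME_R2 = {"high": 0.90, "modest": 0.45, "low": 0.10}

_LD_PROFILES = ("none", "low", "modest", "high", "ar1")


@dataclass(frozen=True)
class RegionSpec:
    """One genome region: a block of SNPs under a common LD regime.

    ``ld_profile`` is one of ``none`` (independent markers), ``low`` /
    ``modest`` / ``high`` (named r^2 regimes, see :data:`REGIME_R2`) or
    ``ar1`` (latent chain correlation given directly by ``ar1_rho``).
    ``maf_range`` bounds the minor allele
    frequencies; for ``high`` and ``modest`` profiles all markers in the
    region share a single MAF drawn from the range, because strongly
    mismatched allele frequencies cap the attainable r^2 well below the
    regime target.
    """

    n_markers: int = 50
    ld_profile: str = "low"
    maf_range: tuple[float, float] = (0.05, 0.5)
    ar1_rho: float | None = None

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.ld_profile not in _LD_PROFILES:
            raise ValueError(f"unknown ld_profile {self.ld_profile!r}")
        if self.ld_profile == "ar1" and self.ar1_rho is None:
            raise ValueError("ar1 profile requires ar1_rho")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered and within (0, 0.5]")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 < h, Z2 < k) for standard bivariate normal with correlation rho.

    Owen (1956) formula via Owen's T function.
    """
    if abs(rho) < 1e-12:
        return special.ndtr(h) * special.ndtr(k)
    if rho > 0.999999:
        return special.ndtr(min(h, k))
    if rho < -0.999999:
        return max(0.0, special.ndtr(h) + special.ndtr(k) - 1.0)
    # avoid division by zero at h == 0 or k == 0
    h = h if abs(h) > 1e-10 else 1e-10
    k = k if abs(k) > 1e-10 else 1e-10
    s = math.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * s)
    a2 = (h - rho * k) / (k * s)
    delta = 0.5 if h * k < 0 else 0.0
    return float(
        0.5 * (special.ndtr(h) + special.ndtr(k))
        - special.owens_t(h, a1)
        - special.owens_t(k, a2)
        - delta
    )


def _allele_corr(p1: float, p2: float, rho: float) -> float:
    """Correlation of threshold allele indicators under latent correlation rho."""
    z1, z2 = ndtri(p1), ndtri(p2)
    p11 = _bvn_cdf(z1, z2, rho)
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return (p11 - p1 * p2) / denom


@functools.lru_cache(maxsize=100_000)
def latent_rho_for_corr(p1: float, p2: float, target_r: float) -> float:
    """Latent-Gaussian correlation producing allele correlation ``target_r``.

    Inverted by bisection; clipped to the attainable range (unequal
    allele frequencies bound the correlation of binary indicators away
    from one).
    """
    if target_r == 0.0:
        return 0.0
    lo, hi = -0.99999, 0.99999
    f = lambda rho: _allele_corr(p1, p2, rho) - target_r
    if f(hi) <= 0:  # unattainable: saturate
        return hi
    if f(lo) >= 0:
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def _draw_mafs(spec: RegionSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.maf_range
    if spec.ld_profile in ("high", "modest"):
        maf = rng.uniform(lo, hi)
        mafs = np.full(spec.n_markers, maf)
    else:
        mafs = rng.uniform(lo, hi, size=spec.n_markers)
    # quantize so the pairwise calibration cache is effective
    return np.clip(np.round(mafs, 3), 0.005, 0.5)


def _chain_rhos(spec: RegionSpec, mafs: np.ndarray) -> np.ndarray:
    """Per-adjacent-pair latent correlations for chain-type LD profiles."""
    m = spec.n_markers
    if m < 2 or spec.ld_profile == "none":
        return np.zeros(max(m - 1, 0))
    if spec.ld_profile == "ar1":
        return np.full(m - 1, float(spec.ar1_rho))
    target_r = math.sqrt(REGIME_R2["low"])
    return np.array(
        [
            latent_rho_for_corr(float(mafs[j]), float(mafs[j + 1]), target_r)
            for j in range(m - 1)
        ]
    )


def _simulate_region(
    spec: RegionSpec, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (genotype block int8, per-marker MAFs).

    ``high`` and ``modest`` regimes are defined over (most) *pairs* in
    the region, so they use an exchangeable latent block — every pair
    of markers shares the same calibrated correlation, like a tight
    haplotype block. ``low``/``ar1`` use a latent chain with decaying
    long-range LD; ``none`` is independent columns.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    mafs = _draw_mafs(spec, rng)
    thresholds = ndtri(mafs)  # allele = 1 (minor) iff latent < threshold
    geno = np.zeros((n_samples, spec.n_markers), dtype=np.int8)
    if spec.ld_profile in ("high", "modest"):
        target_r = math.sqrt(REGIME_R2[spec.ld_profile])
        maf = float(mafs[0])  # shared within exchangeable blocks
        rho = latent_rho_for_corr(maf, maf, target_r)
        for _hap in range(2):
            shared = rng.standard_normal(n_samples)
            eps = rng.standard_normal((n_samples, spec.n_markers))
            z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * eps
            geno += z < thresholds[None, :]
        return geno, mafs
    rhos = _chain_rhos(spec, mafs)
    for _hap in range(2):
        z = rng.standard_normal(n_samples)
        geno[:, 0] += z < thresholds[0]
        for j in range(1, spec.n_markers):
            eps = rng.standard_normal(n_samples)
            z = rhos[j - 1] * z + math.sqrt(1.0 - rhos[j - 1] ** 2) * eps
            geno[:, j] += z < thresholds[j]
    return geno, mafs


def simulate_region(spec: RegionSpec, n_samples: int, rng_seed=0) -> np.ndarray:
    """Simulate one genotype block (``n_samples`` x ``spec.n_markers``).

    Values are additively coded minor-allele dosages in {0, 1, 2},
    Hardy-Weinberg by construction, with adjacent-pair r^2 in the
    regime declared by ``spec.ld_profile``.
    """
    rng = _as_rng(rng_seed)
    block, _ = _simulate_region(spec, n_samples, rng)
    return block


def _correlated_causal_block(
    mafs: np.ndarray, corr: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Mutually correlated causal SNPs via an exchangeable latent copula.

    The single latent correlation is calibrated so realized pairwise
    genotype correlation matches ``corr`` (exactly for equal MAFs).
    """
    k = len(mafs)
    thresholds = ndtri(mafs)
    mean_maf = float(np.round(mafs.mean(), 3))
    rho = latent_rho_for_corr(mean_maf, mean_maf, corr) if corr > 0 else 0.0
    geno = np.zeros((n_samples, k), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal(n_samples)
        eps = rng.standard_normal((n_samples, k))
        z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * eps
        geno += z < thresholds[None, :]
    return geno


def simulate_phenotype(
    genotypes: np.ndarray,
    causal_indices,
    causal_or,
    baseline_prevalence: float = 0.10,
    rng_seed=0,
) -> np.ndarray:
    """Binary phenotype from a logistic model over the causal dosages.

    ``P(Y=1 | G) = expit(alpha0 + sum_j log(OR_j) * G_j)`` with the
    intercept ``alpha0`` solved numerically so that the population
    prevalence equals ``baseline_prevalence``. Returns the
    full-population 0/1 phenotype, before any case-control sampling.
    """
    rng = _as_rng(rng_seed)
    if not (0 < baseline_prevalence < 1):
        raise ValueError("baseline_prevalence must be in (0, 1)")
    causal_indices = np.asarray(causal_indices, dtype=int)
    ors = np.asarray(causal_or, dtype=float)
    if causal_indices.shape != ors.shape:
        raise ValueError("causal_indices and causal_or must have equal length")
    if (ors <= 0).any():
        raise ValueError("odds ratios must be positive")
    if causal_indices.size and causal_indices.max() >= genotypes.shape[1]:
        raise ValueError("causal index out of range")
    score = genotypes[:, causal_indices].astype(float) @ np.log(ors)
    alpha0 = optimize.brentq(
        lambda a: expit(a + score).mean() - baseline_prevalence, -50.0, 50.0
    )
    return (rng.random(genotypes.shape[0]) < expit(alpha0 + score)).astype(np.int8)


def sample_case_control(
    population: GenotypeDataset, n_cases: int, n_controls: int, rng_seed=0
) -> GenotypeDataset:
    """Draw exactly ``n_cases`` cases and ``n_controls`` controls without
    replacement from a simulated population; truth indices are preserved."""
    rng = _as_rng(rng_seed)
    y = population.phenotype
    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if case_idx.size < n_cases:
        raise ValueError(
            f"population has {case_idx.size} cases, {n_cases} requested "
            f"(short by {n_cases - case_idx.size})"
        )
    if control_idx.size < n_controls:
        raise ValueError(
            f"population has {control_idx.size} controls, {n_controls} "
            f"requested (short by {n_controls - control_idx.size})"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ]
    )
    return GenotypeDataset(
        genotypes=population.genotypes[take],
        phenotype=y[take],
        marker_ids=list(population.marker_ids),
        truth=population.truth.copy(),
    )


def scheme_defaults(scenario_id: int, scheme_id: int) -> tuple[list[float], list[float]]:
    """Default (odds ratios, MAFs) of the causal SNPs for a scheme.

    Schemes: 1 — null (all OR 1); 2 — OR ladder 1.1..1.8; 3 — fixed OR
    1.3 with MAFs spread over 0.05..0.5; 4 — uniform weak effect (OR
    1.2). Scenario 4 uses three causal SNPs at OR 1.5 (null under
    scheme 1).
    """
    if scenario_id == 4:
        or_ = 1.0 if scheme_id == 1 else 1.5
        return [or_] * 3, [0.3] * 3
    if scheme_id == 1:
        return [1.0] * 8, [0.3] * 8
    if scheme_id == 2:
        return [round(1.1 + 0.1 * j, 1) for j in range(8)], [0.3] * 8
    if scheme_id == 3:
        return [1.3] * 8, np.round(np.linspace(0.05, 0.5, 8), 3).tolist()
    if scheme_id == 4:
        return [1.2] * 8, [0.3] * 8
    raise ValueError(f"undefined scheme {scheme_id}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulation study condition.

    Scenarios: 1 — causal SNPs mutually independent and LD-free
    (independently generated columns replacing one background column in
    each of 8 distinct regions); 2 — as 1 but causal SNPs pairwise
    correlated at ``causal_corr``; 3 — causal SNPs are in-block members
    sharing their region's LD; 4 — three regions (high / modest / low
    LD), one causal SNP each.
    """

    scenario_id: int
    scheme_id: int = 2
    n_cases: int = 1000
    n_controls: int = 1000
    causal_or: tuple[float, ...] | None = None
    causal_maf: tuple[float, ...] | None = None
    causal_corr: float | None = None
    population_size: int = 100_000
    prevalence: float = 0.10
    n_regions: int = 22
    markers_per_region: int = 50
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_id not in (1, 2, 3, 4):
            raise ValueError(f"undefined scenario {self.scenario_id}")
        ors, mafs = scheme_defaults(self.scenario_id, self.scheme_id)
        if self.causal_or is None:
            object.__setattr__(self, "causal_or", tuple(ors))
        if self.causal_maf is None:
            object.__setattr__(self, "causal_maf", tuple(mafs))
        if self.causal_corr is None:
            corr = 0.1 if self.scenario_id == 2 else 0.0
            object.__setattr__(self, "causal_corr", corr)
        if len(self.causal_or) != len(self.causal_maf):
            raise ValueError("causal_or and causal_maf must have equal length")
        if any(o <= 0 for o in self.causal_or):
            raise ValueError("odds ratios must be positive")
        if not (0 <= self.causal_corr < 1):
            raise ValueError("causal_corr must be in [0, 1)")
        n_causal = len(self.causal_or)
        if self.scenario_id == 4:
            if n_causal != 3:
                raise ValueError("scenario 4 uses exactly 3 causal SNPs")
        elif n_causal > self.n_regions:
            raise ValueError("more causal SNPs than regions")

    @property
    def n_causal(self) -> int:
        return len(self.causal_or)


_BACKGROUND_CYCLE = ("low", "modest", "high")


def _background_regions(spec: ScenarioSpec) -> list[RegionSpec]:
    if spec.scenario_id == 4:
        return [
            RegionSpec(spec.markers_per_region, prof, (m, m))
            for prof, m in zip(("high", "modest", "low"), spec.causal_maf)
        ]
    return [
        RegionSpec(
            spec.markers_per_region,
            _BACKGROUND_CYCLE[i % 3],
            spec.background_maf_range,
        )
        for i in range(spec.n_regions)
    ]


def make_scenario(spec: ScenarioSpec) -> GenotypeDataset:
    """Generate the full simulated population for one scenario/scheme.

    Returns the population-scale dataset (genotypes, phenotype, truth
    indices); use :func:`sample_case_control` or
    :func:`simulate_case_control_study` for the study sample.
    """
    return _make_scenario_core(spec, np.random.default_rng(spec.seed))


def _make_scenario_core(
    spec: ScenarioSpec, rng: np.random.Generator
) -> GenotypeDataset:
    n = spec.population_size
    regions = _background_regions(spec)
    k = spec.n_causal

    if spec.scenario_id == 4:
        causal_regions = np.arange(3)
    else:
        causal_regions = np.sort(
            rng.choice(spec.n_regions, size=k, replace=False)
        )
        if spec.scenario_id == 3:
            # causal SNPs are in-block: pin those regions to the scheme MAF
            for i, r in enumerate(causal_regions):
                m = spec.causal_maf[i]
                regions[r] = replace(regions[r], maf_range=(m, m))

    causal_pos_in_region = rng.integers(
        0, spec.markers_per_region, size=k
    )

    blocks = []
    for reg in regions:
        block, _ = _simulate_region(reg, n, rng)
        blocks.append(block)
    genotypes = np.concatenate(blocks, axis=1)

    truth = np.array(
        [
            r * spec.markers_per_region + p
            for r, p in zip(causal_regions, causal_pos_in_region)
        ],
        dtype=int,
    )

    if spec.scenario_id in (1, 2):
        # causal columns generated independently of the blocks replace
        # one background column per region: LD-free causal SNPs, total
        # marker count preserved
        mafs = np.asarray(spec.causal_maf)
        if spec.scenario_id == 2 and spec.causal_corr > 0:
            causal = _correlated_causal_block(mafs, spec.causal_corr, n, rng)
        else:
            causal = np.zeros((n, k), dtype=np.int8)
            for j in range(k):
                causal[:, j] = rng.binomial(2, mafs[j], size=n).astype(np.int8)
        genotypes[:, truth] = causal

    phenotype = simulate_phenotype(
        genotypes, truth, spec.causal_or, spec.prevalence, rng
    )
    marker_ids = [
        f"R{r + 1:02d}_S{s + 1:02d}"
        for r in range(len(regions))
        for s in range(spec.markers_per_region)
    ]
    return GenotypeDataset(genotypes, phenotype, marker_ids, truth)


def simulate_case_control_study(spec: ScenarioSpec) -> GenotypeDataset:
    """Population generation plus the case-control draw, end to end.

    A single seeded stream drives both stages, so one ``seed`` fully
    determines the study sample.
    """
    rng = np.random.default_rng(spec.seed)
    pop = _make_scenario_core(spec, rng)
    return sample_case_control(pop, spec.n_cases, spec.n_controls, rng)
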