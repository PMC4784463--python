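"""Shared fixtures: small deterministic datasets and a chain-structured
oracle where the Markov blanket of the phenotype is known by construction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from mbfish import GenotypeDataset


def make_chain_dataset(
    n: int = 20_000,
    flip: float = 0.05,
    beta: float = 0.6,
    seed: int = 0,
    extra_null: int = 0,
) -> GenotypeDataset:
    """Chain V -> C -> Y: Y depends on C only; V is a noisy copy of C.

    V's haplotype alleles are C's flipped independently with probability
    ``flip``, so V and C are in strong LD but Y is independent of V
    given C. The true Markov blanket of Y is {C}. Marker order:
    [V, C, nulls...].
    """
    rng = np.random.default_rng(seed)
    maf = 0.3
    c_hap = rng.random((n, 2)) < maf
    flips = rng.random((n, 2)) < flip
    v_hap = c_hap ^ flips
    C = c_hap.sum(axis=1).astype(np.int8)
    V = v_hap.sum(axis=1).astype(np.int8)
    y = (rng.random(n) < expit(-2.0 + beta * C)).astype(np.int8)
    cols = [V, C] + [
        rng.binomial(2, maf, size=n).astype(np.int8) for _ in range(extra_null)
    ]
    return GenotypeDataset(
        np.column_stack(cols), y, truth=np.array([1])
    )


@pytest.fixture
def chain_data() -> GenotypeDataset:
    return make_chain_dataset(seed=1)


@pytest.fixture
def small_null_dataset() -> GenotypeDataset:
    """60 independent SNPs, phenotype independent of all of them."""
    rng = np.random.default_rng(7)
    g = rng.binomial(2, 0.3, size=(800, 60)).astype(np.int8)
    y = rng.integers(0, 2, size=800).astype(np.int8)
    return GenotypeDataset(g, y)
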