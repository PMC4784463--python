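"""The universal in-memory container: samples x markers plus a phenotype.

Genotypes are additively coded minor-allele dosages (0/1/2). The same
container carries quantitative biomarker matrices (methylation betas,
expression, metabolite intensities); the MB search only cares about which
conditional-independence backend is appropriate for the column types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # sentinel for missing genotype in integer matrices


@dataclass
class GenotypeDataset:
    """Sample x marker matrix with a phenotype vector and simulation truth.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_markers)`` array. Integer 0/1/2 dosages for SNP
        data (``MISSING`` allowed before imputation); floats for
        quantitative biomarkers.
    phenotype
        Length ``n_samples``. Binary 0/1 for case-control designs, real
        valued for quantitative phenotypes.
    marker_ids
        Ordered marker labels. Marker order defines the index distance
        used by LD windows and false-positive-cluster gaps.
    truth
        Indices of the causal markers (empty for real data).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    truth: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        self.truth = np.asarray(self.truth, dtype=int)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D sample x marker matrix")
        n, p = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} samples"
            )
        if not self.marker_ids:
            self.marker_ids = [f"M{j}" for j in range(p)]
        if len(self.marker_ids) != p:
            raise ValueError("marker_ids length does not match marker count")
        if self.truth.size and (self.truth.min() < 0 or self.truth.max() >= p):
            raise ValueError("truth indices out of range")
        if np.issubdtype(self.genotypes.dtype, np.integer):
            vals = np.unique(self.genotypes)
            bad = vals[(vals != MISSING) & ((vals < 0) | (vals > 2))]
            if bad.size:
                raise ValueError(f"invalid genotype codes: {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_binary_phenotype(self) -> bool:
        vals = np.unique(self.phenotype)
        return vals.size <= 2 and np.isin(vals, [0, 1]).all()

    def marker(self, j: int) -> np.ndarray:
        return self.genotypes[:, j]
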