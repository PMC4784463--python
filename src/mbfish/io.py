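"""Readers and writers: VCF, PLINK ``.raw`` additive text, delimited
matrices, the truth-index sidecar, and YAML run configuration.

Conventions: VCF coordinates are 1-based as usual; internal marker
indices are 0-based, and marker order in the file defines the index
distance used by LD windows and false-positive-cluster gaps. VCF
genotypes become dosages 0/1/2 by counting ALT alleles; non-biallelic
sites are skipped (with a logged count). Markers missing in more than
5 % of samples are dropped; remaining missing values are imputed to
the marker mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import MISSING, GenotypeDataset
from .simulate import ScenarioSpec

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotype",
    "write_plink_raw",
    "write_matrix",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "load_scenario_config",
    "dump_scenario_config",
]

_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
MAX_MISSING_FRACTION = 0.05


def _impute_and_filter(
    geno: np.ndarray, marker_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    miss = geno == MISSING
    frac = miss.mean(axis=0)
    keep = frac <= MAX_MISSING_FRACTION
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d markers with > %.0f%% missingness",
                    dropped, 100 * MAX_MISSING_FRACTION)
    geno = geno[:, keep].copy()
    ids = [m for m, k in zip(marker_ids, keep) if k]
    for j in np.flatnonzero((geno == MISSING).any(axis=0)):
        col = geno[:, j]
        observed = col[col != MISSING]
        mode = np.bincount(observed, minlength=3).argmax()
        col[col == MISSING] = mode
    return geno, ids


def _read_vcf(path: str | Path) -> tuple[np.ndarray, list[str]]:
    from cyvcf2 import VCF

    cols, ids = [], []
    skipped = 0
    vcf = VCF(str(path))
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        dosage = np.empty(len(vcf.samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:2] if a >= 0]
            dosage[i] = sum(1 for a in alleles if a > 0) if len(alleles) == 2 else MISSING
        cols.append(dosage)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if skipped:
        logger.info("skipped %d non-biallelic VCF sites", skipped)
    if not cols:
        raise ValueError(f"no biallelic sites in {path}")
    return np.column_stack(cols), ids


def _read_plink_raw(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in df.columns if c.upper() in _RAW_META_COLS]
    snp_cols = [c for c in df.columns if c not in meta]
    geno = df[snp_cols].to_numpy()
    geno = np.where(np.isnan(geno.astype(float)), MISSING, geno).astype(np.int8)
    phen = None
    for c in meta:
        if c.upper() == "PHENOTYPE":
            phen = df[c].to_numpy(dtype=float)
            if set(np.unique(phen)) <= {1.0, 2.0}:  # PLINK 1/2 coding
                phen = phen - 1.0
    return geno, snp_cols, phen


def read_genotypes(
    path: str | Path,
    format: str = "matrix",
    phenotype: str | Path | None = None,
) -> GenotypeDataset:
    """Load a genotype/biomarker matrix as a :class:`GenotypeDataset`.

    ``format`` is one of ``vcf``, ``plink_raw`` or ``matrix`` (delimited
    samples x markers with a header row). ``phenotype`` names either a
    column of the matrix file or a separate one-value-per-line file;
    PLINK ``.raw`` files may instead carry their own PHENOTYPE column.
    """
    path = Path(path)
    phen = None
    if format == "vcf":
        geno, ids = _read_vcf(path)
    elif format == "plink_raw":
        geno, ids, phen = _read_plink_raw(path)
    elif format == "matrix":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if phenotype is not None:
            if str(phenotype) in df.columns:
                phen = df.pop(str(phenotype)).to_numpy(dtype=float)
                phenotype = None
            elif not Path(phenotype).exists():
                raise ValueError(
                    f"phenotype column {phenotype!r} not found in {path.name} "
                    "and no such file exists"
                )
        ids = list(df.columns)
        vals = df.to_numpy(dtype=float)
        if np.all(np.isnan(vals) | (vals == np.round(vals))):
            geno = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
        else:
            geno = vals  # quantitative biomarkers: no dosage coding
    else:
        raise ValueError(f"unknown format {format!r}")
    if phenotype is not None:
        phen = read_phenotype(phenotype)
    if phen is None:
        raise ValueError("no phenotype found: pass a column name or file")
    if np.issubdtype(np.asarray(geno).dtype, np.integer):
        geno, ids = _impute_and_filter(geno, ids)
    if set(np.unique(phen)) <= {0.0, 1.0}:
        phen = phen.astype(np.int8)
    return GenotypeDataset(geno, phen, ids)


def read_phenotype(path: str | Path) -> np.ndarray:
    """One phenotype value per line (optionally with a header line)."""
    lines = Path(path).read_text().split()
    try:
        float(lines[0])
    except ValueError:
        lines = lines[1:]
    return np.asarray([float(x) for x in lines])


def write_plink_raw(data: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset as PLINK ``.raw``-style additive text."""
    n = data.n_samples
    df = pd.DataFrame(
        {
            "FID": [f"F{i}" for i in range(n)],
            "IID": [f"I{i}" for i in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": data.phenotype,
        }
    )
    geno = pd.DataFrame(data.genotypes, columns=data.marker_ids)
    pd.concat([df, geno], axis=1).to_csv(path, sep=" ", index=False)


def write_matrix(
    data: GenotypeDataset, path: str | Path, phenotype_col: str = "PHENOTYPE"
) -> None:
    """Delimited matrix (TSV/CSV by extension) with a phenotype column."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(data.genotypes, columns=data.marker_ids)
    df.insert(0, phenotype_col, data.phenotype)
    df.to_csv(path, sep=sep, index=False)


def write_truth_sidecar(data: GenotypeDataset, path: str | Path, **provenance) -> None:
    """JSON sidecar with the causal indices/ids plus provenance fields."""
    payload = {
        "truth_indices": [int(t) for t in data.truth],
        "truth_ids": [data.marker_ids[t] for t in data.truth],
        "n_markers": data.n_markers,
        **provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_truth_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_scenario_config(path: str | Path) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a YAML file mirroring its fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("causal_or", "causal_maf", "maf_range", "background_maf_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return ScenarioSpec(**raw)


def dump_scenario_config(spec: ScenarioSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(spec), sort_keys=False))
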