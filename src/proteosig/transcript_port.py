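"""Port a frozen protein signature to probe-level transcriptomics data:
best-probe selection by coefficient of variation, receptor-based sample
filtering, and per-gene median normalization to discovery medians.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, QuantMatrix
from .prm_quant import quantile_split
from .resources import PROTEIN_TO_GENE
from .signature import SignatureModel
from .survstats import GroupComparison, compare_groups

__all__ = [
    "ProbeMatrix",
    "select_probe_per_gene",
    "filter_tnbc",
    "median_normalize_to_discovery",
    "validate_transcriptomics",
]

log = logging.getLogger(__name__)


@dataclass
class ProbeMatrix:
    """Probes x samples expression on the native (log2 array) scale."""

    values: pd.DataFrame          # index = probe ids, columns = sample ids
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        unmapped = [p for p in self.values.index if p not in self.probe_to_gene]
        if unmapped:
            raise ValueError(f"probes without a gene mapping: {unmapped[:10]}")


def select_probe_per_gene(pm: ProbeMatrix) -> pd.DataFrame:
    """Per gene, keep the probe with the largest CV = SD/mean across samples.

    Probes with non-positive mean on the native scale have undefined CV and
    are skipped with a warning. CV ties break to the lexicographically
    smallest probe id. Single-probe genes pass through unchanged.
    """
    means = pm.values.mean(axis=1)
    sds = pm.values.std(axis=1, ddof=1)
    best: dict[str, tuple[float, str]] = {}
    for probe in sorted(pm.values.index):
        gene = pm.probe_to_gene[probe]
        if means[probe] <= 0:
            warnings.warn(
                f"probe {probe} has non-positive mean; CV undefined, skipped",
                stacklevel=2,
            )
            continue
        cv = sds[probe] / means[probe]
        if gene not in best or cv > best[gene][0]:
            best[gene] = (cv, probe)
    genes = sorted(best)
    out = pm.values.loc[[best[g][1] for g in genes]].copy()
    out.index = genes
    out.index.name = "gene"
    return out


def filter_tnbc(
    gm: pd.DataFrame,
    esr1_threshold: float = 12.0,
    erbb2_threshold: float = 11.8,
) -> list[str]:
    """Samples passing the receptor filter.

    Excludes any sample with ESR1 strictly above ``esr1_threshold`` or
    ERBB2 strictly above ``erbb2_threshold``; boundary values are kept.
    """
    for gene in ("ESR1", "ERBB2"):
        if gene not in gm.index:
            raise ValueError(f"{gene} row required for the receptor filter")
    keep = (gm.loc["ESR1"] <= esr1_threshold) & (gm.loc["ERBB2"] <= erbb2_threshold)
    kept = list(gm.columns[keep])
    if not kept:
        warnings.warn("receptor filter excluded every sample", stacklevel=2)
    return kept


def median_normalize_to_discovery(
    gm: pd.DataFrame, discovery_medians: dict[str, float]
) -> pd.DataFrame:
    """Shift each gene so its cohort median equals the discovery median.

    Genes absent from the discovery medians are dropped with a warning.
    Idempotent for fixed discovery medians.
    """
    present = [g for g in gm.index if g in discovery_medians]
    dropped = [g for g in gm.index if g not in discovery_medians]
    if dropped:
        warnings.warn(
            f"genes without discovery medians dropped: {dropped[:10]}",
            stacklevel=2,
        )
    out = gm.loc[present].copy()
    for g in present:
        out.loc[g] = gm.loc[g] - gm.loc[g].median() + discovery_medians[g]
    return out


def validate_transcriptomics(
    model: SignatureModel,
    gm: pd.DataFrame,
    clin: ClinicalTable,
    cutoff_fraction: float = 0.5,
    protein_to_gene: dict[str, str] | None = None,
) -> tuple[GroupComparison, np.ndarray]:
    """Score a gene-level matrix with a frozen protein signature.

    Model proteins map to gene symbols (shipped fixture map by default);
    genes are cohort-standardized, scored with frozen loadings, and split
    at the stated fraction of the validation score distribution.
    """
    if protein_to_gene is None:
        protein_to_gene = PROTEIN_TO_GENE
    unmapped = [p for p in model.protein_ids if p not in protein_to_gene]
    if unmapped:
        raise ValueError(f"model proteins without gene mapping: {unmapped}")
    genes = [protein_to_gene[p] for p in model.protein_ids]
    missing = [g for g in genes if g not in gm.index]
    if missing:
        raise ValueError(f"genes missing from matrix: {missing}")
    block = gm.loc[genes].to_numpy(dtype=float)
    means = block.mean(axis=1)
    sds = block.std(axis=1, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero-variance gene in validation cohort")
    z = (block - means[:, None]) / sds[:, None]
    score = model.loading @ z
    high = quantile_split(score, cutoff_fraction)
    clin = clin.align_to(list(gm.columns))
    return compare_groups(high, clin.time, clin.event), high


def gene_matrix_from_quant(m: QuantMatrix) -> pd.DataFrame:
    """Convenience view of a QuantMatrix as a gene-indexed DataFrame."""
    return m.to_frame()
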