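"""Targeted (PRM) quantification: light/heavy ratio computation from
transition areas and frozen-model validation on the resulting matrix.

A peptide's value in a sample is ``log2(sum(light ion areas) / sum(heavy
ion areas))``; either channel summing to zero leaves the cell missing with
a QC flag. Peptides aggregate to proteins by the median (robust to one
interfered peptide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, QuantMatrix
from .signature import SignatureModel
from .survstats import GroupComparison, compare_groups

__all__ = [
    "PeptideRatioMatrix",
    "read_transition_table",
    "compute_lh_ratios",
    "aggregate_to_protein",
    "validate_prm",
    "quantile_split",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("peptide", "protein", "sample", "channel", "ion", "area")

# Skyline-export header synonyms, case-insensitive
_SKYLINE_ALIASES = {
    "peptide": ("peptide", "peptide sequence", "peptide modified sequence"),
    "protein": ("protein", "protein name"),
    "sample": ("sample", "replicate", "replicate name"),
    "channel": ("channel", "isotope label", "isotope label type"),
    "ion": ("ion", "fragment ion"),
    "area": ("area", "total area fragment"),
}


@dataclass
class PeptideRatioMatrix:
    """Peptides x samples log2(L/H) values with a peptide->protein map."""

    peptide_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # NaN = missing
    peptide_to_protein: dict[str, str]
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peptide_ids), len(self.sample_ids)):
            raise ValueError("values shape disagrees with peptide/sample ids")


def read_transition_table(path: str | Path) -> pd.DataFrame:
    """Load a long-format transition table, tolerating Skyline headers."""
    path = Path(path)
    sep = "\t"
    with open(path, "r", encoding="utf-8") as fh:
        if "\t" not in fh.readline():
            sep = ","
    df = pd.read_csv(path, sep=sep)
    rename = {}
    lower = {c.lower(): c for c in df.columns}
    for canon, aliases in _SKYLINE_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                break
        else:
            raise ValueError(f"transition table missing a {canon!r} column")
    df = df.rename(columns=rename)[list(REQUIRED_COLUMNS)]
    df["channel"] = df["channel"].str.lower()
    if not df["channel"].isin(("light", "heavy")).all():
        raise ValueError("channel must be 'light' or 'heavy'")
    if (df["area"] < 0).any():
        raise ValueError("negative transition areas")
    dupes = df.duplicated(subset=["peptide", "sample", "channel", "ion"])
    if dupes.any():
        raise ValueError("duplicate (peptide, sample, channel, ion) rows")
    return df


def compute_lh_ratios(transitions: pd.DataFrame) -> PeptideRatioMatrix:
    """Summed-area light/heavy ratios per (peptide, sample), log2 scale."""
    df = transitions
    missing_cols = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"transition table missing columns: {missing_cols}")
    pep_protein = df.drop_duplicates("peptide").set_index("peptide")["protein"]
    conflicts = df.groupby("peptide")["protein"].nunique()
    if (conflicts > 1).any():
        bad = list(conflicts[conflicts > 1].index)
        raise ValueError(f"peptides mapped to multiple proteins: {bad}")

    sums = (
        df.groupby(["peptide", "sample", "channel"])["area"].sum().unstack("channel")
    )
    for ch in ("light", "heavy"):
        if ch not in sums.columns:
            sums[ch] = np.nan

    peptides = sorted(df["peptide"].unique())
    samples = sorted(df["sample"].unique())
    values = np.full((len(peptides), len(samples)), np.nan)
    flags: list[str] = []
    pidx = {p: i for i, p in enumerate(peptides)}
    sidx = {s: j for j, s in enumerate(samples)}
    for (pep, sample), row in sums.iterrows():
        light, heavy = row["light"], row["heavy"]
        if not np.isfinite(light) or not np.isfinite(heavy):
            flags.append(f"{pep}/{sample}: channel absent")
            continue
        if heavy == 0:
            flags.append(f"{pep}/{sample}: heavy sum is zero")
            continue
        if light == 0:
            flags.append(f"{pep}/{sample}: light sum is zero")
            continue
        values[pidx[pep], sidx[sample]] = np.log2(light / heavy)
    for flag in flags:
        log.info("PRM QC: %s", flag)
    return PeptideRatioMatrix(
        peptide_ids=peptides,
        sample_ids=samples,
        values=values,
        peptide_to_protein=dict(pep_protein),
        qc_flags=flags,
    )


def aggregate_to_protein(
    pr: PeptideRatioMatrix, method: str = "median"
) -> QuantMatrix:
    """Per protein/sample aggregate of available peptide log-ratios.

    Missing output iff every contributing peptide is missing — the
    aggregation never manufactures values.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    agg = np.nanmedian if method == "median" else np.nanmean
    proteins = sorted(set(pr.peptide_to_protein.values()))
    values = np.full((len(proteins), len(pr.sample_ids)), np.nan)
    for i, prot in enumerate(proteins):
        rows = [
            k for k, pep in enumerate(pr.peptide_ids)
            if pr.peptide_to_protein[pep] == prot
        ]
        block = pr.values[rows]
        with np.errstate(invalid="ignore"):
            has_any = ~np.all(np.isnan(block), axis=0)
            values[i, has_any] = agg(block[:, has_any], axis=0)
    return QuantMatrix(
        protein_ids=proteins,
        sample_ids=list(pr.sample_ids),
        values=values,
        missing_mask=np.isnan(values),
        unique_peptides=np.array(
            [sum(1 for p in pr.peptide_to_protein.values() if p == prot)
             for prot in proteins]
        ),
    )


def quantile_split(scores: np.ndarray, low_fraction: float) -> np.ndarray:
    """Rank-based split: the ``ceil(f*n)`` smallest scores are low risk."""
    n = scores.size
    k = max(1, min(n, ceil(low_fraction * n)))
    cutoff = np.sort(scores)[k - 1]
    return scores > cutoff


def validate_prm(
    model: SignatureModel,
    protein_matrix: QuantMatrix,
    clin: ClinicalTable,
    cutoff_fraction: float = 0.7,
) -> tuple[GroupComparison, np.ndarray]:
    """Apply a frozen signature to a PRM cohort.

    Cross-platform transfer rule: each model protein is re-standardized
    within the validation cohort (cohort z-score), scored with the frozen
    loadings, and split at the stated fraction's rank quantile of the
    validation score distribution. Loadings are never refit.
    """
    idx = protein_matrix.protein_index(model.protein_ids)
    block = protein_matrix.values[idx]
    if np.isnan(block).any():
        raise ValueError("model proteins have missing values in PRM matrix")
    means = block.mean(axis=1)
    sds = block.std(axis=1, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero-variance model protein in PRM cohort")
    z = (block - means[:, None]) / sds[:, None]
    score = model.loading @ z
    high = quantile_split(score, cutoff_fraction)
    clin = clin.align_to(protein_matrix.sample_ids)
    return compare_groups(high, clin.time, clin.event), high
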