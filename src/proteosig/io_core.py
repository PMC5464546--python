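"""Readers/writers for the pipeline's tabular formats, configuration and manifests.

Canonical on-disk formats are tab-separated UTF-8 text. A quantification
matrix is proteins x samples with the first column holding protein
accessions; a ``unique_peptides`` column is optional, and batch labels live
in a two-column sidecar. Zero or empty intensity cells mean "not
quantified" and are loaded as missing (mask true, value NaN).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QuantMatrix",
    "ClinicalTable",
    "RunConfig",
    "read_quant_matrix",
    "write_quant_matrix",
    "read_clinical",
    "write_clinical",
    "write_manifest",
]

T_STAGES = ("T1", "T2", "T3", "T4", "multifocal", "unknown")
N_STAGES = ("N0", "N1", "N2", "N3", "Nx", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular contract."""


@dataclass
class QuantMatrix:
    """Protein-by-sample quantification matrix with missingness mask.

    ``values`` hold raw intensities before :func:`~proteosig.preprocess.log2_transform`
    and log2 intensities after; masked entries are NaN. ``missing_mask`` is
    True where the protein was not detected in the sample.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    unique_peptides: np.ndarray
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.unique_peptides = np.asarray(self.unique_peptides, dtype=int)
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
        p, n = len(self.protein_ids), len(self.sample_ids)
        if self.values.shape != (p, n):
            raise ValueError(
                f"values shape {self.values.shape} != ({p}, {n})"
            )
        if self.missing_mask.shape != (p, n):
            raise ValueError(
                f"missing_mask shape {self.missing_mask.shape} != ({p}, {n})"
            )
        if self.unique_peptides.shape != (p,):
            raise ValueError("unique_peptides must have one entry per protein")
        if np.any(self.unique_peptides < 0):
            raise ValueError("unique_peptides must be non-negative")
        if self.batch is not None and self.batch.shape != (n,):
            raise ValueError("batch must have one label per sample")
        if len(set(self.protein_ids)) != p:
            raise ValueError("duplicate protein IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            unique_peptides=self.unique_peptides.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )

    def protein_index(self, protein_ids: Sequence[str]) -> np.ndarray:
        """Row indices for the given accessions; errors list the missing ones."""
        lookup = {p: i for i, p in enumerate(self.protein_ids)}
        missing = [p for p in protein_ids if p not in lookup]
        if missing:
            raise KeyError(f"proteins not in matrix: {', '.join(missing)}")
        return np.array([lookup[p] for p in protein_ids], dtype=int)

    def subset_proteins(self, keep: np.ndarray) -> "QuantMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return QuantMatrix(
            protein_ids=[self.protein_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            values=self.values[keep],
            missing_mask=self.missing_mask[keep],
            unique_peptides=self.unique_peptides[keep],
            batch=self.batch,
        )

    def subset_samples(self, keep: np.ndarray) -> "QuantMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return QuantMatrix(
            protein_ids=list(self.protein_ids),
            sample_ids=[self.sample_ids[j] for j in keep],
            values=self.values[:, keep],
            missing_mask=self.missing_mask[:, keep],
            unique_peptides=self.unique_peptides,
            batch=None if self.batch is None else self.batch[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )
        df.index.name = "protein_id"
        return df


@dataclass
class ClinicalTable:
    """Per-sample distant-metastasis-free survival outcome and staging."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    t_stage: list[str] = field(default_factory=list)
    n_stage: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs in clinical table")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event must have one entry per sample")
        if np.any(self.time <= 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(self.time <= 0)]
            raise ValueError(f"non-positive follow-up time for: {', '.join(bad)}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if not self.t_stage:
            self.t_stage = ["unknown"] * n
        if not self.n_stage:
            self.n_stage = ["unknown"] * n
        if len(self.t_stage) != n or len(self.n_stage) != n:
            raise ValueError("stage columns must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def align_to(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        """Reorder rows to match ``sample_ids`` (join by ID, never by order)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(
                f"samples missing from clinical table: {', '.join(missing)}"
            )
        idx = [lookup[s] for s in sample_ids]
        return ClinicalTable(
            sample_ids=list(sample_ids),
            time=self.time[idx],
            event=self.event[idx],
            t_stage=[self.t_stage[i] for i in idx],
            n_stage=[self.n_stage[i] for i in idx],
        )


@dataclass
class RunConfig:
    """Pipeline thresholds and knobs; every analysis stage reads from here."""

    min_unique_peptides: int = 2
    min_detect_frac: float = 0.75
    screen_alpha: float = 0.01
    corr_threshold: float = 0.5
    profile_size_min: int = 3
    profile_size_max: int = 7
    n_profiles: int = 12
    cutoff_fraction: float = 0.5
    n_permutations: int = 1000
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    rng_seed: int = 0
    quant_path: str | None = None
    clinical_path: str | None = None
    batch_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_detect_frac", "screen_alpha", "cutoff_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_unique_peptides", "n_profiles", "n_permutations",
                     "profile_size_min", "profile_size_max"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        if self.profile_size_min > self.profile_size_max:
            raise ValueError("profile_size_min > profile_size_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# quantification matrix IO


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_quant_matrix(
    path: str | Path,
    dialect: str = "plain",
    batch_path: str | Path | None = None,
) -> QuantMatrix:
    """Load a proteins x samples intensity table.

    ``plain`` expects a ``protein_id`` first column, optional
    ``unique_peptides`` column, and one numeric column per sample.
    ``maxquant_like`` expects MaxQuant proteinGroups conventions:
    ``Majority protein IDs`` (or ``Protein IDs``), ``Unique peptides`` and
    ``LFQ intensity <sample>`` columns.

    Zeros and empty cells become missing entries; everything else must be
    numeric (hard error naming the offending row/column).
    """
    path = Path(path)
    if dialect not in ("plain", "maxquant_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        raise FormatError("duplicate sample column names")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if dialect == "maxquant_like":
        id_col = next(
            (c for c in ("Majority protein IDs", "Protein IDs") if c in df.columns),
            None,
        )
        if id_col is None:
            raise FormatError("no protein ID column (Majority protein IDs)")
        pep_col = "Unique peptides" if "Unique peptides" in df.columns else None
        sample_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
        sample_names = [c[len("LFQ intensity "):] for c in sample_cols]
        protein_ids = [v.split(";")[0] for v in df[id_col]]
    else:
        id_col = df.columns[0]
        pep_col = "unique_peptides" if "unique_peptides" in df.columns else None
        sample_cols = [c for c in df.columns[1:] if c != "unique_peptides"]
        sample_names = list(sample_cols)
        protein_ids = list(df[id_col])

    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    if len(set(protein_ids)) != len(protein_ids):
        dupes = pd.Series(protein_ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise FormatError(f"duplicate protein IDs: {', '.join(dupes)}")
    if len(set(sample_names)) != len(sample_names):
        raise FormatError("duplicate sample column names")

    p, n = len(protein_ids), len(sample_names)
    values = np.full((p, n), np.nan)
    mask = np.ones((p, n), dtype=bool)
    for j, col in enumerate(sample_cols):
        raw = df[col].str.strip()
        empty = raw == ""
        numeric = pd.to_numeric(raw.where(~empty, "0"), errors="coerce")
        if numeric.isna().any():
            i = int(numeric.isna().idxmax())
            raise FormatError(
                f"non-numeric intensity {raw.iloc[i]!r} at protein "
                f"{protein_ids[i]!r}, column {col!r}"
            )
        vals = numeric.to_numpy(dtype=float)
        present = ~empty.to_numpy() & (vals != 0.0)
        values[present, j] = vals[present]
        mask[:, j] = ~present

    if pep_col is not None:
        peps = pd.to_numeric(df[pep_col], errors="coerce")
        if peps.isna().any():
            i = int(peps.isna().idxmax())
            raise FormatError(
                f"non-numeric unique-peptide count at protein {protein_ids[i]!r}"
            )
        unique_peptides = peps.to_numpy(dtype=int)
    else:
        unique_peptides = np.zeros(p, dtype=int)

    batch = None
    if batch_path is not None:
        batch = _read_batch_sidecar(batch_path, sample_names)

    return QuantMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_names,
        values=values,
        missing_mask=mask,
        unique_peptides=unique_peptides,
        batch=batch,
    )


def _read_batch_sidecar(path: str | Path, sample_ids: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype=str)
    if "sample" not in df.columns or "batch" not in df.columns:
        raise FormatError("batch sidecar needs 'sample' and 'batch' columns")
    lookup = dict(zip(df["sample"], df["batch"]))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise FormatError(
            f"samples missing from batch sidecar: {', '.join(missing)}"
        )
    return np.array([lookup[s] for s in sample_ids], dtype=object)


def write_quant_matrix(m: QuantMatrix, path: str | Path) -> None:
    """Write the plain TSV dialect; masked entries become empty cells."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "unique_peptides", *m.sample_ids])
        for i, pid in enumerate(m.protein_ids):
            row: list[str] = [pid, str(int(m.unique_peptides[i]))]
            for j in range(m.n_samples):
                if m.missing_mask[i, j]:
                    row.append("")
                else:
                    row.append(repr(float(m.values[i, j])))
            writer.writerow(row)
    if m.batch is not None:
        sidecar = path.with_suffix(path.suffix + ".batch")
        with open(sidecar, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample", "batch"])
            for s, b in zip(m.sample_ids, m.batch):
                writer.writerow([s, str(b)])


# ---------------------------------------------------------------------------
# clinical table IO


def read_clinical(path: str | Path) -> ClinicalTable:
    """Load a clinical TSV with columns sample, time, event (+ t_stage, n_stage)."""
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype=str)
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing column {col!r}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    if time.isna().any():
        raise FormatError("non-numeric time value in clinical table")
    if event.isna().any() or not event.isin((0, 1)).all():
        raise FormatError("event must be 0 or 1 for every sample")
    t_stage = list(df["t_stage"]) if "t_stage" in df.columns else []
    n_stage = list(df["n_stage"]) if "n_stage" in df.columns else []
    return ClinicalTable(
        sample_ids=list(df["sample"]),
        time=time.to_numpy(dtype=float),
        event=event.to_numpy(dtype=int),
        t_stage=t_stage,
        n_stage=n_stage,
    )


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": clin.sample_ids,
            "time": clin.time,
            "event": clin.event,
            "t_stage": clin.t_stage,
            "n_stage": clin.n_stage,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_manifest(
    path: str | Path,
    config: RunConfig,
    stages: list[dict],
    version: str,
) -> None:
    """Record what a run did: config hash, seed, and stage-by-stage counts."""
    manifest = {
        "config_hash": config.digest(),
        "seed": config.rng_seed,
        "package_version": version,
        "stages": stages,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
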