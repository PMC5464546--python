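"""Synthetic cohorts with the statistical structure the pipeline assumes.

One seeded generator drives everything: correlated log2 protein blocks, a
planted prognostic protein set whose latent score scales an exponential
hazard, intensity-dependent (left-censored) missingness, additive batch
shifts, peptide-level PRM transition areas and probe-level arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, QuantMatrix

__all__ = ["SimSpec", "CohortTruth", "simulate_cohort", "simulate_prm_cohort",
           "simulate_array_cohort"]


@dataclass
class SimSpec:
    """Parameters of a simulated discovery-style cohort."""

    n_samples: int = 100
    n_proteins: int = 500
    n_prognostic: int = 10
    beta_per_sd: float = 0.7
    baseline_hazard: float = 0.1   # events / year
    censor_rate: float = 0.1       # censorings / year
    missing_intercept: float = 21.0
    missing_slope: float = 1.0     # per log2 unit; 0 disables MNAR shape
    batch_shift: float = 0.0       # additive log2 offset between batches
    n_batches: int = 1
    corr_block_size: int = 10
    corr_rho: float = 0.5
    mean_log2: float = 25.0
    sd_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prognostic > self.n_proteins:
            raise ValueError("n_prognostic cannot exceed n_proteins")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("hazard rates must be positive")
        if not 0.0 <= self.corr_rho < 1.0:
            raise ValueError("corr_rho must be in [0, 1)")
        if self.n_batches < 1 or self.corr_block_size < 1:
            raise ValueError("n_batches and corr_block_size must be >= 1")


@dataclass
class CohortTruth:
    """Ground truth retained for downstream validation simulators."""

    planted_proteins: list[str]
    latent: np.ndarray                 # standardized per-sample latent score
    log2_true: np.ndarray              # proteins x samples, pre-batch pre-mask
    protein_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


def _block_correlated_normals(
    rng: np.random.Generator, p: int, n: int, block: int, rho: float
) -> np.ndarray:
    """(p, n) standard normals, equicorrelated rho within consecutive blocks."""
    z = rng.standard_normal((p, n))
    if rho == 0.0:
        return z
    n_blocks = -(-p // block)
    shared = rng.standard_normal((n_blocks, n))
    shared_full = np.repeat(shared, block, axis=0)[:p]
    return np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * z


def _protein_latent_corr(k: int, block: int, rho: float) -> float:
    """Correlation between one planted protein and the planted average.

    Planted proteins fill consecutive equicorrelated blocks of size
    ``block`` with within-block correlation ``rho`` and zero across
    blocks; both the variance of the average and the covariance of a
    member with it follow in closed form.
    """
    if k == 1:
        return 1.0
    sizes = [block] * (k // block)
    if k % block:
        sizes.append(k % block)
    var_sum = sum(b + b * (b - 1) * rho for b in sizes)
    var_mean = var_sum / k**2
    b_own = sizes[0] if k >= block else k
    cov = (1 + (b_own - 1) * rho) / k
    return cov / np.sqrt(var_mean)


def simulate_cohort(spec: SimSpec) -> tuple[QuantMatrix, ClinicalTable, CohortTruth]:
    """Draw a raw-intensity cohort plus outcomes driven by a planted score.

    The planted proteins occupy the first rows (and hence share correlation
    blocks); the latent score is their standardized average deviation, and
    event times are exponential with hazard
    ``baseline_hazard * exp(beta_per_sd * latent)`` against an independent
    exponential censoring clock. Missingness follows
    ``P(missing) = logistic(missing_intercept - missing_slope * log2_value)``
    so low-abundance entries vanish preferentially.
    """
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_proteins, spec.n_samples
    protein_ids = [f"PROT{i:05d}" for i in range(p)]
    sample_ids = [f"S{j:04d}" for j in range(n)]

    mu = rng.normal(spec.mean_log2, 2.0, size=p)
    z = _block_correlated_normals(rng, p, n, spec.corr_block_size, spec.corr_rho)
    log2_true = mu[:, None] + spec.sd_log2 * z

    planted = protein_ids[: spec.n_prognostic]
    if spec.n_prognostic > 0:
        latent_raw = z[: spec.n_prognostic].mean(axis=0)
        latent = (latent_raw - latent_raw.mean()) / latent_raw.std(ddof=1)
        # beta_per_sd is the marginal log hazard per 1 SD of a planted
        # protein; the latent (average) coefficient is scaled up by the
        # design correlation between a planted protein and the average.
        corr = _protein_latent_corr(
            spec.n_prognostic, spec.corr_block_size, spec.corr_rho
        )
        beta_latent = spec.beta_per_sd / corr
    else:
        latent = np.zeros(n)
        beta_latent = 0.0

    hazard = spec.baseline_hazard * np.exp(beta_latent * latent)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / spec.censor_rate, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    if event.mean() < 0.05:
        warnings.warn(
            f"degenerate spec: only {event.sum()} of {n} samples have events",
            stacklevel=2,
        )

    batch_labels = np.array(
        [f"B{j % spec.n_batches + 1}" for j in range(n)], dtype=object
    )
    batch_idx = np.array([j % spec.n_batches for j in range(n)], dtype=float)
    shifts = spec.batch_shift * (batch_idx - batch_idx.mean())
    log2_obs = log2_true + shifts[None, :]

    logit = spec.missing_intercept - spec.missing_slope * log2_obs
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(-logit))
    mask = rng.random((p, n)) < p_miss

    values = np.exp2(log2_obs)
    values[mask] = np.nan

    # 1 + Poisson so single-peptide proteins exist and the filter bites
    unique_peptides = 1 + rng.poisson(5.0, size=p)

    qm = QuantMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        values=values,
        missing_mask=mask,
        unique_peptides=unique_peptides,
        batch=batch_labels if spec.n_batches > 1 else None,
    )
    t_choices = ["T1", "T2", "T3", "T4"]
    n_choices = ["N0", "N1", "N2", "N3"]
    clin = ClinicalTable(
        sample_ids=sample_ids,
        time=time,
        event=event,
        t_stage=list(rng.choice(t_choices, size=n)),
        n_stage=list(rng.choice(n_choices, size=n)),
    )
    truth = CohortTruth(
        planted_proteins=list(planted),
        latent=latent,
        log2_true=log2_true,
        protein_ids=protein_ids,
        sample_ids=sample_ids,
    )
    return qm, clin, truth


def simulate_prm_cohort(
    truth: CohortTruth,
    proteins: Sequence[str] | None = None,
    n_peptides_per_protein: int = 2,
    n_ions: int = 4,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Transition-area table consistent with the cohort's protein levels.

    Light-channel areas are ``2**log2_level`` scaled by a fixed per-peptide
    base and split over product ions; heavy areas are constant per
    (peptide, ion) — a spike-in standard. Summed-area log2(L/H) therefore
    recovers the protein level up to a per-peptide offset, plus lognormal
    noise of ``noise_sd`` log2 units.
    """
    rng = np.random.default_rng(seed)
    if proteins is None:
        proteins = truth.planted_proteins
    idx = {pid: i for i, pid in enumerate(truth.protein_ids)}
    rows: list[tuple] = []
    for pid in proteins:
        levels = truth.log2_true[idx[pid]]
        for pep in range(n_peptides_per_protein):
            pep_seq = f"{pid}_PEP{pep + 1}"
            base = np.exp2(rng.uniform(-2.0, 2.0))  # peptide response factor
            ion_frac = rng.dirichlet(np.ones(n_ions) * 5.0)
            heavy_area = np.exp2(rng.uniform(18.0, 22.0)) * ion_frac
            for j, sid in enumerate(truth.sample_ids):
                noise = np.exp2(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                # fixed 25.0 reference keeps light near heavy without tying
                # the scale to the data (ratios shift exactly with levels)
                light_total = base * np.exp2(levels[j] - 25.0) \
                    * heavy_area.sum() * noise
                light = light_total * ion_frac
                for k in range(n_ions):
                    rows.append(
                        (pep_seq, pid, sid, "light", f"y{k + 3}", light[k])
                    )
                    rows.append(
                        (pep_seq, pid, sid, "heavy", f"y{k + 3}", heavy_area[k])
                    )
    return pd.DataFrame(
        rows,
        columns=["peptide", "protein", "sample", "channel", "ion", "area"],
    )


def simulate_array_cohort(
    truth: CohortTruth,
    protein_to_gene: dict[str, str],
    n_probes_per_gene: int = 2,
    esr1_range: tuple[float, float] = (9.0, 14.0),
    erbb2_range: tuple[float, float] = (9.0, 13.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Probe-level array matrix carrying the cohort's signal into gene space.

    Returns ``(probe_df, probe_to_gene)`` where ``probe_df`` is probes x
    samples on a log2 array scale. ESR1 and ERBB2 rows span their ranges so
    the receptor-based sample filter has both kept and excluded samples.
    """
    rng = np.random.default_rng(seed)
    idx = {pid: i for i, pid in enumerate(truth.protein_ids)}
    n = len(truth.sample_ids)
    rows = {}
    probe_to_gene: dict[str, str] = {}
    for pid, gene in protein_to_gene.items():
        levels = truth.log2_true[idx[pid]]
        centered = levels - levels.mean()
        for k in range(n_probes_per_gene):
            probe = f"{gene}_probe{k + 1}"
            gain = rng.uniform(0.6, 1.2)
            offset = rng.uniform(6.0, 10.0)
            rows[probe] = offset + gain * centered + rng.normal(0, noise_sd, n)
            probe_to_gene[probe] = gene
    rows["ESR1_probe1"] = rng.uniform(*esr1_range, size=n)
    probe_to_gene["ESR1_probe1"] = "ESR1"
    rows["ERBB2_probe1"] = rng.uniform(*erbb2_range, size=n)
    probe_to_gene["ERBB2_probe1"] = "ERBB2"
    df = pd.DataFrame(rows, index=truth.sample_ids).T
    df.index.name = "probe_id"
    return df, probe_to_gene
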