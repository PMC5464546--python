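"""Matrix conditioning: quantifiable filter, outlier exclusion, log2,
left-shifted Gaussian imputation, z-score, and empirical-Bayes batch
correction.

The stage order is fixed — filter -> outlier exclusion -> log2 ->
imputation -> z-score -> batch correction — and :func:`run_preprocess`
enforces it while recording per-stage dimensions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import QuantMatrix

__all__ = [
    "PreprocessReport",
    "filter_quantifiable",
    "detect_outlier_samples",
    "log2_transform",
    "impute_missing",
    "zscore",
    "combat_correct",
    "run_preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    n_proteins_in: int = 0
    n_proteins_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    excluded_samples: dict[str, str] = field(default_factory=dict)
    imputed_count: int = 0
    batch_moments_before: dict[str, tuple[float, float]] = field(default_factory=dict)
    batch_moments_after: dict[str, tuple[float, float]] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, m: QuantMatrix) -> None:
        self.stages.append(
            {"stage": stage, "n_proteins": m.n_proteins, "n_samples": m.n_samples}
        )


def filter_quantifiable(
    m: QuantMatrix,
    min_unique_peptides: int = 2,
    min_detect_frac: float = 0.75,
) -> QuantMatrix:
    """Keep proteins with enough unique peptides and detection breadth.

    Both boundaries are inclusive: a protein detected in exactly 75% of
    samples with exactly two unique peptides is quantifiable.
    """
    detect_frac = (~m.missing_mask).mean(axis=1)
    keep = (m.unique_peptides >= min_unique_peptides) & (
        detect_frac >= min_detect_frac
    )
    if not keep.any():
        warnings.warn("no quantifiable proteins survive the filter", stacklevel=2)
    return m.subset_proteins(keep)


def detect_outlier_samples(
    counts: np.ndarray, sample_ids: list[str] | None = None
) -> list[str]:
    """Samples whose identified-unique-peptide count falls below
    mean minus twice the (n-1) standard deviation. Applied once, never
    iterated."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if n < 3:
        raise ValueError("need at least 3 samples for the outlier rule")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    threshold = counts.mean() - 2.0 * counts.std(ddof=1)
    return [sample_ids[i] for i in np.flatnonzero(counts < threshold)]


def log2_transform(m: QuantMatrix) -> QuantMatrix:
    out = m.copy()
    observed = ~m.missing_mask
    vals = m.values[observed]
    if np.any(vals <= 0):
        raise ValueError("log2 transform requires positive unmasked intensities")
    out.values[observed] = np.log2(vals)
    return out


def impute_missing(
    m: QuantMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    rng: np.random.Generator | None = None,
) -> tuple[QuantMatrix, int]:
    """Replace masked entries with draws from a down-shifted Gaussian.

    Each masked entry of protein ``p`` is drawn from
    ``Normal(mean_p - downshift * sd_p, (width * sd_p)^2)`` using that
    protein's observed mean and (n-1) SD. Proteins with fewer than two
    observed values fall back to the sample's (column) observed moments,
    with a log entry. Returns the completed matrix and the number of
    imputed cells.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = m.copy()
    mask = m.missing_mask
    n_imputed = int(mask.sum())
    if n_imputed == 0:
        return out, 0

    observed = ~mask
    n_obs_row = observed.sum(axis=1)
    col_mean = np.array([
        m.values[observed[:, j], j].mean() if observed[:, j].any() else 0.0
        for j in range(m.n_samples)
    ])
    col_sd = np.array([
        m.values[observed[:, j], j].std(ddof=1) if observed[:, j].sum() > 1 else 0.0
        for j in range(m.n_samples)
    ])
    for i in np.flatnonzero(mask.any(axis=1)):
        js = np.flatnonzero(mask[i])
        if n_obs_row[i] >= 2:
            mu = m.values[i, observed[i]].mean()
            sd = m.values[i, observed[i]].std(ddof=1)
            loc = np.full(js.size, mu - downshift * sd)
            scale = np.full(js.size, width * sd)
        else:
            log.info(
                "protein %s has %d observed values; using sample-wise moments",
                m.protein_ids[i], n_obs_row[i],
            )
            loc = col_mean[js] - downshift * col_sd[js]
            scale = width * col_sd[js]
        out.values[i, js] = rng.normal(loc, scale)
    out.missing_mask[:] = False
    return out, n_imputed


def zscore(m: QuantMatrix) -> QuantMatrix:
    """Per-protein standardization with the (n-1) SD; errors on flat rows."""
    out = m.copy()
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = ", ".join(m.protein_ids[i] for i in flat[:10])
        raise ValueError(f"zero-variance proteins cannot be z-scored: {names}")
    out.values = (m.values - mean) / sd
    return out


def _combat_adjust(values: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardize each protein, estimate per-batch additive and
    multiplicative effects, shrink them toward batch-level moment-matched
    priors, remove them, and restore the original scale.
    """
    levels, inv = np.unique(batch, return_inverse=True)
    n_batches = levels.size
    p, n = values.shape
    n_per = np.bincount(inv)

    batch_mean = np.stack(
        [values[:, inv == b].mean(axis=1) for b in range(n_batches)], axis=1
    )  # (p, B)
    grand_mean = batch_mean @ (n_per / n)
    resid = values - batch_mean[:, inv]
    var_pooled = (resid**2).sum(axis=1) / n
    if np.any(var_pooled == 0):
        raise ValueError("zero pooled variance; cannot batch-correct flat protein")
    sd_pooled = np.sqrt(var_pooled)

    z = (values - grand_mean[:, None]) / sd_pooled[:, None]

    gamma_hat = np.stack(
        [z[:, inv == b].mean(axis=1) for b in range(n_batches)], axis=1
    )
    delta_hat = np.stack(
        [z[:, inv == b].var(axis=1, ddof=1) for b in range(n_batches)], axis=1
    )

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    # inverse-gamma hyperparameters by method of moments
    a_prior = (2.0 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(n_batches):
        nb = n_per[b]
        g = gamma_hat[:, b].copy()
        d = delta_hat[:, b].copy()
        zb = z[:, inv == b]
        for _ in range(100):
            g_new = (nb * tau2[b] * gamma_hat[:, b] + d * gamma_bar[b]) / (
                nb * tau2[b] + d
            )
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ss + b_prior[b]) / (nb / 2.0 + a_prior[b] - 1.0)
            if (
                np.max(np.abs(g_new - g)) < 1e-8
                and np.max(np.abs(d_new - d)) < 1e-8
            ):
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        gamma_star[:, b] = g
        delta_star[:, b] = d

    adjusted = (z - gamma_star[:, inv]) / np.sqrt(delta_star[:, inv])
    return adjusted * sd_pooled[:, None] + grand_mean[:, None]


def combat_correct(m: QuantMatrix, batch: np.ndarray | None = None) -> QuantMatrix:
    """Remove additive/multiplicative batch effects (parametric EB).

    A single batch is an identity transform with a logged notice. Requires
    a complete (imputed) matrix and at least two samples per batch.
    """
    out = m.copy()
    if batch is None:
        batch = m.batch
    if batch is None:
        log.info("no batch labels; ComBat skipped (identity)")
        return out
    batch = np.asarray(batch)
    if batch.shape != (m.n_samples,):
        raise ValueError("batch labels must match sample count")
    if m.missing_mask.any():
        raise ValueError("ComBat requires a complete (imputed) matrix")
    levels, counts = np.unique(batch, return_counts=True)
    if levels.size == 1:
        log.info("single batch %r; ComBat is an identity transform", levels[0])
        return out
    if np.any(counts < 2):
        small = levels[counts < 2]
        raise ValueError(f"batches with < 2 samples: {list(small)}")
    out.values = _combat_adjust(m.values, batch)
    return out


def run_preprocess(
    m: QuantMatrix,
    sample_peptide_counts: np.ndarray | None = None,
    min_unique_peptides: int = 2,
    min_detect_frac: float = 0.75,
    impute_width: float = 0.3,
    impute_downshift: float = 1.8,
    rng: np.random.Generator | None = None,
    apply_zscore: bool = True,
) -> tuple[QuantMatrix, PreprocessReport]:
    """Full conditioning chain in the fixed order, with a stage report.

    ``sample_peptide_counts`` (identified unique peptides per sample) feeds
    the outlier rule; when absent, the per-sample count of detected
    proteins is used as a proxy.
    """
    report = PreprocessReport(
        n_proteins_in=m.n_proteins, n_samples_in=m.n_samples
    )
    report.record("input", m)

    # Outlier samples are dropped before the quantifiable filter so that
    # detection fractions are computed on the analyzed sample set.
    if sample_peptide_counts is None:
        sample_peptide_counts = (~m.missing_mask).sum(axis=0)
    excluded = detect_outlier_samples(sample_peptide_counts, m.sample_ids)
    for s in excluded:
        report.excluded_samples[s] = "unique-peptide count below mean - 2 SD"
    keep = np.array([s not in excluded for s in m.sample_ids])
    m1 = m.subset_samples(keep)
    report.record("detect_outlier_samples", m1)

    m2 = filter_quantifiable(m1, min_unique_peptides, min_detect_frac)
    report.record("filter_quantifiable", m2)

    m3 = log2_transform(m2)
    report.record("log2_transform", m3)

    m4, n_imp = impute_missing(m3, impute_width, impute_downshift, rng)
    report.imputed_count = n_imp
    report.record("impute_missing", m4)

    if apply_zscore:
        m5 = zscore(m4)
    else:
        m5 = m4
    report.record("zscore", m5)

    if m5.batch is not None:
        for b in np.unique(m5.batch):
            vals = m5.values[:, m5.batch == b]
            report.batch_moments_before[str(b)] = (
                float(vals.mean()), float(vals.std())
            )
    m6 = combat_correct(m5)
    if m6.batch is not None:
        for b in np.unique(m6.batch):
            vals = m6.values[:, m6.batch == b]
            report.batch_moments_after[str(b)] = (
                float(vals.mean()), float(vals.std())
            )
    report.record("combat_correct", m6)

    report.n_proteins_out = m6.n_proteins
    report.n_samples_out = m6.n_samples
    return m6, report
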