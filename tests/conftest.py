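"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own numerics: the Cox
oracle is a brute-force grid maximization of a hand-written partial
likelihood, and matrix fixtures are built cell by cell.
"""

from __future__ import annotations

import numpy as np
import pytest

from proteosig.io_core import ClinicalTable, QuantMatrix
from proteosig.synthetic_data import SimSpec, simulate_cohort


# ---------------------------------------------------------------------------
# independent Cox oracle (Breslow form; callers feed it tie-free data)


def partial_loglik_grid(betas: np.ndarray, x, time, event) -> np.ndarray:
    """Breslow log partial likelihood on a beta grid, written from the
    definition: sum over events of eta_i - log(sum over risk set of e^eta)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = np.zeros_like(betas)
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        eta = np.outer(betas, x[risk])
        ll += betas * x[i] - np.log(np.exp(eta).sum(axis=1))
    return ll


def grid_argmax_beta(x, time, event, lo=-10.0, hi=10.0) -> float:
    """Two-stage grid maximization of the hand-written partial likelihood."""
    coarse = np.linspace(lo, hi, 4001)
    b0 = coarse[np.argmax(partial_loglik_grid(coarse, x, time, event))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 4001)
    return float(fine[np.argmax(partial_loglik_grid(fine, x, time, event))])


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def tiny_quant() -> QuantMatrix:
    """3 proteins x 4 samples, one missing cell, raw intensity scale."""
    values = np.array(
        [
            [100.0, 200.0, 400.0, 800.0],
            [50.0, np.nan, 100.0, 150.0],
            [10.0, 20.0, 30.0, 40.0],
        ]
    )
    mask = np.isnan(values)
    return QuantMatrix(
        protein_ids=["P1", "P2", "P3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        missing_mask=mask,
        unique_peptides=np.array([3, 2, 1]),
    )


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    return ClinicalTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        time=np.array([1.0, 2.0, 3.0, 4.0]),
        event=np.array([1, 1, 0, 1]),
        t_stage=["T1", "T2", "T1", "T3"],
        n_stage=["N0", "N1", "N0", "N2"],
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium planted cohort without missingness, z-scored log2 values."""
    from proteosig.preprocess import log2_transform, zscore

    spec = SimSpec(
        n_samples=120,
        n_proteins=200,
        n_prognostic=15,
        beta_per_sd=1.0,
        missing_intercept=-50.0,
        seed=11,
    )
    qm, clin, truth = simulate_cohort(spec)
    processed = zscore(log2_transform(qm))
    return processed, clin, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted signal and no missingness."""
    from proteosig.preprocess import log2_transform, zscore

    spec = SimSpec(
        n_samples=80,
        n_proteins=120,
        n_prognostic=0,
        beta_per_sd=0.0,
        missing_intercept=-50.0,
        seed=12,
    )
    qm, clin, truth = simulate_cohort(spec)
    processed = zscore(log2_transform(qm))
    return processed, clin, truth
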