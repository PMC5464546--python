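"""Per-protein univariate Cox proportional-hazards screening against DMFS."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._coxph import CoxFit, newton_fit, newton_fit_many
from .io_core import ClinicalTable, QuantMatrix

__all__ = ["ScreenResult", "cox_fit", "screen_proteins", "screen_all"]

log = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    protein_id: str
    beta: float
    hr: float
    p: float
    n_events: int


def cox_fit(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> CoxFit:
    """Single-covariate Cox fit (Newton–Raphson, Wald p-value).

    Separation or a constant covariate yields a flagged result with NaN
    estimates instead of an exception; zero events is a hard error.
    """
    return newton_fit(x, time, event, ties=ties)


def screen_all(
    m: QuantMatrix,
    clin: ClinicalTable,
    ties: str = "efron",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized univariate fits for every protein row.

    Returns ``(beta, p, flagged)`` aligned with ``m.protein_ids``.
    """
    clin = clin.align_to(m.sample_ids)
    beta, _se, p, flagged = newton_fit_many(m.values, clin.time, clin.event, ties)
    return beta, p, flagged


def screen_proteins(
    m: QuantMatrix,
    clin: ClinicalTable,
    alpha: float = 0.01,
    ties: str = "efron",
) -> list[ScreenResult]:
    """Proteins with Wald p strictly below ``alpha``, sorted by p ascending.

    No multiplicity correction is applied. Flagged fits (separation,
    constant rows) are excluded with a log entry.
    """
    if m.missing_mask.any():
        raise ValueError("screen requires a fully imputed matrix")
    clin_aligned = clin.align_to(m.sample_ids)
    beta, p, flagged = screen_all(m, clin_aligned, ties)
    n_events = int(clin_aligned.event.sum())
    if flagged.any():
        log.info(
            "excluded %d flagged proteins from screen: %s",
            int(flagged.sum()),
            ", ".join(m.protein_ids[i] for i in np.flatnonzero(flagged)[:10]),
        )
    passing = np.flatnonzero(~flagged & (p < alpha))
    order = passing[np.argsort(p[passing], kind="stable")]
    return [
        ScreenResult(
            protein_id=m.protein_ids[i],
            beta=float(beta[i]),
            hr=float(np.exp(beta[i])),
            p=float(p[i]),
            n_events=n_events,
        )
        for i in order
    ]
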