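"""Survival statistics: Kaplan–Meier curves, log-rank tests, group hazard
ratios, multivariate Cox models and t-year survival readout.

Conventions: at tied times deaths are processed before censorings; the
time unit is years; confidence intervals use the normal approximation on
the log hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._coxph import newton_fit
from .io_core import ClinicalTable, N_STAGES, T_STAGES

__all__ = [
    "KMCurve",
    "GroupComparison",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "group_hr",
    "cox_multivariate",
    "compare_groups",
]


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-15):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass
class GroupComparison:
    """High- vs low-risk group contrast in the shape the reports use."""

    chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    dmfs5_low: float
    dmfs5_high: float
    n_low: int
    n_high: int
    flagged: bool = False


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    At tied times, deaths are counted against the full risk set (deaths
    before censorings).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("cannot estimate a survival curve from no samples")
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    distinct = np.unique(t[e == 1])
    surv = []
    risk = []
    s = 1.0
    for td in distinct:
        n_risk = int((t >= td).sum())  # censored at td still at risk
        d = int(((t == td) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
    return KMCurve(
        event_times=distinct,
        survival=np.array(surv),
        at_risk=np.array(risk),
        censor_times=np.sort(t[e == 0]),
    )


def survival_at(curve: KMCurve, t: float) -> tuple[float, bool]:
    """Right-continuous step-function value at ``t``.

    Returns ``(probability, extrapolated)``; the flag is True when ``t``
    lies beyond the last observed time (event or censoring).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    last_observed = max(
        curve.event_times[-1] if curve.event_times.size else 0.0,
        curve.censor_times[-1] if curve.censor_times.size else 0.0,
    )
    idx = np.searchsorted(curve.event_times, t, side="right")
    prob = 1.0 if idx == 0 else float(curve.survival[idx - 1])
    return prob, bool(t > last_observed)


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test with hypergeometric variance.

    Returns ``(chi2, p)``; zero total events yields ``(nan, nan)``.
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        return float("nan"), float("nan")
    all_t = np.concatenate([time_a, time_b])
    all_e = np.concatenate([event_a, event_b])
    grp = np.concatenate([np.zeros(time_a.size), np.ones(time_b.size)])
    death_times = np.unique(all_t[all_e == 1])
    o_minus_e = 0.0
    var = 0.0
    for td in death_times:
        at_risk = all_t >= td
        n = int(at_risk.sum())
        n_a = int((at_risk & (grp == 0)).sum())
        d = int(((all_t == td) & (all_e == 1)).sum())
        d_a = int(((all_t == td) & (all_e == 1) & (grp == 0)).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return float("nan"), float("nan")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def group_hr(
    high: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, tuple[float, float], float, bool]:
    """Hazard ratio of high- vs low-risk with a 95% Wald CI.

    Returns ``(hr, (lo, hi), p, flagged)``. Separation (all events in one
    group before any in the other) flags the result rather than raising.
    """
    x = np.asarray(high, dtype=float)
    fit = newton_fit(x, time, event)
    if fit.flagged:
        return float("nan"), (float("nan"), float("nan")), float("nan"), True
    beta, se = float(fit.beta[0]), float(fit.se[0])
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return float(np.exp(beta)), ci, float(fit.p[0]), False


def _stage_design(values: list[str], levels: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Indicator coding with the first level as reference; unknown rows get
    all-zero indicators (folded into the reference)."""
    reference = levels[0]
    used = [lv for lv in levels[1:] if lv in values and lv != "unknown"]
    cols = np.zeros((len(values), len(used)))
    for j, lv in enumerate(used):
        cols[:, j] = [1.0 if v == lv else 0.0 for v in values]
    names = [f"{lv} (vs {reference})" for lv in used]
    return cols, names


def cox_multivariate(
    clin: ClinicalTable,
    high: np.ndarray | None = None,
    use_t_stage: bool = True,
    use_n_stage: bool = True,
) -> dict[str, dict[str, float]]:
    """Multivariate Cox model of risk group plus staging indicators.

    T and N stages enter as categorical indicators with T1/N0 reference.
    Returns per-covariate ``{"hr", "ci_low", "ci_high", "p"}``. A
    rank-deficient design is an error naming the aliased columns.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if high is not None:
        blocks.append(np.asarray(high, dtype=float)[:, None])
        names.append("high_risk")
    if use_t_stage:
        cols, nm = _stage_design(clin.t_stage, T_STAGES)
        blocks.append(cols)
        names.extend(nm)
    if use_n_stage:
        cols, nm = _stage_design(clin.n_stage, N_STAGES)
        blocks.append(cols)
        names.extend(nm)
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(np.hstack([np.ones((X.shape[0], 1)), X]))
    if rank < X.shape[1] + 1:
        # identify aliased columns by incremental rank
        aliased = []
        base = np.ones((X.shape[0], 1))
        for j in range(X.shape[1]):
            cand = np.hstack([base, X[:, : j + 1]])
            if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(
                np.hstack([base, X[:, :j]])
            ):
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = newton_fit(X, clin.time, clin.event)
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(names):
        if fit.flagged:
            out[name] = {
                "hr": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "p": float("nan"),
            }
        else:
            b, s = float(fit.beta[j]), float(fit.se[j])
            out[name] = {
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * s)),
                "ci_high": float(np.exp(b + 1.96 * s)),
                "p": float(fit.p[j]),
            }
    return out


def compare_groups(
    high: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon_years: float = 5.0,
) -> GroupComparison:
    """Full low/high contrast: log-rank, HR with CI, and t-year survival."""
    high = np.asarray(high, dtype=bool)
    if high.all() or (~high).all():
        return GroupComparison(
            chi2=float("nan"), p=float("nan"), hr=float("nan"),
            hr_ci=(float("nan"), float("nan")),
            dmfs5_low=float("nan"), dmfs5_high=float("nan"),
            n_low=int((~high).sum()), n_high=int(high.sum()), flagged=True,
        )
    chi2, p = logrank_test(time[~high], event[~high], time[high], event[high])
    hr, ci, _hr_p, hr_flagged = group_hr(high.astype(float), time, event)
    s_low, _ = survival_at(km_estimate(time[~high], event[~high]), horizon_years)
    s_high, _ = survival_at(km_estimate(time[high], event[high]), horizon_years)
    return GroupComparison(
        chi2=chi2,
        p=p,
        hr=hr,
        hr_ci=ci,
        dmfs5_low=100.0 * s_low,
        dmfs5_high=100.0 * s_high,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        flagged=hr_flagged,
    )
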