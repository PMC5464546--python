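"""Cox proportional-hazards partial-likelihood engine.

Two entry points share the same likelihood conventions:

* :func:`newton_fit` — multivariate Newton–Raphson with step halving,
  Efron or Breslow tie handling.
* :func:`newton_fit_many` — univariate fits for many covariate rows at
  once, vectorized over rows. This is what makes per-protein screening
  inside permutation loops affordable.

Degenerate inputs (constant covariate on the event risk sets, monotone
likelihood / separation) are flagged rather than raised: a screen over a
thousand proteins must survive a handful of pathological rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_BETA_BOUND = 50.0  # |beta| past this is treated as monotone likelihood
_MIN_HESS = 1e-12


@dataclass
class CoxFit:
    """Result of a single Cox fit; ``flagged`` means no usable estimate."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    n_events: int
    flagged: bool
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)


class _SurvOrder:
    """Pre-sorted survival data shared across Newton iterations.

    Samples are sorted by descending time so prefix sums over the sorted
    order are risk-set sums. ``group_last`` marks, for each distinct time
    (descending), the last sorted position sharing that time.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D and equal length")
        if (event == 1).sum() < 1:
            raise ValueError("at least one event is required for a Cox fit")
        order = np.argsort(-time, kind="stable")
        self.order = order
        self.time = time[order]
        self.event = event[order].astype(float)
        # distinct descending times -> last index of each tie block
        change = np.flatnonzero(np.diff(self.time) != 0)
        self.group_last = np.append(change, len(self.time) - 1)
        self.group_first = np.concatenate(([0], change + 1))
        self.n_events = int(event.sum())
        # per distinct time: number of deaths
        ev_cum = np.concatenate(([0.0], np.cumsum(self.event)))
        self.deaths = (
            ev_cum[self.group_last + 1] - ev_cum[self.group_first]
        )
        self.event_groups = np.flatnonzero(self.deaths > 0)
        self.max_deaths = int(self.deaths.max())


def _efron_fractions(d: int, ties: str) -> np.ndarray:
    if ties == "efron":
        return np.arange(d) / d
    if ties == "breslow":
        return np.zeros(d)
    raise ValueError(f"unknown tie handling {ties!r}")


def _loglik_grad_hess(
    beta: np.ndarray, X: np.ndarray, so: _SurvOrder, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood with gradient and Hessian. X is (n, k) sorted."""
    n, k = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = X * w[:, None]
    wXX = X[:, :, None] * X[:, None, :] * w[:, None, None]

    s0 = np.cumsum(w)
    s1 = np.cumsum(wX, axis=0)
    s2 = np.cumsum(wXX, axis=0)

    ev = so.event.astype(bool)
    ll = float(eta[ev].sum())
    grad = X[ev].sum(axis=0)
    hess = np.zeros((k, k))

    for g in so.event_groups:
        last = so.group_last[g]
        first = so.group_first[g]
        d = int(so.deaths[g])
        r0 = s0[last]
        r1 = s1[last]
        r2 = s2[last]
        if d > 1 or ties == "efron":
            in_g = slice(first, last + 1)
            dmask = ev[in_g]
            d0 = w[in_g][dmask].sum()
            d1 = wX[in_g][dmask].sum(axis=0)
            d2 = wXX[in_g][dmask].sum(axis=0)
        else:
            d0, d1, d2 = 0.0, np.zeros(k), np.zeros((k, k))
        for frac in _efron_fractions(d, ties):
            phi0 = r0 - frac * d0
            phi1 = r1 - frac * d1
            phi2 = r2 - frac * d2
            ll -= np.log(phi0)
            grad -= phi1 / phi0
            hess -= phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
    return ll, grad, hess


def newton_fit(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Maximize the Cox partial likelihood over ``beta`` by Newton–Raphson.

    ``x`` may be 1-D (single covariate) or (n, k). Separation and
    zero-information covariates yield ``flagged=True`` with NaN estimates.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    so = _SurvOrder(time, event)
    X = x[so.order]
    n, k = X.shape

    beta = np.zeros(k)
    ll, grad, hess = _loglik_grad_hess(beta, X, so, ties)
    n_iter = 0
    flagged = False
    for n_iter in range(1, max_iter + 1):
        neg_hess = -hess
        # zero-information covariate -> flagged, not a crash
        if np.any(np.abs(np.diag(neg_hess)) < _MIN_HESS):
            flagged = True
            break
        try:
            step = np.linalg.solve(neg_hess, grad)
        except np.linalg.LinAlgError:
            flagged = True
            break
        # step halving: never accept a likelihood decrease
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_grad_hess(new_beta, X, so, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_grad_hess(new_beta, X, so, ties)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > _BETA_BOUND):
            flagged = True  # monotone likelihood
            break
        if delta < tol:
            break
    else:
        flagged = True

    if flagged:
        nan = np.full(k, np.nan)
        return CoxFit(nan, nan, nan, float(ll), so.n_events, True, n_iter)

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    p = stats.chi2.sf(wald, df=1)
    return CoxFit(beta, se, p, float(ll), so.n_events, False, n_iter)


# ---------------------------------------------------------------------------
# vectorized univariate fits


def newton_fit_many(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Univariate Cox fits for every row of ``X`` (p, n) simultaneously.

    Returns ``(beta, se, p, flagged)`` each of shape (p,). Flagged rows
    (constant covariate, separation, non-convergence) carry NaN.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (proteins x samples)")
    so = _SurvOrder(time, event)
    Xs = X[:, so.order]  # (p, n) sorted by descending time
    p, n = Xs.shape
    ev = so.event.astype(bool)
    last = so.group_last[so.event_groups]
    first = so.group_first[so.event_groups]
    deaths = so.deaths[so.event_groups].astype(int)
    sum_x_events = Xs[:, ev].sum(axis=1)
    needs_death_sums = so.max_deaths > 1 and ties == "efron"

    beta = np.zeros(p)
    flagged = np.zeros(p, dtype=bool)
    converged = np.zeros(p, dtype=bool)
    se = np.full(p, np.nan)

    for _ in range(max_iter):
        active = ~(flagged | converged)
        if not np.any(active):
            break
        eta = np.clip(beta[:, None] * Xs, -500, 500)
        w = np.exp(eta)
        wx = w * Xs
        wxx = wx * Xs
        c0 = np.cumsum(w, axis=1)[:, last]
        c1 = np.cumsum(wx, axis=1)[:, last]
        c2 = np.cumsum(wxx, axis=1)[:, last]

        if needs_death_sums:
            d0 = _group_death_sums(w, so)
            d1 = _group_death_sums(wx, so)
            d2 = _group_death_sums(wxx, so)

        grad = sum_x_events.copy()
        hess = np.zeros(p)
        for g_idx in range(len(last)):
            d = deaths[g_idx]
            r0 = c0[:, g_idx]
            r1 = c1[:, g_idx]
            r2 = c2[:, g_idx]
            for frac in _efron_fractions(d, ties):
                if frac == 0.0:
                    phi0, phi1, phi2 = r0, r1, r2
                else:
                    phi0 = r0 - frac * d0[:, g_idx]
                    phi1 = r1 - frac * d1[:, g_idx]
                    phi2 = r2 - frac * d2[:, g_idx]
                grad -= phi1 / phi0
                hess -= phi2 / phi0 - (phi1 / phi0) ** 2

        info = -hess
        dead = info < _MIN_HESS
        flagged |= dead & active
        active &= ~dead
        step = np.zeros(p)
        np.divide(grad, info, out=step, where=~dead)
        step = np.clip(step, -2.0, 2.0)  # damp early overshoot
        beta = np.where(active, beta + step, beta)
        runaway = np.abs(beta) > _BETA_BOUND
        flagged |= runaway & active  # monotone likelihood
        active &= ~runaway
        se = np.where(dead, np.nan, 1.0 / np.sqrt(np.maximum(info, _MIN_HESS)))
        converged |= active & (np.abs(step) < tol)

    flagged |= ~(flagged | converged)  # never converged
    beta = np.where(flagged, np.nan, beta)
    se = np.where(flagged, np.nan, se)
    wald = (beta / se) ** 2
    pvals = np.where(flagged, np.nan, stats.chi2.sf(wald, df=1))
    return beta, se, pvals, flagged


def _group_death_sums(arr: np.ndarray, so: _SurvOrder) -> np.ndarray:
    """Sum ``arr`` (p, n sorted) over deaths within each event-time group."""
    masked = arr * so.event[None, :]
    sums = np.add.reduceat(masked, so.group_first, axis=1)
    return sums[:, so.event_groups]
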