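"""Risk-signature construction: correlation groups, reduced profiles,
supervised principal-component scoring with a-priori quantile cutoffs,
leave-one-out cross-validation, and permutation significance.

Supervision is the univariate Cox screen: the risk score is the first
principal component of the screened (survival-associated) proteins, with
the sign oriented so that a higher score means higher hazard. Cutoffs are
rank-based: with low-risk fraction ``f`` and ``n`` training samples, the
``ceil(f * n)``-th smallest score is the last low-risk sample, and a score
strictly above that threshold is high-risk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from math import ceil
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._coxph import newton_fit
from .cox_screen import screen_all, screen_proteins
from .io_core import ClinicalTable, QuantMatrix
from .survstats import logrank_test

__all__ = [
    "CorrelationGroups",
    "SignatureModel",
    "RiskAssignment",
    "correlation_groups",
    "sample_reduced_profiles",
    "fit_supervised_pc",
    "assign_risk",
    "loocv_risk",
    "permutation_pvalue",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationGroups:
    """Disjoint partition of screened proteins into correlated groups."""

    groups: list[list[str]]

    def __post_init__(self) -> None:
        flat = [p for g in self.groups for p in g]
        if len(flat) != len(set(flat)):
            raise ValueError("correlation groups must be disjoint")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, protein_id: str) -> int:
        for i, g in enumerate(self.groups):
            if protein_id in g:
                return i
        raise KeyError(protein_id)


@dataclass
class SignatureModel:
    """Frozen risk predictor: protein list, training standardization
    constants, unit-norm PC loading, orientation and cutoff."""

    protein_ids: list[str]
    train_means: np.ndarray
    train_sds: np.ndarray
    loading: np.ndarray
    cox_beta_on_score: float
    cutoff_fraction: float
    cutoff_value: float

    def __post_init__(self) -> None:
        self.train_means = np.asarray(self.train_means, dtype=float)
        self.train_sds = np.asarray(self.train_sds, dtype=float)
        self.loading = np.asarray(self.loading, dtype=float)
        k = len(self.protein_ids)
        for name in ("train_means", "train_sds", "loading"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have one entry per protein")
        norm = np.linalg.norm(self.loading)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"loading must be unit norm, got {norm}")

    def score(self, values: np.ndarray, standardize: bool = True) -> np.ndarray:
        """Scores for a (k, n) value block ordered like ``protein_ids``."""
        z = values
        if standardize:
            z = (values - self.train_means[:, None]) / self.train_sds[:, None]
        return self.loading @ z

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        for key in ("train_means", "train_sds", "loading"):
            payload[key] = [float(v) for v in payload[key]]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class RiskAssignment:
    sample_ids: list[str]
    score: np.ndarray
    high: np.ndarray  # True = high risk

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.high = np.asarray(self.high, dtype=bool)


def correlation_groups(
    m: QuantMatrix, proteins: Sequence[str], r_threshold: float = 0.5
) -> CorrelationGroups:
    """Connected components of the graph with edges where Pearson r is
    strictly above ``r_threshold`` (computed on processed values)."""
    idx = m.protein_index(proteins)
    vals = m.values[idx]
    r = np.corrcoef(vals)
    if r.ndim == 0:  # single protein
        return CorrelationGroups(groups=[[proteins[0]]])
    adj = (r > r_threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[list[str]] = [[] for _ in range(n_comp)]
    for pid, lab in zip(proteins, labels):
        groups[lab].append(pid)
    return CorrelationGroups(groups=groups)


def sample_reduced_profiles(
    groups: CorrelationGroups,
    size_range: tuple[int, int] = (3, 7),
    per_group: tuple[int, int] = (1, 2),
    n_profiles: int = 12,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> list[list[str]]:
    """Random reduced profiles drawing 1–2 proteins per correlation group.

    Each profile takes ``per_group`` proteins from distinct groups until
    its size lands in ``size_range``; profiles are unique and deterministic
    under a seeded generator.
    """
    if rng is None:
        rng = np.random.default_rng()
    if groups.n_groups < 2:
        raise ValueError("need at least 2 correlation groups")
    lo, hi = size_range
    max_size = sum(min(per_group[1], len(g)) for g in groups.groups)
    if lo > max_size:
        raise ValueError(
            f"size_range {size_range} infeasible: at most {max_size} proteins "
            f"available at {per_group[1]} per group"
        )
    seen: set[frozenset] = set()
    profiles: list[list[str]] = []
    attempts = 0
    while len(profiles) < n_profiles:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not draw {n_profiles} distinct profiles in "
                f"{max_attempts} attempts; got {len(profiles)}"
            )
        target = int(rng.integers(lo, hi + 1))
        order = rng.permutation(groups.n_groups)
        chosen: list[str] = []
        for g in order:
            remaining = target - len(chosen)
            if remaining <= 0:
                break
            members = groups.groups[g]
            take = int(rng.integers(per_group[0], per_group[1] + 1))
            take = min(take, len(members), remaining)
            picked = rng.choice(len(members), size=take, replace=False)
            chosen.extend(members[i] for i in picked)
        if len(chosen) != target:
            continue
        key = frozenset(chosen)
        if key in seen:
            continue
        seen.add(key)
        profiles.append(sorted(chosen))
    return profiles


def _quantile_cutoff(scores: np.ndarray, fraction: float) -> float:
    """The ``ceil(f * n)``-th smallest score: last low-risk training score."""
    n = scores.size
    k = max(1, min(n, ceil(fraction * n)))
    return float(np.sort(scores)[k - 1])


def fit_supervised_pc(
    m: QuantMatrix,
    proteins: Sequence[str],
    clin: ClinicalTable,
    cutoff_fraction: float = 0.5,
) -> SignatureModel:
    """Supervised-PC risk model on an already-screened protein set.

    Rows are standardized by training mean/SD; the loading is the first
    right-singular vector of the samples x proteins standardized block;
    orientation is fixed so the Cox coefficient of the score is
    non-negative (ties: first loading coordinate positive); the cutoff is
    the a-priori rank quantile of training scores.
    """
    proteins = list(proteins)
    if len(proteins) < 1:
        raise ValueError("need at least one protein")
    idx = m.protein_index(proteins)
    clin = clin.align_to(m.sample_ids)
    block = m.values[idx]
    means = block.mean(axis=1)
    sds = block.std(axis=1, ddof=1)
    if np.any(sds == 0):
        flat = [proteins[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance proteins: {flat}")
    z = (block - means[:, None]) / sds[:, None]

    if len(proteins) == 1:
        loading = np.array([1.0])
    else:
        # first right-singular vector of samples x proteins
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        if s[0] <= 1e-12:
            raise ValueError("degenerate (rank-0) submatrix")
        loading = vt[0]
    score = loading @ z

    fit = newton_fit(score, clin.time, clin.event)
    beta = float(fit.beta[0]) if not fit.flagged else 0.0
    if beta < 0 or (beta == 0 and loading[0] < 0):
        loading = -loading
        score = -score
        beta = -beta

    cutoff = _quantile_cutoff(score, cutoff_fraction)
    return SignatureModel(
        protein_ids=proteins,
        train_means=means,
        train_sds=sds,
        loading=loading,
        cox_beta_on_score=beta,
        cutoff_fraction=cutoff_fraction,
        cutoff_value=cutoff,
    )


def assign_risk(model: SignatureModel, m: QuantMatrix) -> RiskAssignment:
    """Apply a frozen model: frozen standardization, frozen cutoff.

    A score strictly greater than ``cutoff_value`` is high risk; the
    boundary sample is low risk.
    """
    idx = m.protein_index(model.protein_ids)
    score = model.score(m.values[idx])
    return RiskAssignment(
        sample_ids=list(m.sample_ids),
        score=score,
        high=score > model.cutoff_value,
    )


def _fold_protein_lists(
    m: QuantMatrix, clin: ClinicalTable, alpha: float
) -> list[str]:
    """Screened protein list for one fold; falls back to the single most
    associated protein when nothing passes alpha."""
    results = screen_proteins(m, clin, alpha=alpha)
    if results:
        return [r.protein_id for r in results]
    beta, p, flagged = screen_all(m, clin)
    usable = np.flatnonzero(~flagged)
    if usable.size == 0:
        raise ValueError("no usable protein in fold")
    best = usable[np.argmin(p[usable])]
    return [m.protein_ids[best]]


def loocv_risk(
    m: QuantMatrix,
    clin: ClinicalTable,
    cutoff_fraction: float = 0.5,
    alpha: float = 0.01,
    candidates: Sequence[str] | None = None,
) -> RiskAssignment:
    """Honest leave-one-out cross-validated risk groups.

    Each fold re-screens (the protein list is refit from scratch without
    the held-out sample), refits the supervised-PC loading and cutoff, and
    assigns the held-out sample. Folds with zero events are flagged NaN.
    """
    if m.n_samples < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    clin = clin.align_to(m.sample_ids)
    work = m if candidates is None else m.subset_proteins(m.protein_index(candidates))
    n = m.n_samples
    scores = np.full(n, np.nan)
    high = np.zeros(n, dtype=bool)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        m_train = work.subset_samples(keep)
        clin_train = ClinicalTable(
            sample_ids=m_train.sample_ids,
            time=clin.time[keep],
            event=clin.event[keep],
            t_stage=[clin.t_stage[j] for j in np.flatnonzero(keep)],
            n_stage=[clin.n_stage[j] for j in np.flatnonzero(keep)],
        )
        if clin_train.event.sum() == 0:
            log.info("fold %d has zero events; flagged NA", i)
            continue
        fold_proteins = _fold_protein_lists(m_train, clin_train, alpha)
        model = fit_supervised_pc(m_train, fold_proteins, clin_train, cutoff_fraction)
        held = work.subset_samples(np.eye(n, dtype=bool)[i])
        ra = assign_risk(model, held)
        scores[i] = ra.score[0]
        high[i] = ra.high[0]
    return RiskAssignment(sample_ids=list(m.sample_ids), score=scores, high=high)


def permutation_stats(
    m: QuantMatrix,
    fit_and_split: Callable[[QuantMatrix, ClinicalTable], np.ndarray],
    clin: ClinicalTable,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null log-rank statistics under joint (time, event) permutation.

    Each permutation re-runs ``fit_and_split`` (screen + fit + split) on
    the permuted outcomes and recomputes the log-rank statistic.
    Degenerate permutations (one-sided split, undefined statistic) yield
    ``-inf`` so they never count as exceedances.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if rng is None:
        rng = np.random.default_rng()
    clin = clin.align_to(m.sample_ids)
    n = m.n_samples
    stats = np.full(n_permutations, -np.inf)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        clin_perm = ClinicalTable(
            sample_ids=m.sample_ids,
            time=clin.time[perm],
            event=clin.event[perm],
            t_stage=[clin.t_stage[j] for j in perm],
            n_stage=[clin.n_stage[j] for j in perm],
        )
        try:
            high = np.asarray(fit_and_split(m, clin_perm), dtype=bool)
        except ValueError:
            continue
        if high.all() or (~high).all():
            continue
        chi2, _ = logrank_test(
            clin_perm.time[~high], clin_perm.event[~high],
            clin_perm.time[high], clin_perm.event[high],
        )
        if np.isfinite(chi2):
            stats[b] = chi2
    return stats


def permutation_pvalue(
    observed_stat: float,
    m: QuantMatrix,
    fit_and_split: Callable[[QuantMatrix, ClinicalTable], np.ndarray],
    clin: ClinicalTable,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value with full refitting inside each permutation.

    Uses the add-one estimator ``(1 + #{perm >= obs}) / (B + 1)``.
    """
    stats = permutation_stats(m, fit_and_split, clin, n_permutations, rng)
    exceed = int((stats >= observed_stat).sum())
    return (1 + exceed) / (n_permutations + 1)


def default_fit_and_split(
    alpha: float = 0.01, cutoff_fraction: float = 0.5,
    proteins: Sequence[str] | None = None,
) -> Callable[[QuantMatrix, ClinicalTable], np.ndarray]:
    """Standard closure for :func:`permutation_pvalue`: re-screen (unless a
    fixed profile is given), fit the supervised PC, split at the quantile."""

    def _fit(m: QuantMatrix, clin: ClinicalTable) -> np.ndarray:
        if proteins is None:
            fold = _fold_protein_lists(m, clin, alpha)
        else:
            fold = list(proteins)
        model = fit_supervised_pc(m, fold, clin, cutoff_fraction)
        return assign_risk(model, m).high

    return _fit
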