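"""Exposure-expression agreement: regularized CCA, the categorization
fitness score, and rank-based selection probabilities.

The fitness of a categorization is the mean held-out canonical correlation
between NNLS-refit exposures of WES samples and the expression of a gene
set, averaged over test folds and NMF orders K in a window around K*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.model_selection import KFold

from .catalog import (CohortSequences, build_catalog, normalize_rows,
                      renormalize_signatures)
from .factorization import nmf_kl, nnls_exposures
from .patterns import Categorization


class RegularizedCCA:
    """Linear ridge-regularized CCA via the whitened-SVD formulation.

    Both views are z-scored on training statistics; ``reg`` is added to
    the diagonal of each view's (correlation-scale) covariance before
    whitening.  Constant training columns are dropped with a warning.
    """

    def __init__(self, n_components: int = 1, reg: float = 0.1):
        self.n_components = n_components
        self.reg = reg

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RegularizedCCA":
        self._mx, self._sx, self._keepx, xs = self._standardize(x)
        self._my, self._sy, self._keepy, ys = self._standardize(y)
        n = xs.shape[0]
        cxx = xs.T @ xs / n + self.reg * np.eye(xs.shape[1])
        cyy = ys.T @ ys / n + self.reg * np.eye(ys.shape[1])
        cxy = xs.T @ ys / n
        lx = linalg.cholesky(cxx, lower=True)
        ly = linalg.cholesky(cyy, lower=True)
        m = linalg.solve_triangular(lx, cxy, lower=True)
        m = linalg.solve_triangular(ly, m.T, lower=True).T
        u, s, vt = linalg.svd(m, full_matrices=False)
        d = min(self.n_components, s.size)
        self.x_weights_ = linalg.solve_triangular(lx.T, u[:, :d], lower=False)
        self.y_weights_ = linalg.solve_triangular(ly.T, vt[:d].T, lower=False)
        self.train_correlations_ = s[:d]
        return self

    @staticmethod
    def _standardize(a):
        a = np.asarray(a, float)
        mean = a.mean(axis=0)
        std = a.std(axis=0)
        keep = std > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant columns")
        std = np.where(keep, std, 1.0)
        return mean, std, keep, ((a - mean) / std)[:, keep]

    def transform(self, x: np.ndarray, y: np.ndarray):
        xs = ((np.asarray(x, float) - self._mx) / self._sx)[:, self._keepx]
        ys = ((np.asarray(y, float) - self._my) / self._sy)[:, self._keepy]
        return xs @ self.x_weights_, ys @ self.y_weights_


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cca_test_correlation(w: np.ndarray, e: np.ndarray, n_folds: int = 10,
                         regularization: float = 0.1, n_components: int = 1,
                         seed: int = 0) -> float:
    """Mean held-out first-canonical-pair correlation between two views.

    CCA coefficients are learned on training folds and the Pearson
    correlation of the projected held-out samples is averaged over folds.
    """
    w = np.asarray(w, float)
    e = np.asarray(e, float)
    if w.shape[0] != e.shape[0]:
        raise ValueError("views must have the same number of samples")
    if w.shape[0] < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples for {n_folds} folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rs = []
    for train, test in kf.split(w):
        cca = RegularizedCCA(n_components=n_components, reg=regularization)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cca.fit(w[train], e[train])
        xt, yt = cca.transform(w[test], e[test])
        rs.append(_pearson(xt[:, 0], yt[:, 0]))
    return float(np.mean(rs))


@dataclass
class FitnessConfig:
    """Knobs of the fitness pipeline (NMF order window, CV, CCA)."""

    k_range_radius: int = 2
    n_folds: int = 10
    regularization: float = 0.1
    n_components: int = 1
    nmf_restarts: int = 3
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6


@dataclass
class DatasetBundle:
    """One dataset: WGS cohort for signature learning, WES cohort with
    expression for evaluation, plus per-regime opportunity indices."""

    name: str
    wgs: CohortSequences
    wes: CohortSequences
    expression: np.ndarray              # (n_wes, genes)
    opp_idx_genome: np.ndarray          # (position, alt) universe indices
    opp_idx_exome: np.ndarray
    k_star: int = 3
    fold_seed: int = 0
    nmf_seed: int = 0

    def opportunity_vectors(self, cat: Categorization):
        table = cat.assignment
        m = cat.n_categories
        u_wgs = np.bincount(table[self.opp_idx_genome], minlength=m)
        u_wes = np.bincount(table[self.opp_idx_exome], minlength=m)
        return u_wgs, u_wes


@dataclass
class FitnessScore:
    value: float
    per_k: dict = field(default_factory=dict)   # K -> fold-mean correlation


def categorization_fitness(cat: Categorization, dataset: DatasetBundle,
                           config: FitnessConfig | None = None,
                           k_range: list[int] | None = None) -> FitnessScore:
    """Fitness of a categorization on one dataset.

    Per K in [K*-r, K*+r]: row-normalize the WGS catalog, fit KL-NMF,
    renormalize signatures from genome to exome opportunities, refit WES
    exposures by NNLS, and score the held-out CCA correlation against
    expression; the fitness is the mean over K values and folds.
    """
    cfg = config or FitnessConfig()
    if k_range is None:
        lo = dataset.k_star - cfg.k_range_radius
        if lo < 1:
            warnings.warn("K range lower bound clamped to 1")
        k_range = list(range(max(1, lo), dataset.k_star + cfg.k_range_radius + 1))
    v_wgs = normalize_rows(build_catalog(dataset.wgs, cat))
    v_wes = normalize_rows(build_catalog(dataset.wes, cat))
    u_wgs, u_wes = dataset.opportunity_vectors(cat)
    per_k = {}
    for k in k_range:
        res = nmf_kl(v_wgs, k, n_restarts=cfg.nmf_restarts,
                     max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol,
                     seed=dataset.nmf_seed + k)
        h = renormalize_signatures(res.h, u_wgs, u_wes)
        w = nnls_exposures(v_wes, h)
        per_k[k] = cca_test_correlation(
            w, dataset.expression, n_folds=cfg.n_folds,
            regularization=cfg.regularization,
            n_components=cfg.n_components, seed=dataset.fold_seed)
    return FitnessScore(value=float(np.mean(list(per_k.values()))), per_k=per_k)


# ---------------------------------------------------------------------------
# Ranking and selection
# ---------------------------------------------------------------------------

@dataclass
class RankingTable:
    per_dataset: np.ndarray     # (S, D) ranks, 1 = worst ... S = best
    average: np.ndarray         # (S,) rank of the mean-of-ranks, 1..S

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.average))


def _rank_1_to_s(values: np.ndarray) -> np.ndarray:
    """Ranks 1 (smallest) .. S (largest); ties broken by stable order."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def rank_population(fitness_values: np.ndarray) -> RankingTable:
    """Per-dataset ranks (1 = worst) and the rank of their mean."""
    f = np.atleast_2d(np.asarray(fitness_values, float))
    if f.ndim != 2:
        raise ValueError("expect individuals x datasets")
    if np.any(np.isnan(f)):
        raise ValueError("missing fitness scores")
    per = np.column_stack([_rank_1_to_s(f[:, d]) for d in range(f.shape[1])])
    avg = _rank_1_to_s(per.mean(axis=1))
    return RankingTable(per_dataset=per, average=avg)


def selection_probabilities(ranks: np.ndarray, power: float) -> np.ndarray:
    """P(select i) proportional to rank_i ** power."""
    if power <= 0:
        raise ValueError("power must be positive")
    r = np.asarray(ranks, float) ** power
    return r / r.sum()
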