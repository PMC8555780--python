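"""KL-divergence NMF, NNLS exposure refitting and rank selection.

Signatures are rows of H (probability vectors over categories); exposures
are rows of W.  The factorization V ~ WH is fit by multiplicative updates
minimizing the generalized Kullback-Leibler divergence, with an optional
observation mask so that rank selection can score held-out imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

_EPS = 1e-12


def kl_divergence(v: np.ndarray, w: np.ndarray, h: np.ndarray,
                  mask: np.ndarray | None = None,
                  floor: float = 0.0) -> float:
    """Generalized KL divergence D(V || WH), with 0 log 0 = 0.

    Returns +inf when (WH) vanishes where V is positive; a positive
    ``floor`` clips WH from below instead, giving a large finite penalty
    for categories the model assigns no mass (used when reporting
    out-of-sample errors on held-out samples).
    """
    v = np.asarray(v, float)
    wh = w @ h
    if floor > 0:
        wh = np.maximum(wh, floor)
    if mask is None:
        mask = np.ones_like(v, dtype=bool)
    pos = (v > 0) & mask
    if np.any(wh[pos] == 0):
        return float("inf")
    term = np.zeros_like(v)
    term[pos] = v[pos] * np.log(v[pos] / wh[pos])
    return float((term[mask] - v[mask] + wh[mask]).sum())


def _mu_kl(v, k, rng, max_iter, tol, mask=None, history=None):
    """One multiplicative-update run; returns (w, h, error).

    ``history``, if a list, collects the objective after every iteration.
    """
    n, m = v.shape
    scale = np.sqrt(max(v.mean(), _EPS) / k)
    w = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    h = rng.uniform(_EPS, 1.0, size=(k, m)) * scale
    ones = np.ones_like(v) if mask is None else mask.astype(float)
    vm = v if mask is None else v * mask
    prev = None
    for _ in range(max_iter):
        wh = w @ h
        ratio = vm / np.maximum(wh, _EPS)
        w *= (ratio @ h.T) / np.maximum(ones @ h.T, _EPS)
        wh = w @ h
        ratio = vm / np.maximum(wh, _EPS)
        h *= (w.T @ ratio) / np.maximum(w.T @ ones, _EPS)
        err = kl_divergence(v, w, h, mask=mask)
        if history is not None:
            history.append(err)
        if prev is not None and abs(prev - err) <= tol * max(abs(prev), _EPS):
            prev = err
            break
        prev = err
    return w, h, prev if prev is not None else kl_divergence(v, w, h, mask=mask)


def normalize_factors(w: np.ndarray, h: np.ndarray):
    """Rescale so H rows sum to 1, compensating in W; WH is unchanged."""
    row = h.sum(axis=1)
    row = np.where(row == 0, 1.0, row)
    return w * row[None, :], h / row[:, None]


@dataclass
class NMFResult:
    w: np.ndarray
    h: np.ndarray
    error: float
    seed: int


def nmf_kl(v: np.ndarray, k: int, n_restarts: int = 10,
           max_iter: int = 2000, tol: float = 1e-6, seed: int = 0,
           mask: np.ndarray | None = None) -> NMFResult:
    """Best-of-``n_restarts`` KL-NMF of a non-negative matrix.

    H rows are normalized to probability vectors with the compensating
    rescale absorbed into W.  ``mask`` (1 = observed) restricts the fit to
    observed entries, used for held-out rank selection.
    """
    v = np.asarray(v, float)
    if np.any(v < 0):
        raise ValueError("V must be non-negative")
    n, m = v.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"K={k} out of range for a {n}x{m} matrix")
    root = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        sub = int(root.integers(0, 2**31 - 1))
        w, h, err = _mu_kl(v, k, np.random.default_rng(sub), max_iter, tol,
                           mask=mask)
        if best is None or err < best.error:
            best = NMFResult(w, h, err, sub)
    w, h = normalize_factors(best.w, best.h)
    return NMFResult(w=w, h=h, error=best.error, seed=best.seed)


def nnls_exposures(v: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Per-sample non-negative least-squares exposures for fixed signatures.

    Row j solves min_{w >= 0} ||V_j - w H||_2.
    """
    v = np.asarray(v, float)
    h = np.asarray(h, float)
    if np.any(h.sum(axis=1) == 0):
        raise ValueError("H contains an all-zero signature row")
    w = np.empty((v.shape[0], h.shape[0]))
    for j in range(v.shape[0]):
        w[j], _ = nnls(h.T, v[j])
    return w


def _imputation_error(v, w, h, hidden) -> float:
    """Generalized KL on hidden entries with WH floored at eps, so a
    category driven to zero mass scores a large finite penalty."""
    wh = np.maximum(w @ h, _EPS)
    pos = (v > 0) & hidden
    term = np.zeros_like(v)
    term[pos] = v[pos] * np.log(v[pos] / wh[pos])
    return float((term[hidden] - v[hidden] + wh[hidden]).sum())


@dataclass
class RankSelection:
    k_star: int
    k_candidates: list[int]
    mean_errors: np.ndarray
    se_errors: np.ndarray


def select_k(v: np.ndarray, k_candidates, mask_fraction: float = 0.1,
             n_repeats: int = 3, seed: int = 0, n_restarts: int = 2,
             max_iter: int = 1000, tol: float = 1e-5) -> RankSelection:
    """Simplified cross-validation rank selector ("cv2k_lite").

    For each candidate K, a fraction of entries is hidden at random, a
    masked KL-NMF is fit on the rest, and the generalized KL imputation
    error is scored on the hidden entries; repeated ``n_repeats`` times.
    The chosen K* is the smallest candidate whose mean error is within one
    standard error of the overall minimum (parsimony).
    """
    v = np.asarray(v, float)
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("no K candidates")
    if k_candidates[-1] > min(v.shape):
        raise ValueError("candidate K exceeds matrix rank bound")
    rng = np.random.default_rng(seed)
    errs = np.empty((len(k_candidates), n_repeats))
    for r in range(n_repeats):
        mask = rng.random(v.shape) >= mask_fraction  # True = observed
        # ensure no all-hidden row/column
        mask[mask.sum(axis=1) == 0, 0] = True
        mask[0, mask.sum(axis=0) == 0] = True
        hidden = ~mask
        for i, k in enumerate(k_candidates):
            sub = int(rng.integers(0, 2**31 - 1))
            res = nmf_kl(v, k, n_restarts=n_restarts, max_iter=max_iter,
                         tol=tol, seed=sub, mask=mask)
            errs[i, r] = _imputation_error(v, res.w, res.h, hidden)
    mean = errs.mean(axis=1)
    se = errs.std(axis=1, ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 \
        else np.zeros(len(k_candidates))
    best = int(np.argmin(mean))
    cutoff = mean[best] + se[best]
    k_star = next(k for i, k in enumerate(k_candidates) if mean[i] <= cutoff)
    return RankSelection(k_star=int(k_star), k_candidates=k_candidates,
                         mean_errors=mean, se_errors=se)
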