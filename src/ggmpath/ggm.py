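"""Gaussian graphical model estimation for group brain graphs.

The group graphs are supports of sparse precision matrices: under a
Gaussian graphical model two nodes are conditionally independent given
all others exactly when their precision entry is zero.  Control and
patient precisions are estimated *jointly* with a fused graphical
lasso,

    minimize_Theta  sum_k n_k (-log det Theta_k + tr(S_k Theta_k))
                    + lambda1 * sum_k sum_{i != j} |theta^k_ij|
                    + lambda2 * sum_{k<k'} sum_{i,j} |theta^k_ij - theta^{k'}_ij|,

solved by ADMM.  The l1 penalty sparsifies each class; the fusion
penalty borrows strength across classes (groups, or the windows of one
subject) so that shared structure is estimated once while genuine
differences survive.  Estimated precisions are converted to partial
correlations, each entry is tested parametrically, and edges are kept
where the Benjamini-Hochberg-corrected p-value clears the chosen false
discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .graphs import Graph, NodeId


# --------------------------------------------------------------------------
# value types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceModel:
    """A symmetric positive-definite covariance matrix and its sample size."""

    sigma: np.ndarray
    n_effective: int

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("sigma must be symmetric (tolerance 1e-10)")
        try:
            np.linalg.cholesky(s)
        except np.linalg.LinAlgError as exc:
            raise ValueError("sigma must be positive definite") from exc
        object.__setattr__(self, "sigma", s)

    @property
    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.sigma))
        return self.sigma / np.outer(d, d)


@dataclass
class PrecisionEstimate:
    """Jointly estimated per-class precision matrices.

    ``theta[k]`` is the precision (inverse-covariance) estimate for
    class ``class_labels[k]``; ``n_per_class`` are the sample counts
    that weighted the likelihood terms.
    """

    theta: List[np.ndarray]
    class_labels: List
    lambda1: float
    lambda2: float
    n_per_class: List[int]
    n_iter: int = 0
    objective_trace: List[float] = field(default_factory=list)

    def covariance(self, k: int = 0) -> np.ndarray:
        return np.linalg.inv(self.theta[k])


@dataclass
class EdgeTestResult:
    """Partial correlations, edge p-values and the FDR-thresholded graph."""

    partial_corr: np.ndarray
    p_values: np.ndarray
    q_threshold: float
    adjacency: Graph


# --------------------------------------------------------------------------
# plain correlation and resampling
# --------------------------------------------------------------------------

def sample_correlation(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a time x node data matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (time x node)")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"node {bad} has a constant time course")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fft_resample(series: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited (Fourier zero-padding) upsampling of one series.

    At the default settings a 20-sample window becomes 400 samples
    (factor 20), which stabilises the window covariance estimates.
    """
    if factor < 1:
        raise ValueError("resample factor must be >= 1")
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("series must have at least 2 samples")
    if factor == 1:
        return series.copy()
    return signal.resample(series, series.shape[0] * factor, axis=0)


# --------------------------------------------------------------------------
# fused graphical lasso (ADMM)
# --------------------------------------------------------------------------

def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """L2 isotonic regression (pool adjacent violators), non-decreasing."""
    n = len(y)
    level = list(y)
    weight = [1.0] * n
    idx = []
    for i in range(n):
        idx.append(i)
        while len(idx) > 1 and level[idx[-2]] >= level[idx[-1]]:
            j = idx.pop()
            k = idx[-1]
            tot = weight[k] + weight[j]
            level[k] = (weight[k] * level[k] + weight[j] * level[j]) / tot
            weight[k] = tot
    out = np.empty(n)
    for m, start in enumerate(idx):
        end = idx[m + 1] if m + 1 < len(idx) else n
        out[start:end] = level[start]
    return out


def _prox_allpairs_fusion(a: np.ndarray, tau: float) -> np.ndarray:
    """Prox of tau * sum_{k<k'} |z_k - z_k'| at point ``a`` (length K).

    The minimiser preserves the ordering of ``a``; with the order fixed
    the penalty is linear in the sorted values, so the solution is the
    isotonic (PAVA) projection of a_(k) - tau*(2k - K - 1).
    """
    K = len(a)
    if K == 1 or tau == 0.0:
        return a.copy()
    order = np.argsort(a, kind="stable")
    shift = tau * (2.0 * np.arange(1, K + 1) - K - 1)
    z_sorted = _pava_nondecreasing(a[order] - shift)
    z = np.empty_like(a)
    z[order] = z_sorted
    return z


def _soft(a: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thr, 0.0)


def _penalty_value(thetas: Sequence[np.ndarray], lambda1: float, lambda2: float) -> float:
    p = thetas[0].shape[0]
    off = ~np.eye(p, dtype=bool)
    val = lambda1 * sum(np.abs(t[off]).sum() for t in thetas)
    K = len(thetas)
    for k in range(K):
        for kk in range(k + 1, K):
            val += lambda2 * np.abs(thetas[k] - thetas[kk]).sum()
    return val


def _jgl_objective(thetas, S_list, n_list, lambda1, lambda2) -> float:
    val = 0.0
    for t, S, n in zip(thetas, S_list, n_list):
        sign, logdet = np.linalg.slogdet(t)
        if sign <= 0:
            return np.inf
        val += n * (-logdet + float(np.sum(S * t)))
    return val + _penalty_value(thetas, lambda1, lambda2)


class ConvergenceError(RuntimeError):
    """ADMM failed to reach the residual tolerance; carries the residuals."""

    def __init__(self, msg, primal, dual):
        super().__init__(msg)
        self.primal = primal
        self.dual = dual


def joint_graphical_lasso(S_list: Sequence[np.ndarray],
                          n_list: Sequence[int],
                          lambda1: float,
                          lambda2: float,
                          tol: float = 1e-5,
                          max_iter: int = 1000,
                          rho: Optional[float] = None,
                          class_labels: Optional[Sequence] = None) -> PrecisionEstimate:
    """Fused graphical lasso over K classes by ADMM.

    Parameters
    ----------
    S_list : per-class covariance (or correlation) matrices, same shape.
    n_list : per-class sample counts weighting the likelihood terms.
    lambda1, lambda2 : absolute sparsity and fusion penalty weights.
    tol : relative primal/dual residual tolerance.
    rho : ADMM step; defaults to the mean sample count (the likelihood
        gradient scales with n) and is rebalanced adaptively.

    Returns the sparse consensus iterate, whose exact zeros define the
    estimated conditional-independence structure.
    """
    K = len(S_list)
    if K == 0:
        raise ValueError("need at least one covariance matrix")
    if len(n_list) != K:
        raise ValueError("n_list length must match S_list")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be non-negative")
    S_arr = []
    p = np.asarray(S_list[0]).shape[0]
    for S in S_list:
        S = np.asarray(S, dtype=float)
        if S.shape != (p, p):
            raise ValueError("all covariance matrices must share a dimension")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("covariance input is not symmetric")
        S_arr.append(0.5 * (S + S.T))
    n_arr = [float(n) for n in n_list]
    labels = list(class_labels) if class_labels is not None else list(range(K))

    if lambda1 == 0.0 and lambda2 == 0.0:
        # unpenalised maximum likelihood: closed form
        thetas = [np.linalg.inv(S) for S in S_arr]
        obj = _jgl_objective(thetas, S_arr, n_arr, 0.0, 0.0)
        return PrecisionEstimate(thetas, labels, lambda1, lambda2,
                                 [int(n) for n in n_arr], 0, [obj])

    rho = float(rho) if rho is not None else max(1.0, float(np.mean(n_arr)))
    Theta = [np.linalg.inv(S + 0.1 * np.eye(p)) for S in S_arr]
    Z = [t.copy() for t in Theta]
    U = [np.zeros((p, p)) for _ in range(K)]
    iu, ju = np.triu_indices(p)
    off_mask = iu != ju
    trace = []
    primal = dual = np.inf

    for it in range(max_iter):
        # Theta update: per-class eigen decomposition
        for k in range(K):
            M = rho * (Z[k] - U[k]) - n_arr[k] * S_arr[k]
            M = 0.5 * (M + M.T)
            d, V = np.linalg.eigh(M)
            theta_d = (d + np.sqrt(d * d + 4.0 * rho * n_arr[k])) / (2.0 * rho)
            Theta[k] = (V * theta_d) @ V.T

        # Z update: elementwise fused prox on the upper triangle
        Z_old = [z.copy() for z in Z]
        A = np.stack([Theta[k] + U[k] for k in range(K)])  # (K, p, p)
        A_ut = A[:, iu, ju]                                # (K, m)
        tau2 = lambda2 / rho
        thr1 = lambda1 / rho
        Znew_ut = np.empty_like(A_ut)
        for m in range(A_ut.shape[1]):
            z = _prox_allpairs_fusion(A_ut[:, m], tau2)
            if off_mask[m]:
                z = _soft(z, thr1)
            Znew_ut[:, m] = z
        for k in range(K):
            Zk = np.zeros((p, p))
            Zk[iu, ju] = Znew_ut[k]
            Zk[ju, iu] = Znew_ut[k]
            Z[k] = Zk

        # dual update and residuals
        prim_sq = dual_sq = 0.0
        scale = 0.0
        for k in range(K):
            U[k] += Theta[k] - Z[k]
            prim_sq += float(np.sum((Theta[k] - Z[k]) ** 2))
            dual_sq += float(np.sum((Z[k] - Z_old[k]) ** 2))
            scale = max(scale, float(np.linalg.norm(Theta[k])),
                        float(np.linalg.norm(Z[k])))
        primal = np.sqrt(prim_sq) / max(scale, 1e-12)
        dual = rho * np.sqrt(dual_sq) / max(scale, 1e-12)
        trace.append(_jgl_objective(Theta, S_arr, n_arr, lambda1, lambda2))

        if primal < tol and dual < tol:
            break
        if (it + 1) % 5 == 0:
            # residual balancing keeps the step well scaled
            if primal > 5 * dual:
                rho *= 1.5
                U = [u / 1.5 for u in U]
            elif dual > 5 * primal:
                rho /= 1.5
                U = [u * 1.5 for u in U]
    else:
        raise ConvergenceError(
            f"ADMM did not converge in {max_iter} iterations "
            f"(primal={primal:.2e}, dual={dual:.2e}, tol={tol:.0e})",
            primal, dual)

    # report the sparse consensus iterate when it is PD, else the PD iterate
    out = []
    for k in range(K):
        Zk = 0.5 * (Z[k] + Z[k].T)
        if np.linalg.eigvalsh(Zk)[0] > 1e-12:
            out.append(Zk)
        else:  # pragma: no cover - near-convergence safeguard
            out.append(0.5 * (Theta[k] + Theta[k].T))
    return PrecisionEstimate(out, labels, lambda1, lambda2,
                             [int(n) for n in n_arr], it + 1, trace)


# --------------------------------------------------------------------------
# partial correlation, significance, FDR
# --------------------------------------------------------------------------

ZERO_TOL = 1e-12  # entries below this are treated as structural zeros


def precision_to_partial_correlation(theta: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -omega_ij / sqrt(omega_ii omega_jj)."""
    theta = np.asarray(theta, dtype=float)
    if not np.allclose(theta, theta.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho[np.abs(rho) < ZERO_TOL] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def partial_correlation_significance(partial_corr: np.ndarray, n: int, p: int) -> np.ndarray:
    """Two-sided p-values for each partial correlation entry.

    The t statistic is r * sqrt(df / (1 - r^2)) with df = n - p (n
    samples, p - 2 controlled variables beyond the tested pair).
    Entries that are exactly zero (structural zeros of a sparsified
    precision) get p = 1.
    """
    if n <= p:
        raise ValueError(f"need n > p for the parametric test (n={n}, p={p})")
    r = np.asarray(partial_corr, dtype=float)
    df = n - p
    r2 = np.clip(r * r, 0.0, 1.0 - 1e-16)
    t = np.abs(r) * np.sqrt(df / (1.0 - r2))
    pvals = 2.0 * stats.t.sf(t, df)
    pvals = np.clip(pvals, 0.0, 1.0)
    pvals[np.abs(r) < ZERO_TOL] = 1.0
    np.fill_diagonal(pvals, 1.0)
    return 0.5 * (pvals + pvals.T)


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# --------------------------------------------------------------------------
# group graphs
# --------------------------------------------------------------------------

def edge_test(theta: np.ndarray, n: int, q: float = 0.05,
              node_ids: Optional[Sequence[NodeId]] = None) -> EdgeTestResult:
    """Partial-correlation edge test for one precision matrix.

    Edges are kept where the BH-corrected p-value is below ``q``.
    """
    p = theta.shape[0]
    ids = list(node_ids) if node_ids is not None else list(range(p))
    rho = precision_to_partial_correlation(theta)
    pmat = partial_correlation_significance(rho, n, p)
    iu, ju = np.triu_indices(p, k=1)
    mask = fdr_bh(pmat[iu, ju], q)
    edges = [(ids[i], ids[j]) for i, j, keep in zip(iu, ju, mask) if keep]
    return EdgeTestResult(rho, pmat, q, Graph(ids, edges))


def build_group_graphs(X_by_group: Dict[str, np.ndarray],
                       lambda1: float = 0.1,
                       lambda2: float = 0.05,
                       q: float = 0.05,
                       standardize: bool = True,
                       scale_penalties: bool = True,
                       tol: float = 1e-5,
                       max_iter: int = 1000,
                       node_ids: Optional[Sequence[NodeId]] = None,
                       ) -> Tuple[PrecisionEstimate, Dict[str, EdgeTestResult]]:
    """Jointly estimate and threshold one graph per group.

    ``X_by_group`` maps a group label to that group's concatenated
    time x node matrix.  ``lambda1``/``lambda2`` are on the
    per-observation scale: when ``scale_penalties`` is set they are
    multiplied by the mean group sample count before entering the
    n-weighted objective, so the defaults behave consistently across
    sample sizes.
    """
    labels = list(X_by_group)
    mats = [np.asarray(X_by_group[g], dtype=float) for g in labels]
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise ValueError("all groups must share the node count")
    S_list, n_list = [], []
    for m in mats:
        if standardize:
            sd = m.std(axis=0)
            if np.any(sd == 0):
                bad = int(np.flatnonzero(sd == 0)[0])
                raise ValueError(f"node {bad} has a constant time course")
            m = (m - m.mean(axis=0)) / sd
        S_list.append(np.cov(m, rowvar=False, bias=True))
        n_list.append(m.shape[0])
    scale = float(np.mean(n_list)) if scale_penalties else 1.0
    est = joint_graphical_lasso(S_list, n_list, lambda1 * scale, lambda2 * scale,
                                tol=tol, max_iter=max_iter, class_labels=labels)
    tests = {g: edge_test(est.theta[k], n_list[k], q, node_ids)
             for k, g in enumerate(labels)}
    return est, tests


def select_penalties_aic(X_by_group: Dict[str, np.ndarray],
                         lambda1_grid: Sequence[float] = (0.02, 0.05, 0.1, 0.2),
                         lambda2_grid: Sequence[float] = (0.0, 0.01, 0.05, 0.1),
                         standardize: bool = True,
                         tol: float = 1e-5,
                         max_iter: int = 1000) -> Tuple[float, float]:
    """Grid-search (lambda1, lambda2) minimising an AIC-style score.

    Score = sum_k n_k (-log det Theta_k + tr(S_k Theta_k)) + 2 * df,
    where df counts the free parameters of the sparse estimates (unique
    nonzero off-diagonals plus the diagonal, per class).  Penalties are
    on the per-observation scale, as in :func:`build_group_graphs`.
    """
    labels = list(X_by_group)
    S_list, n_list = [], []
    p = None
    for g in labels:
        m = np.asarray(X_by_group[g], dtype=float)
        if standardize:
            m = (m - m.mean(axis=0)) / m.std(axis=0)
        S_list.append(np.cov(m, rowvar=False, bias=True))
        n_list.append(m.shape[0])
        p = m.shape[1]
    scale = float(np.mean(n_list))
    best = (np.inf, None, None)
    iu, ju = np.triu_indices(p, k=1)
    for lam1 in lambda1_grid:
        for lam2 in lambda2_grid:
            est = joint_graphical_lasso(S_list, n_list, lam1 * scale,
                                        lam2 * scale, tol=tol, max_iter=max_iter)
            loglik = sum(
                n * (-np.linalg.slogdet(t)[1] + float(np.sum(S * t)))
                for t, S, n in zip(est.theta, S_list, n_list))
            df = sum(int(np.count_nonzero(t[iu, ju])) + p for t in est.theta)
            score = loglik + 2.0 * df
            if score < best[0]:
                best = (score, lam1, lam2)
    return best[1], best[2]
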