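"""Covariance decomposition into per-path weights on a GGM support.

For a Gaussian graphical model with precision matrix Omega, the
covariance between nodes x and y splits exactly over the simple paths
joining them:

    sigma_xy = sum over paths P = (p_1 .. p_t), p_1 = x, p_t = y, of
               (-1)^(t+1) * omega_{p1 p2} * ... * omega_{p(t-1) pt}
               * det(Omega_without_P) / det(Omega)

where Omega_without_P drops the rows and columns of the path's nodes
(the determinant of an empty matrix is 1).  Each term is that path's
*covariance weight*; dividing by sqrt(sigma_xx sigma_yy) gives the
*correlation weight*, a constant multiple that is comparable across
node pairs, and correlation weights of all paths of a pair sum to the
marginal correlation rho_xy.  Contribution percentages express a path
subset's share of rho_xy; individual weights may be negative or exceed
the total, only the sum is constrained.

Determinant ratios are evaluated in log-space via Cholesky
factorisations of principal submatrices (all positive definite by
interlacing); the sign is carried analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .graphs import (
    Edge,
    Graph,
    NodeId,
    NodePath,
    canonical_edge,
    connected_components,
    simple_paths,
)

_STRUCT_ZERO = 1e-12


@dataclass(frozen=True)
class PathWeight:
    """One simple path with its covariance / correlation weight.

    ``contribution_pct`` is the signed percentage of the endpoint
    correlation carried by this path (100 * corr_weight / rho_xy).
    """

    path: NodePath
    cov_weight: float
    corr_weight: Optional[float] = None
    contribution_pct: Optional[float] = None


@dataclass(frozen=True)
class PathComparison:
    """Cross-group comparison of the path sets joining one node pair."""

    pair: Edge
    common_paths: Tuple[NodePath, ...]
    distinct_paths: Dict[str, Tuple[NodePath, ...]]
    distinct_contribution_pct: Dict[str, float]
    flagged: bool
    correlation_difference: float
    correlations: Dict[str, float]
    weights: Dict[str, Tuple[PathWeight, ...]]


def _chol_logdet(mat: np.ndarray) -> float:
    if mat.shape[0] == 0:
        return 0.0  # det of the empty matrix is 1
    L = np.linalg.cholesky(mat)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def _check_pd(omega: np.ndarray) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(omega, omega.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    return omega


def path_weight(omega: np.ndarray, path: NodePath,
                node_order: Optional[Sequence[NodeId]] = None) -> float:
    """Covariance weight of one simple path (single decomposition term)."""
    omega = _check_pd(omega)
    p = omega.shape[0]
    order = list(node_order) if node_order is not None else list(range(p))
    index = {nid: i for i, nid in enumerate(order)}
    seq = [index[n] for n in path.sequence]
    t = len(seq)
    logdet_full = _chol_logdet(omega)
    rest = [i for i in range(p) if i not in set(seq)]
    logdet_rest = _chol_logdet(omega[np.ix_(rest, rest)])
    sign = (-1.0) ** (t + 1)
    log_mag = 0.0
    for a, b in zip(seq[:-1], seq[1:]):
        w = omega[a, b]
        if w == 0.0:
            return 0.0
        sign *= np.sign(w)
        log_mag += np.log(abs(w))
    return float(sign * np.exp(log_mag + logdet_rest - logdet_full))


def decompose_pair(omega: np.ndarray, support: Graph, x: NodeId, y: NodeId,
                   node_order: Optional[Sequence[NodeId]] = None,
                   max_length: Optional[int] = None,
                   max_paths: int = 10 ** 6) -> List[PathWeight]:
    """All path weights between ``x`` and ``y`` over the support graph.

    The path universe is the (significance-thresholded) support graph;
    the sum of the returned covariance weights equals the (x, y) entry
    of ``inv(omega)``.  An unreachable pair yields an empty list.
    """
    if x == y:
        raise ValueError("endpoints must differ")
    omega = _check_pd(omega)
    order = list(node_order) if node_order is not None else list(support.nodes)
    if len(order) != omega.shape[0]:
        raise ValueError("node_order length must match omega dimension")
    index = {nid: i for i, nid in enumerate(order)}
    for (u, v) in support.edges:
        if abs(omega[index[u], index[v]]) < _STRUCT_ZERO:
            raise ValueError(
                f"support edge ({u!r}, {v!r}) has a (near-)zero precision entry")
    part = connected_components(support)
    if not part.same_block(x, y):
        return []
    paths = simple_paths(support, x, y, max_length=max_length, max_paths=max_paths)
    return [PathWeight(pth, path_weight(omega, pth, order)) for pth in paths]


def correlation_weights(decomp: Sequence[PathWeight],
                        sigma: "np.ndarray | object",
                        node_order: Optional[Sequence[NodeId]] = None) -> List[PathWeight]:
    """Rescale covariance weights by the endpoint standard deviations.

    corr_weight = cov_weight / sqrt(sigma_xx sigma_yy); for the paths of
    one pair the correlation weights sum to rho_xy, and each path's
    signed share of that total is recorded as ``contribution_pct``.
    """
    sig = getattr(sigma, "sigma", sigma)
    sig = np.asarray(sig, dtype=float)
    p = sig.shape[0]
    order = list(node_order) if node_order is not None else list(range(p))
    index = {nid: i for i, nid in enumerate(order)}
    out: List[PathWeight] = []
    for pw in decomp:
        xi, yi = (index[n] for n in pw.path.endpoints)
        vxx, vyy = sig[xi, xi], sig[yi, yi]
        if vxx <= 0 or vyy <= 0:
            raise ValueError("endpoint variances must be positive")
        out.append(replace(pw, corr_weight=pw.cov_weight / np.sqrt(vxx * vyy)))
    total = endpoint_correlation(out)
    if total != 0.0:
        out = [replace(pw, contribution_pct=100.0 * pw.corr_weight / total)
               for pw in out]
    return out


def endpoint_correlation(weights: Sequence[PathWeight]) -> float:
    """Aggregate the correlation weights of one pair: equals rho_xy."""
    return float(sum(pw.corr_weight for pw in weights))


def contribution(weights: Sequence[PathWeight],
                 subset: Iterable[NodePath]) -> float:
    """Signed percentage of the endpoint correlation carried by a path subset."""
    total = endpoint_correlation(weights)
    if total == 0.0:
        raise ValueError("endpoint correlation is zero; contribution undefined")
    chosen: Set[NodePath] = set(subset)
    part = sum(pw.corr_weight for pw in weights if pw.path in chosen)
    return float(100.0 * part / total)


def compare_path_sets(control: Tuple[np.ndarray, Graph],
                      patient: Tuple[np.ndarray, Graph],
                      x: NodeId, y: NodeId,
                      flag_threshold_pct: float = 50.0,
                      node_order: Optional[Sequence[NodeId]] = None,
                      max_paths: int = 10 ** 6) -> PathComparison:
    """Compare the path trajectories of a still-connected pair across groups.

    Both groups must connect the pair (reachability case 3); otherwise
    the caller should consult the differential report instead.  Paths
    are matched by canonical node sequence; each group's *distinct*
    paths (absent from the other group) are scored by their signed
    share of that group's endpoint correlation and the pair is flagged
    when either share exceeds ``flag_threshold_pct``.
    """
    (omega_c, support_c), (omega_p, support_p) = control, patient
    if support_c.node_set != support_p.node_set:
        raise ValueError("group supports must share a node set")
    for label, support in (("control", support_c), ("patient", support_p)):
        if not connected_components(support).same_block(x, y):
            raise ValueError(
                f"pair ({x!r}, {y!r}) is not reachable in the {label} graph "
                "(not case 3); use differential_report for this pair")
    order = list(node_order) if node_order is not None else list(support_c.nodes)
    results: Dict[str, List[PathWeight]] = {}
    corr: Dict[str, float] = {}
    for label, omega, support in (("control", omega_c, support_c),
                                  ("patient", omega_p, support_p)):
        dec = decompose_pair(omega, support, x, y, node_order=order,
                             max_paths=max_paths)
        dec = correlation_weights(dec, np.linalg.inv(omega), node_order=order)
        results[label] = dec
        corr[label] = endpoint_correlation(dec)
    paths_c = {pw.path for pw in results["control"]}
    paths_p = {pw.path for pw in results["patient"]}
    common = tuple(sorted(paths_c & paths_p, key=lambda pth: (pth.t, pth.sequence)))
    distinct = {
        "control": tuple(sorted(paths_c - paths_p, key=lambda pth: (pth.t, pth.sequence))),
        "patient": tuple(sorted(paths_p - paths_c, key=lambda pth: (pth.t, pth.sequence))),
    }
    distinct_pct = {}
    for label in ("control", "patient"):
        if corr[label] == 0.0:
            distinct_pct[label] = 0.0 if not distinct[label] else np.nan
        else:
            distinct_pct[label] = contribution(results[label], distinct[label])
    flagged = any(np.isfinite(v) and v > flag_threshold_pct
                  for v in distinct_pct.values())
    return PathComparison(
        pair=canonical_edge(x, y),
        common_paths=common,
        distinct_paths=distinct,
        distinct_contribution_pct=distinct_pct,
        flagged=flagged,
        correlation_difference=corr["control"] - corr["patient"],
        correlations=corr,
        weights={k: tuple(v) for k, v in results.items()},
    )
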