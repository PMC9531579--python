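"""Sliding-window dynamic connectivity and brain-state discovery.

Each subject's time courses are cut into overlapping rectangular
windows (default 20 samples, step 5), every window is upsampled by
Fourier zero-padding, and the window covariances are jointly estimated
with the fused graphical lasso (windows of one subject are the classes,
so adjacent structure is shared).  The per-window correlation matrices,
flattened to their upper triangles, are then clustered into recurring
connectivity *states* by k-means with the L1 (Manhattan) distance and
coordinate-wise median centroids, initialised from subject exemplars --
windows at local maxima of the across-feature variance.  State counts
can be chosen by the elbow criterion on the within-cluster cost curve.

Per state, windows' original time points are concatenated by group and
passed back to the static group-graph estimator, and univariate
two-sample t-tests (on per-subject state means) locate cell-wise group
differences under Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .ggm import (
    EdgeTestResult,
    PrecisionEstimate,
    build_group_graphs,
    fdr_bh,
    fft_resample,
    joint_graphical_lasso,
)

# --------------------------------------------------------------------------
# windowing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """Half-open sliding windows [start, start + w) over T samples."""

    window_length: int
    step: int
    starts: Tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.starts)


def sliding_windows(T: int, w: int, s: int) -> WindowSpec:
    """Window layout with K = floor((T - w) / s) windows at multiples of s.

    A typical 162-sample resting-state scan with w = 20, s = 5 gives 28
    windows under this convention.  At least one window must fit.
    """
    if w < 2:
        raise ValueError("window length must be >= 2")
    if s < 1:
        raise ValueError("step must be >= 1")
    if T <= w:
        raise ValueError(f"need T > w (T={T}, w={w})")
    K = (T - w) // s
    if K < 1:
        raise ValueError(f"no window fits: floor((T - w)/s) = 0 for (T={T}, w={w}, s={s})")
    return WindowSpec(w, s, tuple(i * s for i in range(K)))


@dataclass
class WindowedFNC:
    """Per-window correlation matrices of one subject."""

    subject_id: object
    matrices: List[np.ndarray]

    @property
    def features(self) -> np.ndarray:
        """Windows x features matrix of flattened upper triangles."""
        p = self.matrices[0].shape[0]
        iu, ju = np.triu_indices(p, k=1)
        return np.stack([m[iu, ju] for m in self.matrices])


def window_fnc_series(X: np.ndarray, spec: WindowSpec,
                      resample_factor: int = 20,
                      lambda1: float = 0.1, lambda2: float = 0.005,
                      scale_penalties: bool = True,
                      tol: float = 1e-5, max_iter: int = 2000,
                      subject_id: object = None) -> WindowedFNC:
    """Windowed correlation matrices via joint estimation across windows.

    Each window is sliced, FFT-upsampled column-wise by
    ``resample_factor``, and its covariance enters a fused graphical
    lasso whose classes are the subject's windows.  The reported
    per-window matrix is the correlation matrix implied by the inverse
    of that window's precision estimate.

    The default fusion weight is smaller than the two-class group
    default because the all-pairs penalty couples every window with
    every other (K - 1 terms per window); a heavier weight flattens
    genuine state dynamics toward the subject mean.  The many-class
    problem also needs more ADMM iterations, hence the larger default
    cap.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < spec.window_length:
        raise ValueError("time series shorter than the window length")
    S_list, n_list = [], []
    for start in spec.starts:
        seg = X[start:start + spec.window_length]
        seg = fft_resample(seg, resample_factor)
        seg = seg - seg.mean(axis=0)
        sd = seg.std(axis=0)
        sd[sd == 0] = 1.0
        seg = seg / sd
        S_list.append(np.cov(seg, rowvar=False, bias=True))
        n_list.append(seg.shape[0])
    scale = float(np.mean(n_list)) if scale_penalties else 1.0
    est = joint_graphical_lasso(S_list, n_list, lambda1 * scale, lambda2 * scale,
                                tol=tol, max_iter=max_iter)
    mats = []
    for theta in est.theta:
        cov = np.linalg.inv(theta)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        mats.append(np.clip(corr, -1.0, 1.0))
    return WindowedFNC(subject_id, mats)


# --------------------------------------------------------------------------
# exemplars and L1 k-means
# --------------------------------------------------------------------------

def subject_exemplars(fnc: WindowedFNC) -> List[int]:
    """Window indices at local maxima of the across-feature variance.

    Interior windows qualify when strictly greater than both
    neighbours; an endpoint qualifies when strictly greater than its
    single neighbour.  A single window is its own exemplar.
    """
    var = fnc.features.var(axis=1)
    n = len(var)
    if n == 1:
        return [0]
    out = []
    for i in range(n):
        left_ok = i == 0 or var[i] > var[i - 1]
        right_ok = i == n - 1 or var[i] > var[i + 1]
        if left_ok and right_ok:
            out.append(i)
    return out


def kmeans_l1(points: np.ndarray, k: int,
              init: Union[str, np.ndarray] = "random",
              replicates: int = 1, seed: int = 0,
              max_iter: int = 300) -> Tuple[np.ndarray, np.ndarray, float]:
    """k-means with Manhattan distance and coordinate-wise median centroids.

    ``init`` is either "random" (k distinct data points per replicate;
    the best of ``replicates`` runs by total L1 cost is kept) or an
    explicit (k, d) centroid array (a single run).  Empty clusters are
    re-seeded at the point farthest from its assigned centroid.
    Deterministic for a fixed seed.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    rng = np.random.default_rng(seed)

    def run(centroids: np.ndarray):
        centroids = centroids.copy()
        assign = np.full(n, -1)
        for _ in range(max_iter):
            D = cdist(X, centroids, metric="cityblock")
            new_assign = D.argmin(axis=1)
            # re-seed empty clusters at the worst-fit point
            for c in range(k):
                if not np.any(new_assign == c):
                    far = D[np.arange(n), new_assign].argmax()
                    centroids[c] = X[far]
                    D = cdist(X, centroids, metric="cityblock")
                    new_assign = D.argmin(axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c in range(k):
                members = X[assign == c]
                if len(members):
                    centroids[c] = np.median(members, axis=0)
        D = cdist(X, centroids, metric="cityblock")
        assign = D.argmin(axis=1)
        cost = float(D[np.arange(n), assign].sum())
        return centroids, assign, cost

    if isinstance(init, np.ndarray):
        return run(np.asarray(init, dtype=float))
    best = None
    for _ in range(max(1, replicates)):
        idx = rng.choice(n, size=k, replace=False)
        result = run(X[idx])
        if best is None or result[2] < best[2]:
            best = result
    return best


def select_k_elbow(points: np.ndarray, k_range: Sequence[int],
                   replicates: int = 10, seed: int = 0,
                   cost_fn=None) -> int:
    """Elbow choice of k: maximise the second difference of the cost curve.

    W(k) is the best total within-cluster L1 cost; the selected k
    maximises W(k-1) - 2 W(k) + W(k+1) over interior k, ties broken
    toward smaller k.  ``cost_fn`` may inject a cost curve (testing).
    """
    ks = list(k_range)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be contiguous with length >= 3")
    if cost_fn is None:
        costs = [kmeans_l1(points, k, replicates=replicates, seed=seed + i)[2]
                 for i, k in enumerate(ks)]
    else:
        costs = [float(cost_fn(k)) for k in ks]
    best_k, best_score = None, -np.inf
    for i in range(1, len(ks) - 1):
        score = costs[i - 1] - 2.0 * costs[i] + costs[i + 1]
        if score > best_score:
            best_k, best_score = ks[i], score
    return best_k


# --------------------------------------------------------------------------
# state model
# --------------------------------------------------------------------------

@dataclass
class StateModel:
    """Clustered connectivity states over all subjects' windows."""

    k: int
    centroids: np.ndarray
    assignments: Dict[object, np.ndarray]  # subject -> per-window state
    exemplar_indices: Dict[object, List[int]] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return sum(len(a) for a in self.assignments.values())

    def flat_labels(self) -> np.ndarray:
        return np.concatenate([self.assignments[s] for s in self.assignments])


def cluster_states(fncs: Sequence[WindowedFNC], k: int,
                   replicates: int = 50, seed: int = 0) -> StateModel:
    """Two-phase state clustering.

    Phase 1 clusters the pooled subject exemplars with ``replicates``
    random restarts; phase 2 clusters every window of every subject in
    a single run initialised at the exemplar centroids.
    """
    feats = [f.features for f in fncs]
    all_points = np.vstack(feats)
    if k > all_points.shape[0]:
        raise ValueError("more clusters than windows")
    exemplar_idx = {f.subject_id: subject_exemplars(f) for f in fncs}
    ex_points = np.vstack([feats[i][exemplar_idx[f.subject_id]]
                           for i, f in enumerate(fncs)])
    if ex_points.shape[0] >= k:
        centroids, _, _ = kmeans_l1(ex_points, k, init="random",
                                    replicates=replicates, seed=seed)
    else:  # too few exemplars; fall back to random init on all windows
        centroids, _, _ = kmeans_l1(all_points, k, init="random",
                                    replicates=replicates, seed=seed)
    centroids, flat_assign, _ = kmeans_l1(all_points, k, init=centroids)
    assignments: Dict[object, np.ndarray] = {}
    pos = 0
    for i, f in enumerate(fncs):
        nw = feats[i].shape[0]
        assignments[f.subject_id] = flat_assign[pos:pos + nw].copy()
        pos += nw
    return StateModel(k, centroids, assignments, exemplar_idx)


def state_occupancy(model: StateModel, groups: Mapping[object, str]):
    """Occupancy tables for a state model.

    Returns ``(state_wise, composition)`` as pandas DataFrames:
    ``state_wise`` rows are "all" plus each group, giving the
    percentage of that row's windows assigned to each state (rows sum
    to 100); ``composition`` gives, per state, the percentage of its
    windows contributed by each group (rows sum to 100).
    """
    import pandas as pd

    for subject in model.assignments:
        if subject not in groups:
            raise ValueError(f"subject {subject!r} has no group label")
    group_names = sorted(set(groups[s] for s in model.assignments))
    k = model.k
    counts = {g: np.zeros(k, dtype=int) for g in group_names}
    for subject, assign in model.assignments.items():
        g = groups[subject]
        for state in assign:
            counts[g][state] += 1
    total = sum(counts[g] for g in group_names)
    rows = {"all": 100.0 * total / total.sum()}
    for g in group_names:
        denom = counts[g].sum()
        rows[g] = 100.0 * counts[g] / denom if denom else np.zeros(k)
    state_wise = pd.DataFrame(rows, index=[f"state_{i}" for i in range(k)]).T
    comp = {}
    for i in range(k):
        denom = total[i]
        comp[f"state_{i}"] = {
            g: (100.0 * counts[g][i] / denom if denom else 0.0) for g in group_names}
    composition = pd.DataFrame(comp).T[group_names]
    return state_wise, composition


# --------------------------------------------------------------------------
# group tests and per-state graphs
# --------------------------------------------------------------------------

def group_difference_tests(matrices_by_group: Mapping[str, Sequence[np.ndarray]],
                           q: float = 0.05, welch: bool = False):
    """Element-wise two-sample t-tests between two groups of matrices.

    Input maps each of two group labels to a list of per-subject
    symmetric matrices (sFNC, or per-subject state means for dFNC).
    Returns (t matrix, p matrix, BH rejection mask) with the test run
    on the upper triangle and mirrored.
    """
    labels = list(matrices_by_group)
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    stacks = []
    for g in labels:
        mats = list(matrices_by_group[g])
        if len(mats) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
        stacks.append(np.stack(mats))
    p_dim = stacks[0].shape[1]
    iu, ju = np.triu_indices(p_dim, k=1)
    a = stacks[0][:, iu, ju]
    b = stacks[1][:, iu, ju]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    mask = fdr_bh(p, q)
    t_mat = np.zeros((p_dim, p_dim))
    p_mat = np.ones((p_dim, p_dim))
    m_mat = np.zeros((p_dim, p_dim), dtype=bool)
    t_mat[iu, ju] = t
    t_mat[ju, iu] = t
    p_mat[iu, ju] = p
    p_mat[ju, iu] = p
    m_mat[iu, ju] = mask
    m_mat[ju, iu] = mask
    return t_mat, p_mat, m_mat


def state_mean_matrices(model: StateModel,
                        fncs: Mapping[object, WindowedFNC]) -> Dict[int, Dict[object, np.ndarray]]:
    """Per-state mean connectivity matrix for each subject.

    A subject contributes to a state only when at least one of its
    windows is assigned there.
    """
    out: Dict[int, Dict[object, np.ndarray]] = {s: {} for s in range(model.k)}
    for subject, assign in model.assignments.items():
        mats = fncs[subject].matrices
        for s in range(model.k):
            idx = np.flatnonzero(assign == s)
            if idx.size:
                out[s][subject] = np.mean([mats[i] for i in idx], axis=0)
    return out


def state_group_difference_tests(model: StateModel,
                                 fncs: Mapping[object, WindowedFNC],
                                 groups: Mapping[object, str],
                                 q: float = 0.05, welch: bool = False):
    """Univariate dFNC group tests per state on per-subject state means."""
    means = state_mean_matrices(model, fncs)
    group_names = sorted(set(groups.values()))
    out = {}
    for s in range(model.k):
        by_group = {g: [m for subj, m in means[s].items() if groups[subj] == g]
                    for g in group_names}
        if any(len(v) < 2 for v in by_group.values()):
            warnings.warn(f"state {s}: a group has fewer than 2 subjects; test skipped")
            continue
        out[s] = group_difference_tests(by_group, q=q, welch=welch)
    return out


def state_group_graphs(model: StateModel,
                       series: Mapping[object, np.ndarray],
                       groups: Mapping[object, str],
                       spec: WindowSpec,
                       lambda1: float = 0.1, lambda2: float = 0.05,
                       q: float = 0.05,
                       node_ids: Optional[Sequence] = None,
                       tol: float = 1e-5, max_iter: int = 1000,
                       ) -> Dict[int, Tuple[PrecisionEstimate, Dict[str, EdgeTestResult]]]:
    """Per-state group graphs from concatenated member-window time points.

    For each state the original (un-resampled) time points of the
    windows assigned to it are concatenated within each group and fed
    to the static joint group-graph estimator.  States where either
    group has no windows are skipped with a warning.
    """
    group_names = sorted(set(groups.values()))
    out = {}
    for s in range(model.k):
        segs = {g: [] for g in group_names}
        for subject, assign in model.assignments.items():
            X = np.asarray(series[subject], dtype=float)
            g = groups[subject]
            for widx in np.flatnonzero(assign == s):
                start = spec.starts[widx]
                segs[g].append(X[start:start + spec.window_length])
        if any(len(v) == 0 for v in segs.values()):
            warnings.warn(f"state {s}: empty (state, group) cell; state skipped")
            continue
        X_by_group = {g: np.vstack(v) for g, v in segs.items()}
        out[s] = build_group_graphs(X_by_group, lambda1=lambda1, lambda2=lambda2,
                                    q=q, node_ids=node_ids, tol=tol,
                                    max_iter=max_iter)
    return out
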