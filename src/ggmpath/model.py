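"""Model / Results interface over the path-analysis pipeline.

`GroupGraphModel` fits jointly estimated static group graphs from
per-subject time series and returns a `GroupGraphResults` carrying the
precision estimates, edge tests, thresholded graphs, the
disconnector/connector report and path-decomposition helpers.
`DynamicStateModel` runs the sliding-window pipeline (windowed joint
estimation, L1 k-means states, occupancy, per-state graphs and
reports) and returns a `DynamicStateResults`.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import decompose as _decompose
from .dynamics import (
    StateModel,
    WindowedFNC,
    WindowSpec,
    cluster_states,
    select_k_elbow,
    sliding_windows,
    state_group_difference_tests,
    state_group_graphs,
    state_occupancy,
    window_fnc_series,
)
from .ggm import EdgeTestResult, PrecisionEstimate, build_group_graphs, sample_correlation
from .graphs import Graph, NodeId
from .io import Dataset
from .pathdiff import DifferentialReport, differential_report


def _dataset_from_arg(data) -> Dataset:
    if isinstance(data, Dataset):
        return data
    if isinstance(data, Mapping):  # group -> list of matrices
        subjects = []
        for g, mats in data.items():
            for i, m in enumerate(mats):
                subjects.append((f"{g}_{i:02d}", str(g), np.asarray(m, dtype=float)))
        return Dataset(subjects)
    raise TypeError("data must be a Dataset or a mapping group -> list of matrices")


class GroupGraphModel:
    """Static two-group Gaussian graphical model of multi-subject series.

    Parameters
    ----------
    data : Dataset or mapping group -> list of time x node matrices
    reference_group : group treated as the control/reference slot;
        defaults to the alphabetically first label.
    node_ids : optional node identifiers (defaults to 0..p-1).
    """

    def __init__(self, data, reference_group: Optional[str] = None,
                 node_ids: Optional[Sequence[NodeId]] = None):
        self.data = _dataset_from_arg(data)
        groups = sorted(set(self.data.groups.values()))
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {groups}")
        self.reference_group = reference_group or groups[0]
        if self.reference_group not in groups:
            raise ValueError(f"unknown reference group {reference_group!r}")
        self.comparison_group = next(g for g in groups if g != self.reference_group)
        self.node_ids = (list(node_ids) if node_ids is not None
                         else list(range(self.data.n_nodes)))

    def mean_sfnc(self) -> Dict[str, np.ndarray]:
        """Group-mean static FNC (Pearson over the full time course)."""
        sums: Dict[str, list] = {}
        for sid, g, mat in self.data.subjects:
            sums.setdefault(g, []).append(sample_correlation(mat))
        return {g: np.mean(mats, axis=0) for g, mats in sums.items()}

    def fit(self, lambda1: float = 0.1, lambda2: float = 0.05,
            q: float = 0.05, tol: float = 1e-5,
            max_iter: int = 1000) -> "GroupGraphResults":
        X_by_group = self.data.concatenated_by_group()
        est, tests = build_group_graphs(
            X_by_group, lambda1=lambda1, lambda2=lambda2, q=q,
            tol=tol, max_iter=max_iter, node_ids=self.node_ids)
        return GroupGraphResults(self, est, tests)


class GroupGraphResults:
    """Fitted group graphs plus the path-based differential analysis."""

    def __init__(self, model: GroupGraphModel, precision: PrecisionEstimate,
                 edge_tests: Dict[str, EdgeTestResult]):
        self.model = model
        self.precision = precision
        self.edge_tests = edge_tests
        self.graphs: Dict[str, Graph] = {g: t.adjacency for g, t in edge_tests.items()}
        self._report: Optional[DifferentialReport] = None

    def theta(self, group: str) -> np.ndarray:
        k = self.precision.class_labels.index(group)
        return self.precision.theta[k]

    def theta_on_support(self, group: str) -> np.ndarray:
        """Precision projected onto the significance-thresholded graph.

        Off-diagonal entries without a surviving edge are zeroed (with
        diagonal loading if the projection costs positive
        definiteness), so the reported graph and the decomposition's
        path universe describe the same model and the per-path weights
        of a pair sum exactly to its implied correlation.
        """
        theta = self.theta(group).copy()
        ids = self.model.node_ids
        index = {nid: i for i, nid in enumerate(ids)}
        keep = np.eye(len(ids), dtype=bool)
        for (u, v) in self.graphs[group].edges:
            keep[index[u], index[v]] = keep[index[v], index[u]] = True
        theta[~keep] = 0.0
        lo = float(np.linalg.eigvalsh(theta)[0])
        if lo <= 1e-10:
            theta += (1e-6 - lo) * np.eye(len(ids))
        return theta

    @property
    def report(self) -> DifferentialReport:
        if self._report is None:
            self._report = differential_report(
                self.graphs[self.model.reference_group],
                self.graphs[self.model.comparison_group])
        return self._report

    def decompose_pair(self, x: NodeId, y: NodeId, group: str,
                       max_paths: int = 10 ** 6):
        """Per-path correlation weights between x and y in one group."""
        theta = self.theta_on_support(group)
        dec = _decompose.decompose_pair(theta, self.graphs[group], x, y,
                                        node_order=self.model.node_ids,
                                        max_paths=max_paths)
        return _decompose.correlation_weights(dec, np.linalg.inv(theta),
                                              node_order=self.model.node_ids)

    def compare_paths(self, x: NodeId, y: NodeId,
                      flag_threshold_pct: float = 50.0,
                      max_paths: int = 10 ** 6):
        ref, cmp_ = self.model.reference_group, self.model.comparison_group
        return _decompose.compare_path_sets(
            (self.theta_on_support(ref), self.graphs[ref]),
            (self.theta_on_support(cmp_), self.graphs[cmp_]),
            x, y, flag_threshold_pct=flag_threshold_pct,
            node_order=self.model.node_ids, max_paths=max_paths)

    def summary(self) -> str:
        rep = self.report
        ref, cmp_ = self.model.reference_group, self.model.comparison_group
        lines = [
            "Group graphical model: path-based differential analysis",
            "=" * 56,
            f"reference (control) group : {ref}",
            f"comparison (patient) group: {cmp_}",
            f"nodes: {len(self.model.node_ids)}   "
            f"edges {ref}: {len(self.graphs[ref].edges)}   "
            f"edges {cmp_}: {len(self.graphs[cmp_].edges)}",
            f"lambda1={self.precision.lambda1:.6g}  "
            f"lambda2={self.precision.lambda2:.6g}  "
            f"(absolute, after sample-size scaling)",
            "-" * 56,
            f"disconnectors     : {rep.sorted('disconnectors')}",
            f"connectors        : {rep.sorted('connectors')}",
            f"simple missing    : {rep.sorted('simple_missing')}",
            f"simple additional : {rep.sorted('simple_additional')}",
            f"pairs reachable in both groups (case 3): "
            f"{len(rep.pairs_in_case(3))}",
        ]
        return "\n".join(lines)


class DynamicStateModel:
    """Sliding-window dynamic connectivity model with recurring states."""

    def __init__(self, data, window: int = 20, step: int = 5,
                 resample_factor: int = 20,
                 reference_group: Optional[str] = None,
                 node_ids: Optional[Sequence[NodeId]] = None):
        self.data = _dataset_from_arg(data)
        groups = sorted(set(self.data.groups.values()))
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {groups}")
        self.reference_group = reference_group or groups[0]
        self.comparison_group = next(g for g in groups if g != self.reference_group)
        self.window = window
        self.step = step
        self.resample_factor = resample_factor
        self.node_ids = (list(node_ids) if node_ids is not None
                         else list(range(self.data.n_nodes)))
        T = self.data.subjects[0][2].shape[0]
        self.window_spec: WindowSpec = sliding_windows(T, window, step)

    def compute_windowed_fnc(self, lambda1: float = 0.1, lambda2: float = 0.005,
                             tol: float = 1e-5,
                             max_iter: int = 2000) -> Dict[str, WindowedFNC]:
        out = {}
        for sid, _, mat in self.data.subjects:
            out[sid] = window_fnc_series(
                mat, self.window_spec, resample_factor=self.resample_factor,
                lambda1=lambda1, lambda2=lambda2, tol=tol, max_iter=max_iter,
                subject_id=sid)
        return out

    def fit(self, k="auto", replicates: int = 50, seed: int = 0,
            lambda1: float = 0.1, lambda2: float = 0.005,
            lambda2_group: float = 0.05, q: float = 0.05,
            k_range: Sequence[int] = range(2, 8),
            tol: float = 1e-5, max_iter: int = 2000) -> "DynamicStateResults":
        """Run the full dynamic pipeline.

        ``lambda2`` fuses a subject's windows during windowed FNC
        estimation; ``lambda2_group`` fuses the two groups in the
        per-state graph estimation.
        """
        fncs = self.compute_windowed_fnc(lambda1, lambda2, tol, max_iter)
        fnc_list = [fncs[sid] for sid, _, _ in self.data.subjects]
        if k == "auto":
            pooled = np.vstack([f.features for f in fnc_list])
            k = select_k_elbow(pooled, k_range, replicates=max(5, replicates // 5),
                               seed=seed)
        states = cluster_states(fnc_list, int(k), replicates=replicates, seed=seed)
        graphs = state_group_graphs(
            states, self.data.series(), self.data.groups, self.window_spec,
            lambda1=lambda1, lambda2=lambda2_group, q=q, node_ids=self.node_ids,
            tol=tol, max_iter=max_iter)
        return DynamicStateResults(self, fncs, states, graphs, q)


class DynamicStateResults:
    """Fitted dynamic states: occupancy, per-state graphs and reports."""

    def __init__(self, model: DynamicStateModel, fncs: Dict[str, WindowedFNC],
                 states: StateModel,
                 graphs_by_state: Dict[int, Tuple[PrecisionEstimate, Dict[str, EdgeTestResult]]],
                 q: float):
        self.model = model
        self.fncs = fncs
        self.states = states
        self.graphs_by_state = graphs_by_state
        self.q = q

    def occupancy(self):
        return state_occupancy(self.states, self.model.data.groups)

    def group_difference_tests(self, welch: bool = False):
        return state_group_difference_tests(
            self.states, self.fncs, self.model.data.groups, q=self.q, welch=welch)

    def report(self, state: int) -> DifferentialReport:
        _, tests = self.graphs_by_state[state]
        return differential_report(
            tests[self.model.reference_group].adjacency,
            tests[self.model.comparison_group].adjacency)

    def reports(self) -> Dict[int, DifferentialReport]:
        return {s: self.report(s) for s in self.graphs_by_state}

    def summary(self) -> str:
        state_wise, composition = self.occupancy()
        lines = [
            "Dynamic state model: path-based differential analysis",
            "=" * 56,
            f"windows: {self.states.n_windows} "
            f"({self.model.window_spec.count} per subject, "
            f"w={self.model.window}, step={self.model.step})",
            f"states: {self.states.k}",
            "",
            "state-wise occupancy (% of row's windows):",
            state_wise.round(1).to_string(),
            "",
            "state composition (% of state's windows per group):",
            composition.round(1).to_string(),
            "-" * 56,
        ]
        for s in sorted(self.graphs_by_state):
            rep = self.report(s)
            lines.append(f"state {s}: disconnectors {rep.sorted('disconnectors')} "
                         f"connectors {rep.sorted('connectors')}")
        return "\n".join(lines)
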