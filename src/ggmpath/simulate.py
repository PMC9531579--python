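"""Synthetic multi-group Gaussian graphical data with planted differences.

Resting-state fMRI component time courses are modelled as zero-mean Gaussian
node x time matrices drawn from sparse positive-definite precision
matrices.  Generators here plant the exact structures the differential
analysis looks for: bridge edges removed from the patient support
(disconnectors), cross-component edges added to it (connectors), and
state-specific removals in multi-state dynamic data.  Everything is a
pure function of its seed.

These are idealised draws: i.i.d. in time, no hemodynamic
autocorrelation, no site effects, and effect sizes chosen so that
recovery is reliable at desk-scale sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .graphs import Edge, Graph, canonical_edge
from .pathdiff import transition_edges_oracle

DEFAULT_WEIGHT_RANGE = (0.25, 0.45)
MIN_EIGENVALUE = 0.1


def _pd_repair(omega: np.ndarray, min_eig: float = MIN_EIGENVALUE) -> np.ndarray:
    """Diagonal loading so the smallest eigenvalue is at least ``min_eig``."""
    omega = 0.5 * (omega + omega.T)
    lo = float(np.linalg.eigvalsh(omega)[0])
    if lo < min_eig:
        omega = omega + (min_eig - lo) * np.eye(omega.shape[0])
    return omega


def _fill_weights(support_edges, p, rng,
                  weight_range=DEFAULT_WEIGHT_RANGE,
                  signs: Optional[Dict[Edge, float]] = None,
                  magnitudes: Optional[Dict[Edge, float]] = None) -> np.ndarray:
    omega = np.eye(p)
    for (u, v) in support_edges:
        e = canonical_edge(u, v)
        mag = magnitudes[e] if magnitudes and e in magnitudes else rng.uniform(*weight_range)
        sign = signs[e] if signs and e in signs else (1.0 if rng.random() < 0.5 else -1.0)
        omega[u, v] = omega[v, u] = sign * mag
    return _pd_repair(omega)


def random_sparse_precision(p: int, density: float, seed: int = 0,
                            weight_range: Tuple[float, float] = DEFAULT_WEIGHT_RANGE,
                            min_eig: float = MIN_EIGENVALUE) -> np.ndarray:
    """Random sparse PD precision on an Erdos-Renyi support.

    Off-diagonals carry random signs and magnitudes in
    ``weight_range``; the diagonal is loaded until the smallest
    eigenvalue reaches ``min_eig``.
    """
    if p < 2:
        raise ValueError("need p >= 2")
    if density < 0 or density > 1:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i in range(p) for j in range(i + 1, p)
             if rng.random() < density]
    omega = np.eye(p)
    for (i, j) in edges:
        w = rng.uniform(*weight_range) * (1.0 if rng.random() < 0.5 else -1.0)
        omega[i, j] = omega[j, i] = w
    return _pd_repair(omega, min_eig)


def support_graph(omega: np.ndarray, tol: float = 1e-10) -> Graph:
    """Graph of the nonzero off-diagonal pattern of a precision matrix."""
    p = omega.shape[0]
    edges = [(i, j) for i in range(p) for j in range(i + 1, p)
             if abs(omega[i, j]) > tol]
    return Graph(range(p), edges)


@dataclass(frozen=True)
class PlantedScenario:
    """Two-group precisions with known disconnector / connector edges."""

    omega_control: np.ndarray
    omega_patient: np.ndarray
    planted_disconnectors: FrozenSet[Edge]
    planted_connectors: FrozenSet[Edge]
    planted_simple_missing: FrozenSet[Edge]
    planted_simple_additional: FrozenSet[Edge]
    seed: int

    @property
    def support_control(self) -> Graph:
        return support_graph(self.omega_control)

    @property
    def support_patient(self) -> Graph:
        return support_graph(self.omega_patient)


def _random_connected_edges(nodes: Sequence[int], density: float, rng) -> List[Edge]:
    """Random connected support: random spanning tree plus extra edges."""
    order = list(nodes)
    rng.shuffle(order)
    edges = set()
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        edges.add(canonical_edge(order[i], order[j]))
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            if rng.random() < density:
                edges.add(canonical_edge(order[a], order[b]))
    return sorted(edges)


def planted_group_precisions(p: int, density: float = 0.12,
                             n_disconnect: int = 1, n_connect: int = 1,
                             seed: int = 0,
                             weight_range: Tuple[float, float] = DEFAULT_WEIGHT_RANGE,
                             min_eig: float = MIN_EIGENVALUE,
                             max_attempts: int = 100) -> PlantedScenario:
    """Control/patient precision pair with planted path-breaking edits.

    The control support is built in blocks: one connected "arena" block
    from which ``n_disconnect`` bridges are removed in the patient
    support (each removal separates its endpoints), and, when
    ``n_connect`` > 0, a chain of small auxiliary components joined in
    the patient support by ``n_connect`` fresh cross-component edges.
    By construction the transition-edge characterisation recovers the
    planted sets exactly.
    """
    if p < 4:
        raise ValueError("need p >= 4")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        n_aux_blocks = n_connect + 1 if n_connect > 0 else 0
        aux_size = 2 if p - 2 * n_aux_blocks >= n_disconnect + 2 else 1
        arena_size = p - aux_size * n_aux_blocks
        if arena_size < n_disconnect + 2:
            raise ValueError("requested counts infeasible for this p")
        nodes = list(range(p))
        arena = nodes[:arena_size]
        aux_blocks = [nodes[arena_size + i * aux_size: arena_size + (i + 1) * aux_size]
                      for i in range(n_aux_blocks)]

        control_edges = set(_random_connected_edges(arena, density, rng))
        for block in aux_blocks:
            if len(block) == 2:
                control_edges.add(canonical_edge(*block))

        arena_graph = nx.Graph(sorted(e for e in control_edges
                                      if e[0] in set(arena) and e[1] in set(arena)))
        arena_graph.add_nodes_from(arena)
        bridges = sorted(canonical_edge(*b) for b in nx.bridges(arena_graph))
        if len(bridges) < n_disconnect:
            continue
        rng.shuffle(bridges)
        removed = sorted(bridges[:n_disconnect])

        added: List[Edge] = []
        for i in range(n_connect):
            u = aux_blocks[i][int(rng.integers(0, len(aux_blocks[i])))]
            v = aux_blocks[i + 1][int(rng.integers(0, len(aux_blocks[i + 1])))]
            added.append(canonical_edge(u, v))

        patient_edges = (control_edges - set(removed)) | set(added)

        shared_signs: Dict[Edge, float] = {}
        shared_mags: Dict[Edge, float] = {}
        for e in sorted(control_edges | patient_edges):
            shared_signs[e] = 1.0 if rng.random() < 0.5 else -1.0
            shared_mags[e] = rng.uniform(*weight_range)
        omega_c = _fill_weights(sorted(control_edges), p, rng,
                                signs=shared_signs, magnitudes=shared_mags)
        omega_p = _fill_weights(sorted(patient_edges), p, rng,
                                signs=shared_signs, magnitudes=shared_mags)
        omega_c = _pd_repair(omega_c, min_eig)
        omega_p = _pd_repair(omega_p, min_eig)

        scenario = PlantedScenario(
            omega_c, omega_p,
            frozenset(removed), frozenset(added),
            frozenset(), frozenset(), seed)
        # construction invariant: the oracle recovers exactly the planted sets
        gc, gp = scenario.support_control, scenario.support_patient
        if (transition_edges_oracle(gc, gp) == scenario.planted_disconnectors
                and transition_edges_oracle(gp, gc) == scenario.planted_connectors):
            return scenario
    raise RuntimeError(f"could not plant the requested structure in {max_attempts} attempts")


def sample_timeseries(omega: np.ndarray, T: int, n_subjects: int = 1,
                      seed: int = 0) -> List[np.ndarray]:
    """Zero-mean Gaussian time x node draws with covariance inv(omega)."""
    if T < 2:
        raise ValueError("need T >= 2")
    rng = np.random.default_rng(seed)
    sigma = np.linalg.inv(_pd_repair(np.asarray(omega, dtype=float), 1e-8))
    L = np.linalg.cholesky(sigma)
    p = sigma.shape[0]
    return [rng.standard_normal((T, p)) @ L.T for _ in range(n_subjects)]


@dataclass
class DynamicScenario:
    """Multi-state, two-group dynamic dataset with known window labels."""

    series: Dict[str, np.ndarray]            # subject -> time x node
    groups: Dict[str, str]                   # subject -> group label
    true_window_labels: Dict[str, List[Optional[int]]]
    state_precisions: List[Tuple[np.ndarray, np.ndarray]]  # (control, patient)
    affected_state: int
    planted_disconnector: Optional[Edge]
    window_length: int
    step: int
    state_sequences: Dict[str, List[int]] = field(default_factory=dict)


def planted_dynamic_scenario(p: int = 8, k_states: int = 3,
                             subjects_per_group: int = 8, T: int = 162,
                             window_spec: Tuple[int, int] = (20, 5),
                             seed: int = 0,
                             density: float = 0.45,
                             weight_range: Tuple[float, float] = (0.35, 0.5),
                             affected_state: int = 1,
                             segments_per_subject: int = 2,
                             plant_difference: bool = True) -> DynamicScenario:
    """Contiguous-segment multi-state data with one state-specific edit.

    The states share one sparse support but carry state-specific signs
    and magnitudes (distinct sign patterns), the kind of well-separated
    recurring connectivity profiles sliding-window state analysis
    assumes.  One designated pendant node hangs off the shared support
    by a single bridge edge; in ``affected_state`` the patient
    precision drops that bridge (the planted disconnector) while every
    other state is identical across groups.

    Each subject dwells in ``segments_per_subject`` contiguous
    equal-length segments (default two, i.e. one state switch per scan)
    whose states are a seeded random draw of distinct states; segment
    boundaries sit on the window step grid so windows are either pure,
    75/25 blends, or exact 50/50 ties.  Ground-truth window labels
    follow the majority (> 50%) state; windows without a majority are
    labelled None.
    """
    w, s = window_spec
    if segments_per_subject < 1 or segments_per_subject > k_states:
        raise ValueError("segments_per_subject must be in [1, k_states]")
    seg_len = T // segments_per_subject
    if seg_len < w:
        raise ValueError("state segments must be at least one window long")
    rng = np.random.default_rng(seed)

    # shared support over nodes 0..p-2 plus a pendant bridge to node p-1
    core = list(range(p - 1))
    support = set()
    while not support:
        support = {canonical_edge(i, j)
                   for i in core for j in core if i < j and rng.random() < density}
    bridge_anchor = int(rng.integers(0, p - 1))
    bridge = canonical_edge(bridge_anchor, p - 1)
    support.add(bridge)

    state_precisions: List[Tuple[np.ndarray, np.ndarray]] = []
    planted: Optional[Edge] = bridge if plant_difference else None
    for st in range(k_states):
        omega = _fill_weights(sorted(support), p, rng, weight_range=weight_range)
        if plant_difference and st == affected_state:
            omega_p = omega.copy()
            omega_p[bridge[0], bridge[1]] = 0.0
            omega_p[bridge[1], bridge[0]] = 0.0
            state_precisions.append((omega, _pd_repair(omega_p)))
        else:
            state_precisions.append((omega, omega))

    # per-state Cholesky factors for both groups
    chol = [(np.linalg.cholesky(np.linalg.inv(oc)),
             np.linalg.cholesky(np.linalg.inv(op)))
            for oc, op in state_precisions]

    # segment boundaries snapped to the window step grid
    bounds = [int(round((T * k / segments_per_subject) / s)) * s
              for k in range(segments_per_subject)] + [T]
    series: Dict[str, np.ndarray] = {}
    groups: Dict[str, str] = {}
    labels: Dict[str, List[Optional[int]]] = {}
    sequences: Dict[str, List[int]] = {}
    n_windows = (T - w) // s
    for gi, group in enumerate(("control", "patient")):
        for si in range(subjects_per_group):
            subject = f"{group}_{si:02d}"
            order = list(rng.permutation(k_states)[:segments_per_subject])
            X = np.empty((T, p))
            time_state = np.empty(T, dtype=int)
            for seg, st in enumerate(order):
                a, b = bounds[seg], bounds[seg + 1]
                L = chol[st][gi]
                X[a:b] = rng.standard_normal((b - a, p)) @ L.T
                time_state[a:b] = st
            wlabels: List[Optional[int]] = []
            for wi in range(n_windows):
                start = wi * s
                seg_states = time_state[start:start + w]
                vals, counts = np.unique(seg_states, return_counts=True)
                if counts.max() * 2 > w:
                    wlabels.append(int(vals[counts.argmax()]))
                else:
                    wlabels.append(None)
            series[subject] = X
            groups[subject] = group
            labels[subject] = wlabels
            sequences[subject] = order
    return DynamicScenario(series, groups, labels, state_precisions,
                           affected_state, planted, w, s, sequences)


def figure3_fixture() -> Tuple[Graph, Graph]:
    """The 10-node control/patient toy pair used as a worked example.

    The control graph has components {1..7} and {8, 9, 10}; the patient
    graph has {1, 2, 3, 4} and {5..10}.  Edge (2, 5) is the lone
    disconnector, (6, 8) the lone connector, while (1, 4) and (8, 10)
    are simple missing / additional edges that change no reachability.
    """
    nodes = range(1, 11)
    control = Graph(nodes, [(1, 2), (2, 3), (3, 4), (1, 4), (2, 5),
                            (5, 6), (6, 7), (8, 9), (9, 10)])
    patient = Graph(nodes, [(1, 2), (2, 3), (3, 4), (5, 6), (6, 7),
                            (6, 8), (8, 9), (9, 10), (8, 10)])
    return control, patient
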