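"""Dataset readers/writers and report serialisation.

Interchange is plain delimited text: per-subject TSV matrices (rows =
time, columns = nodes), a manifest CSV (subject_id, group, file), an
optional node-metadata CSV (id, label, domain), edge-list CSVs and
GraphML for graphs, and JSON for reports.  Floats are written at 10
significant digits with stable key order so outputs are byte-stable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .decompose import PathComparison, PathWeight
from .graphs import Graph, NodeId
from .pathdiff import DifferentialReport


@dataclass
class Dataset:
    """Per-subject time x node matrices with group labels and node metadata."""

    subjects: List[Tuple[str, str, np.ndarray]]  # (id, group, matrix)
    node_table: Optional[Mapping[NodeId, Tuple[str, str]]] = None
    tr_seconds: Optional[float] = None

    def __post_init__(self):
        ids = [s for s, _, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if not self.subjects:
            raise ValueError("dataset has no subjects")
        p = self.subjects[0][2].shape[1]
        for sid, _, mat in self.subjects:
            if mat.ndim != 2 or mat.shape[1] != p:
                raise ValueError(f"subject {sid!r}: node count mismatch "
                                 f"({mat.shape} vs p={p})")

    @property
    def n_nodes(self) -> int:
        return self.subjects[0][2].shape[1]

    @property
    def groups(self) -> Dict[str, str]:
        return {sid: g for sid, g, _ in self.subjects}

    def series(self) -> Dict[str, np.ndarray]:
        return {sid: mat for sid, _, mat in self.subjects}

    def concatenated_by_group(self) -> Dict[str, np.ndarray]:
        out: Dict[str, List[np.ndarray]] = {}
        for _, g, mat in self.subjects:
            out.setdefault(g, []).append(mat)
        return {g: np.vstack(mats) for g, mats in out.items()}


def read_timeseries_dataset(manifest_path: str, data_dir: Optional[str] = None,
                            node_table_path: Optional[str] = None) -> Dataset:
    """Load a dataset from a manifest CSV (subject_id, group, file)."""
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "file"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = data_dir if data_dir is not None else os.path.dirname(manifest_path)
    subjects = []
    expected_rows = expected_cols = None
    for _, row in manifest.iterrows():
        path = os.path.join(base, str(row["file"]))
        try:
            mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"subject {row['subject_id']!r}: non-numeric cell "
                             f"in {path} ({exc})") from exc
        if expected_cols is None:
            expected_rows, expected_cols = mat.shape
        elif mat.shape != (expected_rows, expected_cols):
            raise ValueError(
                f"subject {row['subject_id']!r}: dimension mismatch "
                f"{mat.shape} vs expected {(expected_rows, expected_cols)}")
        subjects.append((str(row["subject_id"]), str(row["group"]), mat))
    node_table = None
    if node_table_path:
        nt = pd.read_csv(node_table_path)
        node_table = {row["id"]: (str(row["label"]), str(row["domain"]))
                      for _, row in nt.iterrows()}
    return Dataset(subjects, node_table)


def write_dataset(dataset: Dataset, out_dir: str) -> str:
    """Write per-subject TSVs plus a manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for sid, group, mat in dataset.subjects:
        fname = f"{sid}.tsv"
        np.savetxt(os.path.join(out_dir, fname), mat, delimiter="\t", fmt="%.10g")
        rows.append({"subject_id": sid, "group": group, "file": fname})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# --------------------------------------------------------------------------
# serialisation helpers
# --------------------------------------------------------------------------

def _fmt(x: float) -> float:
    return float(f"{x:.10g}")


def write_matrix(mat: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(mat), delimiter="\t", fmt="%.10g")


def write_graph_edgelist(graph: Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("source,target\n")
        for (u, v) in graph.sorted_edges():
            fh.write(f"{u},{v}\n")


def read_graph_edgelist(path: str, nodes: Optional[Sequence[NodeId]] = None) -> Graph:
    df = pd.read_csv(path)
    edges = [(row["source"], row["target"]) for _, row in df.iterrows()]

    def norm(x):
        try:
            i = int(x)
            return i if str(i) == str(x) else x
        except (TypeError, ValueError):
            return x

    edges = [(norm(u), norm(v)) for u, v in edges]
    if nodes is None:
        nodes = sorted({n for e in edges for n in e},
                       key=lambda x: (isinstance(x, str), x))
    return Graph(nodes, edges)


def write_graphml(graph: Graph, path: str) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def report_to_dict(report: DifferentialReport,
                   labels: Optional[Mapping[NodeId, Tuple[str, str]]] = None) -> dict:
    def edge_entry(e):
        entry = {"edge": list(e)}
        if labels:
            entry["labels"] = [list(labels.get(n, (str(n), ""))) for n in e]
        return entry

    return {
        "disconnectors": [edge_entry(e) for e in report.sorted("disconnectors")],
        "connectors": [edge_entry(e) for e in report.sorted("connectors")],
        "simple_missing": [edge_entry(e) for e in report.sorted("simple_missing")],
        "simple_additional": [edge_entry(e) for e in report.sorted("simple_additional")],
        "pair_cases": [{"pair": list(pair), "case": case}
                       for pair, case in sorted(
                           report.pair_cases.items(),
                           key=lambda kv: [(isinstance(n, str), n) for n in kv[0]])],
    }


def write_report_json(report: DifferentialReport, path: str,
                      labels=None) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report, labels), fh, indent=2, sort_keys=True)
        fh.write("\n")


def decomposition_to_dict(weights: Sequence[PathWeight],
                          labels=None) -> dict:
    entries = []
    for pw in weights:
        entry = {"path": list(pw.path.sequence), "cov_weight": _fmt(pw.cov_weight)}
        if pw.corr_weight is not None:
            entry["corr_weight"] = _fmt(pw.corr_weight)
        if pw.contribution_pct is not None:
            entry["contribution_pct"] = _fmt(pw.contribution_pct)
        if labels:
            entry["labels"] = [list(labels.get(n, (str(n), "")))
                               for n in pw.path.sequence]
        entries.append(entry)
    out = {"paths": entries, "n_paths": len(entries)}
    if entries and weights[0].corr_weight is not None:
        out["endpoint_correlation"] = _fmt(sum(pw.corr_weight for pw in weights))
    return out


def write_decomposition_json(weights: Sequence[PathWeight], path: str,
                             labels=None) -> None:
    with open(path, "w") as fh:
        json.dump(decomposition_to_dict(weights, labels), fh, indent=2, sort_keys=True)
        fh.write("\n")
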