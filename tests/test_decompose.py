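"""Covariance path-weight decomposition: closed forms and conservation."""

import numpy as np
import pytest

from ggmpath.decompose import (
    PathWeight,
    compare_path_sets,
    contribution,
    correlation_weights,
    decompose_pair,
    endpoint_correlation,
    path_weight,
)
from ggmpath.graphs import Graph, NodePath
from ggmpath.simulate import random_sparse_precision, support_graph


class TestPathWeight:
    def test_two_by_two_closed_form(self):
        a, b, c = 2.0, -0.7, 1.5
        omega = np.array([[a, b], [b, c]])
        w = path_weight(omega, NodePath([0, 1]), node_order=[0, 1])
        assert w == pytest.approx(-b / (a * c - b * b), abs=1e-12)
        assert w == pytest.approx(np.linalg.inv(omega)[0, 1], abs=1e-12)

    def test_three_node_chain_matches_cofactor(self):
        a, b, c, d, e = 2.0, -0.8, 2.5, 0.6, 1.8
        omega = np.array([[a, b, 0.0], [b, c, d], [0.0, d, e]])
        w = path_weight(omega, NodePath([0, 1, 2]), node_order=[0, 1, 2])
        assert w == pytest.approx(b * d / np.linalg.det(omega), abs=1e-12)
        assert w == pytest.approx(np.linalg.inv(omega)[0, 2], abs=1e-12)

    def test_full_cover_path_uses_empty_determinant_convention(self):
        omega = np.array([[2.0, -0.9, 0.0], [-0.9, 2.2, 0.5], [0.0, 0.5, 1.9]])
        w = path_weight(omega, NodePath([0, 1, 2]), node_order=[0, 1, 2])
        t = 3
        expected = (-1) ** (t + 1) * (-0.9) * 0.5 / np.linalg.det(omega)
        assert w == pytest.approx(expected, abs=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            path_weight(np.array([[1.0, 2.0], [2.0, 1.0]]), NodePath([0, 1]),
                        node_order=[0, 1])


class TestDecomposePair:
    def test_conservation_on_random_sparse_precisions(self):
        # sum of path covariance weights equals the covariance entry
        for seed in range(40):
            p = 4 + seed % 7
            omega = random_sparse_precision(p, 0.3, seed=seed)
            sup = support_graph(omega)
            sigma = np.linalg.inv(omega)
            for x in range(p):
                for y in range(x + 1, p):
                    ws = decompose_pair(omega, sup, x, y, node_order=range(p))
                    assert sum(w.cov_weight for w in ws) == pytest.approx(
                        sigma[x, y], abs=1e-8)

    def test_disconnected_pair_empty_and_zero_covariance(self):
        omega = np.array([[1.0, 0.5, 0, 0], [0.5, 1.2, 0, 0],
                          [0, 0, 1.1, -0.4], [0, 0, -0.4, 1.3]])
        sup = support_graph(omega)
        assert decompose_pair(omega, sup, 0, 2, node_order=range(4)) == []
        assert abs(np.linalg.inv(omega)[0, 2]) < 1e-10

    def test_detour_topology_yields_three_paths(self):
        # edges a-x, x-b, a-b, a-y, y-b around endpoints a, b
        edges = [(0, 2), (2, 1), (0, 1), (0, 3), (3, 1)]
        omega = np.eye(4)
        rng = np.random.default_rng(5)
        for (i, j) in edges:
            omega[i, j] = omega[j, i] = rng.uniform(0.2, 0.4)
        omega += np.eye(4) * (abs(min(np.linalg.eigvalsh(omega))) + 0.2)
        sup = support_graph(omega)
        ws = decompose_pair(omega, sup, 0, 1, node_order=range(4))
        assert len(ws) == 3
        assert {w.path.sequence for w in ws} == {(0, 1), (0, 2, 1), (0, 3, 1)}

    def test_support_with_zero_entry_rejected(self):
        omega = np.diag([1.0, 2.0])
        sup = Graph([0, 1], [(0, 1)])
        with pytest.raises(ValueError, match="zero precision entry"):
            decompose_pair(omega, sup, 0, 1, node_order=[0, 1])

    def test_weight_vanishes_continuously_with_shrinking_edge(self):
        base = np.array([[2.0, -0.5, 0.0], [-0.5, 2.0, 0.5], [0.0, 0.5, 2.0]])
        prev = np.inf
        for scale in (1.0, 0.1, 0.01, 0.001):
            omega = base.copy()
            omega[1, 2] = omega[2, 1] = 0.5 * scale
            w = path_weight(omega, NodePath([0, 1, 2]), node_order=range(3))
            assert abs(w) < prev
            prev = abs(w)
        assert prev < 1e-3


class TestCorrelationWeights:
    def test_printed_per_path_weights_aggregate_to_endpoint_correlations(self):
        # reported per-path correlation weights for one visual-domain pair
        def as_weights(vals):
            paths = [NodePath([0, i + 2, 1]) for i in range(len(vals))]
            return [PathWeight(pth, np.nan, corr_weight=v)
                    for pth, v in zip(paths, vals)]

        control = as_weights([0.0044, 0.0002])
        patient = as_weights([0.0668, 0.0044, 0.0055, 0.0005])
        assert endpoint_correlation(control) == pytest.approx(0.0046, abs=1e-12)
        assert endpoint_correlation(patient) == pytest.approx(0.0772, abs=1e-12)
        one_path = contribution(patient, [patient[2].path])
        assert round(one_path, 1) == 7.1

    def test_sum_equals_marginal_correlation(self):
        omega = random_sparse_precision(6, 0.4, seed=11)
        sup = support_graph(omega)
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        for x in range(6):
            for y in range(x + 1, 6):
                ws = correlation_weights(
                    decompose_pair(omega, sup, x, y, node_order=range(6)),
                    sigma, node_order=range(6))
                if ws:
                    assert endpoint_correlation(ws) == pytest.approx(
                        corr[x, y], abs=1e-8)

    def test_invariant_under_variable_rescaling(self):
        omega = random_sparse_precision(5, 0.5, seed=3)
        sup = support_graph(omega)
        sigma = np.linalg.inv(omega)
        scale = np.diag([1.0, 2.0, 0.5, 3.0, 0.25])
        sigma2 = scale @ sigma @ scale
        omega2 = np.linalg.inv(sigma2)
        # rescaling keeps the support; compare correlation weights
        ws1 = correlation_weights(
            decompose_pair(omega, sup, 0, 4, node_order=range(5)),
            sigma, node_order=range(5))
        ws2 = correlation_weights(
            decompose_pair(omega2, sup, 0, 4, node_order=range(5)),
            sigma2, node_order=range(5))
        for a, b in zip(ws1, ws2):
            assert a.path == b.path
            assert a.corr_weight == pytest.approx(b.corr_weight, abs=1e-10)


class TestContribution:
    def test_full_set_is_hundred_percent_and_partitions_add_up(self, rng):
        omega = random_sparse_precision(7, 0.35, seed=21)
        sup = support_graph(omega)
        sigma = np.linalg.inv(omega)
        ws = correlation_weights(
            decompose_pair(omega, sup, 0, 6, node_order=range(7)),
            sigma, node_order=range(7))
        if not ws:
            pytest.skip("pair disconnected in this draw")
        assert contribution(ws, [w.path for w in ws]) == pytest.approx(100.0, abs=1e-9)
        half = len(ws) // 2
        part_a = contribution(ws, [w.path for w in ws[:half]])
        part_b = contribution(ws, [w.path for w in ws[half:]])
        assert part_a + part_b == pytest.approx(100.0, abs=1e-9)

    def test_individual_contributions_may_exceed_total(self):
        # cancelling weights: one path above 100%, one negative
        paths = [NodePath([0, 2, 1]), NodePath([0, 3, 1])]
        ws = [PathWeight(paths[0], np.nan, corr_weight=0.3),
              PathWeight(paths[1], np.nan, corr_weight=-0.2)]
        assert contribution(ws, [paths[0]]) == pytest.approx(300.0)
        assert contribution(ws, [paths[1]]) == pytest.approx(-200.0)

    def test_zero_total_correlation_is_an_error(self):
        paths = [NodePath([0, 2, 1]), NodePath([0, 3, 1])]
        ws = [PathWeight(paths[0], np.nan, corr_weight=0.5),
              PathWeight(paths[1], np.nan, corr_weight=-0.5)]
        with pytest.raises(ValueError, match="zero"):
            contribution(ws, [paths[0]])


class TestComparePathSets:
    def test_identical_models_have_no_distinct_paths(self):
        omega = random_sparse_precision(6, 0.4, seed=2)
        sup = support_graph(omega)
        pair = None
        from ggmpath.graphs import connected_components
        part = connected_components(sup)
        for x in range(6):
            for y in range(x + 1, 6):
                if part.same_block(x, y):
                    pair = (x, y)
                    break
            if pair:
                break
        cmp_ = compare_path_sets((omega, sup), (omega, sup), *pair,
                                 node_order=range(6))
        assert cmp_.distinct_paths == {"control": (), "patient": ()}
        assert cmp_.distinct_contribution_pct == {"control": 0.0, "patient": 0.0}
        assert not cmp_.flagged
        assert cmp_.correlation_difference == pytest.approx(0.0, abs=1e-12)

    def test_high_weight_detour_is_flagged(self):
        # control: single path 0-1; patient adds a strong detour 0-2-1
        control = np.array([[1.5, -0.1, 0.0], [-0.1, 1.5, 0.0], [0.0, 0.0, 1.0]])
        patient = np.array([[1.5, -0.1, -0.9], [-0.1, 1.5, -0.9], [-0.9, -0.9, 2.4]])
        cmp_ = compare_path_sets((control, support_graph(control)),
                                 (patient, support_graph(patient)),
                                 0, 1, node_order=range(3))
        assert cmp_.distinct_paths["patient"] == (NodePath([0, 2, 1]),)
        # oracle: detour share via direct inversion
        sig = np.linalg.inv(patient)
        rho = sig[0, 1] / np.sqrt(sig[0, 0] * sig[1, 1])
        direct = correlation_weights(
            decompose_pair(patient, support_graph(patient), 0, 1,
                           node_order=range(3)),
            sig, node_order=range(3))
        detour_share = 100.0 * next(
            w.corr_weight for w in direct if w.path.t == 3) / rho
        assert cmp_.distinct_contribution_pct["patient"] == pytest.approx(
            detour_share, abs=1e-9)
        assert detour_share > 50
        assert cmp_.flagged

    def test_reversed_sequences_count_as_common(self):
        omega = np.array([[2.0, -0.5, 0.0], [-0.5, 2.0, 0.5], [0.0, 0.5, 2.0]])
        sup = support_graph(omega)
        cmp_ = compare_path_sets((omega, sup), (omega, sup), 0, 2,
                                 node_order=range(3))
        assert cmp_.common_paths == (NodePath([2, 1, 0]),)

    def test_unreachable_pair_directs_to_differential_report(self):
        omega = np.diag([1.0, 1.0, 1.0])
        sup = support_graph(omega)
        with pytest.raises(ValueError, match="differential_report"):
            compare_path_sets((omega, sup), (omega, sup), 0, 1,
                              node_order=range(3))
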