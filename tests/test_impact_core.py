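import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from impactnet import (
    EdgeRecord,
    SchemeError,
    conditional_probabilities,
    dependency_factor,
    detect_edges,
    edge_passes,
    edge_passes_three_state,
    impact_factor,
    permutation_test,
    read_edges_tsv,
    write_edges_tsv,
)
from impactnet.impact_core import ConditionalPair

from brute_oracle import brute_force_edges, brute_force_pair
from conftest import binary_matrix, three_state_matrix


class TestConditionalProbabilities:
    def test_perfect_coupling(self):
        mat = binary_matrix(np.array([[1, 1], [1, 1], [0, 0], [0, 0]]))
        pair = conditional_probabilities(mat, 0, 1)
        assert pair.p11 == 1.0 and pair.p00 == 1.0

    def test_independent_columns_hand_counts(self):
        mat = binary_matrix(np.array([[1, 1], [1, 0], [0, 1], [0, 0]]))
        pair = conditional_probabilities(mat, 0, 1)
        assert pair.p11 == 0.5 and pair.p00 == 0.5
        assert pair.n_i1 == 2 and pair.n_i0 == 2

    def test_constant_source_flagged_undefined(self):
        mat = binary_matrix(np.array([[1, 1], [1, 0]]))
        pair = conditional_probabilities(mat, 0, 1)
        assert not pair.p00_defined and math.isnan(pair.p00)
        assert pair.p11_defined

    def test_out_of_range_rejected(self):
        mat = binary_matrix(np.array([[1, 0]]))
        with pytest.raises(IndexError):
            conditional_probabilities(mat, 0, 5)

    def test_counts_partition_sequences(self):
        rng = np.random.default_rng(3)
        mat = binary_matrix(rng.integers(0, 2, size=(17, 3)))
        pair = conditional_probabilities(mat, 0, 2)
        assert pair.n_i1 + pair.n_i0 == 17

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_pair(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 2, size=(rng.integers(2, 20), 2))
        pair = conditional_probabilities(binary_matrix(codes), 0, 1)
        bp11, bp00 = brute_force_pair(codes.tolist(), 0, 1)
        assert (bp11 is None) == math.isnan(pair.p11)
        assert (bp00 is None) == math.isnan(pair.p00)
        if bp11 is not None:
            assert pair.p11 == bp11
        if bp00 is not None:
            assert pair.p00 == bp00


class TestEdgePasses:
    def test_boundary_is_inclusive(self):
        assert edge_passes(ConditionalPair(1.0, 1.0, 2, 2), gamma=1.0)

    def test_both_probabilities_must_pass(self):
        assert not edge_passes(ConditionalPair(0.8, 0.69, 5, 5), gamma=0.7)

    def test_undefined_fails_even_at_gamma_zero(self):
        assert not edge_passes(ConditionalPair(1.0, math.nan, 4, 0), gamma=0.0)

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            edge_passes(ConditionalPair(1.0, 1.0, 2, 2), gamma=1.5)


class TestThreeStateCriterion:
    def test_perfect_aligned_coupling(self):
        codes = np.array([[1, 1], [1, 1], [2, 2], [2, 2], [0, 0]])
        mat = three_state_matrix(codes, [2, 2])
        assert edge_passes_three_state(mat, 0, 1, 1.0) == (True, "aligned")

    def test_perfect_swapped_coupling(self):
        codes = np.array([[1, 2], [1, 2], [2, 1], [2, 1], [0, 0]])
        mat = three_state_matrix(codes, [2, 2])
        assert edge_passes_three_state(mat, 0, 1, 1.0) == (True, "swapped")

    def test_single_state_source_reduces_to_binary(self):
        # column 0 has no state 2: criterion is P(1|1) and P(0|0) only
        codes = np.array([[1, 1], [1, 1], [0, 0], [0, 2]])
        mat = three_state_matrix(codes, [1, 2])
        passed, branch = edge_passes_three_state(mat, 0, 1, 0.5)
        assert passed and branch == "aligned"

    def test_excluded_column_never_passes(self):
        codes = np.array([[1, 0], [0, 0]])
        mat = three_state_matrix(codes, [1, 0])
        assert edge_passes_three_state(mat, 0, 1, 0.0) == (False, None)

    def test_wrong_scheme_rejected(self):
        mat = binary_matrix(np.array([[1, 0]]))
        with pytest.raises(SchemeError):
            edge_passes_three_state(mat, 0, 1, 0.5)


class TestPermutationTest:
    def test_perfect_coupling_is_significant(self):
        rng = np.random.default_rng(0)
        col = rng.permutation(np.repeat([0, 1], 500)).astype(np.int8)
        mat = binary_matrix(np.column_stack([col, col]))
        p = permutation_test(mat, 0, 1, n_permutations=2000, seed=1)
        assert p <= 0.01

    def test_single_permutation_bounds(self):
        mat = binary_matrix(np.array([[1, 1], [0, 0], [1, 0], [0, 1]]))
        p = permutation_test(mat, 0, 1, n_permutations=1, seed=0)
        assert p in (0.5, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        mat = binary_matrix(rng.integers(0, 2, size=(60, 2)))
        p1 = permutation_test(mat, 0, 1, seed=11)
        p2 = permutation_test(mat, 0, 1, seed=11)
        assert p1 == p2

    def test_null_pvalues_super_uniform(self):
        # independent columns: P(p <= alpha) <= alpha + Monte-Carlo slack
        rng = np.random.default_rng(7)
        pvals = []
        for k in range(200):
            codes = (rng.random((120, 2)) > 0.3).astype(np.int8)
            pvals.append(
                permutation_test(binary_matrix(codes), 0, 1,
                                 n_permutations=200, seed=k)
            )
        pvals = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.10):
            assert (pvals <= alpha).mean() <= alpha + 3 * math.sqrt(alpha / 200)

    def test_invalid_permutation_count_rejected(self):
        mat = binary_matrix(np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValueError):
            permutation_test(mat, 0, 1, n_permutations=0)


class TestDetectEdges:
    def test_hand_enumerated_example(self):
        codes = np.array(
            [[1, 1, 1], [1, 1, 0], [0, 0, 1], [0, 0, 0]]
        )  # i=col0, j=col1 perfectly coupled; k=col2 independent
        res = detect_edges(binary_matrix(codes), 0.7, significance=False)
        assert {(e.source, e.target) for e in res.edges} == {(1, 2), (2, 1)}

    def test_gamma_zero_passes_all_nonconstant_pairs(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 2, size=(30, 4))
        assert codes.std(axis=0).min() > 0  # no constant column
        res = detect_edges(binary_matrix(codes), 0.0, significance=False)
        assert len(res.edges) == 4 * 3

    def test_identical_rows_give_no_edges(self):
        codes = np.tile([1, 0, 1], (5, 1))
        res = detect_edges(binary_matrix(codes), 0.0, significance=False)
        assert res.edges == [] and res.n_undefined_pairs == 6

    def test_asymmetry_is_realised(self):
        # rare mutations at i nested inside j's mutations: i -> j passes,
        # j -> i fails
        codes = np.array(
            [[0, 0]] * 2 + [[1, 0]] * 1 + [[1, 1]] * 17, dtype=np.int8
        )
        res = detect_edges(binary_matrix(codes), 0.9, significance=False)
        pairs = {(e.source, e.target) for e in res.edges}
        assert (1, 2) in pairs and (2, 1) not in pairs

    def test_reports_significance_discards(self):
        rng = np.random.default_rng(4)
        codes = (rng.random((40, 6)) > 0.5).astype(np.int8)
        res = detect_edges(binary_matrix(codes), 0.0, p_threshold=0.01,
                           n_permutations=99, seed=0)
        assert res.n_gamma_passed == res.n_discarded_significance + len(res.edges)

    def test_three_state_detection_finds_swapped_pairs(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=60)
        swapped = np.select([base == 1, base == 2], [2, 1], default=0)
        other = rng.integers(0, 3, size=60)
        codes = np.column_stack([base, swapped, other]).astype(np.int8)
        mat = three_state_matrix(codes, [2, 2, 2])
        res = detect_edges(mat, 1.0, significance=False)
        found = {(e.source, e.target): e.branch for e in res.edges}
        assert found[(1, 2)] == "swapped" and found[(2, 1)] == "swapped"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        L = int(rng.integers(2, 13))
        codes = (rng.random((n, L)) > rng.random()).astype(np.int8)
        gamma = float(rng.choice([0.0, 0.5, 0.7, 0.9, 1.0]))
        res = detect_edges(binary_matrix(codes), gamma, significance=False)
        got = {(e.source - 1, e.target - 1): (e.p11, e.p00) for e in res.edges}
        expected = {(i, j): (p11, p00) for i, j, p11, p00 in
                    brute_force_edges(codes.tolist(), gamma)}
        assert got == expected


class TestFactors:
    E = lambda self, s, t: EdgeRecord(source=s, target=t, p11=1.0, p00=1.0, gamma=0.7)

    def test_impact_counts_distinct_targets(self):
        edges = [self.E(1, 2), self.E(1, 3), self.E(2, 1)]
        assert impact_factor(edges) == {1: 2, 2: 1, 3: 0}

    def test_dependency_counts_distinct_sources(self):
        edges = [self.E(1, 2), self.E(3, 2)]
        assert dependency_factor(edges) == {1: 0, 2: 2, 3: 0}

    def test_empty_edge_list(self):
        assert impact_factor([], positions=[1, 2]) == {1: 0, 2: 0}

    def test_handshake_identity(self):
        rng = np.random.default_rng(9)
        edges = [self.E(int(s), int(t)) for s, t in
                 {tuple(rng.integers(1, 10, 2)) for _ in range(30)} if s != t]
        assert sum(impact_factor(edges).values()) == len(edges)
        assert sum(dependency_factor(edges).values()) == len(edges)

    def test_reciprocal_pair(self):
        edges = [self.E(1, 2), self.E(2, 1)]
        assert impact_factor(edges) == {1: 1, 2: 1}
        assert dependency_factor(edges) == {1: 1, 2: 1}


class TestEdgeTsv:
    def test_round_trip_identity(self, tmp_path):
        edges = [
            EdgeRecord(source=3, target=7, p11=2 / 3, p00=0.9123456789,
                       gamma=0.7, p_value=0.0049975, scheme="binary"),
            EdgeRecord(source=1, target=2, p11=1.0, p00=1.0, gamma=0.7,
                       p_value=None, scheme="three_state", branch="swapped",
                       p22=0.5, source_tag="A", target_tag="B"),
            EdgeRecord(source=5, target=6, p11=0.99, p00=0.98, gamma=0.8,
                       p_value=0.001, resistant_p00=0.98, sensitive_p11=0.99),
        ]
        path = tmp_path / "edges.tsv"
        write_edges_tsv(edges, path)
        assert read_edges_tsv(path) == edges
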