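"""QAP graph correlation, Jaccard overlap, and the congruency grid."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from classnet import (
    BinarizationSpec,
    BinaryNetwork,
    Roster,
    RosterError,
    ValueNetwork,
    congruency_grid,
    graph_correlation,
    jaccard,
    qap_exact,
    qap_test,
)
from classnet.congruence import DegenerateNetworkError
from classnet.network_model import offdiag_mask

from conftest import binary_net, count_net, random_binary_matrix


def brute_force_qap(a_matrix: np.ndarray, b_matrix: np.ndarray):
    """Independent exhaustive QAP oracle using np.corrcoef directly."""
    n = a_matrix.shape[0]
    mask = offdiag_mask(n)
    a_vec = a_matrix[mask]
    r_obs = np.corrcoef(a_vec, b_matrix[mask])[0, 1]
    null = []
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        permuted = b_matrix[np.ix_(p, p)]
        null.append(np.corrcoef(a_vec, permuted[mask])[0, 1])
    null = np.asarray(null)
    tol = 1e-9  # exact ties must count toward rejection despite rounding
    return (
        r_obs,
        (null >= r_obs - tol).mean(),
        (np.abs(null) >= abs(r_obs) - tol).mean(),
    )


class TestGraphCorrelation:
    def test_self_correlation_is_one(self, roster3):
        net = binary_net(roster3, [[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert graph_correlation(net, net) == pytest.approx(1.0)

    def test_affine_reversal_is_minus_one(self, roster3):
        counts = np.array([[0, 3, 1], [3, 0, 2], [1, 2, 0]])
        reverse = 4 - counts
        np.fill_diagonal(reverse, 0)
        a = count_net(roster3, counts)
        b = count_net(roster3, reverse)
        assert graph_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_computed_pearson_on_toy_pair(self, roster3):
        # off-diagonal cells (row-major): A=(0,1,1,0,1,0), B=(1,1,0,0,1,0)
        a = binary_net(roster3, [[0, 0, 1], [1, 0, 0], [1, 0, 0]])
        b = binary_net(roster3, [[0, 1, 1], [0, 0, 0], [1, 0, 0]])
        # hand Pearson: centered dot 0.5, norms sqrt(1.5) each -> 1/3
        assert graph_correlation(a, b) == pytest.approx(1 / 3)

    def test_zero_variance_rejected(self, roster3):
        flat = np.ones((3, 3), dtype=int)
        np.fill_diagonal(flat, 0)
        a = binary_net(roster3, flat)
        with pytest.raises(DegenerateNetworkError):
            graph_correlation(a, a)

    def test_roster_mismatch_rejected(self, roster3):
        other = Roster(("x", "y", "z"))
        a = binary_net(roster3, [[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        b = binary_net(other, [[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        with pytest.raises(RosterError):
            graph_correlation(a, b)


class TestQAPExact:
    def test_distinct_symmetric_values_self_test(self, roster3):
        # pair values {1,2,3}: only the identity pair-relabeling keeps r=1
        counts = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        net = count_net(roster3, counts)
        res = qap_exact(net, net)
        assert res.r_observed == pytest.approx(1.0)
        assert res.p_greater == pytest.approx(1 / 6)
        assert res.exact and res.n_permutations == 6

    def test_shift_invariance(self, roster3):
        counts = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        shifted = counts + 1
        np.fill_diagonal(shifted, 0)
        a = count_net(roster3, counts)
        b = count_net(roster3, shifted)
        assert qap_exact(a, b).p_greater == qap_exact(a, a).p_greater

    @given(st.integers(0, 2**32 - 1))
    def test_matches_independent_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        roster = Roster(("a", "b", "c", "d"))
        a = random_binary_matrix(rng, 4, 0.5)
        b = random_binary_matrix(rng, 4, 0.5)
        res = qap_exact(binary_net(roster, a), binary_net(roster, b))
        r_ref, p_greater_ref, p_two_ref = brute_force_qap(a, b)
        assert res.r_observed == pytest.approx(r_ref)
        assert res.p_greater == pytest.approx(p_greater_ref)
        assert res.p_two_sided == pytest.approx(p_two_ref)

    def test_size_limit(self):
        n = 9
        roster = Roster(tuple(f"c{i}" for i in range(n)))
        net = binary_net(roster, random_binary_matrix(np.random.default_rng(0), n, 0.5))
        with pytest.raises(Exception):
            qap_exact(net, net)


class TestQAPMonteCarlo:
    def test_self_test_attains_maximum_statistic(self, roster3):
        counts = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        net = count_net(roster3, counts)
        res = qap_test(net, net, n_permutations=499, seed=0)
        assert res.r_observed == pytest.approx(1.0)
        assert res.p_greater >= 1 / 500  # add-one floor

    def test_reproducible_given_seed(self, roster4):
        rng = np.random.default_rng(5)
        a = binary_net(roster4, random_binary_matrix(rng, 4, 0.5))
        b = binary_net(roster4, random_binary_matrix(rng, 4, 0.5))
        r1 = qap_test(a, b, 999, seed=11)
        r2 = qap_test(a, b, 999, seed=11)
        assert r1 == r2

    def test_within_binomial_error_of_exact(self):
        rng = np.random.default_rng(2)
        roster = Roster(tuple("abcde"))
        a = binary_net(roster, random_binary_matrix(rng, 5, 0.5))
        b = binary_net(roster, random_binary_matrix(rng, 5, 0.5))
        exact = qap_exact(a, b)
        mc = qap_test(a, b, n_permutations=4999, seed=0)
        # de-biased Monte-Carlo exceedance proportion
        k = round(mc.p_greater * 5000 - 1)
        se = np.sqrt(exact.p_greater * (1 - exact.p_greater) / 4999)
        assert abs(k / 4999 - exact.p_greater) <= 3 * se

    def test_add_one_convention_bounds_p(self, roster4):
        rng = np.random.default_rng(9)
        a = binary_net(roster4, random_binary_matrix(rng, 4, 0.5))
        b = binary_net(roster4, random_binary_matrix(rng, 4, 0.5))
        res = qap_test(a, b, n_permutations=99, seed=1)
        assert 1 / 100 <= res.p_greater <= 1.0
        assert 1 / 100 <= res.p_two_sided <= 1.0

    @given(st.integers(0, 2**32 - 1))
    def test_r_invariant_under_joint_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        roster = Roster(tuple(f"c{i}" for i in range(n)))
        a = random_binary_matrix(rng, n, 0.4)
        b = random_binary_matrix(rng, n, 0.4)
        perm = rng.permutation(n)
        r_direct = graph_correlation(binary_net(roster, a), binary_net(roster, b))
        r_relab = graph_correlation(
            binary_net(roster, a[np.ix_(perm, perm)]),
            binary_net(roster, b[np.ix_(perm, perm)]),
        )
        assert r_direct == pytest.approx(r_relab)


class TestJaccard:
    def test_identical_networks(self, roster3):
        net = binary_net(roster3, [[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        res = jaccard(net, net)
        assert res.jaccard == 1.0
        assert res.in_both == 3 and res.only_in_a == res.only_in_b == 0

    def test_disjoint_tie_sets(self, roster3):
        a = binary_net(roster3, [[0, 1, 0], [0, 0, 0], [0, 0, 0]])
        b = binary_net(roster3, [[0, 0, 0], [0, 0, 1], [0, 0, 0]])
        assert jaccard(a, b).jaccard == 0.0

    def test_hand_counted_overlap(self, roster3):
        # ties(A) = {a->b, b->c}; ties(B) = {b->c, c->a}
        a = binary_net(roster3, [[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        b = binary_net(roster3, [[0, 0, 0], [0, 0, 1], [1, 0, 0]])
        res = jaccard(a, b)
        assert (res.in_both, res.only_in_a, res.only_in_b) == (1, 1, 1)
        assert res.absent_in_both == 3
        assert res.jaccard == pytest.approx(1 / 3)

    def test_both_empty_defined_as_zero(self, roster3):
        empty = binary_net(roster3, np.zeros((3, 3), dtype=int))
        res = jaccard(empty, empty)
        assert res.jaccard == 0.0
        assert res.n_dyads == 6

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        roster = Roster(tuple(f"c{i}" for i in range(n)))
        a = binary_net(roster, random_binary_matrix(rng, n, 0.4))
        b = binary_net(roster, random_binary_matrix(rng, n, 0.4))
        ab, ba = jaccard(a, b), jaccard(b, a)
        assert ab.jaccard == pytest.approx(ba.jaccard)
        assert ab.n_dyads == n * (n - 1)
        perm = rng.permutation(n)
        relab = jaccard(
            binary_net(roster, a.ties[np.ix_(perm, perm)]),
            binary_net(roster, b.ties[np.ix_(perm, perm)]),
        )
        assert relab.jaccard == pytest.approx(ab.jaccard)


def _identical_informants(n=6):
    """Three informant networks sharing one binary structure exactly."""
    roster = Roster(tuple(f"c{i}" for i in range(n)))
    m = np.zeros((n, n), dtype=int)
    for i, j in ((0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)):
        m[i, j] = m[j, i] = 1
    child = BinaryNetwork(roster, m, directed=True)
    teacher = ValueNetwork(roster, m, kind="rating")
    observed = ValueNetwork(roster, m, kind="count")
    return child, teacher, observed


class TestCongruencyGrid:
    def test_default_grid_shape(self, default_classroom):
        data = default_classroom
        child = BinaryNetwork(data.roster, data.nominations.values, directed=True)
        report = congruency_grid(
            child, data.ratings, data.counts, n_permutations=199, seed=3
        )
        assert set(report.qap_original) == {
            ("child", "teacher"),
            ("child", "researcher"),
            ("teacher", "researcher"),
        }
        assert len(report.qap_binary) == 3 + 6 + 18
        assert len(report.jaccard_binary) == len(report.qap_binary)
        assert report.qap_table().shape == (7, 4)
        assert report.jaccard_table().shape == (7, 4)
        assert len(report.densities) == 10
        for res in report.qap_binary.values():
            assert -1 <= res.r_observed <= 1
        for res in report.jaccard_binary.values():
            assert 0 <= res.jaccard <= 1

    def test_single_cell_grid_matches_direct_calls(self, default_classroom):
        from classnet import binarize_frequency, binarize_rating

        data = default_classroom
        child = BinaryNetwork(data.roster, data.nominations.values, directed=True)
        scheme = BinarizationSpec(family="frequency", rule="fixed", k=1)
        report = congruency_grid(
            child,
            data.ratings,
            data.counts,
            teacher_cutoffs=(2,),
            researcher_schemes=(scheme,),
            n_permutations=99,
            seed=0,
        )
        t_net = binarize_rating(data.ratings, 2)
        r_net = binarize_frequency(data.counts, "fixed", k=1)
        cell = report.qap_binary[("freq>=1", "rating>=2")]
        assert cell.r_observed == pytest.approx(graph_correlation(t_net, r_net))
        jac = report.jaccard_binary[("freq>=1", "rating>=2")]
        assert jac == jaccard(t_net, r_net)

    def test_identical_informants_give_perfect_congruency(self):
        child, teacher, observed = _identical_informants()
        report = congruency_grid(
            child,
            teacher,
            observed,
            teacher_cutoffs=(1,),
            researcher_schemes=(BinarizationSpec(family="frequency", rule="fixed", k=1),),
            n_permutations=99,
            seed=0,
        )
        for res in list(report.qap_original.values()) + list(report.qap_binary.values()):
            assert res.r_observed == pytest.approx(1.0)
        for res in report.jaccard_binary.values():
            assert res.jaccard == 1.0

    def test_report_serialization_round_trip(self, tmp_path, default_classroom):
        import json

        data = default_classroom
        child = BinaryNetwork(data.roster, data.nominations.values, directed=True)
        report = congruency_grid(
            child, data.ratings, data.counts, n_permutations=99, seed=7
        )
        report.write(tmp_path)
        with open(tmp_path / "congruency_report.json") as fh:
            doc = json.load(fh)
        assert doc["seed"] == 7
        assert len(doc["qap_binary"]) == 27
        assert (tmp_path / "qap_binary.csv").exists()
        assert (tmp_path / "jaccard_binary.csv").exists()
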