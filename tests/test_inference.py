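"""Interaction inference, directed network construction and roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from gradientnet.inference import (InteractionMatrix, RickerInteractionModel,
                                   classify_roles, infer_limits,
                                   link_count_significance, role_diversity,
                                   to_network)
from gradientnet.synthetic import simulate_ricker


class TestRickerInteractionModel:
    def test_sklearn_params_roundtrip(self):
        m = RickerInteractionModel(error_threshold=0.07)
        assert clone(m).get_params() == m.get_params()
        m.set_params(bag_iters=11)
        assert m.get_params()["bag_iters"] == 11

    def test_diagonal_only_dynamics_stay_sparse(self):
        A = np.diag(np.full(5, -0.4))
        r = np.full(5, 0.4)
        x0 = np.array([0.5, 1.8, 1.2, 0.7, 1.5])
        traj = simulate_ricker(A, r, x0, 200, noise_sd=0.0)
        m = RickerInteractionModel(random_state=0).fit(traj.T)
        off = m.interaction_matrix_.copy()
        np.fill_diagonal(off, 0.0)
        assert (off != 0).sum() / 20 <= 0.05

    def test_constant_series_gives_zero_estimates(self):
        X = np.ones((60, 3)) * 0.2
        m = RickerInteractionModel(random_state=0).fit(X)
        assert np.allclose(m.interaction_matrix_, 0.0)
        assert np.allclose(m.growth_rates_, 0.0)

    def test_deterministic_under_random_state(self, rng):
        X = rng.uniform(0.1, 1.0, size=(80, 4))
        a = RickerInteractionModel(random_state=5).fit(X)
        b = RickerInteractionModel(random_state=5).fit(X)
        assert np.array_equal(a.interaction_matrix_, b.interaction_matrix_)

    def test_rejects_negative_abundances(self):
        with pytest.raises(ValueError, match="non-negative"):
            RickerInteractionModel().fit(-np.ones((40, 3)))

    def test_rejects_zeros_without_pseudocount(self):
        X = np.ones((40, 3))
        X[5, 1] = 0.0
        with pytest.raises(ValueError, match="pseudocount"):
            RickerInteractionModel(pseudocount=0.0).fit(X)

    def test_short_series_warns(self, rng):
        X = rng.uniform(0.5, 1.5, size=(20, 10))
        with pytest.warns(UserWarning, match="recommended"):
            RickerInteractionModel(random_state=0).fit(X)


class TestInferLimits:
    def test_planted_interactions_recovered_with_sign(self):
        # noiseless dynamics from a planted sparse matrix: the strong
        # off-diagonal entries should come back with the right sign
        # sustained (chaotic-regime) dynamics keep the community excited so
        # the noiseless series stays informative for all 300 steps
        A = np.diag(np.full(5, -3.0))
        A[0, 2], A[1, 3], A[2, 4], A[3, 0] = 0.3, -0.3, 0.25, -0.25
        x_star = np.ones(5)
        r = -A @ x_star
        x0 = x_star * np.array([1.3, 0.7, 1.2, 0.8, 1.1])
        traj = simulate_ricker(A, r, x0, 300, noise_sd=0.0)
        inter = infer_limits(traj, seed=0)
        hits = sum(
            inter.A[i, j] != 0 and np.sign(inter.A[i, j]) == np.sign(A[i, j])
            for i, j in [(0, 2), (1, 3), (2, 4), (3, 0)])
        assert hits >= 3

    def test_interaction_matrix_metadata(self, rng):
        X = rng.uniform(0.1, 1.0, size=(80, 4))
        inter = infer_limits(X.T, seed=1)
        assert inter.taxa == [f"taxon_{k}" for k in range(4)]
        assert inter.A.shape == (4, 4)
        assert 0.0 <= inter.sparsity() <= 1.0
        assert inter.pseudocount >= 0


class TestLinkCountSignificance:
    def test_fully_dense_matrix_is_invariant(self):
        A = np.ones((4, 4)) * 0.2
        assert link_count_significance(A, n_rand=50, seed=0) == 1.0

    def test_p_is_valid_and_deterministic(self):
        A = np.zeros((6, 6))
        A[0, 1] = A[2, 1] = A[3, 4] = 0.3
        p1 = link_count_significance(A, n_rand=100, seed=7)
        p2 = link_count_significance(A, n_rand=100, seed=7)
        assert p1 == p2
        assert 1 / 101 <= p1 <= 1.0

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert link_count_significance(np.zeros((3, 3))) == 1.0

    def test_edge_statistic_is_degenerate_under_shuffle(self):
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 2] = 0.4
        assert link_count_significance(A, n_rand=30, seed=0,
                                       statistic="edges") == 1.0


class TestToNetwork:
    def test_single_entry_direction_and_sign(self):
        A = np.zeros((2, 2))
        A[1, 0] = 0.3  # taxon0 affects taxon1
        net = to_network(A, taxa=["taxon1", "taxon2"])
        assert list(net.edges(data=True)) == [
            ("taxon1", "taxon2", {"weight": 0.3, "sign": "+"})]

    def test_zero_matrix_gives_empty_edge_set(self):
        net = to_network(np.zeros((3, 3)))
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 3

    def test_magnitude_floor(self):
        A = np.zeros((2, 2))
        A[0, 1], A[1, 0] = 0.05, -0.2
        net = to_network(A, magnitude_floor=0.1)
        assert net.number_of_edges() == 1

    def test_self_terms_never_become_edges(self):
        A = np.diag([-0.5, -0.5])
        assert to_network(A).number_of_edges() == 0


class TestClassifyRoles:
    def test_fan_out(self):
        g = nx.DiGraph([("a", "b"), ("a", "c")])
        roles = classify_roles(g)
        assert roles.loc["a", "role"] == "influential"
        assert roles.loc["b", "role"] == "sensitive"
        assert roles.loc["c", "role"] == "sensitive"

    def test_mutual_pair_is_bidirectional(self):
        roles = classify_roles(nx.DiGraph([("a", "b"), ("b", "a")]))
        assert set(roles["role"]) == {"bidirectional"}

    def test_partition_is_total(self):
        g = nx.DiGraph([("a", "b")])
        g.add_node("c")
        roles = classify_roles(g)
        assert len(roles) == 3
        assert roles.loc["c", "role"] == "orphan"

    def test_commutes_with_relabeling(self, rng):
        A = (rng.random((5, 5)) < 0.3) * rng.normal(size=(5, 5))
        np.fill_diagonal(A, 0)
        taxa = [f"t{k}" for k in range(5)]
        roles = classify_roles(to_network(A, taxa=taxa))
        perm = rng.permutation(5)
        A_p = A[np.ix_(perm, perm)]
        taxa_p = [taxa[k] for k in perm]
        roles_p = classify_roles(to_network(A_p, taxa=taxa_p))
        for t in taxa:
            assert roles_p.loc[t, "role"] == roles.loc[t, "role"]


class TestRoleDiversity:
    @staticmethod
    def _fixtures():
        table = pd.DataFrame([[10, 0, 0], [6, 4, 0]],
                             index=["S1", "S2"], columns=["a", "b", "c"])
        roles = pd.DataFrame({
            "in_degree": [0, 1, 1], "out_degree": [2, 0, 0],
            "role": ["influential", "sensitive", "sensitive"],
        }, index=pd.Index(["a", "b", "c"], name="taxon"))
        return table, roles

    def test_relative_abundance_partitions_reads(self):
        table, roles = self._fixtures()
        div = role_diversity(table, roles)
        s1 = div[div["sample"] == "S1"].set_index("role")
        assert s1.loc["influential", "relative_abundance"] == 1.0
        assert s1.loc["sensitive", "relative_abundance"] == 0.0

    def test_single_member_role_richness_bounded(self):
        table, roles = self._fixtures()
        div = role_diversity(table, roles)
        inf = div[div["role"] == "influential"]
        assert (inf["richness"] <= 1).all()

    def test_missing_role_warns(self, caplog):
        table, roles = self._fixtures()
        with caplog.at_level("WARNING", logger="gradientnet.inference"):
            role_diversity(table, roles)
        assert any("orphan" in r.message for r in caplog.records)
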