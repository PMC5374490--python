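import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from freeznet.network import (
    CoactivationNetwork,
    coactivation_matrix,
    compare_networks,
    eigenvector_centrality,
    network_density,
    qap_correlation,
)

NODES = ("Dm", "Vv", "Vs", "POA")


def net_from_R(R, treatment="t", nodes=None):
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    return CoactivationNetwork(
        treatment=treatment,
        nodes=nodes or NODES[:k] if k <= 4 else tuple(f"n{i}" for i in range(k)),
        R=R,
        P=np.zeros((k, k)),
        n_pairs=np.full((k, k), 10.0),
    )


def random_corr_net(seed, k=4, treatment="t"):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, k))
    R = np.corrcoef(X, rowvar=False)
    return net_from_R(R, treatment)


def closed_form_pearson(x, y):
    dx, dy = x - x.mean(), y - y.mean()
    return float(dx @ dy) / math.sqrt(float(dx @ dx) * float(dy @ dy))


class TestCoactivationMatrix:
    def test_identical_nuclei_fully_correlated(self):
        vals = [1.0, 3.0, 2.0, 5.0, 4.0]
        expr = pd.DataFrame({"Dm": vals, "Vs": vals})
        net = coactivation_matrix(expr)
        assert net.R[0, 1] == pytest.approx(1.0)

    def test_independent_large_n_near_zero(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["Dm", "Vv"])
        net = coactivation_matrix(expr)
        assert abs(net.R[0, 1]) < 0.05

    def test_toy_table_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.random((5, 4)), columns=list(NODES))
        net = coactivation_matrix(expr)
        X = expr.to_numpy()
        for i in range(4):
            for j in range(i + 1, 4):
                oracle = closed_form_pearson(X[:, i], X[:, j])
                assert abs(net.R[i, j] - oracle) < 1e-12
                assert net.R[i, j] == net.R[j, i]
        np.testing.assert_array_equal(np.diag(net.R), 1.0)

    def test_zero_variance_nucleus_flagged(self):
        expr = pd.DataFrame({"Dm": [1.0, 2.0, 3.0], "Vv": [5.0, 5.0, 5.0]})
        net = coactivation_matrix(expr)
        assert np.isnan(net.R[0, 1]) and np.isnan(net.P[0, 1])

    def test_pairwise_complete_missing_cells(self):
        expr = pd.DataFrame(
            {"Dm": [1.0, 2.0, 3.0, 4.0], "Vs": [1.0, 2.0, 3.0, np.nan]}
        )
        net = coactivation_matrix(expr)
        assert net.n_pairs[0, 1] == 3
        assert net.R[0, 1] == pytest.approx(1.0)

    def test_too_few_pairs_flagged(self):
        expr = pd.DataFrame({"Dm": [1.0, 2.0, np.nan], "Vs": [1.0, 2.0, 3.0]})
        net = coactivation_matrix(expr)
        assert np.isnan(net.R[0, 1])


class TestQAPCorrelation:
    def test_self_comparison_r_one_and_not_different(self):
        net = random_corr_net(1)
        res = qap_correlation(net, net)
        assert res.r_obs == pytest.approx(1.0)
        assert res.mode == "exact" and res.n_perm == 24
        assert res.p <= 0.05 and res.verdict == "not_different"

    def test_exact_p_matches_independent_enumeration(self):
        A, B = random_corr_net(2, treatment="a"), random_corr_net(3, treatment="b")
        res = qap_correlation(A, B)
        iu = np.triu_indices(4, k=1)
        a = A.R[iu]
        count = 0
        for perm in itertools.permutations(range(4)):
            idx = np.asarray(perm)
            count += closed_form_pearson(a, B.R[np.ix_(idx, idx)][iu]) >= res.r_obs - 1e-12
        assert res.p == pytest.approx(count / 24)
        assert res.p * 24 == pytest.approx(round(res.p * 24))  # granularity 1/24

    def test_monte_carlo_within_binomial_error_of_exact(self):
        A, B = random_corr_net(4, treatment="a"), random_corr_net(5, treatment="b")
        exact = qap_correlation(A, B)
        mc = qap_correlation(A, B, method="monte_carlo", n_perm=10_000, seed=0)
        assert mc.mode == "monte_carlo"
        se = math.sqrt(exact.p * (1 - exact.p) / 10_000)
        assert abs(mc.p - exact.p) <= 3 * se + 2 / 10_000

    def test_relabelled_copy_reaches_r_one_in_null(self):
        A = random_corr_net(6)
        perm = np.array([2, 0, 3, 1])
        B = net_from_R(A.R[np.ix_(perm, perm)])
        iu = np.triu_indices(4, k=1)
        r_values = [
            closed_form_pearson(
                A.R[iu], B.R[np.ix_(np.array(p), np.array(p))][iu]
            )
            for p in itertools.permutations(range(4))
        ]
        assert max(r_values) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        A, B = random_corr_net(7, treatment="a"), random_corr_net(8, treatment="b")
        ab, ba = qap_correlation(A, B), qap_correlation(B, A)
        assert ab.r_obs == pytest.approx(ba.r_obs)
        assert ab.p == pytest.approx(ba.p)

    def test_joint_relabelling_invariance(self):
        A, B = random_corr_net(9, treatment="a"), random_corr_net(10, treatment="b")
        base = qap_correlation(A, B)
        perm = np.array([3, 1, 0, 2])
        A2 = net_from_R(A.R[np.ix_(perm, perm)], "a")
        B2 = net_from_R(B.R[np.ix_(perm, perm)], "b")
        relabelled = qap_correlation(A2, B2)
        assert relabelled.r_obs == pytest.approx(base.r_obs)
        assert relabelled.p == pytest.approx(base.p)

    def test_mismatched_nodes_error(self):
        A = random_corr_net(11)
        B = net_from_R(random_corr_net(12).R, nodes=("a", "b", "c", "d"))
        with pytest.raises(ValueError, match="node sets differ"):
            qap_correlation(A, B)

    def test_fewer_than_three_nodes_error(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        net = net_from_R(R, nodes=("x", "y"))
        with pytest.raises(ValueError, match="3 nodes"):
            qap_correlation(net, net)


class TestNetworkDensity:
    def test_uniform_half(self):
        R = np.full((4, 4), 0.5)
        np.fill_diagonal(R, 1.0)
        assert network_density(net_from_R(R)) == pytest.approx(0.5)

    def test_identity_matrix_zero(self):
        assert network_density(net_from_R(np.eye(4))) == 0.0

    def test_matches_brute_force_mean(self):
        net = random_corr_net(13)
        vals = [abs(net.R[i, j]) for i in range(4) for j in range(i + 1, 4)]
        assert network_density(net) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_relabelling_invariant_and_bounded(self):
        net = random_corr_net(14)
        perm = np.array([1, 3, 2, 0])
        relabelled = net_from_R(net.R[np.ix_(perm, perm)])
        assert network_density(relabelled) == pytest.approx(network_density(net))
        assert 0.0 <= network_density(net) <= 1.0

    def test_undefined_edge_error(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            network_density(net_from_R(R, nodes=("a", "b", "c")))

    def test_significance_filter_drops_edges(self):
        R = np.full((3, 3), 0.6)
        np.fill_diagonal(R, 1.0)
        P = np.full((3, 3), 0.5)
        P[0, 1] = P[1, 0] = 0.01
        net = CoactivationNetwork("t", ("a", "b", "c"), R, P, np.full((3, 3), 9.0))
        assert network_density(net, significant_only=True) == pytest.approx(0.2)


class TestEigenvectorCentrality:
    def test_complete_uniform_graph_equal_centralities(self):
        R = np.full((4, 4), 0.8)
        np.fill_diagonal(R, 1.0)
        cent = eigenvector_centrality(net_from_R(R))
        np.testing.assert_allclose(cent.to_numpy(), 0.5, atol=1e-12)

    def test_star_graph_hub_leaf_ratio_sqrt3(self):
        R = np.eye(4)
        R[0, 1:] = R[1:, 0] = 1.0
        cent = eigenvector_centrality(net_from_R(R))
        assert cent.iloc[0] / cent.iloc[1] == pytest.approx(math.sqrt(3), abs=1e-8)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            W = rng.random((5, 5))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            R = np.minimum(W, 1.0)
            np.fill_diagonal(R, 1.0)
            net = net_from_R(R, nodes=tuple("abcde"))
            # oracle: long-run power iteration on |R| with zero diagonal
            M = np.abs(R).copy()
            np.fill_diagonal(M, 0.0)
            v = np.ones(5)
            for _ in range(5_000):
                v = M @ v
                v /= np.linalg.norm(v)
            cent = eigenvector_centrality(net)
            np.testing.assert_allclose(cent.to_numpy(), v, atol=1e-8)

    def test_matches_networkx(self):
        net = random_corr_net(16)
        M = np.abs(net.R).copy()
        np.fill_diagonal(M, 0.0)
        g = nx.from_numpy_array(M)
        expected = nx.eigenvector_centrality_numpy(g, weight="weight")
        vec = np.array([expected[i] for i in range(4)])
        vec = np.abs(vec) / np.linalg.norm(vec)
        np.testing.assert_allclose(
            eigenvector_centrality(net).to_numpy(), vec, atol=1e-8
        )

    def test_relabelling_permutes_centralities(self):
        net = random_corr_net(17)
        perm = np.array([2, 3, 0, 1])
        relabelled = net_from_R(net.R[np.ix_(perm, perm)])
        base = eigenvector_centrality(net).to_numpy()
        np.testing.assert_allclose(
            eigenvector_centrality(relabelled).to_numpy(), base[perm], atol=1e-10
        )

    def test_all_zero_matrix_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            eigenvector_centrality(net_from_R(np.eye(4)))


class TestCompareNetworks:
    def test_self_pair_not_different(self):
        net = random_corr_net(18, treatment="a")
        table = compare_networks({"a": net}, [("a", "a")])
        assert table["verdict"].iloc[0] == "not_different"

    def test_undeclared_treatment_error(self):
        net = random_corr_net(19, treatment="a")
        with pytest.raises(ValueError, match="undeclared"):
            compare_networks({"a": net}, [("a", "b")])

    def test_node_order_must_match(self):
        a = random_corr_net(20, treatment="a")
        b = net_from_R(random_corr_net(21).R, "b", nodes=("w", "x", "y", "z"))
        with pytest.raises(ValueError, match="node order"):
            compare_networks({"a": a, "b": b}, [("a", "b")])


class TestQAPStructureRecovery:
    """QAP verdicts on simulated cohorts with a non-exchangeable coupling.

    When the three coupled nuclei carry distinct pairwise correlations the
    population matrix has no nontrivial automorphism, so the identity
    permutation is the unique best alignment between two independent
    samples of the same structure: QAP then declares same-structure pairs
    not different and cross-structure pairs different.  (With exactly
    exchangeable couplings several permutations align equally well and the
    minimum attainable p on 4 nodes, 1/24, is reached only when the
    identity happens to win the tie -- a pigeonhole limit of the test, not
    of this implementation.)
    """

    def test_verdicts_recovered_at_large_n(self):
        from freeznet.expression import relative_expression
        from freeznet.synth import (
            coupled_structure,
            decoupled_structure,
            expression_config,
            simulate_expression,
        )

        hetero = decoupled_structure((0.5, 0.7, 0.85))
        ss = np.random.SeedSequence(31)
        not_different = different = 0
        n_rep = 10
        for child in ss.spawn(n_rep):
            rng = np.random.default_rng(child)
            nets = {}
            for name, corr in (
                ("a", hetero), ("b", hetero), ("coup", coupled_structure())
            ):
                ct = simulate_expression(
                    expression_config(name, corr, n_fish=100), rng=rng
                )
                nets[name] = coactivation_matrix(
                    relative_expression(ct)[name], name, log2=True
                )
            not_different += (
                qap_correlation(nets["a"], nets["b"]).verdict == "not_different"
            )
            different += (
                qap_correlation(nets["a"], nets["coup"]).verdict == "different"
            )
        assert not_different / n_rep > 0.5
        assert different / n_rep > 0.5
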