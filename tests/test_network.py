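import numpy as np
import pytest
from scipy.optimize import minimize

import etanet as e
from etanet.network import MatchNetwork, diffuse


def random_graph(rng, n):
    W = np.triu(rng.uniform(0, 2, (n, n)) * (rng.random((n, n)) < 0.5), 1)
    W = W + W.T
    y = rng.choice([-1.0, 0.0, 1.0], size=n)
    return W, y


def objective(f, W, y, alpha):
    """Brute-force diffusion objective (each unordered pair counted once)."""
    pair_term = 0.0
    n = len(y)
    for i in range(n):
        for j in range(i):
            pair_term += W[i, j] * (f[i] - f[j]) ** 2
    return ((f - y) ** 2).sum() + alpha * pair_term


class TestEdgeWeights:
    def test_mean_match_gets_unit_weight(self):
        assert e.edge_weight(0.0) == pytest.approx(1.0)

    def test_two_edge_network_hand_z_scores(self):
        net = MatchNetwork.from_edges(
            ["a", "b", "c"], {("a", "b"): (1.0, 4.0), ("b", "c"): (2.0, 8.0)}
        )
        s_values = {k: edge.s for k, edge in net.edges.items()}
        assert s_values[("a", "b")] == pytest.approx(-1.0)
        assert s_values[("b", "c")] == pytest.approx(1.0)
        assert net.edges[("a", "b")].weight == pytest.approx(np.e)
        assert net.edges[("b", "c")].weight == pytest.approx(1.0 / np.e)

    def test_better_matches_get_strictly_larger_weight(self):
        net = MatchNetwork.from_edges(
            ["a", "b", "c", "d"],
            {("a", "b"): (0.5, 1.0), ("c", "d"): (1.5, 3.0), ("a", "c"): (1.0, 2.0)},
        )
        assert net.edges[("a", "b")].weight > net.edges[("a", "c")].weight
        assert net.edges[("a", "c")].weight > net.edges[("c", "d")].weight

    def test_zero_variance_errors_with_fixed_fallback(self):
        scores = {("a", "b"): (1.0, 2.0), ("b", "c"): (1.0, 2.0)}
        with pytest.raises(ValueError, match="fixed"):
            MatchNetwork.from_edges(["a", "b", "c"], scores)
        net = MatchNetwork.from_edges(["a", "b", "c"], scores, transform="fixed")
        assert all(edge.weight == 1.0 for edge in net.edges.values())

    def test_mean_combined_score_is_zero(self):
        rng = np.random.default_rng(0)
        scores = {
            (f"n{i}", f"n{i+1}"): (rng.uniform(0.2, 2), rng.uniform(0.1, 1))
            for i in range(8)
        }
        net = MatchNetwork.from_edges([f"n{i}" for i in range(9)], scores)
        assert np.mean([edge.s for edge in net.edges.values()]) == pytest.approx(0.0, abs=1e-12)


class TestBuildNetwork:
    def test_edges_are_exactly_same_function_pairs(self, single_bench, single_model):
        net = e.build_network(single_bench.proteins, "6R", single_model)
        expected = {
            (a, b)
            for a in single_bench.proteins
            for b in single_bench.proteins
            if a < b and single_bench.function_of[a] == single_bench.function_of[b]
        }
        assert set(net.edges) == expected
        W = net.W
        assert np.allclose(W, W.T) and np.all(W >= 0) and np.all(np.diag(W) == 0)

    def test_empty_protein_set_gives_edgeless_network(self, single_model):
        spec = e.FixtureSpec(n_proteins=4, n_functions=4, decoy_residues=10, seed=9)
        bench = e.generate_benchmark(spec)
        net = e.build_network(bench.proteins, "6R", single_model)
        assert net.edges == {} and not net.W.any()


class TestDiffuse:
    def test_two_node_closed_form(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        f = diffuse(W, np.array([1.0, 0.0]), alpha=1.0)
        np.testing.assert_allclose(f, [2 / 3, 1 / 3], atol=1e-12)

    def test_alpha_to_zero_limit_returns_labels(self):
        rng = np.random.default_rng(1)
        W, y = random_graph(rng, 8)
        f = diffuse(W, y, alpha=1e-9)
        np.testing.assert_allclose(f, y, atol=1e-6)

    def test_constant_labels_are_fixed_point(self):
        rng = np.random.default_rng(2)
        W, _ = random_graph(rng, 10)
        f = diffuse(W, np.ones(10), alpha=3.0)
        np.testing.assert_allclose(f, np.ones(10), atol=1e-10)

    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            W, y = random_graph(rng, n)
            alpha = float(rng.choice([0.1, 1.0, 10.0]))
            f = diffuse(W, y, alpha)
            res = minimize(objective, y, args=(W, y, alpha), method="L-BFGS-B",
                           tol=1e-12)
            np.testing.assert_allclose(f, res.x, atol=1e-5)
            assert objective(f, W, y, alpha) <= res.fun + 1e-8

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        W, y = random_graph(rng, 9)
        perm = rng.permutation(9)
        f = diffuse(W, y, 1.0)
        f_perm = diffuse(W[np.ix_(perm, perm)], y[perm], 1.0)
        np.testing.assert_allclose(f_perm, f[perm], atol=1e-10)

    def test_strengthening_edge_to_positive_node_raises_score(self):
        W = np.array(
            [[0.0, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.0]]
        )
        y = np.array([1.0, 0.0, -1.0])
        before = diffuse(W, y, 1.0)[1]
        W2 = W.copy()
        W2[0, 1] = W2[1, 0] = 2.0
        after = diffuse(W2, y, 1.0)[1]
        assert after > before

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            diffuse(np.array([[0.0, 1.0], [0.0, 0.0]]), np.zeros(2), 1.0)
        with pytest.raises(ValueError, match="alpha"):
            diffuse(np.zeros((2, 2)), np.zeros(2), 0.0)


class TestConfidenceZ:
    def test_hand_z_scores(self):
        f = np.array([0.2, 0.4, 9.0])
        z = e.confidence_z(f, np.array([True, True, False]))
        np.testing.assert_allclose(z, [-1.0, 1.0])

    def test_constant_scores_warn_and_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            z = e.confidence_z(np.array([0.5, 0.5, 1.0]), np.array([True, True, False]))
        np.testing.assert_array_equal(z, [0.0, 0.0])

    def test_normalization_identity(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=12)
        mask = np.ones(12, dtype=bool)
        z = e.confidence_z(f, mask)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_single_unknown_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            e.confidence_z(np.array([1.0, 2.0]), np.array([True, False]))


class TestCompetitiveDiffusion:
    def two_clique_network(self, attach_to="A"):
        edges = {}
        for grp, members in (("A", ["a0", "a1", "a2"]), ("B", ["b0", "b1", "b2"])):
            for i, x in enumerate(members):
                for y_ in members[i + 1 :]:
                    edges[(x, y_)] = (0.5, 0.3)
        edges[("a0", "u0")] = (0.5, 0.3)
        edges[("a1", "u1")] = (0.52, 0.31)
        nodes = ["a0", "a1", "a2", "b0", "b1", "b2", "u0", "u1"]
        net = MatchNetwork.from_edges(nodes, edges, transform="fixed")
        ann = e.AnnotationTable(
            {m: frozenset({"1.1.1.1"}) for m in ["a0", "a1", "a2"]}
            | {m: frozenset({"1.1.1.2"}) for m in ["b0", "b1", "b2"]}
            | {"u0": frozenset(), "u1": frozenset()}
        )
        return net, ann

    def test_unknown_attached_to_one_clique_gets_its_label(self):
        net, ann = self.two_clique_network()
        result = e.competitive_diffusion(net, ann, alpha=1.0)
        assert result.best["u0"][0] == "1.1.1.1"
        assert result.best["u1"][0] == "1.1.1.1"

    def test_symmetric_tie_resolves_by_documented_rule(self):
        edges = {
            ("a0", "u0"): (1.0, 0.5),
            ("b0", "u0"): (1.0, 0.5),
            ("a0", "u1"): (1.2, 0.6),
            ("b0", "u1"): (1.2, 0.6),
        }
        net = MatchNetwork.from_edges(["a0", "b0", "u0", "u1"], edges, "fixed")
        ann = e.AnnotationTable(
            {"a0": frozenset({"1.1.1.1"}), "b0": frozenset({"1.1.1.2"}),
             "u0": frozenset(), "u1": frozenset()}
        )
        result = e.competitive_diffusion(net, ann, alpha=1.0)
        # perfectly symmetric: ties break to the lexicographically smaller label
        assert result.best["u0"][0] == "1.1.1.1"
        assert abs(result.best["u0"][1]) < 1.5

    def test_stronger_connectivity_breaks_voting_tie(self):
        tie = e.generate_tie_network(seed=2)
        for u, partners in tie.partners.items():
            assert e.plurality_vote(u, partners).label is None
        result = e.competitive_diffusion(tie.network, tie.annotations, alpha=1.0)
        for node, label, _ in result.predictions():
            assert label in tie.truth[node]


class TestConfidenceBands:
    def test_three_band_report(self):
        preds = [("q1", "1.1.1.1", 3.0), ("q2", "1.1.1.1", 1.0), ("q3", "1.1.1.2", 0.1)]
        truth = {"q1": {"1.1.1.1"}, "q2": {"1.1.1.1"}, "q3": {"1.1.1.1"}}
        rows = e.confidence_bands(preds, truth, thresholds=(2.0, 0.5))
        assert [r["threshold"] for r in rows] == [2.0, 0.5]
        assert rows[0] == {"threshold": 2.0, "n": 1, "accuracy": 1.0}
        assert rows[1]["n"] == 2 and rows[1]["accuracy"] == 1.0

    def test_perfectly_informative_fixture(self):
        tie = e.generate_tie_network(seed=2)
        result = e.competitive_diffusion(tie.network, tie.annotations, alpha=1.0)
        rows = e.confidence_bands(result.predictions(), tie.truth, thresholds=(0.0,))
        assert rows[0]["accuracy"] == 1.0
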