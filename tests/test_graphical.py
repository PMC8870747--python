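"""Tests of GGM covariance selection and the discrete Bayesian network."""

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import minimize

from phytocal.graphical import (
    all_edges,
    bn_query,
    deviance,
    edge_scores,
    explained_variance,
    fit_cpts,
    ipf_fit,
    moralize,
    orient_dag,
    partial_corr,
    prune_graph,
)
from phytocal.posterior_analysis import SampleSet, conditional_marginal


def _chain_corr():
    # A - B - C Markov chain: rho_AB = rho_BC = 0.6, rho_AC = 0.36
    return np.array([[1.0, 0.6, 0.36], [0.6, 1.0, 0.6], [0.36, 0.6, 1.0]])


def _pentadiagonal_model():
    prec = np.array(
        [
            [2.0, -1.0, 0.0, 0.0, 0.0],
            [-1.0, 2.0, -1.0, 0.0, 0.0],
            [0.0, -1.0, 2.0, -1.0, 0.0],
            [0.0, 0.0, -1.0, 2.0, -1.0],
            [0.0, 0.0, 0.0, -1.0, 2.0],
        ]
    )
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d), {(0, 1), (1, 2), (2, 3), (3, 4)}


class TestPartialCorr:
    def test_diagonal_matrix_has_no_partial_correlation(self):
        sp = partial_corr(np.eye(4))
        assert np.allclose(sp, np.eye(4))

    def test_markov_chain_conditional_independence(self):
        sp = partial_corr(_chain_corr())
        assert sp[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sp[0, 1] > 0 and sp[1, 2] > 0

    def test_two_by_two_equals_correlation(self):
        s = np.array([[1.0, 0.45], [0.45, 1.0]])
        assert partial_corr(s)[0, 1] == pytest.approx(0.45)

    def test_singular_input_rejected(self):
        with pytest.raises(ValueError):
            partial_corr(np.ones((3, 3)))


class TestIPF:
    def test_saturated_graph_returns_sample_matrix(self):
        s = _chain_corr()
        assert np.allclose(ipf_fit(s, all_edges(3)), s)

    def test_empty_graph_returns_identity(self):
        s = _chain_corr()
        assert np.allclose(ipf_fit(s, set()), np.eye(3), atol=1e-9)

    def test_retained_correlations_unchanged(self, rng):
        x = rng.multivariate_normal(np.zeros(4), np.eye(4) + 0.5, 5000)
        s = np.corrcoef(x, rowvar=False)
        edges = all_edges(4) - {(0, 3)}
        v = ipf_fit(s, edges)
        for i, j in edges:
            assert v[i, j] == pytest.approx(s[i, j], abs=1e-8)
        assert partial_corr(v)[0, 3] == pytest.approx(0.0, abs=1e-10)

    def test_matches_convex_solver_oracle(self, rng):
        """Constrained-MLE oracle: maximize logdet(K) - tr(S K) over the
        free precision entries of the one-missing-edge model."""
        cov, _ = _pentadiagonal_model()
        x = rng.multivariate_normal(np.zeros(5), cov, 20_000)[:, :4]
        s = np.corrcoef(x, rowvar=False)
        missing = (0, 3)
        edges = all_edges(4) - {missing}

        free = [(i, i) for i in range(4)] + sorted(edges)

        def unpack(p):
            K = np.zeros((4, 4))
            for val, (i, j) in zip(p, free):
                K[i, j] = val
                K[j, i] = val
            return K

        def negloglik(p):
            K = unpack(p)
            sign, logdet = np.linalg.slogdet(K)
            if sign <= 0:
                return 1e6
            return -(logdet - np.trace(s @ K))

        p0 = [1.0] * 4 + [0.0] * len(edges)
        res = minimize(negloglik, p0, method="Nelder-Mead",
                       options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-12})
        v_oracle = np.linalg.inv(unpack(res.x))
        d = np.sqrt(np.diag(v_oracle))
        v_oracle = v_oracle / np.outer(d, d)
        v = ipf_fit(s, edges)
        assert np.allclose(v, v_oracle, atol=1e-6)


class TestDeviance:
    def test_zero_for_identical_matrices(self):
        s = _chain_corr()
        assert deviance(s, s, 1000) == pytest.approx(0.0)

    def test_two_by_two_hand_computed(self):
        r = 0.5
        s = np.array([[1.0, r], [r, 1.0]])
        v = ipf_fit(s, set())  # identity
        assert deviance(s, v, 200) == pytest.approx(200 * np.log(1 / (1 - r**2)))

    def test_nested_models_monotone(self, rng):
        cov, _ = _pentadiagonal_model()
        x = rng.multivariate_normal(np.zeros(5), cov, 10_000)[:, :4]
        s = np.corrcoef(x, rowvar=False)
        lattice = [set(), {(0, 1)}, {(0, 1), (1, 2)}, {(0, 1), (1, 2), (2, 3)}, all_edges(4)]
        devs = [deviance(s, ipf_fit(s, e), 10_000) for e in lattice]
        assert np.all(np.diff(devs) <= 1e-6)
        assert all(d >= -1e-6 for d in devs)


class TestEdgeScores:
    def test_saturated_graph_has_no_inclusion_candidates(self):
        s = _chain_corr()
        eed, eid = edge_scores(s, all_edges(3), set(), 1000)
        assert eid == {}
        assert set(eed) == all_edges(3)
        assert all(v >= -1e-8 for v in eed.values())

    def test_irrelevant_edge_scores_near_zero(self, rng):
        cov, true_edges = _pentadiagonal_model()
        x = rng.multivariate_normal(np.zeros(5), cov, 100_000)
        s = np.corrcoef(x, rowvar=False)
        eed, _ = edge_scores(s, all_edges(5), set(), 100_000)
        spurious = all_edges(5) - true_edges
        for e in spurious:
            assert eed[e] < 15.0  # chi2(1)-scale fluctuation
        for e in true_edges:
            assert eed[e] > 1000.0

    def test_removal_and_reinclusion_scores_agree(self):
        s = _chain_corr()
        e = (0, 2)
        eed, _ = edge_scores(s, all_edges(3), set(), 500)
        _, eid = edge_scores(s, all_edges(3) - {e}, {e}, 500)
        assert eid[e] == pytest.approx(eed[e], abs=1e-6)


class TestPruneGraph:
    def test_recovers_known_structure_across_seeds(self):
        cov, true_edges = _pentadiagonal_model()
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.multivariate_normal(np.zeros(5), cov, 100_000)
            s = np.corrcoef(x, rowvar=False)
            model = prune_graph(s, 100_000)
            hits += model.edges == true_edges
        assert hits >= 9

    def test_independent_data_yields_empty_graph(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100_000, 5))
        model = prune_graph(np.corrcoef(x, rowvar=False), 100_000)
        assert model.edges == set()

    def test_zero_thresholds_keep_saturated_graph(self):
        s = _chain_corr()
        model = prune_graph(s, 1000, margin=0.0, eed_floor=0.0)
        assert model.edges == all_edges(3)
        assert np.allclose(model.V, s)

    def test_partial_correlations_vanish_on_removed_edges(self, rng):
        cov, true_edges = _pentadiagonal_model()
        x = rng.multivariate_normal(np.zeros(5), cov, 50_000)
        model = prune_graph(np.corrcoef(x, rowvar=False), 50_000)
        for i, j in model.removed_edges:
            assert model.Vp[i, j] == pytest.approx(0.0, abs=1e-9)

    def test_audit_trail_records_removals(self, rng):
        x = rng.normal(size=(50_000, 4))
        model = prune_graph(np.corrcoef(x, rowvar=False), 50_000)
        assert len(model.trail) == len(model.removed_edges)


class TestExplainedVariance:
    def test_identity_explains_nothing(self):
        assert np.allclose(explained_variance(np.eye(4)), 0.0)

    def test_bivariate_equals_rho_squared(self):
        r = np.array([[1.0, 0.7], [0.7, 1.0]])
        assert np.allclose(explained_variance(r), 0.49)

    def test_matches_least_squares_oracle(self, rng):
        x = rng.multivariate_normal(np.zeros(3), _chain_corr(), 200_000)
        r = np.corrcoef(x, rowvar=False)
        ev = explained_variance(r)
        for i in range(3):
            others = [j for j in range(3) if j != i]
            beta, *_ = np.linalg.lstsq(x[:, others], x[:, i], rcond=None)
            resid = x[:, i] - x[:, others] @ beta
            r2 = 1 - resid.var() / x[:, i].var()
            assert ev[i] == pytest.approx(r2, abs=1e-3)


class TestDAG:
    def test_chain_with_natural_order_is_path(self):
        dag = orient_dag([("a", "b"), ("b", "c")], ["a", "b", "c"])
        assert set(dag.edges) == {("a", "b"), ("b", "c")}

    def test_reversed_order_reverses_edges(self):
        dag = orient_dag([("a", "b"), ("b", "c")], ["c", "b", "a"])
        assert set(dag.edges) == {("b", "a"), ("c", "b")}

    def test_any_ordering_is_acyclic(self, rng):
        nodes = list("abcde")
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "e"), ("e", "d")]
        for _ in range(10):
            order = list(rng.permutation(nodes))
            dag = orient_dag(edges, order)
            assert nx.is_directed_acyclic_graph(dag)

    def test_incomplete_ordering_rejected(self):
        with pytest.raises(ValueError):
            orient_dag([("a", "b")], ["a"])

    def test_moralization_marries_coparents(self):
        dag = nx.DiGraph([("a", "c"), ("b", "c")])
        m = moralize(dag)
        assert m.has_edge("a", "b")

    def test_chain_moralization_adds_nothing(self):
        dag = nx.DiGraph([("a", "b"), ("b", "c")])
        m = moralize(dag)
        assert set(map(frozenset, m.edges)) == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError):
            moralize(nx.DiGraph([("a", "b"), ("b", "a")]))

    def test_moral_graph_covers_original_edges(self, rng):
        """Orient-then-moralize never loses an undirected edge, so the
        undirected model is at least as restrictive as the BN."""
        edges = [("a", "b"), ("b", "c"), ("a", "d"), ("c", "d")]
        for _ in range(5):
            order = list(rng.permutation(["a", "b", "c", "d"]))
            m = moralize(orient_dag(edges, order))
            for u, v in edges:
                assert m.has_edge(u, v)


@pytest.fixture(scope="module")
def posterior_like_samples():
    """Correlated, skewed draws emulating a posterior sample set."""
    rng = np.random.default_rng(11)
    cov = np.array([[1.0, 0.7, 0.3], [0.7, 1.0, 0.5], [0.3, 0.5, 1.0]])
    z = rng.multivariate_normal(np.zeros(3), cov, 200_000)
    x = np.column_stack([np.exp(0.4 * z[:, 0]), z[:, 1], np.exp(0.3 * z[:, 2])])
    return SampleSet(x, names=("p", "q", "r"))


class TestBayesNet:
    def test_cpt_rows_sum_to_one(self, posterior_like_samples):
        dag = orient_dag([("p", "q"), ("q", "r"), ("p", "r")], ["p", "q", "r"])
        bn = fit_cpts(posterior_like_samples, dag, nbins=8)
        for node, cpt in bn.cpts.items():
            assert np.allclose(cpt.sum(axis=-1), 1.0)

    def test_root_cpt_is_marginal_histogram(self, posterior_like_samples):
        from phytocal.posterior_analysis import marginal

        dag = orient_dag([("p", "q")], ["p", "q", "r"])
        bn = fit_cpts(posterior_like_samples, dag, nbins=10, pseudo_count=0.0)
        h = marginal(posterior_like_samples, "p", nbins=10)
        assert np.allclose(bn.cpts["p"], h.probs, atol=1e-12)

    def test_too_many_parents_rejected(self, rng):
        x = rng.normal(size=(1000, 5))
        ss = SampleSet(x, names=tuple("abcde"))
        dag = orient_dag(
            [("a", "e"), ("b", "e"), ("c", "e"), ("d", "e")], list("abcde")
        )
        with pytest.raises(ValueError, match="parents"):
            fit_cpts(ss, dag, nbins=10, max_parents=3)

    def test_independent_child_rows_match_marginal(self, rng):
        x = rng.normal(size=(200_000, 2))
        ss = SampleSet(x, names=("a", "b"))
        bn = fit_cpts(ss, orient_dag([("a", "b")], ["a", "b"]), nbins=5)
        rows = bn.cpts["b"]
        for row in rows:
            assert 0.5 * np.abs(row - rows.mean(axis=0)).sum() < 0.05

    def test_no_evidence_reproduces_fitted_marginals(self, posterior_like_samples):
        from phytocal.posterior_analysis import marginal

        dag = orient_dag([("p", "q"), ("q", "r")], ["p", "q", "r"])
        bn = fit_cpts(posterior_like_samples, dag, nbins=10, pseudo_count=0.5)
        marg = bn_query(bn)
        for node in ("p", "q", "r"):
            h = marginal(posterior_like_samples, node, nbins=10)
            assert 0.5 * np.abs(marg[node] - h.probs).sum() < 0.02

    def test_fully_independent_network_ignores_evidence(self, rng):
        x = rng.normal(size=(100_000, 3))
        ss = SampleSet(x, names=("a", "b", "c"))
        dag = nx.DiGraph()
        dag.add_nodes_from(["a", "b", "c"])
        bn = fit_cpts(ss, dag, nbins=6)
        base = bn_query(bn)
        cond = bn_query(bn, {"a": 5})
        assert np.allclose(base["b"], cond["b"])
        assert np.allclose(base["c"], cond["c"])

    def test_invalid_evidence_rejected(self, posterior_like_samples):
        dag = orient_dag([("p", "q")], ["p", "q", "r"])
        bn = fit_cpts(posterior_like_samples, dag, nbins=6)
        with pytest.raises(ValueError):
            bn_query(bn, {"p": 7})
        with pytest.raises(ValueError):
            bn_query(bn, {"unknown": 0})

    def test_bn_conditionals_match_direct_subsampling(self, posterior_like_samples):
        """Evidence propagation through the BN agrees with conditional
        marginals computed by restricting the raw sample set (total
        variation below 0.1)."""
        ss = posterior_like_samples
        dag = orient_dag([("p", "q"), ("q", "r"), ("p", "r")], ["p", "q", "r"])
        bn = fit_cpts(ss, dag, nbins=10, pseudo_count=1.0)
        col = ss.values[:, 0]
        edges = np.linspace(col.min(), col.max(), 11)
        evidence_bin = 2
        marg = bn_query(bn, {"p": evidence_bin})
        for node in ("q", "r"):
            direct = conditional_marginal(
                ss, node, {"p": (edges[evidence_bin], edges[evidence_bin + 1])}
            )
            tv = 0.5 * np.abs(marg[node] - direct.probs).sum()
            assert tv < 0.1
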