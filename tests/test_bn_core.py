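"""Scoring, likelihoods, lasso candidates, search, and equivalence classes."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bnec.bn_core import (
    DagStructure,
    GaussianNodeParams,
    LearnConfig,
    bic_score,
    cpdag,
    enumerate_dags,
    exhaustive_search,
    fit_node_ml,
    implied_covariance,
    joint_log_likelihood,
    l1_parent_path,
    learn_structure,
    node_log_likelihood,
)
from bnec.preprocess import standardize
from bnec.synthetic import (
    sample_random_dag,
    sample_random_parameters,
    simulate_gaussian_bn,
)

from conftest import make_ts


class TestDagStructure:
    def test_rejects_cycles_and_self_loops(self):
        with pytest.raises(ValueError, match="cycle"):
            DagStructure.from_edges(("a", "b"), [("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="self-loop"):
            DagStructure.from_edges(("a",), [("a", "a")])

    def test_topological_order_respects_edges(self):
        st_ = DagStructure.from_edges(("c", "a", "b"), [("a", "b"), ("b", "c")])
        order = st_.topological_order()
        assert order.index("a") < order.index("b") < order.index("c")


class TestFitNodeMl:
    def test_noise_free_weights_exact(self, rng):
        X = rng.normal(size=(200, 2))
        child = 0.5 * X[:, 0] - 0.3 * X[:, 1]
        ts = make_ts(np.column_stack([X, child]), labels=["p1", "p2", "c"])
        fit = fit_node_ml(ts, "c", {"p1", "p2"})
        assert fit.weights["p1"] == pytest.approx(0.5, abs=1e-10)
        assert fit.weights["p2"] == pytest.approx(-0.3, abs=1e-10)
        assert fit.residual_variance < 1e-18

    def test_empty_parent_set_closed_form(self):
        ts = make_ts(np.array([[1.0], [2.0], [3.0]]), labels=["x"])
        fit = fit_node_ml(ts, "x", set())
        assert fit.mean == pytest.approx(2.0)
        assert fit.residual_variance == pytest.approx(2.0 / 3.0)  # ML: divide by m

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(300, 3))
        y = X @ [0.4, -0.2, 0.7] + rng.normal(size=300)
        ts = make_ts(np.column_stack([X, y]), labels=["a", "b", "c", "y"])
        fit = fit_node_ml(ts, "y", {"a", "b", "c"})
        Z = np.column_stack([np.ones(300), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        for j, p in enumerate(["a", "b", "c"]):
            assert fit.weights[p] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_collinear_parents_rejected(self, rng):
        x = rng.normal(size=100)
        ts = make_ts(np.column_stack([x, 2 * x, rng.normal(size=100)]),
                     labels=["a", "b", "y"])
        with pytest.raises(ValueError, match="collinear"):
            fit_node_ml(ts, "y", {"a", "b"})


class TestLogLikelihood:
    def test_closed_form_at_ml_optimum(self, rng):
        y = rng.normal(size=500)
        ts = make_ts(y[:, None], labels=["x"])
        fit = fit_node_ml(ts, "x", set())
        ll = node_log_likelihood(ts, "x", fit)
        expected = -0.5 * 500 * (np.log(2 * np.pi * fit.residual_variance) + 1)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_duplicating_samples_doubles_loglik(self, rng):
        y = rng.normal(size=100)
        params = GaussianNodeParams(0.1, {}, 1.3)
        one = node_log_likelihood(make_ts(y[:, None], labels=["x"]), "x", params)
        two = node_log_likelihood(
            make_ts(np.concatenate([y, y])[:, None], labels=["x"]), "x", params
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_per_sample_density_oracle(self, rng):
        X = rng.normal(size=(50, 2))
        ts = make_ts(X, labels=["p", "c"])
        params = GaussianNodeParams(0.2, {"p": 0.6}, 0.8)
        ll = node_log_likelihood(ts, "c", params)
        mp = X[:, 0].mean()
        cond = 0.2 + 0.6 * (X[:, 0] - mp)
        oracle = stats.norm(cond, np.sqrt(0.8)).logpdf(X[:, 1]).sum()
        assert ll == pytest.approx(oracle, rel=1e-10)


class TestBicScore:
    def test_parameter_count_rule(self, rng):
        ts = make_ts(rng.normal(size=(50, 8)))
        empty = DagStructure(tuple(ts.node_labels), {})
        assert bic_score(empty, ts).d == 16  # 2n for means+variances
        chain = DagStructure.from_edges(
            tuple(ts.node_labels), [(ts.node_labels[0], ts.node_labels[1])]
        )
        assert bic_score(chain, ts).d == 17

    def test_chain_beats_empty_on_dependent_data(self, chain3):
        structure, params = chain3
        ts = standardize(simulate_gaussian_bn(structure, params, 1000, seed=31))
        chain = DagStructure.from_edges(("X1", "X2", "X3"), [("X1", "X2")])
        empty = DagStructure(("X1", "X2", "X3"), {})
        assert bic_score(chain, ts).total > bic_score(empty, ts).total

    def test_adding_parent_never_decreases_loglik(self, rng):
        ts = make_ts(rng.normal(size=(200, 4)))
        nodes = tuple(ts.node_labels)
        base = DagStructure(nodes, {})
        for parent in nodes[1:]:
            bigger = DagStructure.from_edges(nodes, [(parent, nodes[0])])
            assert (
                bic_score(bigger, ts).total_loglik
                >= bic_score(base, ts).total_loglik - 1e-9
            )

    def test_score_decomposability(self, rng):
        # an edge into v changes only v's per-node term
        ts = make_ts(rng.normal(size=(100, 4)))
        nodes = tuple(ts.node_labels)
        s0 = bic_score(DagStructure(nodes, {}), ts)
        s1 = bic_score(DagStructure.from_edges(nodes, [(nodes[2], nodes[1])]), ts)
        for n in nodes:
            if n != nodes[1]:
                assert s1.per_node_loglik[n] == pytest.approx(s0.per_node_loglik[n])

    def test_total_consistency(self, rng):
        ts = make_ts(rng.normal(size=(100, 3)))
        sc = bic_score(DagStructure(tuple(ts.node_labels), {}), ts)
        assert sc.total == pytest.approx(
            sc.total_loglik - 0.5 * sc.d * np.log(sc.m), rel=1e-12
        )


class TestL1Path:
    def test_starts_empty_and_ends_full(self, rng):
        ts = make_ts(rng.normal(size=(500, 4)))
        ts = standardize(ts)
        cands = l1_parent_path(ts, ts.node_labels[0])
        assert cands[0] == frozenset()
        assert cands[-1] == frozenset(ts.node_labels[1:])

    def test_true_parent_enters_before_noise_node(self):
        structure = DagStructure.from_edges(
            ("X1", "X2", "X3"), [("X1", "X3")]
        )
        params = {
            "X1": GaussianNodeParams(0.0, {}, 1.0),
            "X2": GaussianNodeParams(0.0, {}, 1.0),
            "X3": GaussianNodeParams(0.0, {"X1": 0.8}, 0.36),
        }
        from bnec.bn_core import GaussianBnParameters

        ts = simulate_gaussian_bn(
            structure, GaussianBnParameters(params), 2000, seed=41
        )
        ts = standardize(ts)
        cands = l1_parent_path(ts, "X3")
        first_with_x1 = next(i for i, c in enumerate(cands) if "X1" in c)
        first_with_x2 = next(
            (i for i, c in enumerate(cands) if "X2" in c), len(cands)
        )
        assert first_with_x1 < first_with_x2


class TestLearnStructure:
    def test_chain_recovered_up_to_equivalence_and_matches_oracle(self, chain3):
        structure, params = chain3
        ts = standardize(simulate_gaussian_bn(structure, params, 2000, seed=51))
        model = learn_structure(ts, LearnConfig(seed=1))
        oracle = exhaustive_search(ts)
        assert model.score.total == pytest.approx(oracle.score.total, abs=1e-6)
        assert cpdag(model.structure) == cpdag(structure)

    def test_independent_nodes_give_mostly_empty_graphs(self):
        # BIC false-edge theory at m=1000: an edge enters when the LR stat
        # exceeds 2 * (ln m)/2 = 6.91, i.e. p ~ 0.0086 per pair; across 28
        # pairs P(>=1 false edge) ~ 0.21, so ~16/20 empty in expectation.
        # Assert a 2-sigma-safe lower bound on that binomial.
        empty_runs = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ts = make_ts(rng.normal(size=(1000, 8)))
            model = learn_structure(standardize(ts), LearnConfig(seed=seed))
            empty_runs += model.structure.n_edges == 0
        assert empty_runs >= 12

    def test_output_always_acyclic(self, rng):
        for seed in range(5):
            structure = sample_random_dag(5, 0.4, seed=seed)
            params = sample_random_parameters(structure, seed=seed + 100)
            ts = standardize(simulate_gaussian_bn(structure, params, 500, seed=seed))
            model = learn_structure(ts, LearnConfig(seed=seed, restarts=3))
            assert model.structure.topological_order() is not None

    def test_deterministic_given_seed(self, chain3):
        structure, params = chain3
        ts = standardize(simulate_gaussian_bn(structure, params, 500, seed=52))
        a = learn_structure(ts, LearnConfig(seed=9))
        b = learn_structure(ts, LearnConfig(seed=9))
        assert a.structure.edges() == b.structure.edges()
        assert a.score.total == b.score.total


class TestExhaustiveSearch:
    def test_dag_counts_match_enumeration(self):
        assert enumerate_dags(3) == 25
        assert enumerate_dags(4) == 543

    def test_oracle_bound_on_hill_climb(self, rng):
        ts = make_ts(rng.normal(size=(300, 4)))
        ts = standardize(ts)
        hill = learn_structure(ts, LearnConfig(seed=2, restarts=2))
        oracle = exhaustive_search(ts)
        assert oracle.score.total >= hill.score.total - 1e-9

    def test_too_many_nodes_rejected(self, rng):
        ts = make_ts(rng.normal(size=(50, 5)))
        with pytest.raises(ValueError, match="exhaustive"):
            exhaustive_search(ts)


class TestFactorization:
    def test_joint_density_equals_sum_of_conditionals(self):
        # the product form P(X) = prod_i P(Xi | Pa(Xi)) against a direct
        # multivariate-normal evaluation through the implied covariance
        for seed in range(5):
            structure = sample_random_dag(5, 0.5, seed=seed)
            params = sample_random_parameters(structure, seed=seed + 50)
            ts = simulate_gaussian_bn(structure, params, 200, seed=seed + 99)
            parent_means = {n: params[n].mean for n in structure.nodes}
            total = sum(
                node_log_likelihood(ts, n, params[n], parent_means=parent_means)
                for n in structure.nodes
            )
            joint = joint_log_likelihood(ts, structure, params)
            assert joint == pytest.approx(total, abs=1e-6)


class TestCpdag:
    def test_chain_is_fully_undirected(self):
        st_ = DagStructure.from_edges(("a", "b", "c"), [("a", "b"), ("b", "c")])
        assert cpdag(st_) == frozenset({("--", "a", "b"), ("--", "b", "c")})

    def test_v_structure_is_compelled(self):
        st_ = DagStructure.from_edges(("a", "b", "c"), [("a", "c"), ("b", "c")])
        assert cpdag(st_) == frozenset({("->", "a", "c"), ("->", "b", "c")})

    def test_equivalent_dags_share_cpdag(self):
        fwd = DagStructure.from_edges(("a", "b", "c"), [("a", "b"), ("b", "c")])
        rev = DagStructure.from_edges(("a", "b", "c"), [("b", "a"), ("b", "c")])
        assert cpdag(fwd) == cpdag(rev)

    def test_matches_brute_force_equivalence_oracle(self):
        # compelled = same orientation in every DAG sharing skeleton+v-structures
        from bnec.bn_core import _all_parent_maps

        def brute(struct):
            nodes = struct.nodes
            n = len(nodes)

            def sig(pm):
                skel = frozenset(
                    frozenset((p, c)) for c, ps in enumerate(pm) for p in ps
                )
                vs = set()
                for c, ps in enumerate(pm):
                    for a, b in itertools.combinations(sorted(ps), 2):
                        if frozenset((a, b)) not in skel:
                            vs.add((a, c, b))
                return skel, frozenset(vs)

            ref_pm = tuple(
                frozenset(nodes.index(p) for p in struct.parents[c]) for c in nodes
            )
            ref = sig(ref_pm)
            members = [pm for pm in _all_parent_maps(n) if sig(pm) == ref]
            recs = set()
            for pair in ref[0]:
                a, b = sorted(pair)
                orients = {(a in pm[b]) for pm in members}
                if orients == {True}:
                    recs.add(("->", nodes[a], nodes[b]))
                elif orients == {False}:
                    recs.add(("->", nodes[b], nodes[a]))
                else:
                    recs.add(("--", nodes[a], nodes[b]))
            return frozenset(recs)

        rng = np.random.default_rng(3)
        for seed in range(80):
            st_ = sample_random_dag(4, rng.uniform(0.2, 1.0), seed=seed)
            assert cpdag(st_) == brute(st_), st_.edges()


def test_implied_covariance_positive_definite():
    structure = sample_random_dag(6, 0.4, seed=77)
    params = sample_random_parameters(structure, seed=78)
    _, cov = implied_covariance(structure, params)
    assert np.all(np.linalg.eigvalsh(cov) > 0)
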