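import numpy as np
import pytest

from conftest import (
    brute_map_with_tie_rule,
    make_graph,
    random_instance,
    random_params,
)
from resq import crf
from resq.crf import (
    CRFParameters,
    SGDHyper,
    brute_force_distribution,
    build_instance,
    clique_log_potential,
    energy,
    enumerate_clique_labelings,
    fit_logistic_regression,
    infer_map,
    infer_marginals,
    log_likelihood,
    logistic_predict,
    pattern_index,
    train_sgd,
)


def triangle_instance(features=None, labels=None):
    g = make_graph([(1, 2), (1, 3), (2, 3)], classes=["HH", "HH", "HH"])
    x = np.zeros((3, 2)) if features is None else np.asarray(features)
    return build_instance(g, x, labels=labels)


class TestCliquePotential:
    def test_zero_parameters_give_zero(self):
        inst = triangle_instance()
        params = CRFParameters.zeros(2)
        for labels in [(0, 0, 0), (1, 0, 1), (1, 1, 1)]:
            assert clique_log_potential(inst, params, 0, labels) == 0.0

    def test_triangle_pairwise_counting(self):
        # labels (0,1,1) on A<B<C: patterns 01, 01, 11 over the three connections
        inst = triangle_instance()
        omega = np.array([10.0, 20.0, 30.0, 40.0])
        params = CRFParameters(lam=np.zeros((2, 2)), omega=omega)
        val = clique_log_potential(inst, params, 0, (0, 1, 1))
        assert val == pytest.approx(omega[1] + omega[1] + omega[3])

    def test_three_clique_enumerates_eight_labelings(self):
        inst = triangle_instance()
        params = CRFParameters.zeros(2)
        labelings = enumerate_clique_labelings(inst, params, 0)
        assert len(labelings) == 8
        assert sorted(l for l, _ in labelings) == sorted(
            (a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
        )

    def test_pattern_index_order(self):
        assert [pattern_index(a, b) for a, b in [(0, 0), (0, 1), (1, 0), (1, 1)]] == [0, 1, 2, 3]

    def test_clique_potentials_sum_to_energy(self, rng):
        inst = random_instance(rng, 7, m=3)
        params = random_params(rng, 3)
        labels = rng.integers(0, 2, size=7)
        label_of = {v: labels[inst.node_pos[v]] for v in inst.nodes}
        total = sum(
            clique_log_potential(inst, params, ci, [label_of[v] for v in inst.cliques[ci]])
            for ci in range(len(inst.cliques))
        )
        assert total == pytest.approx(energy(inst, params, labels), abs=1e-9)


class TestBruteForce:
    def test_zero_parameters_uniform(self):
        inst = triangle_instance()
        _, probs = brute_force_distribution(inst, CRFParameters.zeros(2))
        assert np.allclose(probs, 1.0 / 8.0, atol=1e-12)

    def test_normalization_random(self, rng):
        for _ in range(20):
            inst = random_instance(rng, int(rng.integers(2, 11)), m=3)
            _, probs = brute_force_distribution(inst, random_params(rng, 3, scale=2.0))
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_residue_logistic_form(self, rng):
        # a 2-residue chain with zero omega factorizes into independent logits
        g = make_graph([(1, 2)], classes=["CC"])
        x = rng.normal(size=(2, 3))
        inst = build_instance(g, x)
        lam = np.zeros((2, 3))
        lam[1] = rng.normal(size=3)
        params = CRFParameters(lam=lam, omega=np.zeros(4))
        t = x @ lam[1]
        labelings, probs = brute_force_distribution(inst, params)
        p1_first = probs[labelings[:, 0] == 1].sum()
        assert p1_first == pytest.approx(1.0 / (1.0 + np.exp(-t[0])), abs=1e-12)

    def test_size_limit(self, rng):
        inst = random_instance(rng, 17, m=2)
        with pytest.raises(ValueError, match="enumeration"):
            brute_force_distribution(inst, CRFParameters.zeros(2))


class TestInference:
    def test_marginals_match_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            inst = random_instance(rng, n, m=3)
            params = random_params(rng, 3, scale=1.5)
            marg = infer_marginals(inst, params)
            labelings, probs = brute_force_distribution(inst, params)
            expected = (probs[:, None] * labelings).sum(axis=0)
            assert np.allclose(marg, expected, atol=1e-9)

    def test_zero_parameters_half(self, rng):
        inst = random_instance(rng, 8, m=3)
        assert np.allclose(infer_marginals(inst, CRFParameters.zeros(3)), 0.5, atol=1e-12)

    def test_disconnected_components_factorize(self, rng):
        # two separate chains in one graph = product of isolated computations
        edges = [(1, 2), (2, 3), (10, 11), (11, 12)]
        g = make_graph(edges, classes=["CC"] * 4)
        x = rng.normal(size=(6, 2))
        params = random_params(rng, 2)
        inst = build_instance(g, x)
        marg = infer_marginals(inst, params)

        g1 = make_graph([(1, 2), (2, 3)], classes=["CC"] * 2)
        g2 = make_graph([(10, 11), (11, 12)], classes=["CC"] * 2)
        m1 = infer_marginals(build_instance(g1, x[:3]), params)
        m2 = infer_marginals(build_instance(g2, x[3:]), params)
        assert np.allclose(marg, np.concatenate([m1, m2]), atol=1e-12)

    def test_map_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            inst = random_instance(rng, n, m=3)
            params = random_params(rng, 3, scale=1.5)
            assert np.array_equal(infer_map(inst, params), brute_map_with_tie_rule(inst, params))

    def test_ferromagnetic_tie_goes_to_all_ones(self):
        inst = triangle_instance()
        params = CRFParameters(lam=np.zeros((2, 2)), omega=np.array([3.0, 0.0, 0.0, 3.0]))
        assert np.array_equal(infer_map(inst, params), [1, 1, 1])

    def test_single_residue_negative_gain(self):
        g = make_graph([(1, 2)], classes=["CC"])
        x = np.array([[1.0], [0.0]])
        params = CRFParameters(lam=np.array([[0.0], [-2.0]]), omega=np.zeros(4))
        labels = infer_map(build_instance(g, x), params)
        assert labels[0] == 0
        assert labels[1] == 1  # zero gain -> tie -> label 1

    def test_cc_weight_zero_cuts_graph(self, rng):
        # two cliques joined only by CC edges behave as isolated subgraphs
        edges = [(1, 2), (2, 3), (1, 3), (3, 4), (2, 4), (4, 5), (5, 6), (4, 6)]
        classes = ["HH", "HH", "HH", "CC", "CC", "CC", "BB", "CC"]
        g = make_graph(edges, classes=classes)
        x = rng.normal(size=(6, 2))
        params = random_params(rng, 2)
        params.edge_weights["CC"] = 0.0
        marg = infer_marginals(build_instance(g, x), params)

        left = make_graph([(1, 2), (2, 3), (1, 3)], classes=["HH"] * 3)
        right = make_graph([(5, 6)], classes=["BB"])
        ml = infer_marginals(build_instance(left, x[:3]), params)
        mr = infer_marginals(build_instance(right, x[4:]), params)
        assert np.allclose(marg[:3], ml, atol=1e-9)
        assert np.allclose(marg[4:], mr, atol=1e-9)

    def test_label_symmetry(self, rng):
        inst = random_instance(rng, 6, m=2)
        lam = np.zeros((2, 2))
        lam[1] = rng.normal(size=2)
        omega = rng.normal(size=4)
        params = CRFParameters(lam=lam, omega=omega)
        # swap label roles: lam rows exchanged, omega patterns 00<->11, 01<->10
        mirrored = CRFParameters(lam=lam[::-1].copy(), omega=omega[::-1].copy())
        assert np.allclose(
            infer_marginals(inst, params), 1.0 - infer_marginals(inst, mirrored), atol=1e-9
        )


class TestTraining:
    def test_gradient_at_zero_matches_hand_computation(self, rng):
        # 2-residue chain; at theta=0 the distribution is uniform
        g = make_graph([(1, 2)], classes=["HH"])
        x = np.array([[1.0, 2.0], [3.0, -1.0]])
        y = np.array([1, 0])
        inst = build_instance(g, x, labels=y)
        params = CRFParameters.zeros(2)
        g_lam1, g_omega = crf._instance_statistics(inst, params)
        # observed - uniform-expected: node stats (y_r - 0.5) * x_r
        assert np.allclose(g_lam1, (1 - 0.5) * x[0] + (0 - 0.5) * x[1])
        # edge pattern 10 observed once; each pattern expected 0.25
        assert np.allclose(g_omega, [-0.25, -0.25, 0.75, -0.25])

    def test_all_one_labels_increase_their_probability(self, rng):
        instances = [
            random_instance(rng, 5, m=2, with_labels=False) for _ in range(3)
        ]
        for inst in instances:
            inst.labels = np.ones(5, dtype=int)
        _, trace = train_sgd(instances, SGDHyper(learning_rate=0.01, epochs=8, l2_penalty=0.0, seed=1))
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_loglik_nondecreasing_small_lr(self, rng):
        instances = [random_instance(rng, 5, m=2, with_labels=True) for _ in range(5)]
        _, trace = train_sgd(
            instances, SGDHyper(learning_rate=0.002, epochs=10, l2_penalty=0.0, seed=2)
        )
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_nonfinite_gradient_aborts_with_instance_name(self, rng):
        inst = random_instance(rng, 4, m=2, with_labels=True)
        inst.features[0, 0] = np.nan
        inst.model_id = "badapple"
        with pytest.raises(Exception, match="badapple"):
            train_sgd([inst], SGDHyper(epochs=1))

    def test_deterministic_given_seed(self, rng):
        instances = [random_instance(rng, 5, m=2, with_labels=True) for _ in range(4)]
        hyper = SGDHyper(learning_rate=0.05, epochs=3, seed=7)
        p1, t1 = train_sgd(instances, hyper)
        p2, t2 = train_sgd(instances, hyper)
        assert np.array_equal(p1.lam, p2.lam)
        assert np.array_equal(p1.omega, p2.omega)
        assert t1 == t2


class TestLinearBaseline:
    def test_predict_linear_baseline_deterministic(self, rng):
        from resq.evaluate import ModelRecord, predict_linear_baseline
        from resq.synthetic import generate_toy_structure

        model = generate_toy_structure(8, "C" * 8, seed=2)
        x = rng.normal(size=(8, 2))
        record = ModelRecord("m0", model, x, np.zeros(8, dtype=int), ss="C" * 8)
        lam = np.zeros((2, 2))
        lam[1] = [1.0, -0.5]
        params = CRFParameters(lam=lam, omega=np.array([0.2, -0.2, -0.2, 0.2]))
        a = predict_linear_baseline(record, x, params)
        b = predict_linear_baseline(record, x, params)
        assert np.array_equal(a.map_labels, b.map_labels)
        assert np.array_equal(a.marginal_p1, b.marginal_p1)
        assert np.all((a.marginal_p1 >= 0) & (a.marginal_p1 <= 1))

    def test_one_angstrom_graph_is_chain_triangles(self, rng):
        from resq.graph import build_graph
        from resq.synthetic import generate_toy_structure

        model = generate_toy_structure(10, "C" * 10, seed=0)
        g = build_graph(model, 1.0)
        expected = {(i, i + 1) for i in range(1, 10)} | {(i, i + 2) for i in range(1, 9)}
        assert set(g.edges) == expected

    def test_zero_omega_equals_independent_logistic(self, rng):
        from resq.graph import build_graph, classify_edges
        from resq.synthetic import generate_toy_structure

        model = generate_toy_structure(8, "C" * 8, seed=1)
        g = classify_edges(build_graph(model, 1.0), "C" * 8)
        x = rng.normal(size=(8, 3))
        lam = np.zeros((2, 3))
        lam[1] = rng.normal(size=3)
        params = CRFParameters(lam=lam, omega=np.zeros(4))
        marg = infer_marginals(build_instance(g, x), params)
        assert np.allclose(marg, 1.0 / (1.0 + np.exp(-(x @ lam[1]))), atol=1e-12)


class TestLogisticRegression:
    def test_perfectly_separable(self):
        x = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([0, 0, 1, 1])
        beta = fit_logistic_regression(x, y)
        _, labels = logistic_predict(beta, x)
        assert np.array_equal(labels, y)

    def test_zero_information_predicts_prevalence(self, rng):
        x = np.zeros((40, 2))
        y = np.array([1] * 30 + [0] * 10)
        beta = fit_logistic_regression(x, y)
        p, _ = logistic_predict(beta, x)
        assert np.allclose(p, 0.75, atol=1e-4)

    def test_matches_irls_oracle(self, rng):
        x = rng.normal(size=(50, 3))
        logits = x @ np.array([1.0, -2.0, 0.5]) + 0.3
        y = (rng.random(50) < 1 / (1 + np.exp(-logits))).astype(int)
        beta = fit_logistic_regression(x, y)

        # independent IRLS (Newton-Raphson on the logistic log-likelihood)
        xb = np.column_stack([np.ones(50), x])
        b = np.zeros(4)
        for _ in range(100):
            p = 1 / (1 + np.exp(-(xb @ b)))
            w = p * (1 - p)
            h = xb.T @ (xb * w[:, None])
            step = np.linalg.solve(h + 1e-12 * np.eye(4), xb.T @ (y - p))
            b = b + step
            if np.abs(step).max() < 1e-12:
                break
        assert np.allclose(beta, b, atol=1e-4)


class TestParameterFile:
    def test_round_trip_bit_exact(self, rng):
        params = CRFParameters(
            lam=np.vstack([np.zeros(3), rng.normal(size=3)]),
            omega=rng.normal(size=4),
            edge_weights={"HH": 0.9, "BB": 0.8, "HB": 1.0, "CHB": 0.1, "CC": 0.0},
            ca_cutoff=5.0,
            neighbor_cutoff=4.5,
            feature_names=["a", "b", "c"],
            seed=11,
            metadata={"epochs": 50},
        )
        again = CRFParameters.from_json(params.to_json())
        assert np.array_equal(again.lam, params.lam)
        assert np.array_equal(again.omega, params.omega)
        assert again.edge_weights == params.edge_weights
        assert again.feature_names == params.feature_names
        assert again.seed == params.seed
        assert CRFParameters.from_json(again.to_json()).to_json() == again.to_json()

    def test_invalid_edge_weight_rejected(self):
        with pytest.raises(ValueError):
            CRFParameters(lam=np.zeros((2, 1)), omega=np.zeros(4), edge_weights={"HH": 1.5})
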