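import itertools

import numpy as np
import pytest

from stabnet import bn
from stabnet.bn import (
    CptParams,
    EmOptions,
    GaussianTable,
    NetworkSpec,
    Node,
    NoisyOrParams,
    build_model,
    classify_score,
    em_train,
    infer_stability,
    joint_log_prob,
    noisy_or_prob,
    predict_proteome,
)
from conftest import random_tiny_params


class TestStructure:
    def test_bn_svm_structure(self):
        spec = build_model("bn_svm")
        assert len(spec.discrete_nodes) == 20
        assert len(spec.continuous_nodes) == 3
        stability = spec.node(bn.STABILITY)
        assert len(stability.parents) == 4  # 16 parent configurations
        assert len(spec.node(bn.PTM_LATENT).parents) == 4
        assert len(spec.node(bn.DOMAIN_LATENT).parents) == 9
        assert len(spec.node(bn.DISORDER_LATENT).parents) == 2

    def test_bn_drops_sequence_leaf(self):
        spec = build_model("bn")
        names = {n.name for n in spec.nodes}
        assert bn.SVM_LEAF not in names
        assert len(spec.continuous_nodes) == 2

    def test_svm_variant_is_two_nodes(self):
        spec = build_model("svm")
        assert len(spec.nodes) == 2

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_model("boosted")

    def test_cycle_rejected(self):
        nodes = (Node("a", "cpt", ("b",)), Node("b", "cpt", ("a",)))
        with pytest.raises(ValueError, match="cycle"):
            NetworkSpec(nodes)

    def test_continuous_nodes_must_be_leaves(self):
        nodes = (
            Node("a", "cpt"),
            Node("x", "gaussian", ("a",)),
            Node("b", "cpt", ("x",)),
        )
        with pytest.raises(ValueError):
            NetworkSpec(nodes)


class TestNoisyOr:
    @pytest.mark.parametrize(
        "q,c0,states,expected",
        [
            ([0.5, 0.5], 0.0, [0, 0], 0.0),  # OR of nothing, leak-free
            ([0.2], 0.0, [1], 0.8),
            ([0.5, 0.5], 0.0, [1, 1], 0.75),
            ([0.5], 0.5, [0], 0.5),  # pure leak
        ],
    )
    def test_formula(self, q, c0, states, expected):
        params = NoisyOrParams(q=np.array(q, dtype=float), c0=c0)
        assert noisy_or_prob(params, states) == pytest.approx(expected)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            NoisyOrParams(q=np.array([0.0]), c0=0.1)
        with pytest.raises(ValueError):
            NoisyOrParams(q=np.array([0.5]), c0=1.0)


class TestJointLogProb:
    def test_single_node(self):
        spec = NetworkSpec((Node("stability", "cpt"),), variant="svm")
        params = {"stability": CptParams(np.array([0.7, 0.3]))}
        assert joint_log_prob(spec, params, {"stability": 1}) == pytest.approx(np.log(0.3))

    def test_distribution_normalizes(self, tiny_spec):
        rng = np.random.default_rng(0)
        params = random_tiny_params(tiny_spec, rng)
        names = [n.name for n in tiny_spec.discrete_nodes]
        total = sum(
            np.exp(joint_log_prob(tiny_spec, params, dict(zip(names, vals))))
            for vals in itertools.product([0, 1], repeat=len(names))
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_equals_product_of_factors(self, tiny_spec):
        rng = np.random.default_rng(1)
        params = random_tiny_params(tiny_spec, rng)
        asg = {"a": 1, "b": 0, "c": 1, "d": 0, "stability": 1, "x": 0.3}
        manual = (
            np.log(params["a"].table[1])
            + np.log(params["b"].table[1, 0])
            + np.log(noisy_or_prob(params["c"], [1, 0]))
            + np.log(1 - params["d"].table[1, 1])
            + np.log(params["stability"].table[0, 1, 1])
            + bn._log_gaussian(0.3, params["x"].mean[1], params["x"].var[1])
        )
        assert joint_log_prob(tiny_spec, params, asg) == pytest.approx(float(manual))

    def test_missing_discrete_node_rejected(self, tiny_spec):
        params = random_tiny_params(tiny_spec, np.random.default_rng(2))
        with pytest.raises(ValueError, match="missing"):
            joint_log_prob(tiny_spec, params, {"a": 1})


def enumeration_posterior(spec, params, evidence):
    """Independent oracle: sum joint probabilities over every assignment of
    the unobserved discrete nodes."""
    names = [n.name for n in spec.discrete_nodes]
    num = den = 0.0
    for vals in itertools.product([0, 1], repeat=len(names)):
        asg = dict(zip(names, vals))
        if any(asg[k] != v for k, v in evidence.items() if k in asg):
            continue
        for leaf in spec.continuous_nodes:
            asg[leaf.name] = evidence.get(leaf.name)
        w = np.exp(joint_log_prob(spec, params, asg))
        den += w
        if asg["stability"] == 1:
            num += w
    return num / den


class TestInference:
    def test_uniform_network_is_half(self):
        nodes = (Node("a", "cpt"), Node("stability", "cpt", ("a",)))
        spec = NetworkSpec(nodes, variant="bn")
        params = {
            "a": CptParams(np.array([0.5, 0.5])),
            "stability": CptParams(np.full((2, 2), 0.5)),
        }
        assert infer_stability(spec, params, {}) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, tiny_spec, seed):
        rng = np.random.default_rng(seed)
        params = random_tiny_params(tiny_spec, rng)
        evidence = {}
        for name in ("a", "b", "c", "d"):
            r = rng.random()
            if r < 0.4:
                evidence[name] = int(rng.integers(2))
        if rng.random() < 0.7:
            evidence["x"] = float(rng.normal())
        got = infer_stability(tiny_spec, params, evidence)
        want = enumeration_posterior(tiny_spec, params, evidence)
        assert got == pytest.approx(want, abs=1e-12)

    def test_uninformative_continuous_evidence(self, tiny_spec):
        rng = np.random.default_rng(3)
        params = random_tiny_params(tiny_spec, rng)
        table = params["x"]
        params["x"] = GaussianTable(mean=np.array([0.2, 0.2]), var=np.array([1.0, 1.0]))
        base = infer_stability(tiny_spec, params, {"a": 1})
        with_leaf = infer_stability(tiny_spec, params, {"a": 1, "x": 0.7})
        assert with_leaf == pytest.approx(base, abs=1e-12)

    def test_evidence_outside_domain_rejected(self, tiny_spec):
        params = random_tiny_params(tiny_spec, np.random.default_rng(0))
        with pytest.raises(ValueError, match="domain"):
            infer_stability(tiny_spec, params, {"a": 2})

    def test_bn_svm_with_flat_sequence_leaf_equals_bn(self, ground_truth):
        spec_full, params_full = ground_truth
        params_full = dict(params_full)
        params_full[bn.SVM_LEAF] = GaussianTable(
            mean=np.array([0.4, 0.4]), var=np.array([1.3, 1.3])
        )
        spec_bn = build_model("bn")
        params_bn = {k: v for k, v in params_full.items() if k != bn.SVM_LEAF}
        rng = np.random.default_rng(4)
        roots = [
            n.name
            for n in spec_bn.discrete_nodes
            if not n.parents and n.name != bn.STABILITY
        ]
        for _ in range(10):
            evidence = {name: int(rng.integers(2)) for name in roots if rng.random() < 0.7}
            evidence["pwm_tyrosine"] = float(rng.normal(4, 2))
            full = infer_stability(spec_full, params_full, {**evidence, bn.SVM_LEAF: float(rng.normal())})
            plain = infer_stability(spec_bn, params_bn, evidence)
            assert full == pytest.approx(plain, abs=1e-12)

    def test_svm_variant_reduces_to_calibrated_posterior(self):
        from stabnet.svm import CalibratedSvm, svm_posterior

        spec = build_model("svm")
        p1 = 0.6
        params = {
            bn.STABILITY: CptParams(np.array([1 - p1, p1])),
            bn.SVM_LEAF: GaussianTable(mean=np.array([-1.0, 1.2]), var=np.array([0.8, 1.5])),
        }
        cal = CalibratedSvm(
            weights=np.zeros(20),
            offset=0.0,
            means={"unstable": -1.0, "stable": 1.2},
            variances={"unstable": 0.8, "stable": 1.5},
            priors={"unstable": 1 - p1, "stable": p1},
        )
        for s in (-2.0, 0.0, 0.5, 3.0):
            assert infer_stability(spec, params, {bn.SVM_LEAF: s}) == pytest.approx(
                svm_posterior(s, cal), abs=1e-12
            )


class TestEm:
    def _observed_data(self, tiny_spec, n, seed):
        rng = np.random.default_rng(seed)
        params = random_tiny_params(tiny_spec, rng)
        return params, bn.sample_records(tiny_spec, params, n, rng)

    def test_fully_observed_collapses_to_counting(self, tiny_spec):
        _, data = self._observed_data(tiny_spec, 400, 0)
        result = em_train(tiny_spec, data, EmOptions(seed=0, max_iter=2, pseudocount=1.0))
        for name in ("a", "b", "d", "stability"):
            node = tiny_spec.node(name)
            counts = np.zeros((2,) * len(node.parents) + (2,))
            idx = tuple(data[p] for p in node.parents) + (data[name],)
            np.add.at(counts, idx, 1)
            expected = (counts + 1) / (counts + 1).sum(axis=-1, keepdims=True)
            np.testing.assert_allclose(result.params[name].table, expected, atol=1e-12)

    def test_objective_monotone_from_random_starts(self, tiny_spec):
        _, data = self._observed_data(tiny_spec, 300, 1)
        # hide some nodes to create latent structure
        data = dict(data)
        rng = np.random.default_rng(2)
        for name in ("c", "d"):
            col = data[name].copy()
            col[rng.random(len(col)) < 0.5] = bn.MISSING
            data[name] = col
        for seed in range(5):
            result = em_train(tiny_spec, data, EmOptions(seed=seed, max_iter=40))
            trace = result.objective_trace
            assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_pure_ml_loglik_monotone(self, tiny_spec):
        _, data = self._observed_data(tiny_spec, 200, 3)
        data = dict(data)
        data["c"] = np.full_like(data["c"], bn.MISSING)
        result = em_train(tiny_spec, data, EmOptions(seed=0, max_iter=40, pseudocount=0.0))
        trace = result.loglik_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_symmetric_init_preserved_without_evidence(self):
        nodes = (Node("a", "cpt"), Node("b", "cpt", ("a",)))
        spec = NetworkSpec(nodes, variant="bn")
        init = {
            "a": CptParams(np.array([0.5, 0.5])),
            "b": CptParams(np.full((2, 2), 0.5)),
        }
        data = {
            "a": np.full(20, bn.MISSING, dtype=np.int8),
            "b": np.full(20, bn.MISSING, dtype=np.int8),
        }
        result = em_train(spec, data, EmOptions(seed=0, max_iter=5), initial=init)
        np.testing.assert_allclose(result.params["a"].table, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(result.params["b"].table, np.full((2, 2), 0.5), atol=1e-12)

    def test_smoothed_scores_never_degenerate(self, small_dataset):
        # unseen evidence patterns must not produce the degenerate score 1
        spec = build_model("bn_svm")
        cols = bn.vectors_to_data(spec, small_dataset.vectors)
        result = em_train(spec, cols, EmOptions(seed=0, max_iter=30, tol=1e-4))
        rng = np.random.default_rng(0)
        roots = [n.name for n in spec.discrete_nodes if not n.parents]
        for _ in range(25):
            evidence = {name: int(rng.integers(2)) for name in roots}
            evidence[bn.SVM_LEAF] = float(rng.normal(0, 3))
            score = infer_stability(spec, result.params, evidence)
            assert 0.0 < score < 1.0


class TestThresholdClassification:
    @pytest.mark.parametrize(
        "score,thresholds,expected",
        [
            (0.1, (0.2, 0.75), "unstable"),
            (0.5, (0.2, 0.75), "non-assigned"),
            (0.9, (0.2, 0.75), "stable"),
            (0.71, (0.3, 0.7), "stable"),
            (0.2, (0.2, 0.75), "non-assigned"),  # boundaries are non-assigned
            (0.75, (0.2, 0.75), "non-assigned"),
        ],
    )
    def test_bucketing(self, score, thresholds, expected):
        assert classify_score(score, thresholds) == expected

    def test_partition_no_gaps_no_overlap(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        for thresholds in ((0.2, 0.75), (0.3, 0.7)):
            labels = [classify_score(s, thresholds) for s in scores]
            assert all(l in ("stable", "unstable", "non-assigned") for l in labels)
            lo, hi = thresholds
            for s, l in zip(scores, labels):
                assert l == ("unstable" if s < lo else "stable" if s > hi else "non-assigned")

    def test_predict_proteome(self, ground_truth, small_dataset):
        spec, params = ground_truth
        preds = predict_proteome(spec, params, small_dataset.vectors[:50])
        assert [p[0] for p in preds] == [v.protein_id for v in small_dataset.vectors[:50]]
        for _, score, label in preds:
            assert 0.0 < score < 1.0
            assert label == classify_score(score, (0.2, 0.75))
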