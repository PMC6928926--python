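import numpy as np
import pytest

from conftest import make_dag
from hetgo.embedding import EmbeddingMatrix
from hetgo.evaluation import EvalConfig, evaluate
from hetgo.hmc import (
    HierarchicalModel,
    ModelConfig,
    _descendant_lists,
    _init_model,
    featurize,
    forward,
    merge_scores,
    train,
)
from hetgo.ontology import AnnotationSet, LabelMatrix, build_labels, propagate


def toy_emb():
    ids = ["a", "b"]
    vecs = np.array([[1.0, 2.0], [3.0, 4.0]])
    return EmbeddingMatrix(ids, vecs, {"first": (0, 1), "second": (1, 2)})


# a 7-term DAG: root with two branches of three terms each
SEVEN = {
    "GO:0000001": [],
    "GO:0000002": ["GO:0000001"],
    "GO:0000003": ["GO:0000001"],
    "GO:0000004": ["GO:0000002"],
    "GO:0000005": ["GO:0000002"],
    "GO:0000006": ["GO:0000003"],
    "GO:0000007": ["GO:0000003"],
}


class TestFeaturize:
    def test_absent_entity_gets_zero_vector(self):
        X = featurize(["a", "ghost"], toy_emb())
        np.testing.assert_array_equal(X[1], [0.0, 0.0])

    def test_present_entity_gets_exact_row(self):
        X = featurize(["b"], toy_emb())
        np.testing.assert_array_equal(X[0], [3.0, 4.0])

    def test_mixed_batch_matches_per_entity_lookup(self):
        emb = toy_emb()
        ids = ["b", "zzz", "a", "b"]
        X = featurize(ids, emb)
        for i, e in enumerate(ids):
            expected = emb.vector(e) if e in emb else np.zeros(2)
            np.testing.assert_array_equal(X[i], expected)


class TestMaxMerge:
    def test_parent_takes_child_maximum(self):
        dag = make_dag({"GO:0000001": [], "GO:0000002": ["GO:0000001"],
                        "GO:0000003": ["GO:0000002"]})
        terms = ["GO:0000003", "GO:0000002"]  # child before parent
        desc = _descendant_lists(dag, terms)
        raw = np.array([[0.9, 0.2]])
        merged, _ = merge_scores(raw, desc)
        np.testing.assert_allclose(merged, [[0.9, 0.9]])

    def test_leaf_score_unchanged(self):
        dag = make_dag({"GO:0000001": [], "GO:0000002": ["GO:0000001"]})
        merged, _ = merge_scores(np.array([[0.35]]),
                                 _descendant_lists(dag, ["GO:0000002"]))
        assert merged[0, 0] == pytest.approx(0.35)

    def test_chain_matches_bottom_up_scan_oracle(self):
        chain = {f"GO:000000{i}": ([] if i == 1 else [f"GO:000000{i-1}"])
                 for i in range(1, 6)}
        dag = make_dag(chain)
        terms = [f"GO:000000{i}" for i in range(5, 0, -1)]  # leaf ... root
        raw_bottom_up = [0.1, 0.8, 0.3, 0.6, 0.2]  # leaf first
        raw = np.array([raw_bottom_up])
        merged, _ = merge_scores(raw, _descendant_lists(dag, terms))
        expected, running = [], 0.0
        for x in raw_bottom_up:
            running = max(running, x)
            expected.append(running)
        np.testing.assert_allclose(merged[0], expected)

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(4)
        dag = make_dag(SEVEN)
        terms = dag.reverse_topological(set(dag.terms) - {"GO:0000001"})
        desc = _descendant_lists(dag, terms)
        raw = rng.random((10, len(terms)))
        once, _ = merge_scores(raw, desc)
        twice, _ = merge_scores(once, desc)
        np.testing.assert_array_equal(once, twice)

    def test_untrained_model_is_consistent(self):
        dag = make_dag(SEVEN)
        terms = dag.reverse_topological(set(dag.terms) - {"GO:0000001"})
        cfg = ModelConfig(hidden_units=16, seed=1)
        model = _init_model(terms, 4, cfg, dag, np.random.default_rng(1))
        pred = forward(model, np.random.default_rng(2).normal(size=(6, 4)),
                       [f"e{i}" for i in range(6)])
        assert pred.merged
        assert pred.scores.min() >= 0 and pred.scores.max() <= 1
        col = {t: j for j, t in enumerate(terms)}
        for t in terms:
            for p in dag.parents[t]:
                if p in col:
                    assert (pred.scores[:, col[p]] >= pred.scores[:, col[t]] - 1e-12).all()


def cluster_problem(seed, n=200):
    """Two Gaussian feature clusters labeled onto the two branches of SEVEN."""
    rng = np.random.default_rng(seed)
    dag = make_dag(SEVEN)
    half = n // 2
    X = np.vstack([rng.normal(-1.5, 1.0, size=(half, 8)),
                   rng.normal(+1.5, 1.0, size=(n - half, 8))])
    ids = [f"e{i}" for i in range(n)]
    raw = {ids[i]: ({"GO:0000004", "GO:0000005"} if i < half
                    else {"GO:0000006", "GO:0000007"}) for i in range(n)}
    annots = propagate(dag, AnnotationSet(raw))
    terms = dag.reverse_topological(set(dag.terms) - {"GO:0000001"})
    labels = build_labels(annots, terms, entity_ids=ids)
    return dag, X, ids, annots, labels


class TestTraining:
    def test_recovers_separable_clusters(self):
        wins = 0
        for seed in range(5):
            dag, X, ids, annots, labels = cluster_problem(seed)
            rng = np.random.default_rng(seed + 100)
            split = rng.permutation(len(ids))
            tr, te = split[:160], split[160:]
            cfg = ModelConfig(hidden_units=32, max_epochs=30, patience=6, seed=seed)
            model = train(X[tr], LabelMatrix([ids[i] for i in tr], labels.term_ids,
                                             labels.values[tr]), dag, cfg)
            pred = forward(model, X[te], [ids[i] for i in te])
            truth = AnnotationSet({ids[i]: annots.annotations[ids[i]] for i in te},
                                  propagated=True)
            res = evaluate(pred, truth, dag, EvalConfig(namespace="BP"))
            wins += res.fmax >= 0.9
        assert wins >= 3

    def test_permuted_labels_fall_to_prior_level(self):
        dag, X, ids, annots, labels = cluster_problem(0)
        perm = np.random.default_rng(1).permutation(len(ids))
        shuffled = LabelMatrix(labels.entity_ids, labels.term_ids, labels.values[perm])
        cfg = ModelConfig(hidden_units=32, max_epochs=30, patience=6, seed=0)
        model = train(X, shuffled, dag, cfg)
        pred = forward(model, X, ids)
        res = evaluate(pred, AnnotationSet(annots.annotations, propagated=True), dag,
                       EvalConfig(namespace="BP"))
        # prior-based ceiling: guessing the majority structure of these labels
        # (each branch covers half the entities) cannot much exceed 2/3 F
        assert res.fmax < 0.8

    def test_zero_epochs_returns_initialization_with_valid_predictions(self):
        dag, X, ids, annots, labels = cluster_problem(3, n=20)
        cfg = ModelConfig(hidden_units=16, max_epochs=0, seed=7)
        model = train(X, labels, dag, cfg)
        ref = _init_model(labels.term_ids, X.shape[1], cfg, dag,
                          np.random.default_rng(7))
        for k in ref.weights:
            np.testing.assert_array_equal(model.weights[k], ref.weights[k])
        pred = forward(model, X, ids)
        assert pred.merged and pred.scores.min() >= 0 and pred.scores.max() <= 1

    def test_training_is_deterministic(self):
        dag, X, ids, annots, labels = cluster_problem(2, n=40)
        cfg = ModelConfig(hidden_units=16, max_epochs=5, seed=3)
        m1 = train(X, labels, dag, cfg)
        m2 = train(X, labels, dag, cfg)
        for k in m1.weights:
            np.testing.assert_array_equal(m1.weights[k], m2.weights[k])

    def test_empty_and_degenerate_inputs_rejected(self):
        dag, X, ids, annots, labels = cluster_problem(4, n=20)
        with pytest.raises(ValueError, match="two training entities"):
            train(X[:1], LabelMatrix(ids[:1], labels.term_ids, labels.values[:1]),
                  dag, ModelConfig())
        zeros = LabelMatrix(ids, labels.term_ids, np.zeros_like(labels.values))
        with pytest.raises(ValueError, match="no positive labels"):
            train(X, zeros, dag, ModelConfig())

    def test_per_term_head_option_trains_and_stays_consistent(self):
        dag, X, ids, annots, labels = cluster_problem(5, n=60)
        cfg = ModelConfig(hidden_units=16, max_epochs=5, seed=2, head_hidden=4)
        model = train(X, labels, dag, cfg)
        pred = forward(model, X, ids)
        col = {t: j for j, t in enumerate(pred.term_ids)}
        for t in pred.term_ids:
            for p in dag.parents[t]:
                if p in col:
                    assert (pred.scores[:, col[p]] >= pred.scores[:, col[t]] - 1e-12).all()


class TestPredict:
    def test_inference_is_deterministic(self):
        dag, X, ids, annots, labels = cluster_problem(6, n=30)
        model = train(X, labels, dag, ModelConfig(hidden_units=16, max_epochs=3, seed=1))
        a = forward(model, X, ids)
        b = forward(model, X, ids)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_zero_vector_entity_scores_are_valid_and_merged(self):
        dag, X, ids, annots, labels = cluster_problem(7, n=30)
        model = train(X, labels, dag, ModelConfig(hidden_units=16, max_epochs=3, seed=1))
        pred = forward(model, np.zeros((1, X.shape[1])), ["unseen"])
        assert pred.merged
        assert np.isfinite(pred.scores).all()

    def test_save_load_roundtrip(self, tmp_path):
        dag, X, ids, annots, labels = cluster_problem(8, n=30)
        model = train(X, labels, dag, ModelConfig(hidden_units=16, max_epochs=3, seed=2))
        path = tmp_path / "model.npz"
        model.save(path)
        back = HierarchicalModel.load(path, dag)
        np.testing.assert_array_equal(model.predict_scores(X), back.predict_scores(X))

    def test_dimension_mismatch_is_error(self):
        dag, X, ids, annots, labels = cluster_problem(9, n=30)
        model = train(X, labels, dag, ModelConfig(hidden_units=16, max_epochs=2, seed=1))
        with pytest.raises(ValueError, match="dim"):
            forward(model, np.zeros((2, X.shape[1] + 1)), ["x", "y"])
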