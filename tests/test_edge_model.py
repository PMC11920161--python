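"""Edge representations, cosine objective, and the linking-concept MLP."""

import numpy as np
import pytest

from lbdlink.edge_model import (
    EdgeReprConfig,
    ModelConfig,
    _cosine_loss_grad,
    combine,
    cosine_similarity,
    load_model,
    predict_b,
    save_model,
    train_model,
)
from lbdlink.graph_data import ConceptId, DiscoveryDataset, TripletRecord
from lbdlink.line_embed import EmbeddingTable
from lbdlink.rank_eval import rank_candidates


class TestCombine:
    def test_average_is_idempotent_on_equal_inputs(self, rng):
        v = rng.normal(size=6)
        assert np.allclose(combine(v, v, EdgeReprConfig("average", 1.0)), v)

    def test_hadamard_with_ones_is_identity(self, rng):
        a = rng.normal(size=6)
        assert np.allclose(combine(a, np.ones(6), EdgeReprConfig("hadamard", 1.0)), a)

    def test_concat_doubles_dimension(self, rng):
        a, c = rng.normal(size=100), rng.normal(size=100)
        out = combine(a, c, EdgeReprConfig("concat", 1.0))
        assert out.shape == (200,)
        assert np.allclose(out, np.concatenate([a, c]))

    def test_scale_applies_to_each_input_before_combining(self, rng):
        a, c = rng.normal(size=8), rng.normal(size=8)
        assert np.allclose(combine(a, c, EdgeReprConfig("hadamard", 10.0)), 100.0 * a * c)
        assert np.allclose(combine(a, c, EdgeReprConfig("average", 10.0)), 10.0 * (a + c) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine(np.ones(3), np.ones(4), EdgeReprConfig("average", 1.0))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            EdgeReprConfig("sum", 1.0)


class TestCosineSimilarity:
    def test_parallel_anti_parallel_orthogonal(self, rng):
        v = rng.normal(size=5)
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestCosineLoss:
    def test_loss_bounded_in_zero_two(self, rng):
        pred = rng.normal(size=(40, 8))
        target = rng.normal(size=(40, 8))
        value, _ = _cosine_loss_grad(pred, target, "one_minus_cos")
        assert 0.0 <= value <= 2.0

    def test_invariant_to_positive_target_rescaling(self, rng):
        pred = rng.normal(size=(10, 8))
        target = rng.normal(size=(10, 8))
        v1, g1 = _cosine_loss_grad(pred, target, "one_minus_cos")
        v2, g2 = _cosine_loss_grad(pred, 37.5 * target, "one_minus_cos")
        assert v1 == pytest.approx(v2)
        assert np.allclose(g1, g2)


def toy_problem(n=400, dim=16, seed=0):
    """Concepts whose gold B embedding is exactly the normalized average of
    its A and C embeddings — a map the network can represent exactly."""
    rng = np.random.default_rng(seed)
    concepts, vectors, train = [], {}, []
    for i in range(n):
        a = ConceptId("ta", str(i))
        c = ConceptId("tc", str(i))
        b = ConceptId("tb", str(i))
        va, vc = rng.normal(size=dim), rng.normal(size=dim)
        vb = (va + vc) / 2
        vb /= np.linalg.norm(vb)
        vectors.update({a: va, c: vc, b: vb})
        concepts += [a, b, c]
        train.append(TripletRecord(a, b, c, 0.5))
    table = EmbeddingTable.from_dict(vectors, "concatenated")
    gold = train[0]
    dataset = DiscoveryDataset(
        train=train,
        eval_records=[TripletRecord(gold.a, gold.b, gold.c, 1.0)],
        gold=gold)
    return dataset, table


TOY_CFG = ModelConfig(hidden_units=64, dropout=0.0, learning_rate=3e-3,
                      batch_size=32, epochs=50, seed=1)


class TestTrainModel:
    def test_learns_realizable_linear_toy_map(self):
        dataset, table = toy_problem()
        model = train_model(dataset, table, EdgeReprConfig("average", 1.0), TOY_CFG)
        assert model.history["loss"][-1] < 0.05

    def test_toy_gold_ranks_first_in_comprehensive_vocab(self):
        dataset, table = toy_problem()
        model = train_model(dataset, table, EdgeReprConfig("average", 1.0), TOY_CFG)
        pred = predict_b(model, dataset.gold.a, dataset.gold.c, table)
        result = rank_candidates(pred, dataset.comprehensive_vocab, table, dataset.gold.b)
        assert result.gold_rank == 1

    def test_identical_seed_identical_loss(self):
        dataset, table = toy_problem(n=100)
        cfg = ModelConfig(hidden_units=32, epochs=5, seed=9)
        m1 = train_model(dataset, table, EdgeReprConfig("concat", 10.0), cfg)
        m2 = train_model(dataset, table, EdgeReprConfig("concat", 10.0), cfg)
        assert m1.history["loss"] == m2.history["loss"]

    @pytest.mark.parametrize("seed", range(10))
    def test_final_loss_not_above_initial_loss(self, seed):
        dataset, table = toy_problem(n=150, seed=seed)
        cfg = ModelConfig(hidden_units=32, learning_rate=1e-3, epochs=30, seed=seed)
        model = train_model(dataset, table, EdgeReprConfig("average", 1.0), cfg)
        assert model.history["loss"][-1] <= model.history["loss"][0]

    def test_only_positive_triplets_used(self):
        dataset, table = toy_problem(n=50)
        negatives = [TripletRecord(r.a, r.b, r.c, 0.0) for r in dataset.train]
        with_negs = DiscoveryDataset(train=dataset.train + negatives,
                                     eval_records=dataset.eval_records, gold=dataset.gold)
        cfg = ModelConfig(hidden_units=16, epochs=2, seed=3)
        m1 = train_model(dataset, table, EdgeReprConfig("average", 1.0), cfg)
        m2 = train_model(with_negs, table, EdgeReprConfig("average", 1.0), cfg)
        assert m1.history["loss"] == m2.history["loss"]

    def test_missing_embedding_error_or_skip(self):
        dataset, table = toy_problem(n=20)
        stray = TripletRecord(ConceptId("zz", "1"), ConceptId("zz", "2"), ConceptId("zz", "3"), 0.9)
        broken = DiscoveryDataset(train=dataset.train + [stray],
                                  eval_records=dataset.eval_records, gold=dataset.gold)
        cfg = ModelConfig(hidden_units=16, epochs=1, seed=0)
        with pytest.raises(KeyError, match="zz:1"):
            train_model(broken, table, EdgeReprConfig("average", 1.0), cfg, missing="error")
        model = train_model(broken, table, EdgeReprConfig("average", 1.0), cfg, missing="skip")
        assert model.n_skipped == 1


@pytest.fixture(scope="module")
def toy_model():
    dataset, table = toy_problem(n=60)
    cfg = ModelConfig(hidden_units=16, epochs=3, seed=4)
    return dataset, table, {
        mode: train_model(dataset, table, EdgeReprConfig(mode, 10.0), cfg)
        for mode in ("average", "concat", "hadamard")
    }


class TestPredictB:
    def test_output_bounded_and_dimensioned(self, toy_model):
        dataset, table, models = toy_model
        for model in models.values():
            pred = predict_b(model, dataset.gold.a, dataset.gold.c, table)
            assert pred.shape == (table.dim,)
            assert np.all(np.abs(pred) <= 1.0)

    def test_symmetric_modes_ignore_argument_order(self, toy_model):
        dataset, table, models = toy_model
        a, c = dataset.gold.a, dataset.gold.c
        for mode in ("average", "hadamard"):
            assert np.array_equal(predict_b(models[mode], a, c, table),
                                  predict_b(models[mode], c, a, table))
        assert not np.allclose(predict_b(models["concat"], a, c, table),
                               predict_b(models["concat"], c, a, table))

    def test_pure_function(self, toy_model):
        dataset, table, models = toy_model
        p1 = predict_b(models["concat"], dataset.gold.a, dataset.gold.c, table)
        p2 = predict_b(models["concat"], dataset.gold.a, dataset.gold.c, table)
        assert np.array_equal(p1, p2)

    def test_unknown_concept_named_in_error(self, toy_model):
        dataset, table, models = toy_model
        with pytest.raises(KeyError, match="nope:1"):
            predict_b(models["concat"], ConceptId("nope", "1"), dataset.gold.c, table)


def test_checkpoint_round_trip(tmp_path):
    dataset, table = toy_problem(n=30)
    cfg = ModelConfig(hidden_units=16, epochs=2, seed=5)
    model = train_model(dataset, table, EdgeReprConfig("hadamard", 10.0), cfg)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    p1 = predict_b(model, dataset.gold.a, dataset.gold.c, table)
    p2 = predict_b(loaded, dataset.gold.a, dataset.gold.c, table)
    assert np.array_equal(p1, p2)
    assert loaded.model_cfg == model.model_cfg
    assert loaded.history["loss"] == model.history["loss"]
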