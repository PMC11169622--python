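"""Fold splitting, balancing, training behaviour, ensembles and ablation."""

import numpy as np
import pytest

from idrbind import evaluation, synthetic
from idrbind.features import assemble_features
from idrbind.models import (
    EarlyStopper,
    FoldSplit,
    ModelConfig,
    TrainedModel,
    ablate_input,
    consensus_combine,
    ensemble_average,
    make_folds,
    predict_scores,
    train_model,
    undersample,
)


class TestMakeFolds:
    def test_ten_proteins_five_folds_of_two(self):
        split = make_folds([f"P{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(split.fold_ids(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_same_seed_identical(self):
        ids = [f"P{i}" for i in range(23)]
        assert make_folds(ids, seed=7) == make_folds(ids, seed=7)
        assert make_folds(ids, seed=7) != make_folds(ids, seed=8)

    def test_sizes_differ_by_at_most_one(self):
        split = make_folds([f"P{i}" for i in range(11)], k=5, seed=1)
        sizes = sorted(len(split.fold_ids(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_partition_property(self):
        ids = [f"P{i}" for i in range(17)]
        split = make_folds(ids, k=5, seed=2)
        collected = sorted(sum((split.fold_ids(f) for f in range(5)), []))
        assert collected == sorted(ids)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], k=1)


class TestUndersample:
    def _masks(self, n_bind, n_nbdis, n_ord):
        binding = np.concatenate([np.ones(n_bind), np.zeros(n_nbdis + n_ord)])
        disorder = np.concatenate(
            [np.ones(n_bind + n_nbdis), np.zeros(n_ord)]
        )
        return binding.astype(bool), disorder.astype(bool)

    def test_equal_group_counts(self):
        binding, disorder = self._masks(100, 300, 600)
        idx = undersample(binding, disorder, seed=0)
        assert binding[idx].sum() == 100
        assert (~binding[idx] & disorder[idx]).sum() == 100
        assert (~binding[idx] & ~disorder[idx]).sum() == 100

    def test_small_group_kept_whole(self):
        binding, disorder = self._masks(100, 50, 600)
        idx = undersample(binding, disorder, seed=0)
        assert (~binding[idx] & disorder[idx]).sum() == 50
        assert (~binding[idx] & ~disorder[idx]).sum() == 100

    def test_seeded_and_deterministic(self):
        binding, disorder = self._masks(30, 90, 90)
        a = undersample(binding, disorder, seed=5)
        b = undersample(binding, disorder, seed=5)
        assert np.array_equal(a, b)

    def test_no_binding_rejected(self):
        binding, disorder = self._masks(0, 10, 10)
        with pytest.raises(ValueError):
            undersample(binding, disorder)


class TestEarlyStopper:
    def test_monotone_worsening_stops_at_patience_plus_one(self):
        stopper = EarlyStopper(patience=5)
        stopped_at = None
        for epoch, loss in enumerate([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6], 1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 6
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        for epoch, loss in enumerate([1.0, 1.1, 0.9, 1.0, 1.1], 1):
            stop = stopper.update(epoch, loss)
        assert stop
        assert stopper.best_epoch == 3


def _synthetic_tables(effect_size, n_proteins=30, seed=21, m=12):
    config = synthetic.SyntheticConfig(
        n_proteins=n_proteins, length_median=120, length_sigma=0.3,
        min_length=60, max_length=300, m=m, k_informative=4,
        effect_size=effect_size, seed=seed,
    )
    records = synthetic.generate_proteins(config)
    embeddings = synthetic.generate_embeddings(records, config)
    features = {r.id: assemble_features(embeddings[r.id], r.disorder_mask)
                for r in records}
    labels = {r.id: r.binding_mask.astype(float) for r in records}
    disorder = {r.id: r.disorder_mask for r in records}
    return records, features, labels, disorder, m + 1


class TestTrainModel:
    def test_learns_planted_signal(self):
        records, features, labels, disorder, dim = _synthetic_tables(3.0)
        split = make_folds([r.id for r in records], k=5, seed=0)
        config = ModelConfig(input_dim=dim, hidden_units=16, max_epochs=40,
                             seed=0)
        model = train_model(features, labels, disorder, config, split,
                            val_fold=0)
        # validation loss improved over the first epoch
        assert model.history[-1][2] <= model.history[0][2]
        val_ids = split.fold_ids(0)
        y = np.concatenate([labels[i] for i in val_ids])
        d = np.concatenate([disorder[i] for i in val_ids]).astype(bool)
        scores = np.concatenate(
            [predict_scores(model, features[i]) for i in val_ids]
        )
        preds = evaluation.binarize(scores, model.cutoff)
        counts = evaluation.confusion_counts(y > 0, preds, d)
        assert evaluation.metric(counts, "mcc") > 0.8

    def test_null_signal_gives_chance_level(self):
        records, features, labels, disorder, dim = _synthetic_tables(0.0)
        split = make_folds([r.id for r in records], k=5, seed=0)
        config = ModelConfig(input_dim=dim, hidden_units=16, max_epochs=30,
                             seed=0)
        model = train_model(features, labels, disorder, config, split,
                            val_fold=1)
        # the disorder channel still lets the model rule out ordered
        # residues, so the loss improves; but restricted to disordered
        # residues the predictions must sit at chance level
        val_ids = split.fold_ids(1)
        y = np.concatenate([labels[i] for i in val_ids])
        d = np.concatenate([disorder[i] for i in val_ids]).astype(bool)
        scores = np.concatenate(
            [predict_scores(model, features[i]) for i in val_ids]
        )
        preds = evaluation.binarize(scores, model.cutoff)
        est = evaluation.bootstrap_metrics(y > 0, preds, d, seed=0)["mcc"]
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_bit_reproducible(self):
        records, features, labels, disorder, dim = _synthetic_tables(
            2.0, n_proteins=12, seed=5
        )
        split = make_folds([r.id for r in records], k=3, seed=0)
        config = ModelConfig(input_dim=dim, hidden_units=8, max_epochs=5,
                             seed=3)
        a = train_model(features, labels, disorder, config, split, val_fold=0)
        b = train_model(features, labels, disorder, config, split, val_fold=0)
        assert all(np.array_equal(a.weights[k], b.weights[k]) for k in a.weights)
        assert a.history == b.history
        assert a.cutoff == b.cutoff

    def test_checkpoint_roundtrip(self, tmp_path):
        records, features, labels, disorder, dim = _synthetic_tables(
            2.0, n_proteins=12, seed=6
        )
        split = make_folds([r.id for r in records], k=3, seed=0)
        config = ModelConfig(input_dim=dim, hidden_units=8, max_epochs=3,
                             seed=1)
        model = train_model(features, labels, disorder, config, split,
                            val_fold=0)
        path = tmp_path / "fold0.npz"
        model.save(path)
        back = TrainedModel.load(path)
        assert back.config == model.config
        assert back.cutoff == model.cutoff
        some = records[0].id
        assert np.array_equal(
            predict_scores(back, features[some]),
            predict_scores(model, features[some]),
        )


class TestCnnVariant:
    def test_trains_and_learns_planted_signal(self):
        records, features, labels, disorder, dim = _synthetic_tables(
            3.0, n_proteins=15, seed=13, m=8
        )
        split = make_folds([r.id for r in records], k=3, seed=0)
        config = ModelConfig(
            input_dim=dim, architecture="cnn", conv_channels=(8, 4),
            kernel_size=5, max_epochs=15, learning_rate=0.005, seed=0,
        )
        model = train_model(features, labels, disorder, config, split,
                            val_fold=0)
        assert model.config.architecture == "cnn"
        val_ids = split.fold_ids(0)
        y = np.concatenate([labels[i] for i in val_ids])
        d = np.concatenate([disorder[i] for i in val_ids]).astype(bool)
        scores = np.concatenate(
            [predict_scores(model, features[i]) for i in val_ids]
        )
        preds = evaluation.binarize(scores, model.cutoff)
        counts = evaluation.confusion_counts(y > 0, preds, d)
        assert evaluation.metric(counts, "mcc") > 0.3


class TestInference:
    def test_scores_invariant_to_protein_order(self):
        records, features, labels, disorder, dim = _synthetic_tables(
            2.0, n_proteins=12, seed=7
        )
        split = make_folds([r.id for r in records], k=3, seed=0)
        config = ModelConfig(input_dim=dim, hidden_units=8, max_epochs=3,
                             seed=0)
        model = train_model(features, labels, disorder, config, split,
                            val_fold=0)
        ids = [r.id for r in records]
        fwd = {i: predict_scores(model, features[i]) for i in ids}
        rev = {i: predict_scores(model, features[i]) for i in reversed(ids)}
        assert all(np.array_equal(fwd[i], rev[i]) for i in ids)


class TestEnsembleAndConsensus:
    def _const_model(self, value, dim=3):
        cfg = ModelConfig(input_dim=dim, hidden_units=1)
        weights = {
            "W1": np.zeros((dim, 1)),
            "b1": np.zeros(1),
            "W2": np.zeros((1, 1)),
            # logit chosen so sigmoid(b2) == value
            "b2": np.array([np.log(value / (1 - value))]),
        }
        return TrainedModel(config=cfg, weights=weights, cutoff=0.5,
                            fold_id=0, history=[])

    def test_mean_of_constant_models(self):
        models = [self._const_model(0.2), self._const_model(0.6)]
        out = ensemble_average(models, np.ones((4, 3)))
        assert np.allclose(out, 0.4)

    def test_single_model_identity(self):
        m = self._const_model(0.3)
        feat = np.ones((5, 3))
        assert np.allclose(ensemble_average([m], feat),
                           predict_scores(m, feat))

    def test_five_models_equal_independent_mean(self):
        values = [0.1, 0.3, 0.5, 0.7, 0.9]
        models = [self._const_model(v) for v in values]
        out = ensemble_average(models, np.ones((2, 3)))
        assert np.allclose(out, np.mean(values))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([], np.ones((2, 3)))

    def test_consensus_identical_inputs(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        combined, cutoff = consensus_combine(scores, scores, labels)
        assert np.allclose(combined, scores)
        assert cutoff == evaluation.select_cutoff(labels, scores)

    def test_consensus_of_complementary_predictors(self):
        """Two predictors each perfect on half the residues: the consensus
        balanced accuracy is at least each individual's."""
        labels = np.array([1, 1, 0, 0, 1, 0])
        a = np.array([0.9, 0.9, 0.1, 0.1, 0.5, 0.5])  # perfect on first 4
        b = np.array([0.5, 0.5, 0.5, 0.5, 0.9, 0.1])  # perfect on last 2
        combined, cutoff = consensus_combine(a, b, labels)

        def ba(scores, t):
            preds = evaluation.binarize(scores, t)
            c = evaluation.confusion_counts(labels, preds, np.ones(6))
            return evaluation.metric(c, "balanced_accuracy")

        best_a = max(ba(a, t) for t in (0.3, 0.5, 0.7))
        best_b = max(ba(b, t) for t in (0.3, 0.5, 0.7))
        assert ba(combined, cutoff) >= max(best_a, best_b)

    def test_constant_scores_stay_constant(self):
        labels = np.array([0, 1, 0, 1])
        combined, _ = consensus_combine(
            np.full(4, 0.4), np.full(4, 0.6), labels
        )
        assert np.allclose(combined, 0.5)


class TestAblation:
    def test_ignored_column_has_zero_importance(self):
        dim = 4
        cfg = ModelConfig(input_dim=dim, hidden_units=2)
        rng = np.random.default_rng(0)
        weights = {
            "W1": rng.standard_normal((dim, 2)),
            "b1": np.zeros(2),
            "W2": rng.standard_normal((2, 1)),
            "b2": np.zeros(1),
        }
        weights["W1"][2, :] = 0.0  # model ignores input dim 2
        model = TrainedModel(config=cfg, weights=weights, cutoff=0.5,
                             fold_id=0, history=[])
        feats = rng.standard_normal((50, dim))
        labels = rng.integers(0, 2, 50)
        disorder = np.ones(50)
        assert ablate_input(model, feats, labels, disorder, 2) == 0.0

    def test_informative_dimension_has_positive_importance(self):
        records, features, labels, disorder, dim = _synthetic_tables(
            3.0, n_proteins=16, seed=9, m=6
        )
        split = make_folds([r.id for r in records], k=4, seed=0)
        config = ModelConfig(input_dim=dim, hidden_units=8, max_epochs=20,
                             seed=0)
        model = train_model(features, labels, disorder, config, split,
                            val_fold=0)
        val_ids = split.fold_ids(0)
        feats = np.concatenate([features[i] for i in val_ids])
        y = np.concatenate([labels[i] for i in val_ids])
        d = np.concatenate([disorder[i] for i in val_ids])
        importances = [
            ablate_input(model, feats, y, d, k) for k in range(4)
        ]
        assert max(importances) > 0.0

    def test_constant_model_all_zero_importance(self):
        cfg = ModelConfig(input_dim=3, hidden_units=1)
        weights = {
            "W1": np.zeros((3, 1)), "b1": np.zeros(1),
            "W2": np.zeros((1, 1)), "b2": np.array([2.0]),
        }
        model = TrainedModel(config=cfg, weights=weights, cutoff=0.5,
                             fold_id=0, history=[])
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((30, 3))
        labels = rng.integers(0, 2, 30)
        disorder = np.ones(30)
        # constant score 0.88 > cutoff: everything predicted binding, MCC
        # undefined in both conditions -> importance 0 for every dim
        assert all(
            ablate_input(model, feats, labels, disorder, k) == 0.0
            for k in range(3)
        )
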