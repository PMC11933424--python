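import itertools
import math
import random

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from pktables.classifier import (
    TABLE1_GRID,
    Hyperparameters,
    TableClassifier,
    compute_class_weights,
    fit_table_classifier,
    grid_candidates,
    predict,
    predict_many,
    prediction_from_probabilities,
    train,
    tune,
)
from pktables.evaluation import score, stratified_split
from pktables.fixtures import GeneratorConfig, generate_corpus
from pktables.labels import CLASS_ORDER, Label


class TestComputeClassWeights:
    def test_balanced(self):
        weights = compute_class_weights(
            {Label.PK: 10, Label.DEMOGRAPHICS: 10, Label.OTHER: 10}
        )
        assert all(w == 1.0 for w in weights.values())

    def test_published_training_counts(self):
        # oracle: N / (K * n_c) with N = 1584, K = 3
        counts = {Label.PK: 532, Label.DEMOGRAPHICS: 233, Label.OTHER: 819}
        weights = compute_class_weights(counts)
        assert weights[Label.PK] == pytest.approx(1584 / (3 * 532))
        assert weights[Label.DEMOGRAPHICS] == pytest.approx(1584 / (3 * 233))
        assert weights[Label.OTHER] == pytest.approx(1584 / (3 * 819))
        assert weights[Label.PK] == pytest.approx(0.9925, abs=1e-4)
        assert weights[Label.DEMOGRAPHICS] == pytest.approx(2.2661, abs=1e-4)
        assert weights[Label.OTHER] == pytest.approx(0.6447, abs=1e-4)

    def test_extreme_imbalance(self):
        weights = compute_class_weights(
            {Label.PK: 1, Label.DEMOGRAPHICS: 1, Label.OTHER: 998}
        )
        assert weights[Label.OTHER] == pytest.approx(0.3340, abs=1e-4)
        assert weights[Label.PK] == pytest.approx(1000 / 3)

    def test_missing_class_named(self):
        with pytest.raises(ValueError, match="DEMOGRAPHICS"):
            compute_class_weights({Label.PK: 5, Label.OTHER: 5})

    def test_weighted_mass_conserved(self):
        rng = random.Random(2)
        for _ in range(200):
            counts = {label: rng.randint(1, 5000) for label in CLASS_ORDER}
            weights = compute_class_weights(counts)
            total = sum(counts.values())
            assert math.isclose(
                sum(counts[l] * weights[l] for l in CLASS_ORDER), total, rel_tol=1e-12
            )


class TestGridCandidates:
    def test_published_grid_size(self):
        assert len(grid_candidates()) == 3600

    def test_first_candidate_is_lower_bounds(self):
        first = grid_candidates()[0]
        assert (
            first.max_depth,
            first.min_child_weight,
            first.gamma,
            first.subsample,
            first.colsample_bytree,
        ) == (2, 1, 0.1, 0.5, 0.3)

    def test_min_child_weight_axis(self):
        values = sorted({hp.min_child_weight for hp in grid_candidates()})
        assert values == [1, 3, 5]

    def test_degenerate_grid(self):
        spec = {name: (lo, lo, step) for name, (lo, _, step) in TABLE1_GRID.items()}
        assert len(grid_candidates(spec)) == 1

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            grid_candidates({"max_depth": (2, 10, 0)})

    def test_count_matches_product_oracle(self):
        rng = random.Random(9)
        for _ in range(20):
            spec = {
                "max_depth": (2, 2 + 2 * rng.randint(0, 4), 2),
                "gamma": (0.1, 0.1 + 0.1 * rng.randint(0, 4), 0.1),
                "subsample": (0.5, 0.5 + 0.1 * rng.randint(0, 5), 0.1),
            }
            # independent oracle: count each axis by explicit enumeration
            expected = 1
            for lo, hi, step in spec.values():
                n, value = 0, lo
                while value <= hi + 1e-9:
                    n += 1
                    value += step
                expected *= n
            assert len(grid_candidates(spec)) == expected

    def test_row_major_order(self):
        spec = {"max_depth": (2, 4, 2), "min_child_weight": (1, 3, 2)}
        pairs = [(hp.max_depth, hp.min_child_weight) for hp in grid_candidates(spec)]
        assert pairs == list(itertools.product([2, 4], [1, 3]))


def _separable_data(n_per_class=100, seed=0):
    """Linearly separable 3-class BoW-like data: one indicator column per
    class plus noise counts."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for class_idx, label in enumerate(CLASS_ORDER):
        X = rng.integers(0, 3, size=(n_per_class, 8)).astype(float)
        X[:, class_idx] = 5.0
        X[:, (class_idx + 1) % 3] = 0.0
        X[:, (class_idx + 2) % 3] = 0.0
        blocks.append(X)
        labels.extend([label] * n_per_class)
    return np.vstack(blocks), labels


class TestTrain:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = _separable_data(100, seed=1)
        model = train(X, y, seed=1)
        predictions = predict_many(model, X)
        accuracy = np.mean([p.label == t for p, t in zip(predictions, y)])
        assert accuracy == 1.0
        assert model.rounds_used < 1000

    def test_early_stopping_bound(self):
        # no-signal labels: eval AUC plateaus early, so the stopping rule
        # rounds_used <= best_iteration + 1 + patience must bind
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 6))
        y = [CLASS_ORDER[i % 3] for i in range(120)]
        hp = Hyperparameters(max_rounds=200)
        model = train(X, y, hp=hp, seed=3)
        assert model.rounds_used <= model.best_iteration + 1 + hp.early_stopping_rounds
        assert model.rounds_used <= hp.max_rounds

    def test_deterministic_given_seed(self):
        X, y = _separable_data(40, seed=4)
        probe = np.random.default_rng(0).integers(0, 5, size=(10, 8)).astype(float)
        runs = []
        for _ in range(2):
            model = train(X, y, hp=Hyperparameters(subsample=0.7), seed=4)
            runs.append(np.stack([predict(model, row).probabilities for row in probe]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_length_mismatch_error(self):
        X, y = _separable_data(10)
        with pytest.raises(ValueError, match="mismatch"):
            train(X, y[:-1])

    def test_single_class_rejected(self):
        X = np.zeros((20, 3))
        with pytest.raises(ValueError, match="2 classes"):
            train(X, [Label.PK] * 20)

    def test_sample_weights_length_checked(self):
        X, y = _separable_data(10)
        with pytest.raises(ValueError, match="sample_weights"):
            train(X, y, sample_weights=[1.0])


class TestPredict:
    def test_probabilities_sum_to_one(self):
        X, y = _separable_data(30, seed=5)
        model = train(X, y, seed=5)
        for row in X[:20]:
            prediction = predict(model, row)
            assert prediction.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert prediction.confidence == prediction.probabilities.max()

    def test_argmax_label_and_confidence(self):
        prediction = prediction_from_probabilities([0.2, 0.2, 0.6])
        assert prediction.label is Label.OTHER
        assert prediction.confidence == pytest.approx(0.6)

    def test_exact_tie_breaks_to_class_order(self):
        assert prediction_from_probabilities([0.4, 0.2, 0.4]).label is Label.PK
        assert prediction_from_probabilities([0.3, 0.35, 0.35]).label is Label.DEMOGRAPHICS

    def test_dimension_mismatch_error(self):
        X, y = _separable_data(30, seed=6)
        model = train(X, y, seed=6)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(5))


@pytest.fixture(scope="module")
def small_problem():
    return _separable_data(30, seed=7)


class TestTune:
    def test_grid_of_one_returns_that_candidate(self, small_problem):
        X, y = small_problem
        candidate = Hyperparameters(max_depth=3)
        best, report = tune(X, y, grid=[candidate], folds=3, seed=7)
        assert best == candidate
        assert len(report) == 1

    def test_reported_mean_matches_fold_scores(self, small_problem):
        X, y = small_problem
        grid = [Hyperparameters(max_depth=2), Hyperparameters(max_depth=4)]
        _, report = tune(X, y, grid=grid, folds=3, seed=7)
        for entry in report:
            assert entry["mean_macro_f1"] == pytest.approx(
                float(np.mean(entry["fold_macro_f1"]))
            )
            assert entry["sd_macro_f1"] == pytest.approx(
                float(np.std(entry["fold_macro_f1"], ddof=1))
            )

    def test_folds_partition_the_data(self, small_problem):
        # tune uses StratifiedKFold(shuffle=True, random_state=seed); verify
        # the partition property on the identically-constructed splitter
        X, y = small_problem
        encoded = np.array([list(CLASS_ORDER).index(l) for l in y])
        splitter = StratifiedKFold(n_splits=3, shuffle=True, random_state=7)
        seen = []
        for _, test_idx in splitter.split(X, encoded):
            seen.extend(test_idx.tolist())
        assert sorted(seen) == list(range(len(y)))

    def test_class_smaller_than_folds_rejected(self):
        X, y = _separable_data(4, seed=8)
        with pytest.raises(ValueError, match="folds"):
            tune(X, y, grid=[Hyperparameters()], folds=10, seed=8)


class TestHyperparameters:
    def test_defaults_match_stated_caps(self):
        hp = Hyperparameters()
        assert hp.learning_rate == 0.1
        assert hp.max_rounds == 1000
        assert hp.early_stopping_rounds == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"subsample": 0.0},
            {"subsample": 1.5},
            {"colsample_bytree": 0.0},
            {"gamma": -0.1},
            {"max_depth": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparameters(**kwargs)


class TestPipelineBundle:
    def test_save_load_round_trip(self, model600, split600, tmp_path):
        _, _, test_corpus = split600
        path = tmp_path / "model.bin"
        model600.save(path)
        loaded = TableClassifier.load(path)
        probe = test_corpus.records[:20]
        original = [p.label for p in model600.predict_tables(probe)]
        restored = [p.label for p in loaded.predict_tables(probe)]
        assert original == restored
        assert loaded.field_kind == model600.field_kind

    def test_heldout_macro_f1_on_separable_corpus(self):
        corpus = generate_corpus(GeneratorConfig(total=300, noise_rate=0.0, seed=11))
        train_c, _, test_c = stratified_split(corpus, seed=11)
        pipeline = fit_table_classifier(train_c, seed=11)
        predictions = pipeline.predict_tables(test_c.records)
        report = score(test_c.labels(), [p.label for p in predictions])
        assert report.macro_f1 >= 0.95

    def test_unlabeled_corpus_rejected(self, corpus600):
        from pktables.table_io import Corpus, ExtractedTable

        unlabeled = Corpus(records=[ExtractedTable(table_id="x")])
        with pytest.raises(ValueError, match="labeled"):
            fit_table_classifier(unlabeled)
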