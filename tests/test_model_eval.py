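import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosppi.dataset_io import PairFeatureTable
from mosppi.model_eval import (
    BASELINE_ENCODER_PRESET,
    MLPPairClassifier,
    ModelConfig,
    classic_classifier,
    evaluate,
    format_mean_std,
    holdout_repeat,
    predict,
    train_mlp,
)


def rank_auc_oracle(labels, probs):
    """Exhaustive pairwise rank statistic: P(score_pos > score_neg) + ties/2."""
    pos = [p for y, p in zip(labels, probs) if y == 1]
    neg = [p for y, p in zip(labels, probs) if y == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def make_blobs_table(n_per_class=100, dim=58, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(loc=sep / 2, size=(n_per_class, dim))
    Xn = rng.normal(loc=-sep / 2, size=(n_per_class, dim))
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    ids = [(f"a{i}", f"b{i}") for i in range(2 * n_per_class)]
    return PairFeatureTable(pair_ids=ids, X=X, y=y, encoder_name="MOS")


class TestEvaluate:
    def test_perfect_ranking(self):
        m = evaluate([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert m.accuracy == 1.0 and m.recall == 1.0 and m.auc == 1.0

    def test_tie_convention(self):
        assert evaluate([1, 0], [0.5, 0.5]).auc == 0.5

    def test_uninformative_scores(self):
        m = evaluate([1, 1, 0, 0], [0.6, 0.4, 0.6, 0.4])
        assert m.auc == 0.5
        assert m.accuracy == 0.5

    def test_confusion_counts(self):
        m = evaluate([1, 1, 0, 0, 0], [0.9, 0.2, 0.8, 0.3, 0.1])
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 2)
        assert m.accuracy == pytest.approx(3 / 5)
        assert m.recall == pytest.approx(1 / 2)

    def test_loss_on_coin_flip_probs_is_ln2(self):
        m = evaluate([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert m.loss == pytest.approx(np.log(2), abs=1e-12)

    def test_loss_on_perfect_probs_is_tiny(self):
        m = evaluate([1, 0], [1.0, 0.0])
        assert 0 <= m.loss <= 1e-11

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_single_class_auc_nan_with_warning(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            m = evaluate([1, 1], [0.9, 0.8])
        assert np.isnan(m.auc)
        assert m.accuracy == 1.0  # other metrics still computed

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.floats(0, 1)),
            min_size=2, max_size=200,
        ).filter(lambda rows: len({y for y, _ in rows}) == 2)
    )
    def test_auc_matches_rank_oracle(self, rows):
        labels = [y for y, _ in rows]
        probs = [p for _, p in rows]
        m = evaluate(labels, probs)
        assert m.auc == pytest.approx(rank_auc_oracle(labels, probs), abs=1e-10)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.floats(0.01, 0.99)),
            min_size=2, max_size=100,
        ).filter(
            lambda rows: len({y for y, _ in rows}) == 2
            # probabilities exactly at the 0.5 threshold are classified
            # asymmetrically under label swap; exclude the boundary
            and all(abs(p - 0.5) > 1e-9 for _, p in rows)
        )
    )
    def test_label_swap_symmetry_and_row_order_invariance(self, rows):
        labels = np.array([y for y, _ in rows])
        probs = np.array([p for _, p in rows])
        m = evaluate(labels, probs)
        swapped = evaluate(1 - labels, 1 - probs)
        assert swapped.accuracy == pytest.approx(m.accuracy)
        assert swapped.auc == pytest.approx(m.auc, abs=1e-10)
        perm = np.random.default_rng(0).permutation(len(labels))
        shuffled = evaluate(labels[perm], probs[perm])
        assert shuffled.accuracy == m.accuracy
        assert shuffled.auc == pytest.approx(m.auc, abs=1e-12)
        assert shuffled.loss == pytest.approx(m.loss, abs=1e-12)


class TestModelConfig:
    def test_defaults_are_selected_configuration(self):
        cfg = ModelConfig()
        assert (cfg.learning_rate, cfg.width, cfg.depth) == (0.01, 512, 3)
        assert (cfg.batch_size, cfg.dropout, cfg.activation) == (128, 0.0, "relu")

    def test_baseline_preset(self):
        assert BASELINE_ENCODER_PRESET.learning_rate == 0.001
        assert BASELINE_ENCODER_PRESET.width == 256
        assert BASELINE_ENCODER_PRESET.depth == 3

    @pytest.mark.parametrize(
        "kwargs", [{"width": 0}, {"dropout": 1.0}, {"learning_rate": 0.0}]
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


@pytest.fixture(scope="module")
def separable_fit():
    table = make_blobs_table()
    config = ModelConfig(width=32, depth=2, n_steps=300, seed=0)
    return table, train_mlp(table, config)


class TestMLPPairClassifier:

    def test_separable_blobs_reach_high_train_accuracy(self, separable_fit):
        table, model = separable_fit
        m = evaluate(table.y, predict(model, table))
        assert m.accuracy >= 0.99
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_probabilities_bounded(self, separable_fit):
        table, model = separable_fit
        p = predict(model, table)
        assert (p >= 0).all() and (p <= 1).all()

    def test_duplicated_rows_get_identical_probabilities(self, separable_fit):
        table, model = separable_fit
        X2 = np.vstack([table.X[:1], table.X[:1]])
        p = model.predict_proba(X2)[:, 1]
        assert p[0] == p[1]

    def test_empty_table_predicts_empty(self, separable_fit):
        table, model = separable_fit
        empty = table.subset(np.array([], dtype=int))
        assert predict(model, empty).shape == (0,)

    def test_dimension_mismatch_raises(self, separable_fit):
        _, model = separable_fit
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, 10)))

    def test_deterministic_given_seed(self):
        table = make_blobs_table(n_per_class=40, sep=2.0)
        cfg = ModelConfig(width=16, depth=1, n_steps=100, seed=5)
        p1 = predict(train_mlp(table, cfg), table)
        p2 = predict(train_mlp(table, cfg), table)
        np.testing.assert_array_equal(p1, p2)

    def test_dropout_unsupported(self):
        table = make_blobs_table(n_per_class=10)
        clf = MLPPairClassifier(width=8, depth=1, n_steps=10, dropout=0.5)
        with pytest.raises(ValueError, match="dropout"):
            clf.fit(table.X, table.y)

    def test_steps_to_epochs_conversion(self):
        table = make_blobs_table(n_per_class=64)  # 128 rows = 1 batch
        clf = MLPPairClassifier(width=8, depth=1, n_steps=10, batch_size=128)
        clf.fit(table.X, table.y)
        assert clf.n_epochs_ == 10


@pytest.fixture(scope="module")
def table():
    return make_blobs_table(n_per_class=80, sep=3.0)


class TestHoldoutRepeat:

    def test_single_repeat_reports_zero_std(self, table):
        cfg = ModelConfig(width=16, depth=1, n_steps=100)
        summary, runs = holdout_repeat(table, cfg, n_repeats=1, base_seed=0)
        assert len(runs) == 1
        assert all(std == 0.0 for _, std in summary.values())

    def test_mean_std_over_repeats(self, table):
        cfg = ModelConfig(width=16, depth=1, n_steps=100)
        summary, runs = holdout_repeat(table, cfg, n_repeats=3, base_seed=4)
        assert len(runs) == 3
        accs = [m.accuracy for m in runs]
        mean, std = summary["accuracy"]
        assert mean == pytest.approx(np.mean(accs))
        assert std == pytest.approx(np.std(accs, ddof=1))

    def test_format_mean_std(self):
        assert format_mean_std(0.94335, 0.00782) == "0.9434±0.0078"


class TestClassicClassifiers:
    @pytest.mark.parametrize(
        "algorithm", ["decision_tree", "k_neighbors", "random_forest"]
    )
    def test_separable_blobs(self, algorithm):
        table = make_blobs_table(n_per_class=60)
        model = classic_classifier(table, algorithm, seed=0)
        m = evaluate(table.y, model.predict_proba(table.X)[:, 1])
        assert m.accuracy >= 0.99

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            classic_classifier(make_blobs_table(10), "svm", 0)
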