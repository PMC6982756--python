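import numpy as np
import pandas as pd
import pytest

from wearload import (
    FeatureSetSpec,
    evaluate_model,
    export_model,
    load_model_description,
    rank_importance,
    select_pruned_spec,
    split_dataset,
    sweep_size,
    train_model,
)
from wearload.features import LABEL_COLUMN

from conftest import make_corpus_vectors


def _cluster_frame(seed=0, n_per_class=40, sep=10.0, n_features=4):
    """Five well-separated Gaussian clusters, one per activity."""
    rng = np.random.default_rng(seed)
    classes = ["crunches", "jogging", "push-ups", "resting", "squatting"]
    rows, labels = [], []
    for i, cls in enumerate(classes):
        center = np.zeros(n_features)
        center[i % n_features] = i * sep
        rows.append(rng.normal(center, 1.0, size=(n_per_class, n_features)))
        labels += [cls] * n_per_class
    df = pd.DataFrame(np.vstack(rows), columns=[f"f{j}" for j in range(n_features)])
    df[LABEL_COLUMN] = labels
    return df


def _nearest_centroid_accuracy(train, valid):
    feats = [c for c in train.columns if c != LABEL_COLUMN]
    centroids = train.groupby(LABEL_COLUMN)[feats].mean()
    X = valid[feats].to_numpy()
    d = ((X[:, None, :] - centroids.to_numpy()[None, :, :]) ** 2).sum(-1)
    pred = centroids.index.to_numpy()[d.argmin(1)]
    return float((pred == valid[LABEL_COLUMN].to_numpy()).mean())


class FixedPredictions:
    """Evaluation stub returning a preset label sequence."""

    def __init__(self, predictions, class_list):
        self.predictions = np.asarray(predictions, dtype=object)
        self.class_list = tuple(class_list)

    def predict(self, vectors):
        return self.predictions[: len(vectors)]


class TestSplit:
    def test_counts_disjoint_exhaustive(self):
        df = _cluster_frame(n_per_class=20)  # 100 vectors
        train, valid = split_dataset(df, 0.7, seed=0)
        assert len(train) == 70 and len(valid) == 30
        assert set(train.index).isdisjoint(valid.index)
        assert set(train.index) | set(valid.index) == set(df.index)

    def test_same_seed_same_partition(self):
        df = _cluster_frame()
        t1, v1 = split_dataset(df, seed=11)
        t2, v2 = split_dataset(df, seed=11)
        assert list(t1.index) == list(t2.index)
        assert list(v1.index) == list(v2.index)

    def test_stratification_within_one_vector(self):
        df = _cluster_frame(n_per_class=30)
        train, _ = split_dataset(df, 0.7, seed=2)
        for cls, n in train[LABEL_COLUMN].value_counts().items():
            assert abs(n - 0.7 * 30) <= 1

    def test_thin_class_rejected(self):
        df = _cluster_frame(n_per_class=5)
        df = df.drop(df[df[LABEL_COLUMN] == "jogging"].index[1:])
        with pytest.raises(ValueError, match="jogging"):
            split_dataset(df)


class TestTraining:
    def test_single_class_always_predicted(self):
        df = _cluster_frame(n_per_class=10)
        only = df[df[LABEL_COLUMN] == "resting"]
        model = train_model(only, "random_forest", 5, seed=0)
        probe = _cluster_frame(seed=9, n_per_class=4)
        assert set(model.predict(probe)) == {"resting"}

    def test_separable_clusters_classified_perfectly(self):
        df = _cluster_frame(sep=10.0)
        train, valid = split_dataset(df, seed=3)
        assert _nearest_centroid_accuracy(train, valid) == 1.0  # oracle sanity
        for algorithm in ("random_forest", "knn"):
            model = train_model(train, algorithm, 5, seed=3)
            assert evaluate_model(model, valid).overall_accuracy == 1.0

    def test_retraining_reproduces_predictions(self):
        df = _cluster_frame()
        train, valid = split_dataset(df, seed=4)
        p1 = train_model(train, "random_forest", 24, seed=4).predict(valid)
        p2 = train_model(train, "random_forest", 24, seed=4).predict(valid)
        assert (p1 == p2).all()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model(_cluster_frame().iloc[0:0], "random_forest", 5)


class TestEvaluation:
    def test_perfect_predictions_identity_confusion(self):
        df = _cluster_frame(n_per_class=6)
        stub = FixedPredictions(df[LABEL_COLUMN].tolist(), sorted(df[LABEL_COLUMN].unique()))
        report = evaluate_model(stub, df)
        assert report.overall_accuracy == 1.0
        assert np.allclose(report.confusion.to_numpy(), np.eye(5))

    def test_all_wrong_zero_diagonal(self):
        df = _cluster_frame(n_per_class=4)
        df = df[df[LABEL_COLUMN].isin(["jogging", "resting"])]
        flipped = df[LABEL_COLUMN].map({"jogging": "resting", "resting": "jogging"})
        stub = FixedPredictions(flipped.tolist(), ("jogging", "resting"))
        report = evaluate_model(stub, df)
        assert report.overall_accuracy == 0.0
        assert np.trace(report.confusion.to_numpy()) == 0.0

    def test_hand_tallied_confusion(self):
        labels = ["jogging"] * 5 + ["resting"] * 5
        preds = ["jogging"] * 4 + ["resting"] + ["resting"] * 3 + ["jogging"] * 2
        df = pd.DataFrame({"f0": np.zeros(10), LABEL_COLUMN: labels})
        stub = FixedPredictions(preds, ("jogging", "resting"))
        report = evaluate_model(stub, df)
        assert report.overall_accuracy == pytest.approx(0.7)
        assert report.counts.loc["jogging", "jogging"] == 4
        assert report.counts.loc["jogging", "resting"] == 1
        assert report.counts.loc["resting", "jogging"] == 2
        assert report.counts.loc["resting", "resting"] == 3

    def test_rows_sum_to_one(self, pruned_vectors):
        train, valid = split_dataset(pruned_vectors, seed=0)
        model = train_model(train, "random_forest", 24, seed=0)
        report = evaluate_model(model, valid)
        assert np.allclose(report.confusion.sum(axis=1), 1.0, atol=1e-9)
        # overall accuracy equals the support-weighted diagonal
        weighted = sum(
            report.confusion.loc[c, c] * report.support[c] for c in report.support
        ) / sum(report.support.values())
        assert report.overall_accuracy == pytest.approx(weighted, abs=1e-9)

    def test_unknown_label_rejected(self):
        df = pd.DataFrame({"f0": [0.0], LABEL_COLUMN: ["jogging"]})
        stub = FixedPredictions(["resting"], ("resting",))
        with pytest.raises(ValueError, match="jogging"):
            evaluate_model(stub, df)


class TestSweep:
    def test_sweep_entry_count(self):
        df = _cluster_frame(n_per_class=12)
        train, valid = split_dataset(df, seed=0)
        curve = sweep_size(train, valid, "random_forest", range(2, 12), seed=0)
        assert len(curve) == 10
        assert [s for s, _ in curve] == list(range(2, 12))

    def test_single_point_matches_direct_training(self):
        df = _cluster_frame(n_per_class=12)
        train, valid = split_dataset(df, seed=1)
        ((size, acc),) = sweep_size(train, valid, "random_forest", [7], seed=1)
        from wearload.classifier import _child_seed

        direct = train_model(train, "random_forest", 7, seed=_child_seed(1, 7))
        assert acc == evaluate_model(direct, valid).overall_accuracy

    def test_accuracy_near_oracle_on_separable_data(self):
        df = _cluster_frame(sep=10.0)
        train, valid = split_dataset(df, seed=2)
        oracle = _nearest_centroid_accuracy(train, valid)
        curve = sweep_size(train, valid, "random_forest", [2, 5, 10, 24], seed=2)
        assert all(acc >= oracle - 0.05 for _, acc in curve)


class TestImportance:
    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 300
        df = pd.DataFrame(
            {
                "noise_a": rng.normal(size=n),
                "signal": rng.normal(size=n),
                "noise_b": rng.normal(size=n),
            }
        )
        df[LABEL_COLUMN] = np.where(df["signal"] > 0, "jogging", "resting")
        model = train_model(df, "random_forest", 30, seed=0)
        ranking = rank_importance(model)
        assert max(ranking, key=ranking.get) == "signal"

    def test_normalized_and_constant_feature_unimportant(self, pruned_vectors):
        df = pruned_vectors.copy()
        df.insert(0, "constant", 1.0)
        model = train_model(df, "random_forest", 24, seed=0)
        ranking = rank_importance(model)
        assert sum(ranking.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in ranking.values())
        assert ranking["constant"] <= 0.01

    def test_knn_has_no_importance(self):
        df = _cluster_frame(n_per_class=10)
        model = train_model(df, "knn", 3, seed=0)
        with pytest.raises(ValueError, match="random forest"):
            rank_importance(model)


class TestPrunedSpecSelection:
    def test_drop_four_of_fifteen(self):
        ranking = {f"f{i}": (i + 1) / 120 for i in range(15)}
        spec = select_pruned_spec(ranking, 4)
        assert len(spec) == 11
        assert set(("f0", "f1", "f2", "f3")).isdisjoint(spec.names)

    def test_drop_zero_is_identity(self):
        ranking = {"a": 0.5, "b": 0.3, "c": 0.2}
        assert select_pruned_spec(ranking, 0).names == ("a", "b", "c")

    def test_dropped_set_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(size=15)
        values /= values.sum()
        ranking = {f"f{i}": v for i, v in enumerate(values)}
        spec = select_pruned_spec(ranking, 4)
        smallest = set(sorted(ranking, key=ranking.get)[:4])
        assert set(ranking) - set(spec.names) == smallest

    def test_drop_count_too_large(self):
        with pytest.raises(ValueError):
            select_pruned_spec({"a": 1.0}, 1)


class TestExport:
    def test_replay_matches_live_predictions(self, tmp_path, pruned_vectors):
        train, _ = split_dataset(pruned_vectors, seed=0)
        model = train_model(train, "random_forest", 24, seed=0)
        path = tmp_path / "model.json"
        export_model(model, path)
        desc = load_model_description(path)
        probe = make_corpus_vectors(seed=77, n_sessions=3)  # 720 fresh vectors
        assert (desc.predict(probe) == model.predict(probe)).all()

    def test_single_stump_has_one_split(self):
        df = pd.DataFrame({"f0": [0.0, 1.0] * 10, LABEL_COLUMN: ["jogging", "resting"] * 10})
        from sklearn.ensemble import RandomForestClassifier

        model = train_model(df, "random_forest", 1, seed=0)
        model.estimator = RandomForestClassifier(
            n_estimators=1, max_depth=1, random_state=0, bootstrap=False
        ).fit(df[["f0"]], df[LABEL_COLUMN])
        import tempfile, os

        path = os.path.join(tempfile.mkdtemp(), "stump.json")
        export_model(model, path)
        desc = load_model_description(path)
        assert desc.n_trees == 1
        assert desc.n_split_nodes() == 1

    def test_description_lists_24_trees(self, tmp_path, pruned_vectors):
        train, _ = split_dataset(pruned_vectors, seed=1)
        model = train_model(train, "random_forest", 24, seed=1)
        export_model(model, tmp_path / "m.json")
        assert load_model_description(tmp_path / "m.json").n_trees == 24

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier
        from wearload.classifier import TrainedModel

        model = TrainedModel(
            algorithm="random_forest", size_param=5,
            feature_spec=FeatureSetSpec(("f0",)), class_list=("resting",),
            estimator=RandomForestClassifier(), seed=0,
        )
        with pytest.raises(ValueError, match="not fitted"):
            export_model(model, "/tmp/never.json")
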