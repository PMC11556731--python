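"""Tests of fusion, stratified splitting, training, metrics and CV."""

import numpy as np
import pandas as pd
import pytest

from texfuse import classify, mdfs
from texfuse.types import ParameterError

from conftest import brute_force_auc

SINGLETON = classify.GridSpec(**{k: (v,) for k, v in classify.tuned_params().items()})


def gaussian_table(n_per_class=50, n_features=3, sep=3.0, seed=0, labels=("neg", "pos")):
    """Well-separated Gaussian classes: means +-sep, unit sd."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, label in enumerate(labels):
        mu = sep * (2 * i - 1)
        data = {f"f{j}": mu + rng.standard_normal(n_per_class) for j in range(n_features)}
        frame = pd.DataFrame(data)
        frame["class"] = label
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table.index = pd.Index([f"s{i}" for i in range(len(table))], name="id")
    return table


class TestFuseFeatures:
    def _tables(self, n=4):
        idx = pd.Index([f"i{k}" for k in range(n)], name="id")
        static = pd.DataFrame({"s1": range(n), "s2": range(n), "class": ["A", "B"] * (n // 2)},
                              index=idx)
        dynamic = pd.DataFrame({"d1": range(n), "class": ["A", "B"] * (n // 2)}, index=idx)
        return static, dynamic

    def test_column_arity(self):
        static, dynamic = self._tables()
        fused = classify.fuse_features(static, dynamic)
        assert list(fused.columns) == ["s1", "s2", "d1", "class"]

    def test_hybrid_width_25_plus_1024(self):
        idx = pd.Index(["a", "b"], name="id")
        static = pd.DataFrame(np.zeros((2, 25)), columns=[f"s{i}" for i in range(25)], index=idx)
        static["class"] = ["A", "B"]
        dynamic = pd.DataFrame(np.zeros((2, 1024)),
                               columns=[f"deep_{i:04d}" for i in range(1024)], index=idx)
        dynamic["class"] = ["A", "B"]
        fused = classify.fuse_features(static, dynamic)
        assert fused.shape[1] - 1 == 1049

    def test_empty_dynamic_is_identity(self):
        static, dynamic = self._tables()
        fused = classify.fuse_features(static, dynamic[["class"]])
        pd.testing.assert_frame_equal(fused, static)

    def test_id_mismatch_rejected(self):
        static, dynamic = self._tables()
        dynamic = dynamic.rename(index={"i0": "zz"})
        with pytest.raises(ParameterError, match="zz"):
            classify.fuse_features(static, dynamic)


class TestStratifiedSplit:
    def test_exact_division(self):
        table = gaussian_table(n_per_class=10)
        train, test = classify.stratified_split(table, classify.SplitSpec(0.2, seed=1))
        assert test["class"].value_counts().to_dict() == {"neg": 2, "pos": 2}
        assert len(train) + len(test) == 20
        assert set(train.index).isdisjoint(test.index)

    def test_largest_remainder_2017_of_10084(self):
        """Four balanced classes of 2521 at fraction 0.2 give a 2017-row test
        set: three classes contribute 504, one contributes 505."""
        table = pd.DataFrame({"f": np.zeros(4 * 2521)})
        table["class"] = np.repeat(["bacterial", "covid", "normal", "viral"], 2521)
        train, test = classify.stratified_split(table, classify.SplitSpec(0.2, seed=0))
        counts = test["class"].value_counts()
        assert len(test) == 2017
        assert sorted(counts.to_numpy()) == [504, 504, 504, 505]
        assert len(train) == 10084 - 2017

    def test_five_rows_fraction_point2(self):
        table = pd.DataFrame({"f": range(10), "class": ["A"] * 5 + ["B"] * 5})
        _, test = classify.stratified_split(table, classify.SplitSpec(0.2, seed=3))
        assert test["class"].value_counts().to_dict() == {"A": 1, "B": 1}

    def test_reproducible_from_seed(self):
        table = gaussian_table()
        a = classify.stratified_split(table, classify.SplitSpec(0.25, seed=9))[1]
        b = classify.stratified_split(table, classify.SplitSpec(0.25, seed=9))[1]
        assert list(a.index) == list(b.index)

    def test_single_row_class_rejected(self):
        table = pd.DataFrame({"f": [1, 2, 3], "class": ["A", "A", "B"]})
        with pytest.raises(ParameterError):
            classify.stratified_split(table, classify.SplitSpec(0.2))


class TestGridSearchTrain:
    def test_singleton_grid_returned(self):
        table = gaussian_table()
        model, best = classify.grid_search_train(table, SINGLETON, seed=0)
        assert best == classify.tuned_params()

    def test_separable_classes_fit_perfectly(self):
        table = gaussian_table(n_per_class=100)
        model, _ = classify.grid_search_train(table, SINGLETON, seed=0)
        pred, proba = classify.predict(model, table)
        assert (pred == table["class"].to_numpy()).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_small_grid_deterministic(self):
        table = gaussian_table(n_per_class=20, sep=1.0)
        grid = classify.GridSpec(
            booster=("gbtree",), colsample_bytree=(1,), learning_rate=(0.1, 0.3),
            max_depth=(2, 3), n_estimators=(20,), subsample=(1,),
        )
        _, best1 = classify.grid_search_train(table, grid, seed=5)
        _, best2 = classify.grid_search_train(table, grid, seed=5)
        assert best1 == best2

    def test_grid_combinations_order(self):
        grid = classify.GridSpec()
        combos = grid.combinations()
        assert len(combos) == 2 * 4 * 4 * 4 * 4 * 4
        assert combos[0]["booster"] == "gbtree" and combos[-1]["booster"] == "gblinear"

    def test_single_class_rejected(self):
        table = gaussian_table(labels=("only",))
        with pytest.raises(ParameterError):
            classify.grid_search_train(table, SINGLETON)

    def test_column_mismatch_named_in_error(self):
        table = gaussian_table()
        model, _ = classify.grid_search_train(table, SINGLETON, seed=0)
        with pytest.raises(ParameterError, match="f0"):
            classify.predict(model, table.rename(columns={"f0": "g0"}))


class TestClassificationReport:
    def test_perfect_predictions(self):
        truth = ["A", "B", "C", "A"]
        report = classify.classification_report(truth, truth)
        assert report.accuracy == 1.0
        assert np.trace(report.confusion) == 4
        for stats in report.per_class.values():
            assert stats["precision"] == stats["recall"] == stats["f1"] == 1.0

    def test_hand_counted_binary_case(self):
        report = classify.classification_report(
            ["A", "A", "A", "B"], ["A", "A", "B", "B"]
        )
        a = report.per_class["A"]
        assert a["precision"] == pytest.approx(1.0)
        assert a["recall"] == pytest.approx(2 / 3)
        assert a["f1"] == pytest.approx(0.8)

    def test_zero_predicted_positives_warns(self):
        with pytest.warns(UserWarning, match="no predicted positives"):
            report = classify.classification_report(["A", "B"], ["A", "A"])
        assert report.per_class["B"]["precision"] == 0.0

    def test_confusion_conservation_and_weighted_identity(self, rng):
        labels = np.array(["x", "y", "z"])
        truth = labels[rng.integers(0, 3, 60)]
        pred = labels[rng.integers(0, 3, 60)]
        report = classify.classification_report(truth, pred)
        assert report.confusion.sum() == 60
        supports = np.array([report.per_class[y]["support"] for y in report.labels])
        np.testing.assert_array_equal(report.confusion.sum(axis=1), supports)
        f1s = np.array([report.per_class[y]["f1"] for y in report.labels])
        expected = float((f1s * supports).sum() / supports.sum())
        assert report.weighted_avg["f1"] == pytest.approx(expected, abs=1e-12)


class TestRocAuc:
    def _scores(self, values, positive="pos"):
        return pd.DataFrame({positive: values})

    def test_perfectly_ordered(self):
        truth = ["pos", "pos", "neg", "neg"]
        assert classify.roc_auc_ovr(truth, self._scores([0.9, 0.8, 0.2, 0.1]), "pos") == 1.0

    def test_perfectly_reversed(self):
        truth = ["pos", "pos", "neg", "neg"]
        assert classify.roc_auc_ovr(truth, self._scores([0.1, 0.2, 0.8, 0.9]), "pos") == 0.0

    def test_one_discordant_pair(self):
        truth = ["pos", "neg", "pos", "neg"]
        auc = classify.roc_auc_ovr(truth, self._scores([0.9, 0.8, 0.7, 0.1]), "pos")
        assert auc == pytest.approx(0.75)

    def test_matches_pairwise_concordance_on_random_sets(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 50))
            truth = np.where(rng.uniform(size=n) < 0.5, "pos", "neg")
            if len(set(truth)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            got = classify.roc_auc_ovr(truth, self._scores(scores), "pos")
            assert got == pytest.approx(brute_force_auc(truth, scores, "pos"))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ParameterError):
            classify.roc_auc_ovr(["pos", "pos"], self._scores([0.4, 0.6]), "pos")


class TestKFoldCV:
    def test_fold_apportionment(self):
        table = gaussian_table(n_per_class=4, sep=5.0)
        report = classify.kfold_cv(table, k=2, params=classify.tuned_params(), seed=0,
                                   select=False)
        assert report.k == 2 and len(report.accuracies) == 2

    def test_separable_table_all_folds_perfect(self):
        # lattice-valued features: every held-out value also occurs in
        # training, so the class gap dominates any learned threshold
        vals = np.tile([-0.1, 0.0, 0.1], 10)
        table = pd.DataFrame({f"f{j}": np.concatenate([vals - 3, vals + 3])
                              for j in range(3)})
        table["class"] = ["neg"] * 30 + ["pos"] * 30
        report = classify.kfold_cv(table, k=3, seed=1)
        assert report.accuracies == [1.0, 1.0, 1.0]
        assert report.mean == 1.0 and report.sd == 0.0

    def test_same_seed_identical_folds(self):
        table = gaussian_table(n_per_class=20, sep=1.0)
        a = classify.kfold_cv(table, k=4, seed=6)
        b = classify.kfold_cv(table, k=4, seed=6)
        assert a.accuracies == b.accuracies

    def test_k_exceeding_smallest_class_rejected(self):
        table = gaussian_table(n_per_class=3)
        with pytest.raises(ParameterError):
            classify.kfold_cv(table, k=4)

    def test_selection_fitted_inside_training_folds_only(self, rng):
        """Leakage guard: a feature that separates classes only through rows
        of the held-out fold must not be selected when that fold is held out.

        Construction: with k=2 and fold assignment known from the seed, build
        a feature equal on both classes over one fold's training rows and
        informative only on the test rows.
        """
        from sklearn.model_selection import StratifiedKFold

        table = gaussian_table(n_per_class=20, sep=4.0, seed=2)
        y = table["class"].to_numpy()
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        train_idx, test_idx = next(iter(skf.split(table.drop(columns="class"), y)))
        leaky = np.zeros(len(table))
        leaky[test_idx] = np.where(y[test_idx] == "pos", 10.0, -10.0)
        table = table.copy()
        table["leaky"] = leaky

        train_fold = table.iloc[train_idx]
        sel = mdfs.mdfs_select(train_fold)
        assert "leaky" not in sel.intersection  # constant on training rows

        # and the full-table selection WOULD keep it: the failure mode guarded against
        sel_full = mdfs.mdfs_select(table)
        assert "leaky" in sel_full.intersection


class TestExportModel:
    def test_roundtrip_identical_predictions(self, tmp_path):
        table = gaussian_table(n_per_class=15)
        sel = mdfs.mdfs_select(table)
        reduced = mdfs.apply_selection(table, sel)
        model, _ = classify.grid_search_train(reduced, SINGLETON, seed=0)
        path = tmp_path / "bundle.joblib"
        size = classify.export_model(model, sel, path)
        assert size > 0 and size == path.stat().st_size
        bundle = classify.load_model(path)
        pred0, proba0 = classify.predict(model, reduced)
        pred1, proba1 = classify.predict(bundle["model"], reduced)
        np.testing.assert_array_equal(pred0, pred1)
        np.testing.assert_array_equal(proba0.to_numpy(), proba1.to_numpy())
        assert bundle["selection"]["tolerance"] == sel.tolerance
        assert bundle["selection"]["intersection"] == sel.intersection

    def test_missing_bundle_errors(self, tmp_path):
        with pytest.raises(IOError):
            classify.load_model(tmp_path / "absent.joblib")
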