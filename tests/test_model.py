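import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from rigwatch.features import WindowConfig, WindowDataset
from rigwatch.model import (
    BalancedRandomForest,
    ConfusionMatrix,
    RfSpec,
    confusion_matrix,
    grouped_stratified_split,
    hand_till_auc,
    per_class_metrics,
    stratified_split,
    train_random_forest,
)

from _oracles import brute_force_hand_till


def make_dataset(class_counts: dict[str, int], seed=0, informative=True):
    """Synthetic window dataset: one Gaussian blob per class."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for i, (cls, n) in enumerate(sorted(class_counts.items())):
        center = 10.0 * i if informative else 0.0
        feats.append(rng.normal(center, 1.0, size=(n, 2)))
        labels += [cls] * n
    X = pd.DataFrame(np.vstack(feats), columns=["maximum", "range"])
    labels = np.array(labels, dtype=object)
    order = rng.permutation(len(labels))
    return WindowDataset(
        config=WindowConfig(3, 0, 25.0),
        features=X.iloc[order].reset_index(drop=True),
        labels=labels[order],
        end_t=np.arange(len(labels), dtype=np.int64),
    )


class TestStratifiedSplit:
    def test_per_class_arithmetic(self):
        ds = make_dataset({"a": 90, "b": 60, "c": 30, "d": 300})
        train, test = stratified_split(ds, seed=1)
        tc = train.class_counts()
        assert tc["a"] == 60 and tc["b"] == 40 and tc["c"] == 20 and tc["d"] == 200
        sc = test.class_counts()
        assert sc["a"] == 30 and sc["b"] == 20 and sc["c"] == 10 and sc["d"] == 100

    def test_partition(self):
        ds = make_dataset({"a": 20, "b": 35})
        train, test = stratified_split(ds, seed=2)
        assert len(train) + len(test) == len(ds)
        all_t = set(train.end_t) | set(test.end_t)
        assert len(all_t) == len(ds)  # disjoint by construction of end_t

    def test_fraction_within_one_row_for_all_small_counts(self):
        """round(2n/3) is within one row of exact 2/3 for n = 3..50."""
        for n in range(3, 51):
            n_train = int(np.floor(2 / 3 * n + 0.5))
            assert abs(n_train - 2 * n / 3) <= 1
            ds = make_dataset({"a": n, "b": 12})
            train, _ = stratified_split(ds, seed=3)
            assert train.class_counts()["a"] == n_train

    def test_small_class_rejected_by_name(self):
        ds = make_dataset({"a": 2, "b": 30})
        with pytest.raises(ValueError, match="'a'"):
            stratified_split(ds)

    def test_reproducible_under_seed(self):
        ds = make_dataset({"a": 30, "b": 30})
        t1, _ = stratified_split(ds, seed=9)
        t2, _ = stratified_split(ds, seed=9)
        np.testing.assert_array_equal(t1.end_t, t2.end_t)


class TestGroupedSplit:
    def test_runs_never_straddle_the_split(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(["a", "b", "a", "b", "a", "b", "a", "b"],
                           rng.integers(5, 30, 8)).astype(object)
        ds = WindowDataset(
            config=WindowConfig(3, 0, 25.0),
            features=pd.DataFrame({"maximum": rng.normal(size=len(labels)),
                                   "range": rng.normal(size=len(labels))}),
            labels=labels,
            end_t=np.arange(len(labels), dtype=np.int64),
        )
        train, test = grouped_stratified_split(ds, seed=5)
        # contiguous runs of end_t indices must be wholly on one side
        run_edges = np.nonzero(labels[:-1] != labels[1:])[0] + 1
        runs = np.split(np.arange(len(labels)), run_edges)
        train_set = set(train.end_t)
        for run in runs:
            sides = {i in train_set for i in run}
            assert len(sides) == 1
        assert len(train) + len(test) == len(ds)
        assert set(train.labels) == set(test.labels) == {"a", "b"}


class TestForest:
    def test_separable_data_high_oob_accuracy(self):
        ds = make_dataset({"a": 80, "b": 80, "c": 80, "d": 80}, seed=6)
        model = train_random_forest(ds, RfSpec(n_tree=50, seed=6), record_oob=True)
        curve = model.oob_accuracy_curve(ds.labels)
        assert curve["overall"].iloc[-1] >= 0.95

    def test_bootstrap_is_class_balanced(self):
        y = np.array([0] * 10 + [1] * 50 + [2] * 7 + [3] * 100)
        rng = np.random.default_rng(0)
        boot = BalancedRandomForest.balanced_bootstrap(y, 7, rng)
        assert len(boot) == 4 * 7
        drawn = y[boot]
        assert all((drawn == c).sum() == 7 for c in range(4))

    def test_single_tree_matches_independent_cart(self):
        """n_tree=1 with a fixed seed equals a directly grown sklearn CART
        on the same balanced bootstrap."""
        ds = make_dataset({"a": 40, "b": 40, "c": 40, "d": 40}, seed=8)
        spec = RfSpec(n_tree=1, seed=13)
        model = train_random_forest(ds, spec)
        labels, _ = model.predict_with_scores(ds.features)

        # independent reconstruction of the one bootstrap and tree
        seed = int(np.random.SeedSequence(13).spawn(1)[0].generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(seed)
        classes = sorted(set(ds.labels))
        y_codes = np.array([classes.index(l) for l in ds.labels])
        per_class = min(np.bincount(y_codes))
        boot = np.concatenate([
            rng.choice(np.nonzero(y_codes == c)[0], size=per_class, replace=True)
            for c in range(4)
        ])
        cart = DecisionTreeClassifier(max_features=1, random_state=seed)
        cart.fit(ds.features.to_numpy()[boot], y_codes[boot])
        expect = np.array(classes, dtype=object)[cart.predict(ds.features.to_numpy())]
        np.testing.assert_array_equal(labels, expect)

    def test_scores_are_vote_fractions(self):
        ds = make_dataset({"a": 30, "b": 30, "c": 30, "d": 30}, seed=9)
        model = train_random_forest(ds, RfSpec(n_tree=20, seed=9))
        _, scores = model.predict_with_scores(ds.features)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-12)
        votes = model.vote_counts(ds.features)
        np.testing.assert_allclose(scores, votes / 20)

    def test_missing_class_rejected(self):
        ds = make_dataset({"a": 30})
        with pytest.raises(ValueError, match="2 classes"):
            train_random_forest(ds, RfSpec(n_tree=5))

    def test_predictor_mismatch_rejected(self):
        ds = make_dataset({"a": 30, "b": 30})
        model = train_random_forest(ds, RfSpec(n_tree=5, seed=1))
        bad = ds.features.rename(columns={"maximum": "mean"})
        with pytest.raises(ValueError, match="mismatch"):
            model.predict_with_scores(bad)

    def test_oob_curve_shape_and_plateau(self):
        ds = make_dataset({"a": 100, "b": 100, "c": 100, "d": 100}, seed=10)
        model = train_random_forest(ds, RfSpec(n_tree=150, seed=10), record_oob=True)
        curve = model.oob_accuracy_curve(ds.labels)
        assert len(curve) == 150
        # on separable data accuracy plateaus: 150 vs 50 trees within 2 points
        assert abs(curve["overall"].iloc[149] - curve["overall"].iloc[49]) <= 0.02


class TestConfusionAndMetrics:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["a"] * 5 + ["b"] * 3
        cm = confusion_matrix(labels, labels, ["a", "b"])
        assert cm.counts[0, 0] == 5 and cm.counts[1, 1] == 3
        assert cm.counts[0, 1] == cm.counts[1, 0] == 0
        m = per_class_metrics(cm)
        assert (m["sensitivity_pct"] == 100).all()
        assert (m["f1"] == 1).all()
        assert (m["balanced_accuracy_pct"] == 100).all()

    def test_grand_total_and_counts_orientation(self):
        pred = ["a", "a", "b", "b", "b"]
        act = ["a", "b", "b", "a", "b"]
        cm = confusion_matrix(pred, act, ["a", "b"])
        assert cm.total == 5
        assert cm.counts[0, 1] == 1  # predicted a, actually b
        assert cm.counts[1, 0] == 1  # predicted b, actually a

    def test_matrix_round_trips_through_pairs(self):
        """Re-entering a count table as (predicted, actual) pairs rebuilds it."""
        classes = ["set_choker", "travel_away", "travel_to_log", "clear"]
        counts = np.array([[12, 3, 0, 5], [1, 9, 2, 0], [0, 1, 20, 2], [4, 0, 1, 30]])
        pred, act = [], []
        for i, p in enumerate(classes):
            for j, a in enumerate(classes):
                pred += [p] * counts[i, j]
                act += [a] * counts[i, j]
        cm = confusion_matrix(pred, act, classes)
        np.testing.assert_array_equal(cm.counts, counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(["a"], ["z"], ["a", "b"])

    def test_ba_is_mean_of_se_and_sp(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[8, 3], [2, 7]]))
        m = per_class_metrics(cm)
        np.testing.assert_allclose(
            m["balanced_accuracy_pct"],
            (m["sensitivity_pct"] + m["specificity_pct"]) / 2,
        )

    def test_empty_actual_class_flagged_not_zeroed(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[4, 0], [1, 0]]))
        with pytest.warns(UserWarning, match="no actual"):
            m = per_class_metrics(cm)
        assert np.isnan(m.loc["b", "sensitivity_pct"])


class TestHandTillAuc:
    def test_perfect_ranking_gives_one(self):
        actual = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        scores = np.zeros((9, 3))
        for i, cls in enumerate(actual):
            scores[i, ["a", "b", "c"].index(cls)] = 1.0
        assert hand_till_auc(scores, actual, ["a", "b", "c"]) == 1.0

    def test_all_tied_scores_give_half(self):
        actual = ["a"] * 4 + ["b"] * 4
        scores = np.full((8, 2), 0.5)
        assert hand_till_auc(scores, actual, ["a", "b"]) == 0.5

    def test_matches_brute_force_enumeration(self, rng):
        """Random 3- and 4-class score tables vs exhaustive pair counting."""
        for n_classes in (3, 4):
            classes = [f"c{i}" for i in range(n_classes)]
            for _ in range(8):
                n = int(rng.integers(6, 30))
                actual = [classes[i] for i in rng.integers(0, n_classes, n)]
                while len(set(actual)) < n_classes:
                    actual = [classes[i] for i in rng.integers(0, n_classes, n)]
                raw = rng.random((n, n_classes))
                scores = raw / raw.sum(axis=1, keepdims=True)
                ours = hand_till_auc(scores, actual, classes)
                theirs = brute_force_hand_till(scores, list(actual))
                assert ours == pytest.approx(theirs, abs=1e-12)

    def test_binary_case_equals_mann_whitney_auc(self, rng):
        actual = ["neg"] * 20 + ["pos"] * 12
        scores_pos = rng.random(32)
        scores = np.column_stack([1 - scores_pos, scores_pos])
        ours = hand_till_auc(scores, actual, ["neg", "pos"])
        sk = roc_auc_score([a == "pos" for a in actual], scores_pos)
        assert ours == pytest.approx(sk, abs=1e-12)

    def test_invariance_to_relabeling_and_monotone_transform(self, rng):
        classes = ["a", "b", "c"]
        actual = [classes[i] for i in rng.integers(0, 3, 30)]
        raw = rng.random((30, 3))
        base = hand_till_auc(raw, actual, classes)
        # strictly monotone transform of each score column
        transformed = np.exp(3 * raw) + 5
        assert hand_till_auc(transformed, actual, classes) == pytest.approx(base)
        # relabel classes (consistent permutation of names and columns)
        perm = [1, 2, 0]  # new column i holds the old class now named classes[i]
        renamed = {"a": "c", "b": "a", "c": "b"}
        actual2 = [renamed[a] for a in actual]
        assert hand_till_auc(raw[:, perm], actual2, classes) == pytest.approx(base)

    def test_absent_class_dropped_with_warning(self):
        actual = ["a"] * 4 + ["b"] * 4
        scores = np.random.default_rng(0).random((8, 3))
        with pytest.warns(UserWarning, match="dropped"):
            val = hand_till_auc(scores, actual, ["a", "b", "c"])
        assert 0.0 <= val <= 1.0
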