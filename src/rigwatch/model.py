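"""Class-balanced random forests, confusion-matrix metrics, multiclass AUC,
and the window-size/overlap model sweep.

The activity classes are heavily imbalanced (most of a shift is spent "in
the clear"), so each tree of the forest is grown on a stratified bootstrap
that draws the same number of rows, with replacement, from every class —
the count of the least common class.  Model comparison across the window
grid uses the Hand-and-Till multiclass AUC computed from the forests'
vote-fraction scores.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

from .features import EstimatorConfig, WindowConfig, WindowDataset, build_dataset
from .io import LabeledMagnitudeSeries


# ---------------------------------------------------------------------------
# splitting


def stratified_split(
    dataset: WindowDataset, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[WindowDataset, WindowDataset]:
    """Random per-class split preserving class ratios.

    Within each class, round(train_fraction * n_c) rows (half-up) go to
    training and the rest to testing; the two parts are disjoint and
    exhaustive.  Classes with fewer than 3 rows cannot populate both
    sides meaningfully and raise an error naming the class.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_mask = np.zeros(len(labels), dtype=bool)
    for cls in sorted(set(labels)):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 3:
            raise ValueError(
                f"class {cls!r} has only {len(idx)} rows; need at least 3"
            )
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        chosen = rng.permutation(idx)[:n_train]
        train_mask[chosen] = True

    def subset(mask):
        return WindowDataset(
            config=dataset.config,
            features=dataset.features.loc[mask].reset_index(drop=True),
            labels=dataset.labels[mask],
            end_t=dataset.end_t[mask],
        )

    return subset(train_mask), subset(~train_mask)


def grouped_stratified_split(
    dataset: WindowDataset, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[WindowDataset, WindowDataset]:
    """Episode-level split: overlapping windows never straddle the split.

    Windows are grouped into contiguous same-label runs (one run per
    activity episode, boundary windows aside), and whole runs are assigned
    to train until each class's window count reaches the train fraction.
    Stricter than the window-level split: with overlapping windows the
    window-level split lets test windows share most of their samples with
    a training neighbour, which leaks realization-level information.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    run_id = np.zeros(len(labels), dtype=np.int64)
    for i in range(1, len(labels)):
        run_id[i] = run_id[i - 1] + (labels[i] != labels[i - 1])
    train_mask = np.zeros(len(labels), dtype=bool)
    for cls in sorted(set(labels)):
        cls_mask = labels == cls
        runs = np.unique(run_id[cls_mask])
        if len(runs) < 2:
            raise ValueError(
                f"class {cls!r} has only {len(runs)} episode run(s); "
                "cannot populate both split sides"
            )
        target = train_fraction * cls_mask.sum()
        got = 0
        for r in rng.permutation(runs):
            if got >= target:
                break
            m = run_id == r
            train_mask[m] = True
            got += int(m.sum())
        if got == cls_mask.sum():  # keep at least one run for testing
            last = rng.choice(runs)
            train_mask[run_id == last] = False

    def subset(mask):
        return WindowDataset(
            config=dataset.config,
            features=dataset.features.loc[mask].reset_index(drop=True),
            labels=dataset.labels[mask],
            end_t=dataset.end_t[mask],
        )

    return subset(train_mask), subset(~train_mask)


def split_dataset(
    dataset: WindowDataset,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    mode: str = "window",
) -> tuple[WindowDataset, WindowDataset]:
    """Dispatch to the window-level or episode-grouped split."""
    if mode == "window":
        return stratified_split(dataset, train_fraction, seed)
    if mode in ("episode", "session", "grouped"):
        return grouped_stratified_split(dataset, train_fraction, seed)
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# forest


@dataclasses.dataclass
class RfSpec:
    """Random-forest hyperparameters.

    ``m_try`` (features tried per split) defaults to floor(sqrt(p));
    ``per_class_sample`` defaults to the least common class's training
    count, giving each tree a class-balanced bootstrap.
    """

    n_tree: int = 150
    m_try: int | None = None
    stratified: bool = True
    per_class_sample: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")


class BalancedRandomForest:
    """Bagged CART ensemble with per-class balanced bootstraps.

    Each of the ``n_tree`` trees is grown on a bootstrap drawing
    ``per_class_sample`` rows with replacement from every class; rows a
    tree never saw are its out-of-bag (OOB) set.  Prediction is by
    majority vote and class scores are vote fractions.
    """

    def __init__(self, spec: RfSpec, record_oob: bool = True):
        self.spec = spec
        self.record_oob = record_oob
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.feature_names_: list[str] | None = None
        self._oob: list[tuple[np.ndarray, np.ndarray]] = []  # (row idx, pred code)
        self._n_train = 0

    @staticmethod
    def tree_seeds(seed: int, n_tree: int) -> np.ndarray:
        """Deterministic per-tree seeds spawned from the master seed."""
        ss = np.random.SeedSequence(seed)
        return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n_tree)])

    @staticmethod
    def balanced_bootstrap(
        y_codes: np.ndarray, per_class: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Indices of one class-balanced bootstrap (per_class rows per class)."""
        parts = [
            rng.choice(np.nonzero(y_codes == c)[0], size=per_class, replace=True)
            for c in range(y_codes.max() + 1)
        ]
        return np.concatenate(parts)

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "BalancedRandomForest":
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        self.feature_names_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        code_of = {c: i for i, c in enumerate(self.classes_)}
        y_codes = np.array([code_of[lab] for lab in y])
        counts = np.bincount(y_codes)
        if np.any(counts == 0):
            raise ValueError("a class is absent from the training data")
        per_class = self.spec.per_class_sample or int(counts.min())
        p = Xv.shape[1]
        m_try = self.spec.m_try or max(1, int(np.floor(np.sqrt(p))))
        if not 1 <= m_try <= p:
            raise ValueError(f"m_try must be in [1, {p}]")
        self._n_train = len(y)

        seeds = self.tree_seeds(self.spec.seed, self.spec.n_tree)
        self.trees_ = []
        self._oob = []
        for s in seeds:
            rng = np.random.default_rng(int(s))
            if self.spec.stratified:
                boot = self.balanced_bootstrap(y_codes, per_class, rng)
            else:
                boot = rng.choice(len(y), size=len(y), replace=True)
            tree = DecisionTreeClassifier(max_features=m_try, random_state=int(s))
            tree.fit(Xv[boot], y_codes[boot])
            self.trees_.append(tree)
            if self.record_oob:
                oob_mask = np.ones(len(y), dtype=bool)
                oob_mask[boot] = False
                oob_idx = np.nonzero(oob_mask)[0]
                pred = self._tree_codes(tree, Xv[oob_idx])
                self._oob.append((oob_idx, pred.astype(np.int8)))
        return self

    def _tree_codes(self, tree: DecisionTreeClassifier, Xv: np.ndarray) -> np.ndarray:
        # tree.classes_ are the bootstrap's class codes; map back to ensemble codes
        return tree.classes_[np.argmax(tree.predict_proba(Xv), axis=1)]

    def _check_schema(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names_:
            raise ValueError(
                f"predictor mismatch: model expects {self.feature_names_}, "
                f"got {list(X.columns)}"
            )
        return X.to_numpy(dtype=float)

    def vote_counts(self, X: pd.DataFrame) -> np.ndarray:
        Xv = self._check_schema(X)
        k = len(self.classes_)
        votes = np.zeros((len(Xv), k), dtype=np.int64)
        for tree in self.trees_:
            pred = self._tree_codes(tree, Xv)
            votes[np.arange(len(Xv)), pred] += 1
        return votes

    def predict_with_scores(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Majority-vote labels and vote-fraction scores (rows sum to 1).

        Vote ties resolve to the first class in the fixed (sorted) class
        order.
        """
        votes = self.vote_counts(X)
        scores = votes / votes.sum(axis=1, keepdims=True)
        labels = self.classes_[np.argmax(votes, axis=1)]
        return labels, scores

    def oob_accuracy_curve(self, y: Sequence[str]) -> pd.DataFrame:
        """Overall and per-class OOB accuracy as trees accumulate.

        Row t gives accuracies using only the first t trees' OOB votes;
        rows where a class has no OOB-voted member yet are NaN for that
        class.
        """
        if not self._oob:
            raise ValueError("fit with record_oob=True to get an OOB curve")
        y = np.asarray(y, dtype=object)
        code_of = {c: i for i, c in enumerate(self.classes_)}
        y_codes = np.array([code_of[lab] for lab in y])
        k = len(self.classes_)
        votes = np.zeros((self._n_train, k), dtype=np.int32)
        rows = []
        for oob_idx, pred in self._oob:
            votes[oob_idx, pred] += 1
            seen = votes.sum(axis=1) > 0
            pred_codes = votes.argmax(axis=1)
            correct = (pred_codes == y_codes) & seen
            row = {"overall": correct[seen].sum() / max(1, seen.sum())}
            for c, cls in enumerate(self.classes_):
                m = seen & (y_codes == c)
                row[str(cls)] = correct[m].sum() / m.sum() if m.any() else np.nan
            rows.append(row)
        out = pd.DataFrame(rows)
        out.index = np.arange(1, len(rows) + 1)
        out.index.name = "n_trees"
        return out


def predict_with_scores(
    model: BalancedRandomForest, X: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and vote-fraction scores for feature rows."""
    return model.predict_with_scores(X)


def train_random_forest(
    train: WindowDataset,
    spec: RfSpec,
    predictors: Sequence[str] | None = None,
    record_oob: bool = False,
) -> BalancedRandomForest:
    """Fit a class-balanced forest on a window dataset's predictor columns."""
    X = train.features[list(predictors)] if predictors is not None else train.features
    return BalancedRandomForest(spec, record_oob=record_oob).fit(X, train.labels)


# ---------------------------------------------------------------------------
# metrics


@dataclasses.dataclass
class ConfusionMatrix:
    """Square count table, rows = predicted class, columns = actual class."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="predicted"),
            columns=pd.Index(self.classes, name="actual"),
        )


def confusion_matrix(
    predicted: Sequence[str], actual: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Count (predicted, actual) pairs in the given class order."""
    predicted = np.asarray(predicted, dtype=object)
    actual = np.asarray(actual, dtype=object)
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual must have equal length")
    code_of = {c: i for i, c in enumerate(classes)}
    try:
        p = np.array([code_of[x] for x in predicted])
        a = np.array([code_of[x] for x in actual])
    except KeyError as err:
        raise ValueError(f"label {err.args[0]!r} outside the class list") from None
    k = len(classes)
    counts = np.bincount(p * k + a, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(list(classes), counts)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Sensitivity, specificity, precision (%), F1 (rate) and balanced accuracy.

    For class c: TP is the diagonal cell, FN the rest of c's actual
    column, FP the rest of c's predicted row, TN everything else.
    Se = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP), F1 the harmonic
    mean of precision and sensitivity computed from the rates, and
    BA = (Se+Sp)/2 from the percentages.  A class with an empty actual
    column gets NaN metrics (flagged, never silently zero).
    """
    C = cm.counts
    total = C.sum()
    rows = []
    for i, cls in enumerate(cm.classes):
        tp = C[i, i]
        fn = C[:, i].sum() - tp
        fp = C[i, :].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {cls!r} has no actual instances; metrics NaN")
            rows.append(dict.fromkeys(
                ["sensitivity_pct", "specificity_pct", "precision_pct",
                 "f1", "balanced_accuracy_pct"], np.nan))
            continue
        se = tp / (tp + fn)
        sp = tn / (tn + fp) if tn + fp > 0 else np.nan  # no negative cases
        pr = tp / (tp + fp) if tp + fp > 0 else np.nan
        f1 = 2 * pr * se / (pr + se) if pr == pr and pr + se > 0 else np.nan
        rows.append(
            {
                "sensitivity_pct": 100 * se,
                "specificity_pct": 100 * sp,
                "precision_pct": 100 * pr,
                "f1": f1,
                "balanced_accuracy_pct": (100 * se + 100 * sp) / 2,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(cm.classes, name="activity"))


def hand_till_auc(
    scores: np.ndarray, actual: Sequence[str], classes: Sequence[str] | None = None
) -> float:
    """Hand-and-Till multiclass AUC, M.

    For each unordered class pair (i, j), A(i|j) is the Mann-Whitney
    probability that a random class-i case outranks a random class-j case
    on the class-i score (ties count 1/2); the pair's AUC is the average
    of A(i|j) and A(j|i), and M averages over all pairs.  Classes with no
    test cases are dropped from the pairing with a warning.
    """
    actual = np.asarray(actual, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(actual):
        raise ValueError("scores and actual must align")
    if classes is None:
        classes = sorted(set(actual))
    classes = list(classes)
    present = [c for c in classes if np.any(actual == c)]
    if len(present) < len(classes):
        warnings.warn(
            "classes with no cases dropped from AUC: "
            + ", ".join(set(classes) - set(present))
        )
    if len(present) < 2:
        raise ValueError("need at least 2 classes with cases")
    col = {c: classes.index(c) for c in present}

    def a_given(i: str, j: str) -> float:
        # probability a class-i case outranks a class-j case on score_i
        si = scores[actual == i, col[i]]
        sj = scores[actual == j, col[i]]
        ranks = rankdata(np.concatenate([si, sj]))
        ri = ranks[: len(si)].sum()
        return (ri - len(si) * (len(si) + 1) / 2) / (len(si) * len(sj))

    pair_aucs = []
    for a_i in range(len(present)):
        for a_j in range(a_i + 1, len(present)):
            i, j = present[a_i], present[a_j]
            pair_aucs.append((a_given(i, j) + a_given(j, i)) / 2)
    return float(np.mean(pair_aucs))


# ---------------------------------------------------------------------------
# sweep


@dataclasses.dataclass
class ModelResult:
    """Evaluation of one (window size, overlap) configuration."""

    config: WindowConfig
    predictors: list[str]
    confusion: ConfusionMatrix
    metrics: pd.DataFrame
    multiclass_auc: float
    n_train: int
    n_test: int
    oob_curve: pd.DataFrame | None = None
    failed: str | None = None


def evaluate_configuration(
    series: LabeledMagnitudeSeries,
    config: WindowConfig,
    predictors: Sequence[str],
    rf: RfSpec,
    classes: Sequence[str],
    estimators: EstimatorConfig | None = None,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    record_oob: bool = False,
    split_mode: str = "window",
) -> ModelResult:
    """Window, split, train and score one grid configuration."""
    dataset = build_dataset(series, config, estimators)
    present = set(dataset.labels)
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes lost in windowing: {missing}")
    train, test = split_dataset(dataset, train_fraction, seed=seed, mode=split_mode)
    model = train_random_forest(train, rf, predictors, record_oob=record_oob)
    Xte = test.features[list(predictors)]
    pred, raw_scores = model.predict_with_scores(Xte)
    # score columns follow the requested class order
    reorder = [list(model.classes_).index(c) for c in classes]
    scores = raw_scores[:, reorder]
    cm = confusion_matrix(pred, test.labels, classes)
    return ModelResult(
        config=config,
        predictors=list(predictors),
        confusion=cm,
        metrics=per_class_metrics(cm),
        multiclass_auc=hand_till_auc(scores, test.labels, classes),
        n_train=len(train),
        n_test=len(test),
        oob_curve=model.oob_accuracy_curve(train.labels) if record_oob else None,
    )


DEFAULT_SIZES = tuple(range(1, 16))
DEFAULT_OVERLAPS = (0, 25, 50, 75, 90)


def run_sweep(
    series: LabeledMagnitudeSeries,
    classes: Sequence[str],
    predictors: Sequence[str],
    sizes: Sequence[float] = DEFAULT_SIZES,
    overlaps: Sequence[float] = DEFAULT_OVERLAPS,
    rf: RfSpec | None = None,
    estimators: EstimatorConfig | None = None,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    split_mode: str = "window",
) -> tuple[list[ModelResult], ModelResult]:
    """Evaluate the full window-size x overlap grid and pick the best model.

    Best = highest multiclass AUC; ties break to the smaller window, then
    the larger overlap.  A configuration that loses a class in windowing
    is recorded as failed and the sweep continues.
    """
    rf = rf or RfSpec(seed=seed)
    results: list[ModelResult] = []
    for size in sizes:
        for ov in overlaps:
            config = WindowConfig(size, ov, series.rate_hz)
            try:
                res = evaluate_configuration(
                    series, config, predictors, rf, classes,
                    estimators=estimators, train_fraction=train_fraction,
                    seed=seed, split_mode=split_mode,
                )
            except ValueError as err:
                res = ModelResult(
                    config=config, predictors=list(predictors),
                    confusion=ConfusionMatrix(list(classes),
                                              np.zeros((len(classes),) * 2, int)),
                    metrics=pd.DataFrame(), multiclass_auc=np.nan,
                    n_train=0, n_test=0, failed=str(err),
                )
            results.append(res)
    ok = [r for r in results if r.failed is None]
    if not ok:
        raise ValueError("every configuration failed")
    best = max(
        ok,
        key=lambda r: (r.multiclass_auc, -r.config.window_s, r.config.overlap_pct),
    )
    return results, best


def sweep_table(results: list[ModelResult], worker_type: str) -> pd.DataFrame:
    """Flatten sweep results into the persistable results table."""
    rows = []
    for r in results:
        row = {
            "worker_type": worker_type,
            "window_s": r.config.window_s,
            "overlap_pct": r.config.overlap_pct,
            "auc": r.multiclass_auc,
            "n_train": r.n_train,
            "n_test": r.n_test,
            "failed": r.failed or "",
        }
        if r.failed is None:
            for cls in r.confusion.classes:
                m = r.metrics.loc[cls]
                row[f"se_{cls}"] = m["sensitivity_pct"]
                row[f"sp_{cls}"] = m["specificity_pct"]
                row[f"pr_{cls}"] = m["precision_pct"]
                row[f"f1_{cls}"] = m["f1"]
                row[f"ba_{cls}"] = m["balanced_accuracy_pct"]
        rows.append(row)
    return pd.DataFrame(rows)
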