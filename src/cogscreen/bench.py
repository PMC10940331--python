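"""Classifier benchmark: feature spaces, model zoo, metrics, bootstrap.

The sixteen feature spaces F1-F16 mix IRT scores (five-dimensional:
``SSHO, dccs5D, ...``; two-dimensional: ``SSHO2D, dccs2D, psm2D``),
classical number-correct scores, total response times, composites, and
demographics.  Categorical demographics enter as the integer codes of
the cohort's frequency table.

Seven classifier families are benchmarked, each with a fixed
hyperparameter grid searched by stratified 5-fold cross-validation on
the training split (best mean CV accuracy wins; ties go to the first
grid point).  Evaluation metrics are computed from the confusion matrix
with *impaired* as the positive class; a weighted-average convention is
also available for comparison with reports that use it.

The bootstrap protocol resamples the full cohort with replacement,
re-splits the resample 80/20 (stratified), re-runs the grid search on
the 80% and evaluates on the 20%; metric means and SDs are taken over
replications, skipping replications where a metric is undefined (the
skip count is reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureSpace",
    "FEATURE_SPACES",
    "ModelSpec",
    "MODEL_ZOO",
    "ConfusionMatrix",
    "EvalResult",
    "BootstrapSummary",
    "build_feature_matrix",
    "split_cohort",
    "grid_search_train",
    "evaluate",
    "bootstrap_evaluate",
    "kmeans_elbow",
]


@dataclass(frozen=True)
class FeatureSpace:
    """Named, ordered list of score-bundle columns."""

    name: str
    features: tuple[str, ...]


_DEMO = ("race", "gender", "income", "education")
_IRT5 = ("SSHO", "dccs5D", "psm5D", "arw5D", "mfs5D", "nsm5D")
_IRT2 = ("SSHO2D", "dccs2D", "psm2D")
_RT3 = ("psm_rt", "arw_rt", "dccs_rt")

#: Registry of the sixteen benchmark feature spaces.
FEATURE_SPACES: dict[str, FeatureSpace] = {
    fs.name: fs
    for fs in (
        FeatureSpace("F1", _IRT5 + _RT3 + _DEMO),                       # 13
        FeatureSpace("F2", _IRT5 + _RT3),                               # 9
        FeatureSpace("F3", _DEMO + _IRT5),                              # 10
        FeatureSpace("F4", _IRT5),                                      # 6
        FeatureSpace("F5", _DEMO + _IRT2 + ("dccs_rt", "psm_rt")),      # 9
        FeatureSpace("F6", _DEMO + _IRT2),                              # 7
        FeatureSpace("F7", _IRT2),                                      # 3
        FeatureSpace("F8", ("Composite1",)),
        FeatureSpace("F9", ("Composite2",)),
        FeatureSpace("F10", ("Composite3",)),
        FeatureSpace("F11", ("age", "Composite4")),
        FeatureSpace("F12", ("Composite5",)),
        FeatureSpace("F13", ("psm", "psm_rt", "age")),
        FeatureSpace("F14", ("dccs", "dccs_rt", "age")),
        FeatureSpace("F15", ("age", "SSHO2D")),
        FeatureSpace("F16", ("age", "dccs2D", "psm2D", "dccs_rt", "psm_rt")),
    )
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    name: str
    grid: dict[str, list]

    def make_estimator(self, seed: int | None = 0):
        if self.name == "SVC":
            return SVC(kernel="rbf", probability=True, random_state=seed)
        if self.name == "LRG":
            return LogisticRegression(penalty="l2", solver="lbfgs", max_iter=5000)
        if self.name == "Tree":
            return DecisionTreeClassifier(random_state=seed)
        if self.name == "KNN":
            return KNeighborsClassifier()
        if self.name == "RF":
            return RandomForestClassifier(random_state=seed)
        if self.name == "GB":
            return GradientBoostingClassifier(random_state=seed)
        if self.name == "ANN":
            return MLPClassifier(max_iter=1000, random_state=seed)
        raise ValueError(f"unknown model {self.name!r}")


#: Benchmark model zoo with its fixed hyperparameter grids.
MODEL_ZOO: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in (
        ModelSpec("SVC", {"C": [1, 10, 50, 100]}),
        ModelSpec("LRG", {"C": list(np.geomspace(0.01, 5, 20))}),
        ModelSpec("Tree", {"max_depth": [3, 7, 12, 16, 21, 25, 30]}),
        ModelSpec("KNN", {"n_neighbors": [3, 5, 7, 9]}),
        ModelSpec("RF", {"n_estimators": list(np.linspace(10, 500, 10).astype(int))}),
        ModelSpec("GB", {"n_estimators": [10, 30, 50]}),
        ModelSpec(
            "ANN",
            {
                "hidden_layer_sizes": [(150, 100, 50), (120, 80, 40)],
                "activation": ["tanh", "relu"],
                "alpha": [0.01, 0.3, 1],
                "solver": ["sgd", "adam"],
                "learning_rate": ["constant", "adaptive"],
            },
        ),
    )
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with *impaired* (label 1) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, predictions: np.ndarray, labels: np.ndarray) -> "ConfusionMatrix":
        p = np.asarray(predictions).astype(int)
        y = np.asarray(labels).astype(int)
        if p.shape != y.shape:
            raise ValueError("predictions and labels differ in length")
        return cls(
            tp=int(np.sum((p == 1) & (y == 1))),
            fp=int(np.sum((p == 1) & (y == 0))),
            fn=int(np.sum((p == 0) & (y == 1))),
            tn=int(np.sum((p == 0) & (y == 0))),
        )


@dataclass
class EvalResult:
    """Confusion-matrix metrics; undefined ratios are nan, never 0."""

    confusion: ConfusionMatrix
    precision: float
    recall: float
    accuracy: float
    specificity: float
    f_score: float
    qwk: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "f_score": self.f_score,
            "qwk": self.qwk,
            "auc": self.auc,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(
    predictions: np.ndarray,
    labels: np.ndarray,
    scores: np.ndarray | None = None,
    average: str = "binary",
) -> EvalResult:
    """Confusion-matrix metric suite for one prediction vector.

    ``average="binary"`` (default) computes per-positive-class
    precision/recall/F; ``average="weighted"`` computes the
    class-frequency-weighted averages some reports use (under which
    precision = recall = accuracy for binary data).  QWK is Cohen's
    kappa with quadratic weights (equal to unweighted kappa for binary
    labels).  AUC requires ``scores`` and both classes present; ties
    count one half.
    """
    cm = ConfusionMatrix.from_predictions(predictions, labels)
    if average == "binary":
        precision = _ratio(cm.tp, cm.tp + cm.fp)
        recall = _ratio(cm.tp, cm.tp + cm.fn)
    elif average == "weighted":
        prec_pos = _ratio(cm.tp, cm.tp + cm.fp)
        prec_neg = _ratio(cm.tn, cm.tn + cm.fn)
        rec_pos = _ratio(cm.tp, cm.tp + cm.fn)
        rec_neg = _ratio(cm.tn, cm.tn + cm.fp)
        n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
        precision = (prec_pos * n_pos + prec_neg * n_neg) / cm.n
        recall = (rec_pos * n_pos + rec_neg * n_neg) / cm.n
    else:
        raise ValueError(f"unknown average {average!r}")
    accuracy = _ratio(cm.tp + cm.tn, cm.n)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f_score = float("nan")
    else:
        f_score = 2 * precision * recall / (precision + recall)
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    qwk = float(cohen_kappa_score(y, p, weights="quadratic")) if len(set(y) | set(p)) > 1 else float("nan")
    if scores is not None and len(set(y)) > 1:
        auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    else:
        auc = float("nan")
    return EvalResult(cm, precision, recall, accuracy, specificity, f_score, qwk, auc)


def split_cohort(n: int, ratio: float, seed: int, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split (test fraction = 1 - ratio).

    The test side gets ceil(n * (1 - ratio)) rows, matching the 68/18
    split of an 86-patient cohort at ratio 0.8.  Disjoint, exhaustive,
    reproducible by seed; raises if a class would be absent from either
    side.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    y = np.asarray(labels)
    if y.shape[0] != n:
        raise ValueError("labels length must be n")
    idx = np.arange(n)
    train, test = train_test_split(
        idx, test_size=1.0 - ratio, stratify=y, random_state=seed, shuffle=True
    )
    for side, name in ((train, "train"), (test, "test")):
        if len(np.unique(y[side])) < 2:
            raise ValueError(f"stratified split left a single class in the {name} side")
    return np.sort(train), np.sort(test)


def build_feature_matrix(scores: pd.DataFrame, space: FeatureSpace | str) -> pd.DataFrame:
    """Select and order the columns of a feature space.

    Categorical demographics must already be integer-coded in the score
    bundle (see :func:`cogscreen.synthetic.encode_demographics`).
    Raises on a missing feature, naming it and the space.
    """
    if isinstance(space, str):
        space = FEATURE_SPACES[space]
    missing = [f for f in space.features if f not in scores.columns]
    if missing:
        raise ValueError(f"feature space {space.name}: missing features {missing}")
    X = scores[list(space.features)]
    if not all(np.issubdtype(dt, np.number) for dt in X.dtypes):
        bad = [c for c, dt in X.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"feature space {space.name}: non-numeric columns {bad}")
    return X.copy()


def _forest_grid_search(spec: ModelSpec, X: np.ndarray, y: np.ndarray, folds: int, seed: int):
    """Exact n_estimators grid search from one max-size forest per fold.

    A forest's first k trees are identical to a separately fitted
    k-tree forest with the same random_state (tree seeds are drawn
    sequentially), so CV accuracy for every tree count in the grid can
    be read off cumulative tree-probability averages of a single fit.
    Produces the same CV scores and grid-order tie-breaking as the
    generic search, at a fraction of the cost.
    """
    grid = list(spec.grid["n_estimators"])
    k_max = max(grid)
    cv = StratifiedKFold(n_splits=folds)
    fold_acc = np.zeros((folds, len(grid)))
    for f, (tr, va) in enumerate(cv.split(X, y)):
        forest = RandomForestClassifier(n_estimators=k_max, random_state=seed).fit(X[tr], y[tr])
        tree_proba = np.stack([t.predict_proba(X[va]) for t in forest.estimators_])
        # trees see the classes present in their bootstrap sample of the
        # fold; map each tree's columns onto the forest's class set
        if tree_proba.shape[2] != len(forest.classes_):  # pragma: no cover
            raise RuntimeError("tree class mismatch")
        cum = np.cumsum(tree_proba, axis=0)
        for g, k in enumerate(grid):
            pred = forest.classes_[np.argmax(cum[k - 1], axis=1)]
            fold_acc[f, g] = np.mean(pred == y[va])
    mean_acc = fold_acc.mean(axis=0)
    best_k = grid[int(np.argmax(mean_acc))]
    refit = RandomForestClassifier(n_estimators=best_k, random_state=seed).fit(X, y)
    refit.best_params_ = {"n_estimators": best_k}
    refit.cv_mean_accuracy_ = dict(zip(grid, mean_acc))
    return refit


def grid_search_train(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    folds: int = 5,
    seed: int = 0,
):
    """Stratified k-fold grid search on the training set.

    Every grid point is scored by mean CV accuracy; ties break in grid
    order; the winner is refit on the full training set.  Returns the
    fitted estimator (``best_params_`` exposed on the returned object).
    The random-forest tree-count grid uses an exact shared-forest
    shortcut (see :func:`_forest_grid_search`); all other specs go
    through :class:`~sklearn.model_selection.GridSearchCV`.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contain a single class")
    if spec.name == "RF" and set(spec.grid) == {"n_estimators"}:
        return _forest_grid_search(spec, X_train, y_train, folds, seed)
    gs = GridSearchCV(
        spec.make_estimator(seed),
        spec.grid,
        cv=folds,
        scoring="accuracy",
        n_jobs=None,
        refit=True,
    )
    gs.fit(X_train, y_train)
    return gs


def _prediction_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


@dataclass
class BootstrapSummary:
    """Mean/SD of each metric over bootstrap replications."""

    means: dict[str, float]
    sds: dict[str, float]
    skipped: dict[str, int]
    n_replications: int
    seed: int
    replications: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"Bootstrap evaluation: {self.n_replications} replications (seed {self.seed})"]
        lines.append(f"  {'metric':>12}  {'mean':>7}  {'sd':>7}  {'skipped':>7}")
        for m in self.means:
            lines.append(
                f"  {m:>12}  {self.means[m]:>7.3f}  {self.sds[m]:>7.3f}  {self.skipped[m]:>7d}"
            )
        return "\n".join(lines)


def bootstrap_evaluate(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec,
    B: int = 100,
    seed: int = 0,
    ratio: float = 0.8,
    folds: int = 5,
) -> BootstrapSummary:
    """B rounds of resample-with-replacement bootstrap evaluation.

    Each round: draw n rows with replacement, stratified 80/20 split of
    the resample, grid-search-train on the 80%, evaluate on the 20%.
    Metric means/SDs are over rounds with the metric defined; skip
    counts are reported per metric.
    """
    if B < 1:
        raise ValueError("need B >= 1 replications")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(B):
        while True:
            take = rng.integers(0, n, size=n)
            yb = y[take]
            # a resample must contain both classes to be splittable
            if 0 < yb.sum() < n:
                break
        Xb = X[take]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        train, test = split_cohort(n, ratio, rep_seed, yb)
        est = grid_search_train(spec, Xb[train], yb[train], folds=folds, seed=rep_seed)
        preds = est.predict(Xb[test])
        scores = _prediction_scores(est, Xb[test])
        res = evaluate(preds, yb[test], scores=scores)
        rows.append(res.as_dict())
    reps = pd.DataFrame(rows)
    means = {m: float(reps[m].mean()) for m in reps.columns}
    sds = {m: float(reps[m].std(ddof=1)) if reps[m].notna().sum() > 1 else 0.0 for m in reps.columns}
    skipped = {m: int(reps[m].isna().sum()) for m in reps.columns}
    return BootstrapSummary(means, sds, skipped, B, seed, reps)


def kmeans_elbow(
    data: np.ndarray, k_max: int = 10, seed: int = 0, chosen_k: int = 3
) -> tuple[pd.Series, np.ndarray]:
    """Inertia for k = 1..k_max plus cluster labels at ``chosen_k``.

    Inertia is the within-cluster sum of squared distances to the
    nearest center; it is non-increasing in k (each run uses multiple
    restarts to avoid poor local optima).
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] < k_max:
        raise ValueError("need at least k_max points")
    inertia = {}
    labels = None
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(X)
        inertia[k] = float(km.inertia_)
        if k == chosen_k:
            labels = km.labels_.copy()
    return pd.Series(inertia, name="inertia"), labels
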