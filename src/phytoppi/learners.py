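"""The two classifier branches and their evaluation.

The sequence branch is a radial-kernel SVM over 420-dimensional pair
auto-covariance vectors (classifier plus epsilon/nu regression variants
whose outputs are thresholded at 0.5 for binary use).  The functional
branch is a random forest over 8 features (4 co-expression + 3
association scores + phylogenetic-profile similarity) or 4 features when
co-expression is unavailable; its probability is the fraction of trees
voting for interaction, and feature importances are reported as mean
decrease of accuracy (MDA, seeded permutation) and mean decrease of Gini
importance (MDGI).

Evaluation uses nested cross-validation: hyperparameters are selected by
an inner grid search on the training folds only, so held-out folds never
influence model choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR, NuSVR

#: Published operating points for the sequence SVM on the two negative schemes.
DEFAULT_SVM_HYPER = {
    "loc": {"log2_C": 5.0, "log2_gamma": -1.0},
    "rand": {"log2_C": 1.0, "log2_gamma": 1.0},
}

#: Inner-search grid: log2 C over -5..15, log2 gamma over -15..3, step 2.
DEFAULT_SVM_GRID = {
    "log2_C": list(range(-5, 16, 2)),
    "log2_gamma": list(range(-15, 4, 2)),
}

RF_FEATURES_8 = (
    "mr_microarray", "pcc_microarray", "mr_rnaseq", "pcc_rnaseq",
    "ias", "cas", "pas", "profile_similarity",
)
RF_FEATURES_4 = ("ias", "cas", "pas", "profile_similarity")

DEFAULT_RF_TREES = 500
MDA_REPEATS = 10


@dataclass
class SVMHyperparams:
    log2_C: float
    log2_gamma: float
    variant: str = "classifier"  # classifier | epsilon_regression | nu_regression
    epsilon: float = 0.1
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.variant == "nu_regression" and not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        if self.variant not in {"classifier", "epsilon_regression", "nu_regression"}:
            raise ValueError(f"unknown SVM variant {self.variant!r}")


@dataclass
class FeatureImportance:
    feature_names: tuple[str, ...]
    mda: np.ndarray
    mdgi: np.ndarray
    permutation_seed: int

    def ranking(self, metric: str = "mda") -> list[str]:
        vals = self.mda if metric == "mda" else self.mdgi
        order = np.argsort(vals)[::-1]
        return [self.feature_names[i] for i in order]


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else float("nan")


@dataclass
class TrainedModelBundle:
    """A fitted branch model with its training-fold scaler and metadata."""

    kind: str  # e.g. svm_loc | svm_rand | rf_loc | rf_rand
    pipeline: Pipeline
    hyperparams: dict
    feature_names: tuple[str, ...]
    seed: int = 0
    importance: FeatureImportance | None = None

    def decide(self, X: np.ndarray) -> np.ndarray:
        """Binary interaction decisions for a feature matrix."""
        if self.kind.startswith("svm") and self.hyperparams.get("variant", "classifier") != "classifier":
            return self.pipeline.predict(X) > 0.5
        if self.kind.startswith("rf"):
            return self.predict_probability(X) > 0.5
        return self.pipeline.predict(X).astype(bool)

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """Interaction score: tree vote fraction (RF), regression output or
        decision-function value (SVM)."""
        if self.kind.startswith("rf"):
            return rf_vote_probability(self.pipeline, X)
        est = self.pipeline
        if hasattr(est[-1], "decision_function"):
            return est.decision_function(X)
        return est.predict(X)


def _check_finite(X: np.ndarray, feature_names: Sequence[str] | None = None) -> None:
    X = np.asarray(X, dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        col = int(np.argwhere(bad)[0][1])
        name = feature_names[col] if feature_names else f"column {col}"
        raise ValueError(f"non-finite feature value in {name}")


def make_svm(hyper: SVMHyperparams) -> Pipeline:
    """Scaler + radial-kernel SVM pipeline for the given hyperparameters."""
    C = 2.0 ** hyper.log2_C
    gamma = 2.0 ** hyper.log2_gamma
    if hyper.variant == "classifier":
        est = SVC(kernel="rbf", C=C, gamma=gamma)
    elif hyper.variant == "epsilon_regression":
        est = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=hyper.epsilon)
    else:
        est = NuSVR(kernel="rbf", C=C, gamma=gamma, nu=hyper.nu)
    return Pipeline([("scaler", StandardScaler()), ("svm", est)])


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    hyper: SVMHyperparams,
    kind: str = "svm_loc",
    feature_names: tuple[str, ...] | None = None,
) -> TrainedModelBundle:
    """Fit the sequence-branch SVM (features are z-scored inside the pipeline)."""
    X = np.asarray(X, dtype=float)
    _check_finite(X, feature_names)
    pipe = make_svm(hyper)
    pipe.fit(X, np.asarray(y))
    names = feature_names or tuple(f"ac_{i}" for i in range(X.shape[1]))
    return TrainedModelBundle(
        kind, pipe, hyperparams=vars(hyper).copy(), feature_names=names
    )


def rf_vote_probability(pipeline: Pipeline, X: np.ndarray) -> np.ndarray:
    """Fraction of decision trees voting for the positive class."""
    forest: RandomForestClassifier = pipeline[-1]
    Xt = pipeline[:-1].transform(X) if len(pipeline) > 1 else np.asarray(X)
    votes = np.stack([tree.predict(Xt) for tree in forest.estimators_])
    return votes.mean(axis=0)


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...],
    n_trees: int = DEFAULT_RF_TREES,
    seed: int = 0,
    kind: str = "rf_rand",
    importance_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModelBundle:
    """Fit the functional-branch random forest and compute importances.

    MDA is the mean accuracy decrease over ``MDA_REPEATS`` seeded
    permutations of each feature on held-out data (``importance_data``,
    defaulting to the training set); MDGI is the impurity-based
    importance from the forest's split bookkeeping.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names must match the feature matrix width")
    _check_finite(X, feature_names)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    pipe = Pipeline([("rf", forest)])
    pipe.fit(X, np.asarray(y))
    X_imp, y_imp = importance_data if importance_data is not None else (X, y)
    perm = permutation_importance(
        forest, X_imp, y_imp, n_repeats=MDA_REPEATS,
        random_state=seed, scoring="accuracy",
    )
    imp = FeatureImportance(
        tuple(feature_names),
        mda=perm.importances_mean,
        mdgi=forest.feature_importances_,
        permutation_seed=seed,
    )
    return TrainedModelBundle(
        kind, pipe, hyperparams={"n_trees": n_trees}, feature_names=tuple(feature_names),
        seed=seed, importance=imp,
    )


def evaluate(
    predictions: np.ndarray,
    labels: np.ndarray,
    scores: np.ndarray | None = None,
) -> EvalReport:
    """Confusion counts, derived metrics and (when scores are given) ROC/AUC.

    AUC is the trapezoid area under the ROC curve; it is left NaN when
    the labels contain a single class.
    """
    pred = np.asarray(predictions).astype(bool)
    lab = np.asarray(labels).astype(bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    report = EvalReport(
        tp=int(np.sum(pred & lab)),
        fp=int(np.sum(pred & ~lab)),
        tn=int(np.sum(~pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
    )
    if scores is not None and 0 < lab.sum() < lab.size:
        fpr, tpr, _ = roc_curve(lab.astype(int), np.asarray(scores, dtype=float))
        report.roc = list(zip(fpr.tolist(), tpr.tolist()))
        report.auc = float(np.trapezoid(tpr, fpr))
    return report


@dataclass
class FoldResult:
    fold: int
    report: EvalReport
    selected_params: dict


def _svm_estimator_grid(variant: str, grid: dict) -> tuple[Pipeline, dict]:
    base = make_svm(SVMHyperparams(0.0, 0.0, variant=variant))
    param_grid = {
        "svm__C": [2.0 ** v for v in grid["log2_C"]],
        "svm__gamma": [2.0 ** v for v in grid["log2_gamma"]],
    }
    return base, param_grid


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    learner: str = "svm",
    grid: dict | None = None,
    inner_k: int = 5,
    seed: int = 0,
    variant: str = "classifier",
) -> list[FoldResult]:
    """Nested cross-validation over pre-assigned outer folds.

    For each outer fold an inner ``inner_k``-fold grid search on the
    remaining folds selects hyperparameters (maximizing accuracy); the
    model is refit on those folds and evaluated once on the held-out
    fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = np.asarray(folds)
    results = []
    for fold in sorted(set(folds.tolist())):
        test = folds == fold
        train = ~test
        if len(set(y[test].tolist())) < 2 or len(set(y[train].tolist())) < 2:
            raise ValueError(f"fold {fold} is single-class; cannot evaluate")
        if learner == "svm":
            est, param_grid = _svm_estimator_grid(variant, grid or DEFAULT_SVM_GRID)
        elif learner == "rf":
            est = Pipeline([
                ("rf", RandomForestClassifier(random_state=seed))
            ])
            g = grid or {"n_estimators": [100, DEFAULT_RF_TREES]}
            param_grid = {f"rf__{k}": v for k, v in g.items()}
        else:
            raise ValueError(f"unknown learner {learner!r}")
        search = GridSearchCV(
            est, param_grid, cv=inner_k, scoring="accuracy", n_jobs=None
        )
        search.fit(X[train], y[train])
        best = search.best_estimator_
        pred = best.predict(X[test]).astype(bool)
        if hasattr(best[-1], "decision_function"):
            scores = best.decision_function(X[test])
        elif hasattr(best[-1], "predict_proba"):
            scores = best.predict_proba(X[test])[:, 1]
        else:
            scores = best.predict(X[test])
        results.append(
            FoldResult(int(fold), evaluate(pred, y[test], scores), dict(search.best_params_))
        )
    return results


def pooled_report(results: Sequence[FoldResult]) -> EvalReport:
    """Sum the confusion counts of per-fold reports into one report."""
    return EvalReport(
        tp=sum(r.report.tp for r in results),
        fp=sum(r.report.fp for r in results),
        tn=sum(r.report.tn for r in results),
        fn=sum(r.report.fn for r in results),
    )
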