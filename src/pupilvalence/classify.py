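"""Leakage-safe grouped cross-validation with fold-internal SMOTE.

Trials are grouped by participant: a participant's trials never appear in
both the training and the test side of a fold.  SMOTE oversampling, when
enabled, is applied inside each training fold only — never to the full
dataset before partitioning — and every synthetic row carries a provenance
tag pointing at the original training row it interpolates from.

Eleven classifier identifiers are accepted: logistic regression, SVM,
decision tree, random forest, k-NN, XGBoost, LightGBM, easy ensemble,
balanced random forest, RUSBoost, and a plain bagging ensemble.  All use
default hyperparameters (no tuning) with the run seed pinned.  The three
imbalance-aware ensembles are implemented here as random-undersampling
ensembles over scikit-learn base learners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .metrics import compute_metrics, mean_roc
from .types import CLASSIFIER_NAMES, MetricSet, RunConfig, ValidationError

__all__ = [
    "FoldPlan",
    "group_kfold_split",
    "smote_oversample",
    "make_classifier",
    "fit_predict_fold",
    "run_cv",
    "grid_run",
    "feature_attribution",
    "CVResult",
    "GridCell",
    "AttributionReport",
]

logger = logging.getLogger(__name__)

#: classifiers that see z-scored features (fit on the training fold only)
_SCALE_SENSITIVE = {"logistic", "svm", "knn"}


# ---------------------------------------------------------------------------
# fold planning


@dataclass
class FoldPlan:
    """Participant-level k-fold partition."""

    folds: list  # list of (train_participants: frozenset, test_participants: frozenset)

    def __post_init__(self) -> None:
        seen = set()
        for train, test in self.folds:
            if train & test:
                raise ValidationError("train and test participants overlap")
            if seen & test:
                raise ValidationError("participant in more than one test set")
            seen |= test


def group_kfold_split(records: pd.DataFrame, k: int, seed: int) -> FoldPlan:
    """Partition participants into k near-equal groups by seeded shuffle."""
    participants = np.array(sorted(records["participant_id"].unique()))
    if participants.size < k:
        raise ValidationError(
            f"need at least {k} participants, got {participants.size}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(participants)
    folds = []
    for test in np.array_split(participants, k):
        test_set = frozenset(test.tolist())
        train_set = frozenset(participants.tolist()) - test_set
        folds.append((train_set, test_set))
    return FoldPlan(folds=folds)


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(X, y, k_neighbors: int, seed: int):
    """Balance classes by minority-class interpolation.

    Each synthetic sample is ``x + u * (x_nn - x)`` for a minority row x,
    one of its ``k_neighbors`` nearest minority neighbors (Euclidean), and
    u uniform on [0, 1].  Returns ``(X_aug, y_aug, source_idx, is_synthetic)``
    where ``source_idx[i]`` is the input row a synthetic row derives from
    (its own index for original rows).  Deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError("SMOTE requires exactly two classes present")
    n = len(y)
    source_idx = np.arange(n)
    is_synth = np.zeros(n, dtype=bool)
    if counts[0] == counts[1]:
        return X, y, source_idx, is_synth
    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(y == minority)
    n_needed = int(abs(counts[0] - counts[1]))
    if len(min_idx) <= k_neighbors:
        raise ValidationError(
            f"minority class has {len(min_idx)} samples; needs more than "
            f"k_neighbors={k_neighbors} (try a smaller k)"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X[min_idx])
    _, neigh = nn.kneighbors(X[min_idx])  # column 0 is the point itself
    new_rows, new_src = [], []
    bases = rng.choice(len(min_idx), size=n_needed, replace=True)
    picks = rng.integers(1, k_neighbors + 1, size=n_needed)
    us = rng.uniform(0.0, 1.0, size=n_needed)
    for b, p, u in zip(bases, picks, us):
        xi = X[min_idx[b]]
        xn = X[min_idx[neigh[b, p]]]
        new_rows.append(xi + u * (xn - xi))
        new_src.append(min_idx[b])
    X_aug = np.vstack([X, np.array(new_rows)])
    y_aug = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    source_idx = np.concatenate([source_idx, np.array(new_src)])
    is_synth = np.concatenate([is_synth, np.ones(n_needed, dtype=bool)])
    return X_aug, y_aug, source_idx, is_synth


# ---------------------------------------------------------------------------
# classifiers


class _UndersampleEnsemble:
    """Bagging over balanced random undersamples of the majority class."""

    def __init__(self, base, n_estimators: int, seed: int, bootstrap: bool = False):
        self.base = base
        self.n_estimators = n_estimators
        self.seed = seed
        self.bootstrap = bootstrap

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.seed)
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        n_min = min(counts.values())
        self.estimators_ = []
        for _ in range(self.n_estimators):
            idx = []
            for c in self.classes_:
                pool = np.flatnonzero(y == c)
                take = rng.choice(pool, size=n_min, replace=self.bootstrap)
                idx.append(take)
            idx = np.concatenate(idx)
            est = clone(self.base)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
            est.fit(X[idx], y[idx])
            self.estimators_.append(est)
        return self

    def predict_proba(self, X):
        probs = np.mean([e.predict_proba(X) for e in self.estimators_], axis=0)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _RUSBoost:
    """AdaBoost (SAMME) with random undersampling before each boosting round."""

    def __init__(self, n_estimators: int = 50, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValidationError("RUSBoost implemented for binary problems")
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)
        n = len(y)
        w = np.full(n, 1.0 / n)
        rng = np.random.default_rng(self.seed)
        n_min = min(int(np.sum(ypm > 0)), int(np.sum(ypm < 0)))
        self.estimators_, self.alphas_ = [], []
        for _ in range(self.n_estimators):
            idx = []
            for sign in (1.0, -1.0):
                pool = np.flatnonzero(ypm == sign)
                p = w[pool] / w[pool].sum()
                idx.append(rng.choice(pool, size=n_min, replace=True, p=p))
            idx = np.concatenate(idx)
            stump = DecisionTreeClassifier(
                max_depth=1, random_state=int(rng.integers(0, 2**31 - 1))
            )
            stump.fit(X[idx], ypm[idx])
            pred = stump.predict(X)
            err = float(np.sum(w * (pred != ypm)))
            err = min(max(err, 1e-10), 1 - 1e-10)
            alpha = 0.5 * np.log((1 - err) / err)
            w = w * np.exp(-alpha * ypm * pred)
            w /= w.sum()
            self.estimators_.append(stump)
            self.alphas_.append(alpha)
            if err >= 0.5:
                break
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        agg = np.zeros(len(X))
        for est, a in zip(self.estimators_, self.alphas_):
            agg += a * est.predict(X)
        return agg

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1],
                        self.classes_[0])


def make_classifier(name: str, seed: int = 1004):
    """Instantiate one of the accepted classifiers with default settings."""
    if name not in CLASSIFIER_NAMES:
        raise ValidationError(
            f"unknown classifier {name!r}; accepted: {CLASSIFIER_NAMES}"
        )
    if name == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif name == "svm":
        clf = SVC(random_state=seed)  # scores via decision_function
    elif name == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif name == "random_forest":
        clf = RandomForestClassifier(random_state=seed)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif name == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    elif name == "lightgbm":
        from lightgbm import LGBMClassifier

        clf = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    elif name == "easy_ensemble":
        clf = _UndersampleEnsemble(
            AdaBoostClassifier(n_estimators=10), n_estimators=10, seed=seed
        )
    elif name == "balanced_random_forest":
        clf = _UndersampleEnsemble(
            DecisionTreeClassifier(max_features="sqrt"),
            n_estimators=100,
            seed=seed,
            bootstrap=True,
        )
    elif name == "rusboost":
        clf = _RUSBoost(n_estimators=50, seed=seed)
    else:  # bagging
        clf = BaggingClassifier(random_state=seed)
    if name in _SCALE_SENSITIVE:
        clf = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def _scores_of(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos_col = int(np.argmax(model.classes_ == 1)) if hasattr(
            model, "classes_"
        ) else 1
        return np.asarray(proba[:, pos_col], dtype=float)
    return np.asarray(model.decision_function(X), dtype=float)


def fit_predict_fold(
    X_train, y_train, X_test, classifier_name: str, seed: int = 1004
):
    """Fit one classifier on a training fold and score the test fold.

    ``y`` is binary with 1 = positive valence.  Returns (predicted labels,
    continuous scores, fitted model).  Raises on a single-class training
    fold or an unknown classifier name.
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValidationError("training fold contains a single class")
    model = make_classifier(classifier_name, seed)
    model.fit(np.asarray(X_train, dtype=float), y_train)
    X_test = np.asarray(X_test, dtype=float)
    return model.predict(X_test), _scores_of(model, X_test), model


# ---------------------------------------------------------------------------
# cross-validation runs


@dataclass
class CVResult:
    per_fold: list  # MetricSet per fold
    mean: dict
    sd: dict
    fold_pairs: list = field(default_factory=list)  # (y_true binary, scores)
    fold_plan: FoldPlan | None = None

    @classmethod
    def from_folds(cls, per_fold, fold_pairs=None, fold_plan=None) -> "CVResult":
        mean, sd = {}, {}
        for name in MetricSet.METRIC_NAMES:
            vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
            mean[name] = float(vals.mean())
            sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return cls(per_fold=list(per_fold), mean=mean, sd=sd,
                   fold_pairs=fold_pairs or [], fold_plan=fold_plan)


def _design(records: pd.DataFrame):
    X = records[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = (records["valence"].to_numpy() == "positive").astype(int)
    return X, y


def run_cv(records: pd.DataFrame, config: RunConfig) -> CVResult:
    """Grouped k-fold cross-validation of one classifier configuration.

    SMOTE (when ``config.smote_k_neighbors`` is set) runs on each training
    fold after the participant split, never on the pooled data; test folds
    are evaluated untouched.  A fold whose test set has a single class gets
    flagged metrics but is retained in the average.
    """
    plan = group_kfold_split(records, config.cv_folds, config.random_seed)
    X, y = _design(records)
    pids = records["participant_id"].to_numpy()
    per_fold, fold_pairs = [], []
    for train_p, test_p in plan.folds:
        tr = np.isin(pids, list(train_p))
        te = np.isin(pids, list(test_p))
        X_tr, y_tr = X[tr], y[tr]
        if config.smote_k_neighbors is not None and np.unique(y_tr).size == 2:
            X_tr, y_tr, _, _ = smote_oversample(
                X_tr, y_tr, config.smote_k_neighbors, config.random_seed
            )
        pred, scores, _ = fit_predict_fold(
            X_tr, y_tr, X[te], config.classifier_name, config.random_seed
        )
        per_fold.append(compute_metrics(y[te], pred, scores, positive_class=1))
        fold_pairs.append((y[te], scores))
    return CVResult.from_folds(per_fold, fold_pairs, plan)


@dataclass
class GridCell:
    arousal_level: str
    sf_level: int
    n_samples: int
    class_counts: dict
    results: pd.DataFrame  # one row per configuration
    best_by_auc: dict
    best_by_p4: dict


def grid_run(
    records: pd.DataFrame,
    config: RunConfig,
    classifiers=None,
    smote_values=(None, 1, 2, 3, 4, 5),
    folds_values=(3, 5, 7),
) -> tuple[list[GridCell], list[tuple[str, int]], pd.DataFrame]:
    """Stratified sweep over arousal x SF cells and configurations.

    For each non-empty cell, every classifier x SMOTE-k x fold-count
    configuration is cross-validated; the per-cell best configuration is
    recorded twice — by mean AUC and by mean P4, the two selection
    conventions used for tables and heatmaps respectively.  Cells with a
    missing class, or with fewer samples per class than the smallest fold
    count, are reported absent rather than imputed.

    Returns (cells, absent cell keys, long results table).
    """
    classifiers = list(classifiers or CLASSIFIER_NAMES)
    cells, absent, all_rows = [], [], []
    for (arousal, sf), sub in records.groupby(["arousal_level", "sf_level"]):
        counts = sub["valence"].value_counts().to_dict()
        min_folds = min(folds_values)
        if len(counts) < 2 or min(counts.values()) < min_folds:
            absent.append((str(arousal), int(sf)))
            continue
        rows = []
        for k_folds in folds_values:
            if sub["participant_id"].nunique() < k_folds:
                continue
            for smote_k in smote_values:
                for name in classifiers:
                    cfg = RunConfig(
                        random_seed=config.random_seed,
                        cv_folds=k_folds,
                        smote_k_neighbors=smote_k,
                        classifier_name=name,
                        frames_per_trial=config.frames_per_trial,
                    )
                    try:
                        res = run_cv(sub, cfg)
                    except ValidationError as exc:
                        logger.info(
                            "cell (%s, sf=%s) cfg (%s, k=%s, folds=%d) skipped: %s",
                            arousal, sf, name, smote_k, k_folds, exc,
                        )
                        continue
                    row = {
                        "arousal_level": str(arousal),
                        "sf_level": int(sf),
                        "cv_folds": k_folds,
                        "k_neighbors": 0 if smote_k is None else smote_k,
                        "model": name,
                    }
                    for m in MetricSet.METRIC_NAMES:
                        row[f"{m}_mean"] = res.mean[m]
                        row[f"{m}_sd"] = res.sd[m]
                    rows.append(row)
        if not rows:
            absent.append((str(arousal), int(sf)))
            continue
        cell_df = pd.DataFrame(rows)
        all_rows.append(cell_df)
        cells.append(
            GridCell(
                arousal_level=str(arousal),
                sf_level=int(sf),
                n_samples=len(sub),
                class_counts=counts,
                results=cell_df,
                best_by_auc=cell_df.loc[cell_df["auc_mean"].idxmax()].to_dict(),
                best_by_p4=cell_df.loc[cell_df["p4_mean"].idxmax()].to_dict(),
            )
        )
    table = (
        pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    )
    return cells, absent, table


# ---------------------------------------------------------------------------
# feature attribution


@dataclass
class AttributionReport:
    method: str  # "linear" or "permutation"
    feature_names: list
    mean_abs: np.ndarray
    ranking: list  # feature names, descending mean |contribution|
    per_sample: np.ndarray | None = None  # (n_samples, n_features) or None


def feature_attribution(
    model, X, feature_names=None, y=None, seed: int = 1004
) -> AttributionReport:
    """Per-feature contribution report for a fitted model.

    Linear models (a ``coef_`` attribute, possibly behind a scaling
    pipeline) get exact per-sample additive contributions
    ``coef_j * (x_j - mean(x_j))`` on the model's input scale — the Shapley
    value of a linear model under feature independence.  Other families
    fall back to seeded permutation importance (requires ``y``); only the
    per-feature magnitude is reported in that case.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    X = np.asarray(X, dtype=float)
    est, Xt = model, X
    if isinstance(model, Pipeline):
        est = model.named_steps[list(model.named_steps)[-1]]
        Xt = model[:-1].transform(X)
    if hasattr(est, "coef_"):
        coef = np.asarray(est.coef_).ravel()
        contrib = coef * (Xt - Xt.mean(axis=0))
        mean_abs = np.abs(contrib).mean(axis=0)
        method, per_sample = "linear", contrib
    else:
        if y is None:
            raise ValidationError(
                "permutation attribution needs labels; pass y for non-linear models"
            )
        imp = permutation_importance(
            model, X, np.asarray(y), n_repeats=10, random_state=seed,
            scoring="roc_auc",
        )
        mean_abs = np.abs(imp.importances_mean)
        method, per_sample = "permutation", None
    order = np.argsort(-mean_abs, kind="stable")
    return AttributionReport(
        method=method,
        feature_names=feature_names,
        mean_abs=mean_abs,
        ranking=[feature_names[i] for i in order],
        per_sample=per_sample,
    )
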