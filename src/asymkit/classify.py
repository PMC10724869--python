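"""Random-forest sex classification per (index, measure) with evaluation stats.

The classifier sees, per subject, the 34 per-ROI values of one asymmetry
index plus age (35 predictors) and predicts sex.  Evaluation follows the
confusion-matrix convention with the target on columns and the prediction
on rows, male first: the upper-left quadrant counts males predicted male.
Reported statistics: accuracy, Cohen's Kappa (chance-corrected agreement,
computed from the confusion matrix), the no-information rate (NIR — the
accuracy of always predicting the test set's majority class), and a
one-sided exact binomial test of accuracy against the NIR.  Predictor
importance is permutation-based on the held-out partition, with the
forest's impurity importance retained for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

__all__ = [
    "split_train_test",
    "train_random_forest",
    "FittedForest",
    "evaluate_model",
    "cohen_kappa",
    "nir_test",
    "kappa_band",
    "rank_predictors",
    "ClassificationSummary",
    "classify_index_table",
]

CLASSES = ("male", "female")  # male first: Fig-style upper-left = male->male


def split_train_test(X: pd.DataFrame, y: pd.Series, train_frac: float = 0.8, seed: int = 0):
    """Stratified-by-class random split; disjoint, exhaustive, seed-reproducible."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    counts = y.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need at least 2 subjects per class to split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed
    )
    for part, name in ((y_tr, "train"), (y_te, "test")):
        if part.nunique() < 2:
            raise ValueError(f"a class is absent from the {name} partition")
    return X_tr, X_te, y_tr, y_te


@dataclass
class FittedForest:
    """A trained forest plus the provenance needed to reuse it."""

    estimator: RandomForestClassifier
    predictors: list[str]
    cv_folds: int | None
    mtry_grid: tuple | None
    best_mtry: object
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[self.predictors])


def train_random_forest(
    X: pd.DataFrame,
    y: pd.Series,
    cv_folds: int = 10,
    mtry_grid: tuple | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> FittedForest:
    """Fit a bagged random forest, optionally grid-tuning ``max_features``.

    The feature-subset size per split (``mtry``) is the one tuned
    hyperparameter; when ``mtry_grid`` is given it is selected by
    ``cv_folds``-fold cross-validation on the training partition only, and
    the winning model is refit on the full training set.  Constant predictor
    columns are dropped with a warning (all-constant is an error).
    """
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = sorted(set(X.columns) - set(keep))
    if not keep:
        raise ValueError("all predictor columns are constant")
    if dropped:
        warnings.warn(f"dropping constant predictor(s): {dropped}", stacklevel=2)
    X = X[keep]

    base = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if mtry_grid:
        grid = [g for g in mtry_grid if (not isinstance(g, int)) or g <= len(keep)]
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(base, {"max_features": grid}, cv=cv, n_jobs=1)
        search.fit(X, y)
        est, best = search.best_estimator_, search.best_params_["max_features"]
    else:
        est, best = base.fit(X, y), base.max_features
    return FittedForest(
        estimator=est, predictors=keep, cv_folds=cv_folds if mtry_grid else None,
        mtry_grid=tuple(mtry_grid) if mtry_grid else None, best_mtry=best, seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation statistics


def cohen_kappa(confusion: np.ndarray) -> float:
    """Cohen's Kappa (p_o - p_e) / (1 - p_e) from a KxK count matrix."""
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e == 1.0:
        return 0.0  # degenerate marginals: no chance-corrected information
    return (p_o - p_e) / (1.0 - p_e)


def nir_test(correct: int, n_test: int, nir: float) -> float:
    """One-sided exact binomial tail P(X >= correct | n, p = NIR)."""
    if not 0 < nir < 1:
        raise ValueError("NIR must lie strictly between 0 and 1")
    if not 0 <= correct <= n_test:
        raise ValueError("correct count outside [0, n]")
    return float(stats.binomtest(correct, n_test, nir, alternative="greater").pvalue)


def kappa_band(kappa: float) -> str:
    """Conventional qualitative reading of a Kappa value (label only)."""
    if kappa < 0:
        return "worse-than-chance"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "good"
    return "very good"


@dataclass
class ClassificationSummary:
    """Confusion counts and derived statistics for one fitted model."""

    confusion: pd.DataFrame          # rows = prediction, cols = target (male first)
    accuracy: float
    kappa: float
    nir: float
    p_value: float
    row_pct: pd.DataFrame            # within-prediction percentages
    col_pct: pd.DataFrame            # within-target percentages
    importances: pd.DataFrame | None = None
    top6: list[str] = field(default_factory=list)
    split_seed: int | None = None
    cv_folds: int | None = None
    grid: tuple | None = None
    kappa_label: str = ""


def evaluate_model(model: FittedForest, X_test: pd.DataFrame, y_test: pd.Series) -> ClassificationSummary:
    """Score a fitted forest on the held-out partition."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    labels = list(CLASSES)
    counts = np.zeros((2, 2), dtype=int)
    for p, t in zip(pred, y_test):
        counts[labels.index(p), labels.index(t)] += 1
    confusion = pd.DataFrame(
        counts,
        index=pd.Index(labels, name="prediction"),
        columns=pd.Index(labels, name="target"),
    )
    n = counts.sum()
    accuracy = float(np.trace(counts)) / n
    nir = float(confusion.sum(axis=0).max()) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = confusion.div(confusion.sum(axis=1), axis=0) * 100
        col_pct = confusion.div(confusion.sum(axis=0), axis=1) * 100
    kappa = cohen_kappa(counts)
    return ClassificationSummary(
        confusion=confusion,
        accuracy=accuracy,
        kappa=kappa,
        nir=nir,
        p_value=nir_test(int(np.trace(counts)), int(n), nir),
        row_pct=row_pct,
        col_pct=col_pct,
        kappa_label=kappa_band(kappa),
    )


def rank_predictors(
    model: FittedForest,
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Permutation importance on held-out data, descending; ties break by name.

    The forest's impurity-based importance is carried along for comparison.
    Returns a frame with columns ``importance`` (permutation),
    ``impurity_importance`` and ``rank``.
    """
    result = permutation_importance(
        model.estimator, X[model.predictors], y,
        n_repeats=n_repeats, random_state=seed, n_jobs=1,
    )
    out = pd.DataFrame(
        {
            "predictor": model.predictors,
            "importance": result.importances_mean,
            "impurity_importance": model.estimator.feature_importances_,
        }
    )
    out = out.sort_values(
        ["importance", "predictor"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classify_index_table(
    index_values: pd.DataFrame,
    meta: pd.DataFrame,
    seed: int = 0,
    train_frac: float = 0.8,
    cv_folds: int = 10,
    mtry_grid: tuple | None = None,
    n_trees: int = 500,
    importance_repeats: int = 10,
) -> ClassificationSummary:
    """End-to-end split/train/evaluate/rank for one subjects-by-ROI table.

    Predictors are the 34 per-ROI index values plus age; rows with any
    undefined index value are dropped (complete-case).
    """
    common = index_values.index.intersection(meta.index)
    X = index_values.loc[common].copy()
    X["age"] = meta.loc[common, "age"]
    y = meta.loc[common, "sex"]
    ok = X.notna().all(axis=1)
    X, y = X[ok], y[ok]
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, train_frac=train_frac, seed=seed)
    model = train_random_forest(
        X_tr, y_tr, cv_folds=cv_folds, mtry_grid=mtry_grid, n_trees=n_trees, seed=seed
    )
    summary = evaluate_model(model, X_te, y_te)
    ranking = rank_predictors(model, X_te, y_te, seed=seed, n_repeats=importance_repeats)
    summary.importances = ranking
    summary.top6 = ranking["predictor"].head(6).tolist()
    summary.split_seed = seed
    summary.cv_folds = model.cv_folds
    summary.grid = model.mtry_grid
    return summary
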