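"""Supervised vesicle-class discrimination on lipid-range features.

Two morphologically distinct vesicle classes are discriminated from their
m/z 500–1,100 feature intensities by gradient-boosted trees under
stratified 3-fold validation.  Feature importance is the mean absolute
SHAP value per feature (exact tree-path SHAP, computed on the held-out
instances of each fold and averaged over folds); features with nonzero
mean |SHAP| are selected and the model is retrained on them to verify
their discriminative ability.  A 2-D t-SNE embedding with the cosine
distance is provided for visualization only, never for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold

from .cluster import wilcoxon_rank_sum
from .spectra import PeakMatrix

__all__ = [
    "ClassifierReport",
    "train_classifier",
    "shap_select",
    "retrain_on_selected",
    "embed_tsne",
    "DEFAULT_PARAMS",
]

# Fixed, logged hyperparameters: reproducibility over tuning.
DEFAULT_PARAMS = dict(
    max_depth=4,
    n_estimators=200,
    learning_rate=0.1,
    n_jobs=1,
    tree_method="hist",
)


@dataclass
class ClassifierReport:
    """Per-fold held-out performance of the two-class model."""

    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray  # 2x2, summed over folds; rows = true class
    roc_points: list[pd.DataFrame]  # per fold: fpr, tpr
    seed: int
    classes: np.ndarray
    feature_mz: np.ndarray | None = None
    # artifacts needed downstream (SHAP on held-out folds, retraining)
    models: list = field(default_factory=list, repr=False)
    fold_test_indices: list = field(default_factory=list, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": self.confusion.tolist(),
            "roc_points": [df.to_dict(orient="list") for df in self.roc_points],
            "seed": self.seed,
            "classes": [str(c) for c in self.classes],
        }


def _matrix_values(matrix) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(matrix, PeakMatrix):
        return np.asarray(matrix.values, dtype=float), matrix.feature_mz
    return np.asarray(matrix, dtype=float), None


def train_classifier(
    matrix,
    labels,
    folds: int = 3,
    seed: int = 0,
    mz_window: tuple[float, float] | None = None,
    params: dict | None = None,
) -> ClassifierReport:
    """Stratified k-fold gradient-boosted-tree classification.

    ``mz_window`` (e.g. (500, 1100) for the lipid range) restricts the
    features when the matrix carries feature m/z values.  All metrics are
    computed on held-out data only; the seed fixes both the fold split and
    the tree construction.
    """
    if isinstance(matrix, PeakMatrix) and mz_window is not None:
        matrix = matrix.restrict(*mz_window)
    X, feature_mz = _matrix_values(matrix)
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {len(classes)}: {classes}")
    if np.min(np.bincount(y)) < folds:
        raise ValueError("each class needs at least `folds` members")

    p = dict(DEFAULT_PARAMS, **(params or {}))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, rocs, models, test_idx = [], [], [], []
    conf = np.zeros((2, 2), dtype=int)
    for train, test in skf.split(X, y):
        model = xgb.XGBClassifier(random_state=seed, **p)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        prob = model.predict_proba(X[test])[:, 1]
        accs.append(float(np.mean(pred == y[test])))
        conf += confusion_matrix(y[test], pred, labels=[0, 1])
        fpr, tpr, _ = roc_curve(y[test], prob)
        rocs.append(pd.DataFrame({"fpr": fpr, "tpr": tpr}))
        models.append(model)
        test_idx.append(test)
    return ClassifierReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)),
        confusion=conf,
        roc_points=rocs,
        seed=seed,
        classes=classes,
        feature_mz=feature_mz,
        models=models,
        fold_test_indices=test_idx,
    )


def shap_values(model: xgb.XGBClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact tree-path SHAP contributions for each instance.

    Returns (contributions, base_values); contributions has one column per
    feature, and contributions.sum(axis=1) + base_value equals the model's
    raw margin for each instance (additivity).
    """
    booster = model.get_booster()
    contrib = booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)), pred_contribs=True)
    return contrib[:, :-1], contrib[:, -1]


def shap_select(
    report: ClassifierReport,
    matrix,
    labels,
) -> pd.DataFrame:
    """Rank features by mean |SHAP| over the held-out instances of each fold.

    Returns an importance table with one row per feature: mean |SHAP| (raw
    and normalized so the maximum is 1), the class with the higher mean
    intensity, a two-sided Wilcoxon rank-sum p value between the classes,
    and a ``selected`` flag (nonzero mean |SHAP|).
    """
    X, feature_mz = _matrix_values(matrix)
    if report.feature_mz is not None:
        feature_mz = report.feature_mz
    y_raw = np.asarray(labels)
    _, y = np.unique(y_raw, return_inverse=True)

    per_fold = []
    for model, test in zip(report.models, report.fold_test_indices):
        contrib, _ = shap_values(model, X[test])
        per_fold.append(np.abs(contrib).mean(axis=0))
    mean_abs = np.mean(per_fold, axis=0)
    top = mean_abs.max()
    normalized = mean_abs / top if top > 0 else mean_abs

    n_feat = X.shape[1]
    direction, pvals = [], []
    a, b = y == 0, y == 1
    for j in range(n_feat):
        direction.append(
            str(report.classes[0]) if X[a, j].mean() >= X[b, j].mean() else str(report.classes[1])
        )
        _, p = wilcoxon_rank_sum(X[a, j], X[b, j])
        pvals.append(p)
    return pd.DataFrame(
        {
            "feature": np.arange(n_feat),
            "feature_mz": feature_mz if feature_mz is not None else np.full(n_feat, np.nan),
            "mean_abs_shap": mean_abs,
            "normalized_importance": normalized,
            "higher_in": direction,
            "wilcoxon_p": pvals,
            "selected": mean_abs > 0,
        }
    )


def retrain_on_selected(
    matrix,
    labels,
    importance: pd.DataFrame,
    subset: str | np.ndarray = "selected",
    folds: int = 3,
    seed: int = 0,
    params: dict | None = None,
) -> ClassifierReport:
    """Re-run the identical training protocol on a feature subset.

    ``subset`` is either ``'selected'`` (all nonzero-|SHAP| features), or an
    explicit index array/boolean mask (e.g. the annotated subset).
    """
    X, feature_mz = _matrix_values(matrix)
    if isinstance(subset, str):
        if subset != "selected":
            raise ValueError(f"unknown subset {subset!r}")
        idx = importance.loc[importance["selected"], "feature"].to_numpy()
    else:
        idx = np.asarray(subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
    if len(idx) == 0:
        raise ValueError("feature subset is empty")
    sub = X[:, idx]
    rep = train_classifier(sub, labels, folds=folds, seed=seed, params=params)
    if feature_mz is not None:
        rep.feature_mz = np.asarray(feature_mz)[idx]
    return rep


def embed_tsne(
    matrix,
    distance: str = "cosine",
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """2-D t-SNE embedding (cosine distance by default), seed-recorded.

    Perplexity is auto-reduced with a warning when there are too few
    points.  For plotting only.
    """
    X, _ = _matrix_values(matrix)
    n = len(X)
    if n < 5:
        raise ValueError(f"need at least 5 points for an embedding, got {n}")
    max_perp = (n - 1) / 3.0
    if perplexity > max_perp:
        warnings.warn(f"perplexity reduced from {perplexity} to {max_perp:.1f} for n={n}")
        perplexity = max_perp
    ts = TSNE(
        n_components=2,
        metric=distance,
        random_state=seed,
        init="random",
        perplexity=perplexity,
    )
    return ts.fit_transform(X)
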