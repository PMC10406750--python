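"""Per-view boosted-tree classifiers with case-level leave-one-out validation.

The classifier is a stagewise additive ensemble of depth-limited regression
trees fit to the logistic loss (the LogitBoost / adaptive-logistic-regression
family), realised with scikit-learn's gradient boosting. Each image is one
training instance carrying its case's difficulty label, so a view model sees
both the left and right image of every case; at validation time all images
of the held-out case are excluded from training (case-level LOOCV) and the
case score is the median of its image scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .registry import feature_names
from .texture_features import zscore_normalize

__all__ = [
    "ModelParams",
    "SelectedFeatures",
    "train_boosted_trees",
    "predict_scores",
    "loocv_view_scores",
    "predictor_importance",
    "select_top_features",
]

POSITIVE_LABEL = "difficult"


@dataclass
class ModelParams:
    n_trees: int = 500
    max_splits_per_tree: int = 10
    learn_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.learn_rate <= 1.0:
            raise ValueError("learn_rate must be in (0, 1]")
        if self.max_splits_per_tree < 1:
            raise ValueError("max_splits_per_tree must be >= 1")


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        return (y == POSITIVE_LABEL).astype(int)
    return y.astype(int)


def train_boosted_trees(X, y, params: ModelParams) -> GradientBoostingClassifier:
    """Fit the boosted ensemble; deterministic given ``params.seed``."""
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("training labels contain a single class")
    model = GradientBoostingClassifier(
        loss="log_loss",
        n_estimators=params.n_trees,
        learning_rate=params.learn_rate,
        max_leaf_nodes=params.max_splits_per_tree + 1,
        max_depth=None,
        random_state=params.seed,
    )
    model.fit(np.asarray(X, dtype=float), yb)
    return model


def predict_scores(model: GradientBoostingClassifier, X) -> np.ndarray:
    """Probability of the difficult class: logistic link on the ensemble margin."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features_in_}, got {X.shape[1]}"
        )
    return model.predict_proba(X)[:, 1]


def predictor_importance(
    model: GradientBoostingClassifier, names: list[str] | None = None
) -> pd.Series:
    """Per-feature total split-criterion improvement divided by the tree count.

    For every internal node the weighted impurity decrease
    ``w*i(node) - w_l*i(left) - w_r*i(right)`` is credited to the split
    feature; sums are divided by the number of boosting stages. Features
    never used in a split score exactly 0.
    """
    gains = np.zeros(model.n_features_in_)
    n_trees = 0
    for stage in model.estimators_:
        for est in np.ravel(stage):
            t = est.tree_
            internal = t.children_left != -1
            node_gain = (
                t.weighted_n_node_samples * t.impurity
                - np.where(
                    internal,
                    t.weighted_n_node_samples[t.children_left] * t.impurity[t.children_left]
                    + t.weighted_n_node_samples[t.children_right] * t.impurity[t.children_right],
                    0.0,
                )
            )
            np.add.at(gains, t.feature[internal], node_gain[internal])
            n_trees += 1
    gains = np.clip(gains, 0.0, None) / n_trees
    if names is None:
        names = list(getattr(model, "feature_names_in_", range(model.n_features_in_)))
    return pd.Series(gains, index=names, name="importance")


def loocv_view_scores(
    features: pd.DataFrame,
    labels: pd.Series,
    view: str,
    params: ModelParams,
    paper_mode: bool = False,
    holdout_features: pd.DataFrame | None = None,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Case-level leave-one-out scores for one view's model.

    ``features`` holds one row per image with ``case_id`` and ``view``
    columns plus the feature columns; ``labels`` maps case_id to
    difficult/easy. For each fold, all images of one case are held out, the
    remaining images are z-scored fold-internally (or once globally when
    ``paper_mode``), the ensemble is trained, and the held-out case's score
    is the median of its image scores.

    ``holdout_features`` is a diagnostics hook: a parallel table from which
    the held-out rows are drawn instead (same index/columns), used e.g. by
    leakage canaries. Training rows always come from ``features``.

    Returns one row per case: case_id, view, score, label and the per-image
    scores (as a list) for downstream late fusion.
    """
    feature_cols = feature_cols or [c for c in feature_names() if c in features.columns]
    if not feature_cols:
        raise ValueError("no feature columns found")
    rows = features[features["view"] == view]
    rows = rows[rows["case_id"].isin(labels.index)]
    case_ids = sorted(labels.index)
    counts = rows.groupby("case_id").size()
    missing = [c for c in case_ids if counts.get(c, 0) == 0]
    if missing:
        raise ValueError(f"cases with no {view} image: {missing[:5]}")
    if len(labels.unique()) < 2:
        raise ValueError("both classes must be present")

    hold = rows if holdout_features is None else holdout_features.loc[rows.index]
    X_all = rows[feature_cols]

    def apply_norm(X, mean, sd):
        out = (X - mean) / sd.where(sd >= 1e-12, 1.0)
        out.loc[:, (sd < 1e-12).to_numpy()] = 0.0
        return out

    if paper_mode:
        X_norm, mean_g, sd_g = zscore_normalize(X_all)
    out = []
    for case in case_ids:
        test_idx = rows.index[rows["case_id"] == case]
        train_idx = rows.index[rows["case_id"] != case]
        if paper_mode:
            X_train = X_norm.loc[train_idx]
            X_test = apply_norm(hold.loc[test_idx, feature_cols], mean_g, sd_g)
        else:
            X_train, mean, sd = zscore_normalize(X_all.loc[train_idx])
            X_test = apply_norm(hold.loc[test_idx, feature_cols], mean, sd)
        y_train = rows.loc[train_idx, "case_id"].map(labels)
        model = train_boosted_trees(X_train, y_train, params)
        img_scores = predict_scores(model, X_test)
        out.append(
            {
                "case_id": case,
                "view": view,
                "score": float(np.median(img_scores)),
                "label": labels[case],
                "image_scores": [float(s) for s in img_scores],
            }
        )
    return pd.DataFrame(out)


@dataclass
class SelectedFeatures:
    names: list[str]
    mean_score: float
    mode: str


def select_top_features(
    importances: pd.Series, k: int | None = None, mode: str = "topk"
) -> SelectedFeatures:
    """Pick the most useful features by importance.

    ``topk`` keeps the k highest scores, breaking ties by position in the
    input (registry order). ``scree`` sorts descending and cuts after the
    position j >= 2 with the largest drop s_j - s_{j+1} (an explicit elbow
    heuristic standing in for a visual scree reading).
    """
    s = importances.astype(float)
    if mode == "topk":
        if k is None:
            raise ValueError("k required in topk mode")
        if not 1 <= k <= len(s):
            raise ValueError(f"k must be in 1..{len(s)}")
        order = np.argsort(-s.to_numpy(), kind="stable")[:k]
        names = [s.index[i] for i in order]
    elif mode == "scree":
        order = np.argsort(-s.to_numpy(), kind="stable")
        if len(s) < 3:
            names = [s.index[i] for i in order]
        else:
            vals = s.to_numpy()[order]
            drops = vals[:-1] - vals[1:]  # drops[idx] = s_{idx+1} - s_{idx+2}, 1-based
            j = int(np.argmax(drops[1:])) + 2  # elbow position j >= 2, keep 1..j
            names = [s.index[i] for i in order[:j]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SelectedFeatures(
        names=names, mean_score=float(s[names].mean()), mode=mode
    )
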