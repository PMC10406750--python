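"""Model evaluation: late fusion, AUC with DeLong machinery, rank tests, and
the end-to-end analysis runner.

AUC is the Mann-Whitney pair statistic (ties count 0.5). Confidence
intervals and the paired model comparison use DeLong's structural-component
estimator of the (co)variance of correlated AUCs, with a two-sided normal
test. Group comparisons (per-feature difficult vs easy, and difficulty by
breast-density group) use the Kruskal-Wallis rank test with tie correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import reader_scoring
from .modeling import ModelParams, loocv_view_scores, predictor_importance, select_top_features, train_boosted_trees
from .preprocessing import crop_to_breast, make_mask, orient_left, read_tiff
from .registry import feature_names
from .roi_extraction import largest_inscribed_square, lattice_blocks
from .texture_features import FeatureParams, extract_image_features, zscore_normalize

__all__ = [
    "AucResult",
    "DelongResult",
    "KruskalResult",
    "AnalysisConfig",
    "fuse_views",
    "auc_ci",
    "delong_test",
    "kruskal_wallis",
    "feature_significance",
    "extract_cohort_features",
    "run_full_analysis",
    "analyze_cohort",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "difficult"


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


@dataclass
class KruskalResult:
    H: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# DeLong structural components


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged)."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels01: np.ndarray):
    """AUCs and covariance matrix of k correlated AUCs (fast DeLong).

    ``scores`` is (k, n); labels01 marks positives. Returns (aucs, S) where
    S[a, b] is the estimated covariance of AUC_a and AUC_b.
    """
    pos = scores[:, labels01 == 1]
    neg = scores[:, labels01 == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for i in range(k):
        all_r = _midrank(np.concatenate([pos[i], neg[i]]))
        pos_r = _midrank(pos[i])
        neg_r = _midrank(neg[i])
        auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
        aucs[i] = auc
        v10[i] = (all_r[:m] - pos_r) / n
        v01[i] = 1.0 - (all_r[m:] - neg_r) / m
    s10 = np.cov(v10, bias=False).reshape(k, k) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01, bias=False).reshape(k, k) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    S = s10 / m + s01 / n
    return aucs, S


def _as_labels01(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        return (labels == POSITIVE_LABEL).astype(int)
    return labels.astype(int)


def auc_ci(scores, labels, alpha: float = 0.05) -> AucResult:
    """AUC with a DeLong-variance normal-approximation CI, clipped to [0, 1]."""
    y = _as_labels01(labels)
    s = np.asarray(scores, dtype=float)[None, :]
    aucs, S = _delong_components(s, y)
    se = float(np.sqrt(max(S[0, 0], 0.0)))
    zq = stats.norm.ppf(1 - alpha / 2)
    return AucResult(
        auc=float(aucs[0]),
        ci_low=float(np.clip(aucs[0] - zq * se, 0.0, 1.0)),
        ci_high=float(np.clip(aucs[0] + zq * se, 0.0, 1.0)),
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
    )


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Two-sided DeLong test for two correlated AUCs on the same cases.

    Identical (or perfectly covarying) score vectors give z = 0, p = 1
    rather than a 0/0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired (same cases, same order)")
    y = _as_labels01(labels)
    aucs, S = _delong_components(np.vstack([a, b]), y)
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var < 1e-12:
        return DelongResult(float(aucs[0]), float(aucs[1]), 0.0, 1.0)
    z = float((aucs[0] - aucs[1]) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(float(aucs[0]), float(aucs[1]), z, p)


def kruskal_wallis(values, group_labels) -> KruskalResult:
    """Kruskal-Wallis rank test with tie correction; chi-square p on k-1 df."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if np.ptp(values) == 0:  # all values identical: H = 0 by convention
        return KruskalResult(H=0.0, df=len(groups) - 1, p=1.0)
    H, p = stats.kruskal(*groups)
    return KruskalResult(H=float(H), df=len(groups) - 1, p=float(p))


def fuse_views(
    cc_scores: pd.DataFrame, mlo_scores: pd.DataFrame, mode: str = "pooled"
) -> pd.DataFrame:
    """Late fusion of the per-view models into one fused score per case.

    ``pooled`` (default): median of the pooled per-image scores from both
    view models (typically four values per case). ``case-median``: median of
    the two case-level scores, which for two values is their mean.
    """
    cc = cc_scores.set_index("case_id")
    mlo = mlo_scores.set_index("case_id")
    if set(cc.index) != set(mlo.index):
        raise ValueError("CC and MLO score tables cover different case sets")
    rows = []
    for case in sorted(cc.index):
        if mode == "pooled":
            pooled = list(cc.loc[case, "image_scores"]) + list(mlo.loc[case, "image_scores"])
        elif mode == "case-median":
            pooled = [cc.loc[case, "score"], mlo.loc[case, "score"]]
        else:
            raise ValueError(f"unknown fusion mode {mode!r}")
        rows.append(
            {
                "case_id": case,
                "view": "fused",
                "score": float(np.median(pooled)),
                "label": cc.loc[case, "label"],
                "image_scores": [float(v) for v in pooled],
            }
        )
    return pd.DataFrame(rows)


def feature_significance(
    features: pd.DataFrame,
    labels: pd.Series,
    level: str = "case",
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis comparison of difficult vs easy cases.

    ``level="case"`` averages each case's image rows first (the four views
    of one case are not independent observations); ``level="image"`` tests
    raw image rows. p-values are reported unadjusted, with a
    Benjamini-Hochberg column alongside.
    """
    feature_cols = feature_cols or [c for c in feature_names() if c in features.columns]
    df = features[features["case_id"].isin(labels.index)]
    if level == "case":
        df = df.groupby("case_id")[feature_cols].mean().reset_index()
    elif level != "image":
        raise ValueError(f"unknown level {level!r}")
    y = df["case_id"].map(labels)
    if y.nunique() < 2 or y.value_counts().min() < 2:
        raise ValueError("need >= 2 cases per class")
    rows = []
    for col in feature_cols:
        vals = df[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            res = KruskalResult(H=0.0, df=1, p=1.0)
        else:
            res = kruskal_wallis(vals, y.to_numpy())
        rows.append({"feature": col, "H": res.H, "p": res.p})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < 0.05
    ranked = out["p"].rank(method="first")
    bh = (out["p"] * len(out) / ranked).clip(upper=1.0)
    # enforce monotonicity of the BH step-up
    order = np.argsort(out["p"].to_numpy())
    adj = bh.to_numpy()[order]
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out["p_bh"] = pd.Series(adj, index=out.index[order]).sort_index()
    return out


# ---------------------------------------------------------------------------
# end-to-end analysis


@dataclass
class AnalysisConfig:
    """Settings of the full analysis run."""

    threshold: int | None = None  # None = canonical 100, auto-scaled by bit depth
    block_size: int = 214
    coverage_min: float = 0.9
    n_levels: int = 64
    model: ModelParams = field(default_factory=ModelParams)
    top_k: int = 3
    paper_mode: bool = False  # True: z-score once globally before model building
    fusion: str = "pooled"
    feature_test_level: str = "case"

    def feature_params(self) -> FeatureParams:
        return FeatureParams(
            n_levels=self.n_levels,
            block_size=self.block_size,
            coverage_min=self.coverage_min,
        )


def _preprocess_and_extract(image, config: AnalysisConfig) -> pd.Series:
    oriented = orient_left(image)
    mask = make_mask(oriented, threshold=config.threshold)
    cropped, cmask, _ = crop_to_breast(oriented, mask)
    grid = lattice_blocks(cmask.mask, config.block_size, config.coverage_min)
    square = largest_inscribed_square(cmask.mask)
    return extract_image_features(
        cropped.pixels, cmask.mask, grid, square, config.feature_params()
    )


def extract_cohort_features(images, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run preprocessing + ROI + feature extraction over an image iterable.

    Returns one row per image: case_id, view, laterality + the 34 features.
    """
    config = config or AnalysisConfig()
    rows = []
    for image in images:
        feats = _preprocess_and_extract(image, config)
        rec = {"case_id": image.case_id, "view": image.view, "laterality": image.laterality}
        rec.update(feats.to_dict())
        rows.append(rec)
    return pd.DataFrame(rows)


def analyze_cohort(
    images,
    reports: pd.DataFrame,
    bd_categories: pd.Series | dict,
    config: AnalysisConfig | None = None,
    features: pd.DataFrame | None = None,
) -> dict:
    """Full analysis on in-memory inputs; returns the evaluation report dict.

    Stages: reader scoring (collapse, difficulty, tertiles) -> feature
    extraction for difficult/easy cases -> per-view case-level LOOCV ->
    median late fusion -> AUC + DeLong comparisons -> full-data importance
    and top-k selection -> per-feature and density-group Kruskal-Wallis.
    """
    config = config or AnalysisConfig()

    collapsed = reader_scoring.collapse_ratings(reports)
    records = reader_scoring.difficulty_records(collapsed, bd_categories)
    records = reader_scoring.tertile_split(records)
    selected = reader_scoring.select_difficult_easy(records)
    labels = selected.set_index("case_id")["tertile"]

    if features is None:
        images = [im for im in images if im.case_id in set(labels.index)]
        features = extract_cohort_features(images, config)
    else:
        features = features[features["case_id"].isin(labels.index)].reset_index(drop=True)

    cc = loocv_view_scores(features, labels, "CC", config.model, config.paper_mode)
    mlo = loocv_view_scores(features, labels, "MLO", config.model, config.paper_mode)
    fused = fuse_views(cc, mlo, mode=config.fusion)

    aucs = {
        name: asdict(auc_ci(df["score"], df["label"]))
        for name, df in (("CC", cc), ("MLO", mlo), ("CC+MLO", fused))
    }
    cc_s = cc.sort_values("case_id")
    mlo_s = mlo.sort_values("case_id")
    fused_s = fused.sort_values("case_id")
    y = cc_s["label"].to_numpy()
    delong = {
        "CC_vs_fused": asdict(delong_test(cc_s["score"], fused_s["score"], y)),
        "MLO_vs_fused": asdict(delong_test(mlo_s["score"], fused_s["score"], y)),
        "CC_vs_MLO": asdict(delong_test(cc_s["score"], mlo_s["score"], y)),
    }

    # full-data per-view models for the importance profile
    cols = feature_names()
    importances = {}
    top = {}
    for view in ("CC", "MLO"):
        rows = features[features["view"] == view]
        Xn, _, _ = zscore_normalize(rows[cols])
        yv = rows["case_id"].map(labels)
        model = train_boosted_trees(Xn, yv, config.model)
        imp = predictor_importance(model, cols)
        importances[view] = imp
        sel_k = select_top_features(imp, k=config.top_k, mode="topk")
        sel_scree = select_top_features(imp, mode="scree")
        top[view] = {
            "topk": {"names": sel_k.names, "mean_score": sel_k.mean_score},
            "scree": {"names": sel_scree.names, "mean_score": sel_scree.mean_score},
        }

    sig = feature_significance(features, labels, level=config.feature_test_level)

    bd_known = selected[selected["bd_group"].isin(["low", "high"])]
    bd_kw = kruskal_wallis(
        bd_known["difficulty_score"].to_numpy(), bd_known["bd_group"].to_numpy()
    )

    report = {
        "n_cases_rated": int(records["case_id"].nunique()),
        "n_cases_analyzed": int(labels.size),
        "n_images_processed": int(len(features)),
        "class_counts": labels.value_counts().to_dict(),
        "auc": aucs,
        "delong": delong,
        "selected_features": top,
        "n_significant_features": int(sig["significant"].sum()),
        "bd_group_kruskal": asdict(bd_kw),
        "config": {
            "threshold": config.threshold,
            "block_size": config.block_size,
            "coverage_min": config.coverage_min,
            "n_levels": config.n_levels,
            "n_trees": config.model.n_trees,
            "learn_rate": config.model.learn_rate,
            "max_splits_per_tree": config.model.max_splits_per_tree,
            "seed": config.model.seed,
            "paper_mode": config.paper_mode,
            "fusion": config.fusion,
            "feature_test_level": config.feature_test_level,
        },
    }
    return {
        "report": report,
        "scores": pd.concat([cc, mlo, fused], ignore_index=True),
        "importances": pd.DataFrame(importances),
        "significance": sig,
        "features": features,
        "records": records,
    }


def run_full_analysis(cohort_dir, config: AnalysisConfig | None = None, out_dir=None) -> dict:
    """Run the whole pipeline on a written cohort directory.

    Expects ``manifest.csv`` and ``reports.csv`` as written by
    ``synthetic_cohort.write_cohort`` (or equivalently formatted real data).
    If ``out_dir`` is given, writes report.json plus scores/importances/
    significance CSVs.
    """
    cohort = Path(cohort_dir)
    manifest = pd.read_csv(cohort / "manifest.csv")
    reports = pd.read_csv(cohort / "reports.csv")
    bd = manifest.drop_duplicates("case_id").set_index("case_id")["bd_category"]

    def load_images():
        for _, row in manifest.iterrows():
            yield read_tiff(
                cohort / row["path"], row["case_id"], row["view"], row["laterality"]
            )

    result = analyze_cohort(load_images(), reports, bd, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(result["report"], indent=2, sort_keys=True)
        )
        result["scores"].drop(columns=["image_scores"]).to_csv(
            out / "scores.csv", index=False
        )
        result["importances"].rename_axis("feature").to_csv(out / "importances.csv")
        result["significance"].to_csv(out / "significance.csv", index=False)
    return result
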