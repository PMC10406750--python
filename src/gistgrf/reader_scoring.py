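"""Reader-error difficulty scoring of truth-normal screening cases.

Readers rate each case on the 1-5 RANZCR scale (1 = normal, 2 = benign,
3-5 = increasing confidence of malignancy). On a truth-normal case any
rating of 3 or above is a false positive. A case's difficulty score is the
fraction of readers who made that error; cases are then split into
difficulty tertiles and only the top ("difficult") and bottom ("easy")
tertiles feed the downstream models. BI-RADS density categories A-D are
grouped into low (A, B) and high (C, D) density.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "collapse_ratings",
    "difficulty_records",
    "tertile_split",
    "select_difficult_easy",
    "bd_group",
]

VALID_RATINGS = {1, 2, 3, 4, 5}
INCORRECT_MIN = 3  # rating >= 3 on a normal case is a false positive

REPORT_COLUMNS = ["reader_id", "case_id", "rating"]


def _validate_reports(reports: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPORT_COLUMNS if c not in reports.columns]
    if missing:
        raise ValueError(f"reports table missing columns {missing}")
    bad = set(reports["rating"].unique()) - VALID_RATINGS
    if bad:
        raise ValueError(f"invalid ratings outside 1-5: {sorted(bad)}")
    return reports


def collapse_ratings(reports: pd.DataFrame) -> pd.DataFrame:
    """Reduce to one row per (reader, case), keeping the highest rating.

    A reader who flagged several suspected abnormalities on one case
    contributes multiple rows; only the maximum rating counts.
    """
    _validate_reports(reports)
    out = (
        reports.groupby(["reader_id", "case_id"], as_index=False)["rating"]
        .max()
        .sort_values(["reader_id", "case_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def difficulty_records(
    reports: pd.DataFrame, bd_categories: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Per-case difficulty scores from collapsed reader reports.

    Returns one row per case with n_readers, n_incorrect (ratings >= 3) and
    difficulty_score = n_incorrect / n_readers. If ``bd_categories`` maps
    case_id to a BI-RADS category, a bd_group column (low/high) is added.
    """
    _validate_reports(reports)
    if reports.empty:
        raise ValueError("no reader reports")
    grp = reports.groupby("case_id")["rating"]
    rec = pd.DataFrame(
        {
            "n_readers": grp.size(),
            "n_incorrect": grp.apply(lambda r: int((r >= INCORRECT_MIN).sum())),
        }
    ).reset_index()
    rec["difficulty_score"] = rec["n_incorrect"] / rec["n_readers"]
    if bd_categories is not None:
        bd = pd.Series(bd_categories)
        rec["bd_group"] = rec["case_id"].map(lambda c: bd_group(bd.get(c, None), permissive=True))
    return rec


def tertile_split(records: pd.DataFrame) -> pd.DataFrame:
    """Label cases difficult / intermediate / easy by difficulty tertile.

    Cases are sorted by score descending with ascending case_id as the
    deterministic tie-break; the top floor(n/3) become ``difficult``, the
    bottom floor(n/3) ``easy``, the remainder ``intermediate``.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 cases for a tertile split")
    ordered = records.sort_values(
        ["difficulty_score", "case_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    n = len(ordered)
    k = n // 3
    labels = ["intermediate"] * n
    for idx in range(k):
        labels[idx] = "difficult"
    for idx in range(n - k, n):
        labels[idx] = "easy"
    ordered["tertile"] = labels
    return ordered


def select_difficult_easy(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only the difficult and easy tertiles for downstream analysis."""
    if "tertile" not in records.columns:
        raise ValueError("records not tertile-labelled; run tertile_split first")
    return records[records["tertile"].isin(["difficult", "easy"])].reset_index(drop=True)


def bd_group(category, permissive: bool = False) -> str:
    """Map a BI-RADS density category to the low/high-density group.

    A (fatty) and B (fibroglandular) are low density; C (heterogeneously
    dense) and D (extremely dense) are high. Case-insensitive. Unknown
    categories raise, or return ``"unknown"`` in permissive mode.
    """
    if isinstance(category, str):
        cat = category.strip().upper()
        if cat in ("A", "B"):
            return "low"
        if cat in ("C", "D"):
            return "high"
    if permissive:
        return "unknown"
    raise ValueError(f"unknown BI-RADS density category {category!r}")
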