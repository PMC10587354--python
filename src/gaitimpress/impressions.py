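"""Likert aggregation, Pearson predictor screening, and summary-statistic tests.

The unit of analysis for screening is the animation (one walker trial under
one footwear condition): observer ratings are averaged into per-animation
A-scores (attractiveness) and F-scores (femininity), and each candidate
gait/physique feature is tested against each score with Pearson's r.  A
feature is selected as an observed variable for the structural models when
|r| > 0.3 (strict) and p <= 0.05.

Summary-statistic comparisons used for the footwear contrasts (Student's
pooled two-sample t, Cohen's d with the equal-n pooled SD, coefficient of
variation) are also provided, so published group summaries can be checked
without row-level data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def aggregate_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-animation mean A-/F-scores.

    ``ratings`` columns: observer_id, animation_id, attractiveness,
    femininity (integers 1..7).  Missing (observer, animation) pairs simply
    reduce that animation's ``n_raters``.
    """
    if ratings.empty:
        raise ValueError("empty rating table")
    for col in ("attractiveness", "femininity"):
        vals = ratings[col].to_numpy()
        if np.any((vals < 1) | (vals > 7)):
            raise ValueError(f"{col} ratings outside 1..7")
    if ratings.duplicated(["observer_id", "animation_id"]).any():
        raise ValueError("duplicate (observer, animation) rating rows")
    out = (
        ratings.groupby("animation_id")
        .agg(
            a_score=("attractiveness", "mean"),
            f_score=("femininity", "mean"),
            n_raters=("attractiveness", "size"),
        )
        .reset_index()
    )
    return out


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from the t-transform (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the arguments")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def screen_predictors(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    condition: str | None = None,
    feature_names: list[str] | None = None,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen of every feature against the A- and F-scores.

    ``features`` must carry an ``animation_id`` column (or walker/trial/
    condition columns from which one is derived) plus numeric feature
    columns; ``scores`` is the output of :func:`aggregate_scores`.  Returns
    one row per (feature, score) with r, p, n, and the selection flag
    ``selected = (|r| > r_threshold) & (p <= p_threshold)``.
    """
    feats = features.copy()
    if "animation_id" not in feats.columns:
        needed = {"walker_id", "trial_id", "condition"}
        if not needed.issubset(feats.columns):
            raise ValueError("features need animation_id or walker/trial/condition columns")
        feats["animation_id"] = [
            f"{r.walker_id}_{r.trial_id}_{r.condition}" for r in feats.itertuples()
        ]
    if condition is not None:
        if "condition" not in feats.columns:
            raise ValueError("cannot filter by condition: no condition column")
        feats = feats[feats["condition"] == condition]
    merged = feats.merge(scores, on="animation_id", how="inner")
    if merged.empty:
        raise ValueError(
            "feature/score join produced no rows; check animation_id values "
            f"(features: {len(feats)}, scores: {len(scores)})"
        )
    if len(merged) < len(feats):
        raise ValueError(
            f"join dropped {len(feats) - len(merged)} feature rows without scores"
        )

    if feature_names is None:
        skip = {"animation_id", "walker_id", "trial_id", "condition", "height_m", "weight_kg"}
        feature_names = [
            c for c in feats.columns
            if c not in skip and pd.api.types.is_numeric_dtype(feats[c])
        ]
    rows = []
    for name in feature_names:
        for score in ("a_score", "f_score"):
            r, p = pearson_test(merged[name], merged[score])
            rows.append(
                {
                    "feature": name,
                    "score": score,
                    "condition": condition,
                    "r": r,
                    "p": p,
                    "n": len(merged),
                    "selected": (abs(r) > r_threshold) and (p <= p_threshold),
                }
            )
    return pd.DataFrame(rows)


def correlation_table(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot a screening report into a feature x (score, statistic) table."""
    wide = report.pivot_table(
        index="feature", columns="score", values=["r", "p"], aggfunc="first"
    )
    wide.columns = [f"{score}_{stat}" for stat, score in wide.columns]
    return wide


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t from group summaries.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.  When both SDs are
    zero and the means equal, t = 0 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference with the equal-n pooled SD.

    d = |mean2 - mean1| / sqrt((sd1^2 + sd2^2) / 2).
    """
    denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if denom == 0:
        raise ValueError("both SDs are zero")
    return float(abs(mean2 - mean1) / denom)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """SD / mean; rejected for zero mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(sd / mean)


def observer_level_table(
    ratings: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Join observer-level ratings to trial features (the SEM sample).

    One row per (observer, animation) carrying the animation's features and
    the observer's two ratings; pooling ~60 observers over ~34 animations
    gives the ≈2040-row samples the structural models are fitted on.
    """
    feats = features.copy()
    if "animation_id" not in feats.columns:
        feats["animation_id"] = [
            f"{r.walker_id}_{r.trial_id}_{r.condition}" for r in feats.itertuples()
        ]
    merged = ratings.merge(feats, on="animation_id", how="inner")
    if merged.empty:
        raise ValueError("ratings/features join produced no rows")
    return merged
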