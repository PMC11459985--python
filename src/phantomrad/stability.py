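"""Feature stability across reconstruction settings via coefficient of variation.

A feature is stable when its value barely moves as reconstruction
parameters change.  The COV (sample SD over absolute mean, in percent)
is computed within each of the four setting families (subsets,
iterations, filter, TOF), combined into an overall score, and mapped to
one of four categories: stable (COV ≤ 5%), moderately stable
(5% < COV ≤ 10%), poorly stable (10% < COV ≤ 20%), unstable (> 20%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "DEFAULT_THRESHOLDS",
    "FAMILIES",
    "StabilityRecord",
    "cov",
    "categorize",
    "stability_table",
    "category_counts",
]

FAMILIES = ("subsets", "iterations", "filter", "tof")
CATEGORIES = ("stable", "moderately_stable", "poorly_stable", "unstable")
DEFAULT_THRESHOLDS = (5.0, 10.0, 20.0)

#: Relative scale below which a mean is treated as zero (COV undefined).
ZERO_MEAN_EPS = 1e-12


def cov(values, eps: float = ZERO_MEAN_EPS) -> float:
    """Coefficient of variation in percent: 100 × sample SD / |mean|.

    Uses the n−1 (sample) standard deviation.  Returns ``nan`` — the
    undefined-COV flag — when the mean is within ``eps`` of zero
    relative to the magnitude of the values; such features are excluded
    from categorization and reported separately.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("COV needs at least two values")
    mean = x.mean()
    scale = max(float(np.abs(x).max()), 1.0)
    if abs(mean) <= eps * scale:
        return math.nan
    return float(100.0 * x.std(ddof=1) / abs(mean))


def categorize(cov_value: float,
               thresholds=DEFAULT_THRESHOLDS) -> str:
    """Map a COV percentage to its stability category.

    Boundaries are inclusive on the more stable side: exactly 5% is
    stable, exactly 10% moderately stable, exactly 20% poorly stable.
    ``nan`` (undefined COV) maps to "undefined".
    """
    if math.isnan(cov_value):
        return "undefined"
    if cov_value < 0:
        raise ValueError("COV cannot be negative")
    t1, t2, t3 = thresholds
    if cov_value <= t1:
        return "stable"
    if cov_value <= t2:
        return "moderately_stable"
    if cov_value <= t3:
        return "poorly_stable"
    return "unstable"


@dataclass(frozen=True)
class StabilityRecord:
    feature_name: str
    cov_per_family: dict[str, float]
    cov_overall: float
    category: str
    category_per_family: dict[str, str]


def _validate_table(table: pd.DataFrame) -> None:
    required = {"feature", "shape_id", "setting_id", "family", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    if table["value"].isna().any():
        raise ValueError("feature table has missing cells")


def stability_table(table: pd.DataFrame, shape_id: int,
                    thresholds=DEFAULT_THRESHOLDS,
                    overall: str = "family-mean") -> list[StabilityRecord]:
    """Per-feature stability records for one insert shape.

    ``table`` is long-form with columns (feature, shape_id, setting_id,
    family, value); each setting belongs to the family of its varied
    parameter, so the clinical default contributes to every family whose
    variation list contains its value.  ``overall`` selects how family
    COVs combine: "family-mean" (arithmetic mean of the four family
    COVs) or "pooled" (one COV over all settings).
    """
    if overall not in ("family-mean", "pooled"):
        raise ValueError("overall must be 'family-mean' or 'pooled'")
    _validate_table(table)
    sub = table[table["shape_id"] == shape_id]
    if sub.empty:
        raise ValueError(f"no rows for shape {shape_id}")
    n_settings = sub["setting_id"].nunique()
    records: list[StabilityRecord] = []
    for feature, grp in sub.groupby("feature", sort=True):
        if grp["setting_id"].nunique() != n_settings:
            raise ValueError(f"incomplete settings for feature {feature!r}")
        fam_cov: dict[str, float] = {}
        fam_cat: dict[str, str] = {}
        for fam in FAMILIES:
            vals = grp.loc[grp["family"] == fam, "value"].to_numpy()
            if vals.size < 2:
                raise ValueError(f"family {fam!r} needs >= 2 settings")
            fam_cov[fam] = cov(vals)
            fam_cat[fam] = categorize(fam_cov[fam], thresholds)
        if overall == "family-mean":
            c = float(np.mean([fam_cov[f] for f in FAMILIES]))
        else:
            c = cov(grp["value"].to_numpy())
        records.append(StabilityRecord(
            feature_name=str(feature),
            cov_per_family=fam_cov,
            cov_overall=c,
            category=categorize(c, thresholds),
            category_per_family=fam_cat,
        ))
    return records


def category_counts(records: list[StabilityRecord]) -> dict[str, dict[str, int]]:
    """Category histograms, overall and per setting family."""
    out: dict[str, dict[str, int]] = {
        "overall": {c: 0 for c in (*CATEGORIES, "undefined")}}
    for fam in FAMILIES:
        out[fam] = {c: 0 for c in (*CATEGORIES, "undefined")}
    for r in records:
        out["overall"][r.category] += 1
        for fam in FAMILIES:
            out[fam][r.category_per_family[fam]] += 1
    return out


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    """Flatten stability records into a tidy frame (one row per feature)."""
    rows = []
    for r in records:
        row = {"feature": r.feature_name}
        for fam in FAMILIES:
            row[f"cov_{fam}"] = r.cov_per_family[fam]
        row["cov_overall"] = r.cov_overall
        row["category"] = r.category
        rows.append(row)
    return pd.DataFrame(rows)
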