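"""Concordance between the standard rule and the simplified rules.

Each person is cross-classified by the standard diagnosis (mean of
readings 2-3 vs 140/90) and a simplified diagnosis into four groups:

==============  ===============  =================
standard        simplified       group
==============  ===============  =================
hypertensive    hypertensive     consistent_htn
hypertensive    not              missed
not             hypertensive     over_diagnosed
not             not              consistent_non_htn
==============  ===============  =================

The missed proportion is ``missed / (missed + consistent_htn)`` and the
over-diagnosis proportion is ``over / (over + consistent_non_htn)``,
both as percentages.  Region- and global-level summaries are the
unweighted mean/SD/median/min/max of the country-level proportions
(SD with the n-1 denominator); pooled individual-level proportions are
additionally emitted, clearly labelled, for diagnostics.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import rules
from .errors import ConfigError

__all__ = [
    "GROUPS",
    "classify",
    "concordance_counts",
    "missed_proportion",
    "over_proportion",
    "country_proportions",
    "aggregate",
]

GROUPS = ("missed", "over_diagnosed", "consistent_htn", "consistent_non_htn")

COUNT_COLUMNS = ["n_missed", "n_over", "n_consistent_htn", "n_consistent_non_htn"]


def classify(
    records: pd.DataFrame,
    approaches: Sequence[str] = rules.SIMPLIFIED_IDS,
) -> pd.DataFrame:
    """Per-person, per-approach concordance group.

    Returns a long frame with columns person_id, country, region,
    approach_id, group (plus ``standard_htn`` and ``simplified_htn``
    flags for traceability).
    """
    std = rules.diagnose(records, "standard")["hypertensive"].to_numpy()
    frames = []
    for a in approaches:
        spec = rules.get_approach(a)
        if spec.approach_id == "standard":
            raise ConfigError("classify: the standard rule cannot be compared to itself")
        simp = rules.diagnose(records, spec)["hypertensive"].to_numpy()
        group = np.where(
            std,
            np.where(simp, "consistent_htn", "missed"),
            np.where(simp, "over_diagnosed", "consistent_non_htn"),
        )
        frames.append(pd.DataFrame({
            "person_id": records["person_id"].to_numpy(),
            "country": records["country"].to_numpy(),
            "region": records["region"].to_numpy(),
            "approach_id": spec.approach_id,
            "standard_htn": std,
            "simplified_htn": simp,
            "group": group,
        }))
    return pd.concat(frames, ignore_index=True)


def concordance_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Four-group counts per country x approach (long format)."""
    ct = (
        classified.groupby(["approach_id", "region", "country", "group"], observed=True)
        .size()
        .unstack("group", fill_value=0)
        .reindex(columns=GROUPS, fill_value=0)
        .reset_index()
    )
    ct = ct.rename(columns={
        "missed": "n_missed",
        "over_diagnosed": "n_over",
        "consistent_htn": "n_consistent_htn",
        "consistent_non_htn": "n_consistent_non_htn",
    })
    ct.columns.name = None
    return ct


def missed_proportion(n_missed: int, n_consistent_htn: int) -> float:
    """Missed cases as % of standard-positive cases.

    Zero denominator yields NaN (the unit is reported as missing, never
    as 0) with a warning.
    """
    denom = n_missed + n_consistent_htn
    if denom == 0:
        warnings.warn("missed proportion undefined: no standard-positive cases", stacklevel=2)
        return float("nan")
    return 100.0 * n_missed / denom


def over_proportion(n_over: int, n_consistent_non_htn: int) -> float:
    """Over-diagnosed cases as % of standard-negative cases."""
    denom = n_over + n_consistent_non_htn
    if denom == 0:
        warnings.warn("over-diagnosis proportion undefined: no standard-negative cases",
                      stacklevel=2)
        return float("nan")
    return 100.0 * n_over / denom


def country_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Append p_missed / p_over (%) columns to a country-level count table."""
    out = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom_m = out["n_missed"] + out["n_consistent_htn"]
        denom_o = out["n_over"] + out["n_consistent_non_htn"]
        out["p_missed"] = np.where(denom_m > 0, 100.0 * out["n_missed"] / denom_m, np.nan)
        out["p_over"] = np.where(denom_o > 0, 100.0 * out["n_over"] / denom_o, np.nan)
    n_undef = int((denom_m == 0).sum() + (denom_o == 0).sum())
    if n_undef:
        warnings.warn(f"{n_undef} country-level proportion(s) undefined (zero denominator); "
                      "reported as missing", stacklevel=2)
    return out


def _across_countries(g: pd.DataFrame, col: str) -> dict:
    v = g[col].dropna()
    return {
        "mean": v.mean() if len(v) else np.nan,
        "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
        "median": v.median() if len(v) else np.nan,
        "min": v.min() if len(v) else np.nan,
        "max": v.max() if len(v) else np.nan,
        "n_countries": int(len(v)),
    }


def aggregate(country_table: pd.DataFrame, level: str = "global") -> pd.DataFrame:
    """Summarise country-level proportions at region or global level.

    ``country_table`` is the output of :func:`country_proportions`.
    Summary statistics (mean, SD, median, min, max) are computed across
    countries, unweighted — the convention of multi-country survey
    reports; pooled counts and pooled individual-level proportions are
    appended under ``pooled_*`` labels for diagnostics.
    """
    if level not in {"region", "global"}:
        raise ConfigError(f"aggregate: level must be 'region' or 'global', got {level!r}")
    keys = ["approach_id"] if level == "global" else ["approach_id", "region"]
    if country_table.empty:
        raise ConfigError("aggregate: empty country table")
    rows = []
    for key, g in country_table.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        for stat, val in _across_countries(g, "p_missed").items():
            row[f"missed_{stat}"] = val
        for stat, val in _across_countries(g, "p_over").items():
            row[f"over_{stat}"] = val
        for c in COUNT_COLUMNS:
            row[c] = int(g[c].sum())
        n_std_pos = row["n_missed"] + row["n_consistent_htn"]
        n_std_neg = row["n_over"] + row["n_consistent_non_htn"]
        row["pooled_p_missed"] = (100.0 * row["n_missed"] / n_std_pos) if n_std_pos else np.nan
        row["pooled_p_over"] = (100.0 * row["n_over"] / n_std_neg) if n_std_neg else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
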