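"""Blood-pressure screening rules.

The standard screening protocol takes three serial BP measurements and
diagnoses hypertension when the mean of the second and third readings is
>= 140 mm Hg systolic or >= 90 mm Hg diastolic.  This module implements
that rule together with nine simplified alternatives that use fewer
readings:

* a single reading (first or second),
* the average of the first two readings,
* a conditionally triggered second reading: the second reading is used
  only when the first reading exceeds a threshold (e.g. >= 130/80) or
  falls inside a window (e.g. 130-145/80-95); otherwise the first
  reading itself is the effective BP.

Trigger conditions combine the systolic and diastolic parts with OR, and
all bounds are inclusive.  Effective BP is kept at full floating-point
precision; no rounding happens before the 140/90 comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, IncompleteRecordError

__all__ = [
    "SBP_CUTOFF",
    "DBP_CUTOFF",
    "ApproachSpec",
    "Diagnosis",
    "APPROACHES",
    "STANDARD",
    "SIMPLIFIED_IDS",
    "ALL_IDS",
    "get_approach",
    "effective_bp",
    "diagnose",
    "diagnose_all",
    "is_hypertensive",
]

#: Diagnostic cut-offs applied to the effective BP (inclusive).
SBP_CUTOFF = 140.0
DBP_CUTOFF = 90.0

READING_COLUMNS = ["sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"]


@dataclass(frozen=True)
class ApproachSpec:
    """Definition of one screening rule.

    kind:
        ``standard``   mean of readings 2 and 3;
        ``single``     one fixed reading (``reading`` is 1-based);
        ``average12``  mean of readings 1 and 2;
        ``threshold``  reading 2 if reading 1 >= (sbp_low OR dbp_low), else reading 1;
        ``window``     reading 2 if reading 1 falls inside [sbp_low, sbp_high]
                       OR [dbp_low, dbp_high], else reading 1.
    """

    approach_id: str
    label: str
    kind: str
    reading: int | None = None
    sbp_low: float | None = None
    sbp_high: float | None = None
    dbp_low: float | None = None
    dbp_high: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"standard", "single", "average12", "threshold", "window"}:
            raise ConfigError(f"ApproachSpec.kind: unknown kind {self.kind!r}")
        if self.kind == "single" and self.reading not in (1, 2, 3):
            raise ConfigError("ApproachSpec.reading: must be 1, 2 or 3 for kind 'single'")
        if self.kind in {"threshold", "window"} and (self.sbp_low is None or self.dbp_low is None):
            raise ConfigError("ApproachSpec.sbp_low/dbp_low: required for conditional rules")
        if self.kind == "window" and (self.sbp_high is None or self.dbp_high is None):
            raise ConfigError("ApproachSpec.sbp_high/dbp_high: required for window rules")

    @property
    def conditional(self) -> bool:
        return self.kind in {"threshold", "window"}

    def trigger(self, sbp1: np.ndarray, dbp1: np.ndarray) -> np.ndarray:
        """Whether the first reading triggers a second measurement.

        SBP and DBP conditions are OR-combined; bounds are inclusive.
        """
        if self.kind == "threshold":
            return (sbp1 >= self.sbp_low) | (dbp1 >= self.dbp_low)
        if self.kind == "window":
            return ((sbp1 >= self.sbp_low) & (sbp1 <= self.sbp_high)) | (
                (dbp1 >= self.dbp_low) & (dbp1 <= self.dbp_high)
            )
        raise ConfigError(f"approach {self.approach_id!r} has no trigger")


def _build_registry() -> Mapping[str, ApproachSpec]:
    specs = [
        ApproachSpec("standard", "Mean of 2nd and 3rd BP records (standard)", "standard"),
        ApproachSpec("first", "1st BP record", "single", reading=1),
        ApproachSpec("second", "2nd BP record", "single", reading=2),
        ApproachSpec("avg_first_two", "Average of 1st and 2nd BP records", "average12"),
        ApproachSpec(
            "second_if_ge_130_80",
            "2nd BP record if 1st BP record ≥ 130/80",
            "threshold", sbp_low=130, dbp_low=80,
        ),
        ApproachSpec(
            "second_if_ge_135_85",
            "2nd BP record if 1st BP record ≥ 135/85",
            "threshold", sbp_low=135, dbp_low=85,
        ),
        ApproachSpec(
            "second_if_ge_140_90",
            "2nd BP record if 1st BP record ≥ 140/90",
            "threshold", sbp_low=140, dbp_low=90,
        ),
        ApproachSpec(
            "second_if_130_145_80_95",
            "2nd BP record if 1st BP record = 130–145/80–95",
            "window", sbp_low=130, sbp_high=145, dbp_low=80, dbp_high=95,
        ),
        ApproachSpec(
            "second_if_130_150_80_100",
            "2nd BP record if 1st BP record = 130–150/80–100",
            "window", sbp_low=130, sbp_high=150, dbp_low=80, dbp_high=100,
        ),
        ApproachSpec(
            "second_if_130_155_80_105",
            "2nd BP record if 1st BP record = 130–155/80–105",
            "window", sbp_low=130, sbp_high=155, dbp_low=80, dbp_high=105,
        ),
    ]
    return {s.approach_id: s for s in specs}


APPROACHES: Mapping[str, ApproachSpec] = _build_registry()
STANDARD: ApproachSpec = APPROACHES["standard"]
#: The nine simplified rules, in canonical (i)-(ix) order.
SIMPLIFIED_IDS: tuple[str, ...] = tuple(k for k in APPROACHES if k != "standard")
ALL_IDS: tuple[str, ...] = tuple(APPROACHES)


def get_approach(approach: str | ApproachSpec) -> ApproachSpec:
    if isinstance(approach, ApproachSpec):
        return approach
    try:
        return APPROACHES[approach]
    except KeyError:
        raise ConfigError(
            f"unknown approach {approach!r}; known ids: {', '.join(APPROACHES)}"
        ) from None


def _require_complete(df: pd.DataFrame) -> None:
    missing_cols = [c for c in READING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise IncompleteRecordError(f"missing reading columns: {missing_cols}")
    bad = df[READING_COLUMNS].isna().any(axis=1)
    if bad.any():
        ids = df.index[bad][:5].tolist()
        raise IncompleteRecordError(
            f"{int(bad.sum())} record(s) are missing BP readings "
            f"(first offenders: {ids}); readings are never imputed"
        )


def effective_bp(
    df: pd.DataFrame, approach: str | ApproachSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective (SBP, DBP) pair per person under one rule.

    Returns ``(sbp, dbp, readings_used)`` where ``readings_used`` counts
    the readings entering the effective BP (2 for the standard rule, the
    average of the first two, and triggered conditional rules; else 1).
    """
    spec = get_approach(approach)
    _require_complete(df)
    s1, s2, s3 = (df["sbp1"].to_numpy(float), df["sbp2"].to_numpy(float), df["sbp3"].to_numpy(float))
    d1, d2, d3 = (df["dbp1"].to_numpy(float), df["dbp2"].to_numpy(float), df["dbp3"].to_numpy(float))
    if spec.kind == "standard":
        return (s2 + s3) / 2.0, (d2 + d3) / 2.0, np.full(len(df), 2)
    if spec.kind == "single":
        s = (s1, s2, s3)[spec.reading - 1]
        d = (d1, d2, d3)[spec.reading - 1]
        return s, d, np.full(len(df), 1)
    if spec.kind == "average12":
        return (s1 + s2) / 2.0, (d1 + d2) / 2.0, np.full(len(df), 2)
    trig = spec.trigger(s1, d1)
    return np.where(trig, s2, s1), np.where(trig, d2, d1), np.where(trig, 2, 1)


def is_hypertensive(sbp, dbp):
    """140/90 OR-rule, inclusive thresholds, on an effective BP pair."""
    return (np.asarray(sbp) >= SBP_CUTOFF) | (np.asarray(dbp) >= DBP_CUTOFF)


@dataclass(frozen=True)
class Diagnosis:
    """Screening outcome for a single person under a single rule."""

    approach_id: str
    effective_sbp: float
    effective_dbp: float
    hypertensive: bool
    readings_used: int


def diagnose(df: pd.DataFrame, approach: str | ApproachSpec) -> pd.DataFrame:
    """Apply one rule to a cohort table.

    Returns a frame indexed like ``df`` with columns ``effective_sbp``,
    ``effective_dbp``, ``hypertensive`` and ``readings_used``.
    """
    spec = get_approach(approach)
    sbp, dbp, used = effective_bp(df, spec)
    return pd.DataFrame(
        {
            "effective_sbp": sbp,
            "effective_dbp": dbp,
            "hypertensive": is_hypertensive(sbp, dbp),
            "readings_used": used,
        },
        index=df.index,
    )


def diagnose_all(
    df: pd.DataFrame, approaches: Iterable[str | ApproachSpec] = ALL_IDS
) -> pd.DataFrame:
    """Hypertension flags for several rules at once (one column per rule)."""
    out = {}
    for a in approaches:
        spec = get_approach(a)
        out[spec.approach_id] = diagnose(df, spec)["hypertensive"]
    return pd.DataFrame(out, index=df.index)
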