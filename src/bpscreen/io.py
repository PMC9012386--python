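"""Reading and writing cohorts and configurations.

CSV is the canonical interchange format (survey microdata usually ship
as statistical-package files; converting them is a documented
preprocessing step).  Column headers are matched case-insensitively
through an alias map so that unit-suffixed exports like
``SBP1 (mmHg)`` parse without renaming.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, CovariateParams, BPEffects, SBP_BAND, DBP_BAND
from .errors import SchemaError

__all__ = [
    "RowReport",
    "read_cohort",
    "write_cohort",
    "save_cohort_config",
    "load_cohort_config",
    "write_provenance",
    "config_hash",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "country", "region", "sex", "age", "bmi", "waist", "smoker", "fpg", "tc",
    "known_htn", "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3",
]
OPTIONAL_COLUMNS = ["person_id", "diabetes_history"]
READING_COLUMNS = ["sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"]

#: Extra spellings mapped onto canonical names (after normalisation:
#: lower-case, alphanumerics only).
DEFAULT_ALIASES = {
    "id": "person_id",
    "participantid": "person_id",
    "countrycode": "country",
    "whoregion": "region",
    "gender": "sex",
    "ageyears": "age",
    "bmikgm2": "bmi",
    "waistcm": "waist",
    "waistcircumference": "waist",
    "currentsmoker": "smoker",
    "smoking": "smoker",
    "fastingglucose": "fpg",
    "fpgmmoll": "fpg",
    "totalcholesterol": "tc",
    "tcmmoll": "tc",
    "knownhypertension": "known_htn",
    "priorhypertension": "known_htn",
    "diabeteshistory": "diabetes_history",
    "historydiabetes": "diabetes_history",
}
for _i in (1, 2, 3):
    DEFAULT_ALIASES[f"sbp{_i}"] = f"sbp{_i}"
    DEFAULT_ALIASES[f"sbp{_i}mmhg"] = f"sbp{_i}"
    DEFAULT_ALIASES[f"systolic{_i}"] = f"sbp{_i}"
    DEFAULT_ALIASES[f"dbp{_i}"] = f"dbp{_i}"
    DEFAULT_ALIASES[f"dbp{_i}mmhg"] = f"dbp{_i}"
    DEFAULT_ALIASES[f"diastolic{_i}"] = f"dbp{_i}"

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _normalise(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def _canonical_columns(columns, alias_map=None) -> dict:
    aliases = dict(DEFAULT_ALIASES)
    if alias_map:
        aliases.update({_normalise(k): v for k, v in alias_map.items()})
    known = set(MANDATORY_COLUMNS) | set(OPTIONAL_COLUMNS)
    mapping = {}
    for col in columns:
        norm = _normalise(str(col))
        if norm in known:
            mapping[col] = norm
        elif norm in aliases:
            mapping[col] = aliases[norm]
    return mapping


def _parse_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if pd.isna(v):
            return np.nan
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        return np.nan
    return series.map(one)


@dataclass(frozen=True)
class RowReport:
    """Row-level accounting of a cohort read."""

    rows_in: int
    rejected_missing_readings: int
    rejected_out_of_band: int
    rows_out: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_cohort(path, alias_map: dict | None = None) -> tuple[pd.DataFrame, RowReport]:
    """Read and validate a participant-level CSV.

    Missing mandatory columns are fatal (:class:`SchemaError` naming
    them).  Rows with any missing BP reading, or readings outside the
    physiologic sanity bands (SBP 50-300, DBP 30-200 mm Hg), are
    rejected and counted in the returned :class:`RowReport`.
    """
    raw = pd.read_csv(path)
    mapping = _canonical_columns(raw.columns, alias_map)
    df = raw.rename(columns=mapping)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")
    df = df[[c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]].copy()
    if "person_id" not in df.columns:
        df["person_id"] = np.arange(len(df))
    for col in ("smoker", "known_htn", "diabetes_history"):
        if col in df.columns:
            df[col] = _parse_bool(df[col])
    for col in READING_COLUMNS + ["age", "bmi", "waist", "fpg", "tc"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()

    n_in = len(df)
    incomplete = df[READING_COLUMNS].isna().any(axis=1)
    sbp = df[["sbp1", "sbp2", "sbp3"]]
    dbp = df[["dbp1", "dbp2", "dbp3"]]
    out_of_band = (
        sbp.lt(SBP_BAND[0]).any(axis=1) | sbp.gt(SBP_BAND[1]).any(axis=1)
        | dbp.lt(DBP_BAND[0]).any(axis=1) | dbp.gt(DBP_BAND[1]).any(axis=1)
    ) & ~incomplete
    keep = ~(incomplete | out_of_band)
    report = RowReport(
        rows_in=n_in,
        rejected_missing_readings=int(incomplete.sum()),
        rejected_out_of_band=int(out_of_band.sum()),
        rows_out=int(keep.sum()),
    )
    if report.rows_out < n_in:
        logger.warning("read_cohort: rejected %d of %d rows (%d incomplete readings, "
                       "%d out-of-band)", n_in - report.rows_out, n_in,
                       report.rejected_missing_readings, report.rejected_out_of_band)
    return df.loc[keep].reset_index(drop=True), report


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (value round-trips through :func:`read_cohort`)."""
    df.to_csv(path, index=False)


# -- configuration ------------------------------------------------------

def save_cohort_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config.to_dict()), fh, sort_keys=True)


def load_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key, cls in (("covariate_params", CovariateParams), ("risk_effect", BPEffects)):
        if isinstance(d.get(key), dict):
            d[key] = cls(**d[key])
    for key in ("n_range", "age_range", "sbp_mean_range", "dbp_mean_range",
                "first_excess_range", "reading_offsets"):
        if isinstance(d.get(key), list):
            d[key] = tuple(d[key])
    return CohortConfig(**d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    """Stable SHA-256 of a configuration mapping (for provenance)."""
    d = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    blob = json.dumps(_jsonable(d), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_provenance(path, seed, config, extra: dict | None = None) -> None:
    """Emit a provenance sidecar: seed, config hash, package version."""
    from . import __version__

    payload = {
        "seed": seed,
        "config_sha256": config_hash(config),
        "bpscreen_version": __version__,
    }
    if extra:
        payload.update(_jsonable(extra))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
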