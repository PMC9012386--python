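"""Chart-style 10-year cardiovascular risk scoring.

Risk is used here as a continuous cardiometabolic summary in [0, 1],
computed from a configurable log-linear coefficient table in the
structural form of chart-based 10-year risk scores::

    lp    = sum_k beta_k * x_k
    risk  = 1 - (1 - baseline_risk) ** exp(lp - lp_ref)

where ``lp_ref`` is the linear predictor at a configured reference
covariate profile and ``baseline_risk`` is the 10-year risk at that
profile (optionally region-specific).  Because ``1 - baseline_risk`` is
in (0, 1] and ``exp`` is positive, the transform saturates and the risk
stays in [0, 1] for any finite covariates.

Diabetes uses an expanded definition capturing both aware and unaware
cases: self-reported history OR fasting plasma glucose >= 7.0 mmol/L
(equivalently 126 mg/dl).

The packaged :data:`SYNTHETIC_RISK_MODEL` is a synthetic, documented
coefficient set intended for simulation and testing; externally
obtained chart coefficients can be loaded from YAML without code
changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import rules
from .errors import ConfigError

__all__ = [
    "RiskModelConfig",
    "SYNTHETIC_RISK_MODEL",
    "mgdl_to_mmol",
    "flag_diabetes",
    "score",
]

logger = logging.getLogger(__name__)

#: Conventional glucose unit conversion factor (mg/dl per mmol/L).
GLUCOSE_MGDL_PER_MMOL = 18.0

COVARIATES = ("age", "male", "smoker", "sbp", "tc", "diabetes")


def mgdl_to_mmol(fpg_mgdl):
    """Convert fasting plasma glucose from mg/dl to mmol/L."""
    return np.asarray(fpg_mgdl, dtype=float) / GLUCOSE_MGDL_PER_MMOL


@dataclass(frozen=True)
class RiskModelConfig:
    """Coefficient table and transform for the 10-year risk score.

    coefficients:
        log-hazard-ratio style coefficients keyed by covariate
        (age [per year], male, smoker, sbp [per mm Hg], tc [per
        mmol/L], diabetes).
    baseline_risk:
        10-year risk at the reference profile; scalar or a per-region
        mapping.
    reference:
        covariate values at which the linear predictor is centred.
    countries_without_model:
        country codes for which the model provides no estimate; their
        risk is reported missing, never raised as an error.
    """

    coefficients: Mapping[str, float]
    baseline_risk: float | Mapping[str, float] = 0.05
    reference: Mapping[str, float] = field(
        default_factory=lambda: {"age": 50.0, "male": 0.0, "smoker": 0.0,
                                 "sbp": 130.0, "tc": 5.0, "diabetes": 0.0}
    )
    fpg_diabetes_cutoff: float = 7.0
    countries_without_model: frozenset[str] = frozenset()
    schema_version: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(COVARIATES)
        if unknown:
            raise ConfigError(f"coefficients: unknown covariates {sorted(unknown)}")
        if self.fpg_diabetes_cutoff <= 0:
            raise ConfigError("fpg_diabetes_cutoff: must be > 0")
        for b in self._baseline_values():
            if not 0.0 < b < 1.0:
                raise ConfigError("baseline_risk: must be in (0, 1)")

    def _baseline_values(self):
        if isinstance(self.baseline_risk, Mapping):
            return list(self.baseline_risk.values())
        return [self.baseline_risk]

    def baseline_for(self, region) -> np.ndarray:
        if isinstance(self.baseline_risk, Mapping):
            try:
                return np.asarray([self.baseline_risk[r] for r in region], dtype=float)
            except KeyError as e:
                raise ConfigError(f"baseline_risk: no baseline for region {e.args[0]!r}") from None
        return np.full(len(region), float(self.baseline_risk))

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "coefficients": dict(self.coefficients),
            "baseline_risk": (dict(self.baseline_risk)
                              if isinstance(self.baseline_risk, Mapping)
                              else float(self.baseline_risk)),
            "reference": dict(self.reference),
            "fpg_diabetes_cutoff": float(self.fpg_diabetes_cutoff),
            "countries_without_model": sorted(self.countries_without_model),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RiskModelConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            coefficients=payload["coefficients"],
            baseline_risk=payload.get("baseline_risk", 0.05),
            reference=payload.get("reference", {}),
            fpg_diabetes_cutoff=payload.get("fpg_diabetes_cutoff", 7.0),
            countries_without_model=frozenset(payload.get("countries_without_model", [])),
            schema_version=payload.get("schema_version", 1),
        )


#: Synthetic coefficient set for simulation and testing (plausible
#: magnitudes for a laboratory-based chart-style score; NOT fitted to
#: any published risk chart).
SYNTHETIC_RISK_MODEL = RiskModelConfig(
    coefficients={
        "age": 0.055, "male": 0.30, "smoker": 0.50,
        "sbp": 0.016, "tc": 0.11, "diabetes": 0.65,
    },
    baseline_risk=0.05,
)


def flag_diabetes(history, fpg, cutoff: float = 7.0) -> np.ndarray:
    """Expanded diabetes flag: history OR FPG >= cutoff (mmol/L).

    A missing FPG with no history counts as non-diabetic; that
    imputation is logged.  Negative FPG is a validation error.
    """
    history = np.asarray(history, dtype=bool)
    fpg = np.asarray(fpg, dtype=float)
    if cutoff <= 0:
        raise ConfigError("fpg_diabetes_cutoff: must be > 0")
    if np.any(fpg < 0):
        raise ConfigError("fpg: negative fasting plasma glucose")
    missing = np.isnan(fpg)
    n_imputed = int((missing & ~history).sum())
    if n_imputed:
        logger.info("flag_diabetes: %d record(s) with missing FPG and no history "
                    "treated as non-diabetic", n_imputed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        high = fpg >= cutoff
    return history | (high & ~missing)


def score(
    records: pd.DataFrame,
    config: RiskModelConfig = SYNTHETIC_RISK_MODEL,
    sbp: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-person 10-year cardiovascular risk.

    ``sbp`` selects which systolic pressure enters the score; the
    default is the standard-rule effective SBP (mean of readings 2-3).
    Returns a frame with person_id, diabetes, risk; risk is NaN for
    countries in ``config.countries_without_model``.
    """
    if sbp is None:
        sbp = rules.diagnose(records, "standard")["effective_sbp"].to_numpy()
    else:
        sbp = np.asarray(sbp, dtype=float)
        if len(sbp) != len(records):
            raise ConfigError("sbp: length must match the cohort")
    history = records["diabetes_history"].to_numpy(bool) if "diabetes_history" in records \
        else np.zeros(len(records), dtype=bool)
    diabetes = flag_diabetes(history, records["fpg"], config.fpg_diabetes_cutoff)

    x = {
        "age": records["age"].to_numpy(float),
        "male": (records["sex"].to_numpy() == "male").astype(float),
        "smoker": records["smoker"].to_numpy(bool).astype(float),
        "sbp": sbp,
        "tc": records["tc"].to_numpy(float),
        "diabetes": diabetes.astype(float),
    }
    lp = np.zeros(len(records))
    lp_ref = 0.0
    for k, beta in config.coefficients.items():
        lp += beta * x[k]
        lp_ref += beta * float(config.reference.get(k, 0.0))
    s0 = 1.0 - config.baseline_for(records["region"].to_numpy())
    risk = 1.0 - np.power(s0, np.exp(lp - lp_ref))

    if config.countries_without_model:
        no_model = records["country"].isin(config.countries_without_model).to_numpy()
        risk = np.where(no_model, np.nan, risk)
    return pd.DataFrame(
        {"person_id": records["person_id"].to_numpy(), "diabetes": diabetes, "risk": risk},
        index=records.index,
    )
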