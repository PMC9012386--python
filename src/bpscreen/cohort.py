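"""Synthetic survey-cohort generator.

Emulates the structure of multi-country STEPS-style surveys: countries
nested in world regions, adults aged 18-69, cardiometabolic covariates,
and three serial blood-pressure readings per person in which the first
reading is systematically the highest (the well-known combination of an
alerting reaction and regression to the mean).

Generative model, per person ``i`` in country ``c``::

    latent_sbp_i = mu_sbp_c + b_age*(age-43.5) + b_bmi*(bmi-25.5)
                   + b_male*male + b_smoker*smoker + e_i
    sbp_reading_k = latent_sbp_i + offset_k + noise_ik

with ``(e_sbp, e_dbp)`` bivariate Gaussian (configurable correlation)
and iid Gaussian reading noise.  The per-country offsets default to
``(t_c, +0.7, -0.7)`` with ``t_c`` drawn uniformly from the calibration
range 0.70-5.75 mm Hg, so the mean excess of the first reading over the
average of the last two is exactly ``t_c``.  Covariates are mutually
independent except through their configured effects on the latent BP,
which keeps parameter-recovery tests interpretable.

Default country structure: 6 regions x 10 countries, per-country sample
sizes drawn uniformly from 215-7,431.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "CovariateParams",
    "BPEffects",
    "CohortConfig",
    "EligibilityReport",
    "generate_cohort",
    "apply_eligibility",
]

SBP_BAND = (50.0, 300.0)
DBP_BAND = (30.0, 200.0)


@dataclass
class CovariateParams:
    """Marginal distributions of the cardiometabolic covariates.

    Units: BMI kg/m2, waist cm, FPG and TC mmol/L; smoking prevalence,
    male fraction, and prevalence flags are proportions.
    """

    bmi_mean: float = 25.5
    bmi_sd: float = 4.2
    waist_intercept: float = 88.0      # waist at BMI 25.5, cm
    waist_per_bmi: float = 2.3         # cm per kg/m2
    waist_resid_sd: float = 6.0
    fpg_mean: float = 5.1
    fpg_sd: float = 1.2
    tc_mean: float = 4.4
    tc_sd: float = 1.0
    smoking_prevalence: float = 0.22
    male_fraction: float = 0.42
    diabetes_history_prevalence: float = 0.04

    def validate(self) -> None:
        for name in ("bmi_sd", "waist_resid_sd", "fpg_sd", "tc_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"covariate_params.{name}: must be > 0")
        for name in ("smoking_prevalence", "male_fraction", "diabetes_history_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"covariate_params.{name}: must be in [0, 1]")


@dataclass
class BPEffects:
    """Additive effects of covariates on latent SBP (mm Hg per unit).

    DBP effects are these values scaled by ``dbp_scale``.  Nonzero
    defaults make misdiagnosis-correlate recovery testable downstream.
    """

    age: float = 0.45       # per year, centred at 43.5
    bmi: float = 0.80       # per kg/m2, centred at 25.5
    male: float = 3.0
    smoker: float = 1.0
    dbp_scale: float = 0.5


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic cohort.

    Per-country latent means, sample sizes and first-reading offsets may
    be given explicitly (sequences over all countries, region-major
    order) or left ``None`` to be drawn once from the ``*_range``
    calibration intervals using the config seed.
    """

    n_regions: int = 6
    countries_per_region: int | Sequence[int] = 10
    n_per_country: Sequence[int] | None = None
    n_range: tuple[int, int] = (215, 7431)
    age_range: tuple[float, float] = (18, 69)

    latent_sbp_mean: Sequence[float] | None = None
    sbp_mean_range: tuple[float, float] = (118.0, 139.0)
    latent_sbp_sd: float = 14.0
    latent_dbp_mean: Sequence[float] | None = None
    dbp_mean_range: tuple[float, float] = (74.0, 84.0)
    latent_dbp_sd: float = 9.0
    sbp_dbp_correlation: float = 0.7

    # per-reading systematic shifts; None -> per-country (t_c, +0.7, -0.7)
    reading_offsets: tuple[float, float, float] | None = None
    first_excess_range: tuple[float, float] = (0.70, 5.75)
    dbp_offset_scale: float = 0.6
    reading_noise_sd: float = 6.0
    dbp_reading_noise_sd: float = 4.5

    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    risk_effect: BPEffects = field(default_factory=BPEffects)
    known_htn_prevalence: float = 0.12
    seed: int | None = 0

    # -- derived layout -------------------------------------------------
    @property
    def countries_per_region_list(self) -> list[int]:
        c = self.countries_per_region
        if isinstance(c, int):
            return [c] * self.n_regions
        return list(c)

    @property
    def n_countries(self) -> int:
        return sum(self.countries_per_region_list)

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions: must be >= 1")
        cpr = self.countries_per_region_list
        if len(cpr) != self.n_regions or any(c < 1 for c in cpr):
            raise ConfigError("countries_per_region: need one positive count per region")
        if self.n_per_country is not None:
            if len(self.n_per_country) != self.n_countries:
                raise ConfigError("n_per_country: length must equal total country count")
            if any(n < 2 for n in self.n_per_country):
                raise ConfigError("n_per_country: every country needs n >= 2")
        lo, hi = self.age_range
        if not (18 <= lo < hi <= 69):
            raise ConfigError("age_range: must lie within [18, 69] with lo < hi")
        for name in ("latent_sbp_sd", "latent_dbp_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        for name in ("reading_noise_sd", "dbp_reading_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if not -1 < self.sbp_dbp_correlation < 1:
            raise ConfigError("sbp_dbp_correlation: must be in (-1, 1)")
        if self.reading_offsets is not None:
            if len(self.reading_offsets) != 3 or not all(
                math.isfinite(o) for o in self.reading_offsets
            ):
                raise ConfigError("reading_offsets: need three finite values")
        if not 0 <= self.known_htn_prevalence < 1:
            raise ConfigError("known_htn_prevalence: must be in [0, 1)")
        for seq, name in ((self.latent_sbp_mean, "latent_sbp_mean"),
                          (self.latent_dbp_mean, "latent_dbp_mean")):
            if seq is not None and len(seq) != self.n_countries:
                raise ConfigError(f"{name}: length must equal total country count")
        self.covariate_params.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def _country_layout(config: CohortConfig, rng: np.random.Generator):
    """Resolve per-country parameters (drawn once from the config ranges)."""
    regions, countries = [], []
    for r, n_c in enumerate(config.countries_per_region_list):
        rid = f"R{r + 1}"
        for c in range(n_c):
            regions.append(rid)
            countries.append(f"{rid}_C{c + 1:02d}")
    k = len(countries)
    if config.n_per_country is not None:
        sizes = np.asarray(config.n_per_country, dtype=int)
    else:
        sizes = rng.integers(config.n_range[0], config.n_range[1] + 1, size=k)
    if config.latent_sbp_mean is not None:
        mu_s = np.asarray(config.latent_sbp_mean, dtype=float)
    else:
        mu_s = rng.uniform(*config.sbp_mean_range, size=k)
    if config.latent_dbp_mean is not None:
        mu_d = np.asarray(config.latent_dbp_mean, dtype=float)
    else:
        mu_d = rng.uniform(*config.dbp_mean_range, size=k)
    if config.reading_offsets is not None:
        offs = np.tile(np.asarray(config.reading_offsets, float), (k, 1))
    else:
        t = rng.uniform(*config.first_excess_range, size=k)
        offs = np.column_stack([t, np.full(k, 0.7), np.full(k, -0.7)])
    return regions, countries, sizes, mu_s, mu_d, offs


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a tidy table (one row per person).

    Deterministic given the seed (``seed`` argument overrides
    ``config.seed``).  Columns: person_id, country, region, sex, age,
    bmi, waist, smoker, fpg, tc, diabetes_history, known_htn,
    sbp1..sbp3, dbp1..dbp3.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ConfigError("seed: a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    regions, countries, sizes, mu_s, mu_d, offs = _country_layout(config, rng)

    cp = config.covariate_params
    eff = config.risk_effect
    frames = []
    start = 0
    for j, country in enumerate(countries):
        n = int(sizes[j])
        age = rng.uniform(config.age_range[0], config.age_range[1], n)
        male = rng.random(n) < cp.male_fraction
        bmi = np.clip(rng.normal(cp.bmi_mean, cp.bmi_sd, n), 14.0, 60.0)
        waist = (cp.waist_intercept + cp.waist_per_bmi * (bmi - 25.5)
                 + rng.normal(0.0, cp.waist_resid_sd, n))
        smoker = rng.random(n) < cp.smoking_prevalence
        fpg = np.clip(rng.normal(cp.fpg_mean, cp.fpg_sd, n), 2.5, None)
        tc = np.clip(rng.normal(cp.tc_mean, cp.tc_sd, n), 1.5, None)
        diabetes_history = rng.random(n) < cp.diabetes_history_prevalence
        known_htn = rng.random(n) < config.known_htn_prevalence

        shift = (eff.age * (age - 43.5) + eff.bmi * (bmi - 25.5)
                 + eff.male * male + eff.smoker * smoker)
        rho = config.sbp_dbp_correlation
        z = rng.standard_normal((n, 2))
        e_s = z[:, 0] * config.latent_sbp_sd
        e_d = (rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]) * config.latent_dbp_sd
        latent_s = mu_s[j] + shift + e_s
        latent_d = mu_d[j] + eff.dbp_scale * shift + e_d

        sbp = latent_s[:, None] + offs[j][None, :] + rng.normal(
            0.0, config.reading_noise_sd, (n, 3)) if config.reading_noise_sd > 0 else \
            latent_s[:, None] + offs[j][None, :]
        d_offs = offs[j] * config.dbp_offset_scale
        dbp = latent_d[:, None] + d_offs[None, :] + rng.normal(
            0.0, config.dbp_reading_noise_sd, (n, 3)) if config.dbp_reading_noise_sd > 0 else \
            latent_d[:, None] + d_offs[None, :]
        sbp = np.clip(sbp, *SBP_BAND)
        dbp = np.clip(dbp, *DBP_BAND)

        frames.append(pd.DataFrame({
            "person_id": np.arange(start, start + n),
            "country": country,
            "region": regions[j],
            "sex": np.where(male, "male", "female"),
            "age": age,
            "bmi": bmi,
            "waist": waist,
            "smoker": smoker,
            "fpg": fpg,
            "tc": tc,
            "diabetes_history": diabetes_history,
            "known_htn": known_htn,
            "sbp1": sbp[:, 0], "sbp2": sbp[:, 1], "sbp3": sbp[:, 2],
            "dbp1": dbp[:, 0], "dbp2": dbp[:, 1], "dbp3": dbp[:, 2],
        }))
        start += n
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EligibilityReport:
    """Flow-chart style accounting of the eligibility filter."""

    rows_in: int
    excluded_missing_known_htn: int
    excluded_known_htn: int
    excluded_age: int
    rows_out: int

    def to_dict(self) -> dict:
        return asdict(self)


def apply_eligibility(
    records: pd.DataFrame, age_range: tuple[float, float] = (18, 69)
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Restrict to the screening target population.

    Keeps people free of known hypertension (no self-reported diagnosis
    or antihypertensive medication) and aged within ``age_range``
    (inclusive at both ends).  A record whose ``known_htn`` flag is
    missing cannot be confirmed eligible and is excluded; counts per
    exclusion reason are returned alongside the filtered table.  The
    filter is idempotent.
    """
    if "known_htn" not in records.columns or "age" not in records.columns:
        raise ConfigError("apply_eligibility: records need 'known_htn' and 'age' columns")
    n_in = len(records)
    missing = records["known_htn"].isna()
    known = records["known_htn"].where(~missing, False).astype(bool)
    lo, hi = age_range
    age_out = ~records["age"].between(lo, hi)
    # reasons are assessed hierarchically: missing flag, then known HTN, then age
    excl_missing = missing
    excl_known = known & ~excl_missing
    excl_age = age_out & ~excl_missing & ~excl_known
    keep = ~(excl_missing | excl_known | excl_age)
    report = EligibilityReport(
        rows_in=n_in,
        excluded_missing_known_htn=int(excl_missing.sum()),
        excluded_known_htn=int(excl_known.sum()),
        excluded_age=int(excl_age.sum()),
        rows_out=int(keep.sum()),
    )
    return records.loc[keep].copy(), report
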