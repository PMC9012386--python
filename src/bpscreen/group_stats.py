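"""Cardiovascular-risk comparisons between concordance groups.

Within each country and screening approach, the mean 10-year risk of
the missed, over-diagnosed and consistent non-hypertension groups is
compared against the consistent-hypertension reference group with
two-sided t tests (Welch's unequal-variance variant by default;
Student's pooled variant by flag).  Crude and Bonferroni-adjusted
p-values are both reported; the default family size is 3 — the three
non-reference groups within one country x approach.  The relative mean
risk is also reported as ``100 * mean(group) / mean(reference)`` %.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import GROUPS
from .errors import ConfigError

__all__ = ["GroupComparison", "risk_ratio_pct", "compare_groups", "compare_by_country"]

REFERENCE_GROUP = "consistent_htn"
COMPARISON_GROUPS = ("missed", "over_diagnosed", "consistent_non_htn")
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """One group-vs-reference mean-risk comparison."""

    group: str
    n_group: int
    n_reference: int
    mean_risk: float
    sd_risk: float
    mean_reference: float
    sd_reference: float
    t_statistic: float
    p_value: float
    p_bonferroni: float
    ratio_pct: float
    status: str  # 'ok' | 'too_small' | 'degenerate'

    def to_dict(self) -> dict:
        return asdict(self)


def risk_ratio_pct(mean_group: float, mean_reference: float) -> float:
    """Group mean risk as a percentage of the reference mean.

    A non-positive reference mean leaves the ratio undefined (NaN).
    """
    if not mean_reference > 0:
        return float("nan")
    return 100.0 * mean_group / mean_reference


def _one_comparison(
    g: np.ndarray, ref: np.ndarray, name: str, family_size: int, equal_var: bool
) -> GroupComparison:
    n_g, n_r = len(g), len(ref)
    mean_g = float(np.mean(g)) if n_g else float("nan")
    sd_g = float(np.std(g, ddof=1)) if n_g > 1 else float("nan")
    mean_r, sd_r = float(np.mean(ref)), float(np.std(ref, ddof=1)) if n_r > 1 else float("nan")
    ratio = risk_ratio_pct(mean_g, mean_r) if n_g else float("nan")
    if n_g < 2 or n_r < 2:
        return GroupComparison(name, n_g, n_r, mean_g, sd_g, mean_r, sd_r,
                               float("nan"), float("nan"), float("nan"), ratio, "too_small")
    if np.ptp(g) == 0 and np.ptp(ref) == 0:
        # no variance anywhere: t is 0/0; flagged, p reported missing
        return GroupComparison(name, n_g, n_r, mean_g, sd_g, mean_r, sd_r,
                               float("nan"), float("nan"), float("nan"), ratio, "degenerate")
    t, p = stats.ttest_ind(g, ref, equal_var=equal_var)
    p_bonf = min(1.0, family_size * float(p))
    return GroupComparison(name, n_g, n_r, mean_g, sd_g, mean_r, sd_r,
                           float(t), float(p), p_bonf, ratio, "ok")


def compare_groups(
    risks_by_group: Mapping[str, Sequence[float]],
    reference_group: str = REFERENCE_GROUP,
    family_size: int = 3,
    equal_var: bool = False,
) -> list[GroupComparison]:
    """Compare each non-reference group's mean risk to the reference.

    ``equal_var=False`` (default) is Welch's t test; ``True`` gives the
    pooled-variance Student variant.  Missing risks are dropped before
    testing.  The reference group must be nonempty.
    """
    if reference_group not in risks_by_group:
        raise ConfigError(f"reference group {reference_group!r} absent")
    ref = np.asarray(risks_by_group[reference_group], dtype=float)
    ref = ref[~np.isnan(ref)]
    if len(ref) == 0:
        raise ConfigError(f"reference group {reference_group!r} is empty")
    if family_size < 1:
        raise ConfigError("family_size: must be >= 1")
    out = []
    for name, values in risks_by_group.items():
        if name == reference_group:
            continue
        g = np.asarray(values, dtype=float)
        g = g[~np.isnan(g)]
        out.append(_one_comparison(g, ref, name, family_size, equal_var))
    return out


def compare_by_country(
    classified_with_risk: pd.DataFrame,
    family_size: int = 3,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Run the group comparisons per country x approach.

    Input is a long frame with columns country, approach_id, group and
    risk (the per-person classification joined with the risk score).
    Countries whose reference group is empty are reported with status
    'no_reference' rather than raising.
    """
    rows = []
    for (country, approach), g in classified_with_risk.groupby(
        ["country", "approach_id"], observed=True
    ):
        by_group = {
            grp: g.loc[g["group"] == grp, "risk"].to_numpy() for grp in GROUPS
        }
        ref = by_group[REFERENCE_GROUP]
        if len(ref[~np.isnan(ref)]) == 0:
            for name in COMPARISON_GROUPS:
                rows.append({"country": country, "approach_id": approach, "group": name,
                             "status": "no_reference"})
            continue
        for comp in compare_groups(by_group, family_size=family_size, equal_var=equal_var):
            row = {"country": country, "approach_id": approach}
            row.update(comp.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
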