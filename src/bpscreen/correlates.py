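"""Multilevel Poisson models for correlates of missed diagnosis.

For each simplified screening rule, an individual-level log-link
Poisson regression of the binary outcome "missed" (hypertensive by the
standard rule, not by the simplified rule — yes/no) is fitted on ALL
eligible individuals, with fixed effects for female sex, age (years),
BMI (kg/m2) and 10-year cardiovascular risk (on its native 0-1 scale,
so its coefficient is per absolute risk unit), and random intercepts
for countries nested within regions.  A Poisson rather than logistic
model is kept deliberately: the exponentiated coefficients are
prevalence ratios (PRs), the effect measure of interest.  95% CIs are
Wald-type; robust (sandwich) errors are not applied.

Estimation is maximum likelihood under the Laplace approximation, in
the style of lme4's glmer: for candidate variance components the
penalized log-likelihood is maximized jointly over fixed effects and
random intercepts by Newton's method, the Laplace-corrected marginal
likelihood is profiled, and the two variance parameters (country
within region, region) are optimized on the log-SD scale.  Standard
errors are conditional on the estimated variance components, as is
conventional.  The fit is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from . import concordance
from .errors import ConvergenceError, DegenerateDesignError, NoEventsError

__all__ = ["GLMMTerm", "GLMMEstimate", "fit_poisson_glmm", "fit_missed_model"]

FIXED_TERMS = ("female_sex", "age", "bmi", "cv_risk")

#: Bounds for the random-intercept log-SDs; the lower bound is an
#: effective zero (SD 0.0025) so variance components may collapse.
LOG_SD_BOUNDS = (-6.0, 2.0)
_Z975 = 1.959963984540054


@dataclass(frozen=True)
class GLMMTerm:
    """One fixed-effect estimate on the prevalence-ratio scale."""

    coef: float
    se: float
    pr: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class GLMMEstimate:
    """Fitted misdiagnosis-correlate model for one approach."""

    approach_id: str
    terms: dict[str, GLMMTerm] = field(repr=False)
    var_country_in_region: float
    var_region: float
    n_obs: int
    n_events: int
    gradient_norm: float
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.terms.items():
            d = {"approach_id": self.approach_id, "term": name}
            d.update(asdict(t))
            rows.append(d)
        df = pd.DataFrame(rows)
        df["var_country_in_region"] = self.var_country_in_region
        df["var_region"] = self.var_region
        df["n_obs"] = self.n_obs
        return df


def _design(records: pd.DataFrame, risk: np.ndarray) -> np.ndarray:
    return np.column_stack([
        np.ones(len(records)),
        (records["sex"].to_numpy() == "female").astype(float),
        records["age"].to_numpy(float),
        records["bmi"].to_numpy(float),
        np.asarray(risk, dtype=float),
    ])


def _grouping(country: np.ndarray, region: np.ndarray):
    """Integer codes for countries/regions plus the nesting map."""
    countries = pd.unique(country)
    regions = pd.unique(region)
    if len(regions) < 2:
        raise DegenerateDesignError(
            f"need >= 2 regions for nested random intercepts, got {len(regions)}"
        )
    per_region = pd.Series(country).groupby(pd.Series(region)).nunique()
    thin = per_region[per_region < 2]
    if len(thin):
        raise DegenerateDesignError(
            "need >= 2 countries per region; offending region(s): "
            + ", ".join(map(str, thin.index))
        )
    c_idx = pd.Categorical(country, categories=countries).codes.astype(np.intp)
    r_idx = pd.Categorical(region, categories=regions).codes.astype(np.intp)
    # each country sits in exactly one region (nesting)
    r_of_c = np.empty(len(countries), dtype=np.intp)
    r_of_c[c_idx] = r_idx
    return c_idx, r_idx, len(countries), len(regions), r_of_c


class _LaplaceState:
    """Working quantities for one model; reused across outer iterations."""

    def __init__(self, y, X, c_idx, r_idx, n_c, n_r, r_of_c):
        self.y, self.X = y, X
        self.c_idx, self.r_idx = c_idx, r_idx
        self.n_c, self.n_r, self.r_of_c = n_c, n_r, r_of_c
        self.p = X.shape[1]
        self.q = n_c + n_r
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.q)
        self.n_inner_fail = 0

    def eta(self, beta, u):
        return self.X @ beta + u[self.c_idx] + u[self.n_c + self.r_idx]

    def penalized_ll(self, beta, u, d_inv):
        eta = np.clip(self.eta(beta, u), -40.0, 40.0)
        return float(self.y @ eta - np.exp(eta).sum() - 0.5 * (d_inv * u * u).sum())

    def hessian(self, w, d_inv):
        """Negative Hessian of the penalized log-likelihood (PD)."""
        X, p, n_c, n_r = self.X, self.p, self.n_c, self.n_r
        H = np.zeros((p + self.q, p + self.q))
        Xw = X * w[:, None]
        H[:p, :p] = Xw.T @ X
        Bc = np.stack([np.bincount(self.c_idx, w * X[:, j], minlength=n_c)
                       for j in range(p)])
        Br = np.stack([np.bincount(self.r_idx, w * X[:, j], minlength=n_r)
                       for j in range(p)])
        H[:p, p:p + n_c] = Bc
        H[:p, p + n_c:] = Br
        H[p:p + n_c, :p] = Bc.T
        H[p + n_c:, :p] = Br.T
        wc = np.bincount(self.c_idx, w, minlength=n_c)
        wr = np.bincount(self.r_idx, w, minlength=n_r)
        uu = H[p:, p:]
        uu[np.arange(n_c), np.arange(n_c)] = wc
        uu[n_c + np.arange(n_r), n_c + np.arange(n_r)] = wr
        uu[np.arange(n_c), n_c + self.r_of_c] = wc
        uu[n_c + self.r_of_c, np.arange(n_c)] = wc
        H[p:, p:] += np.diag(d_inv)
        return H

    def inner_newton(self, d_inv, tol=1e-8, max_iter=60):
        """Maximize the penalized log-likelihood over (beta, u)."""
        beta, u = self.beta.copy(), self.u.copy()
        f = self.penalized_ll(beta, u, d_inv)
        H = None
        for _ in range(max_iter):
            eta = np.clip(self.eta(beta, u), -40.0, 40.0)
            mu = np.exp(eta)
            resid = self.y - mu
            g = np.concatenate([
                self.X.T @ resid,
                np.concatenate([
                    np.bincount(self.c_idx, resid, minlength=self.n_c),
                    np.bincount(self.r_idx, resid, minlength=self.n_r),
                ]) - d_inv * u,
            ])
            gnorm = float(np.abs(g).max())
            H = self.hessian(mu, d_inv)
            if gnorm < tol * (1.0 + abs(f)):
                break
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            for _ in range(40):
                nb, nu = beta + t * step[:self.p], u + t * step[self.p:]
                fn = self.penalized_ll(nb, nu, d_inv)
                if fn > f - 1e-12:
                    break
                t *= 0.5
            else:
                self.n_inner_fail += 1
                break
            beta, u, f = nb, nu, fn
        self.beta, self.u = beta, u  # warm start for the next outer step
        return beta, u, f, H, gnorm

    def laplace_ll(self, phi):
        """Profiled Laplace marginal log-likelihood at log-SDs ``phi``."""
        sd_c, sd_r = np.exp(phi)
        d_inv = np.concatenate([
            np.full(self.n_c, sd_c**-2), np.full(self.n_r, sd_r**-2)])
        _, _, f, H, _ = self.inner_newton(d_inv)
        sign, logdet_uu = np.linalg.slogdet(H[self.p:, self.p:])
        if sign <= 0:
            return -np.inf
        return (f - 0.5 * logdet_uu
                - (self.n_c * phi[0] + self.n_r * phi[1]))


def fit_poisson_glmm(
    outcome: np.ndarray,
    exog: np.ndarray,
    country: np.ndarray,
    region: np.ndarray,
    approach_id: str = "",
    term_names: tuple[str, ...] = FIXED_TERMS,
) -> GLMMEstimate:
    """Fit a log-link Poisson model with country-in-region intercepts.

    ``exog`` must carry an intercept as its first column; the remaining
    columns are reported under ``term_names``.  Raises
    :class:`NoEventsError` when the outcome has no positive cases,
    :class:`DegenerateDesignError` on unusable grouping, and
    :class:`ConvergenceError` when the optimum is not reached (the
    exception carries the residual gradient norm).
    """
    y = np.asarray(outcome, dtype=float)
    n_events = int(y.sum())
    if n_events == 0:
        raise NoEventsError(f"{approach_id or 'model'}: outcome has zero positive cases")
    c_idx, r_idx, n_c, n_r, r_of_c = _grouping(np.asarray(country), np.asarray(region))

    # standardize non-intercept columns for conditioning; slopes and SEs
    # are transformed back afterwards
    X = np.asarray(exog, dtype=float)
    centre = X[:, 1:].mean(axis=0)
    scale = X[:, 1:].std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X.copy()
    Xs[:, 1:] = (X[:, 1:] - centre) / scale

    state = _LaplaceState(y, Xs, c_idx, r_idx, n_c, n_r, r_of_c)
    # initialise the fixed effects at the no-random-effect optimum
    state.inner_newton(np.full(state.q, 1e12))

    res = minimize(lambda phi: -state.laplace_ll(phi), x0=np.log([0.3, 0.3]),
                   method="Powell",
                   bounds=[LOG_SD_BOUNDS, LOG_SD_BOUNDS],
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 200})
    phi = np.clip(res.x, *LOG_SD_BOUNDS)
    sd_c, sd_r = np.exp(phi)

    d_inv = np.concatenate([np.full(n_c, sd_c**-2), np.full(n_r, sd_r**-2)])
    beta, u, f, H, gnorm = state.inner_newton(d_inv, tol=1e-10)
    if gnorm > 1e-4 * (1.0 + abs(f)) or not np.isfinite(f):
        raise ConvergenceError(
            f"{approach_id or 'model'}: Laplace fit did not converge "
            f"(inner gradient norm {gnorm:g})", gradient_norm=gnorm)

    cov = np.linalg.inv(H)
    coefs = beta[1:] / scale
    ses = np.sqrt(np.diag(cov)[1:state.p]) / scale
    z = coefs / ses
    terms = {}
    for name, b_, s_, z_ in zip(term_names, coefs, ses, z):
        terms[name] = GLMMTerm(
            coef=float(b_), se=float(s_), pr=float(np.exp(b_)),
            ci_low=float(np.exp(b_ - _Z975 * s_)),
            ci_high=float(np.exp(b_ + _Z975 * s_)),
            p_value=float(2.0 * stats.norm.sf(abs(z_))),
        )
    return GLMMEstimate(
        approach_id=approach_id,
        terms=terms,
        var_country_in_region=float(sd_c**2),
        var_region=float(sd_r**2),
        n_obs=len(y),
        n_events=n_events,
        gradient_norm=gnorm,
        message=f"laplace ML, {res.nfev} outer evaluations",
    )


def fit_missed_model(
    records: pd.DataFrame,
    approach_id: str,
    risk: pd.Series | np.ndarray,
) -> GLMMEstimate:
    """Fit the missed-diagnosis model for one simplified approach.

    ``records`` is the eligible cohort; ``risk`` the per-person 10-year
    risk aligned with it.  Rows with missing risk are excluded (a
    country without a risk model contributes no rows), matching a
    complete-case analysis; the outcome is computed internally from the
    standard and simplified diagnoses.
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(records):
        raise ValueError("risk must align with records")
    cls = concordance.classify(records, [approach_id])
    outcome = (cls["group"].to_numpy() == "missed").astype(float)
    keep = ~np.isnan(risk)
    sub = records.loc[keep]
    return fit_poisson_glmm(
        outcome[keep],
        _design(sub, risk[keep]),
        sub["country"].to_numpy(),
        sub["region"].to_numpy(),
        approach_id=approach_id,
    )
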