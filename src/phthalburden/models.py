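"""Pooled association models with a cohort random intercept.

Continuous outcomes are fit with linear mixed models (REML, via
``statsmodels`` MixedLM); dichotomous outcomes with a random-intercept
logistic model fit by adaptive Gauss–Hermite maximum likelihood (the same
algorithm as lme4's ``glmer``), implemented here because no installed
Python package provides a frequentist binomial GLMM. Since every
dichotomous outcome is rare (<10%), odds ratios are interpreted as risk
ratios downstream.

The default adjustment set is maternal age (continuous years), maternal
race/ethnicity (4 levels), maternal education (dichotomised: high school or
less vs some college and higher), parity (0 / 1 / >=2), and child sex;
child sex and parity are dropped when the outcome is the birthweight-for-
gestational-age z-score (they are already in the standardisation).
Categorical missingness is retained as an explicit "missing" level;
dyads missing a continuous covariate, the outcome, or the exposure are
dropped, and each result reports the n actually used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "DEFAULT_COVARIATES",
    "OUTCOME_FAMILIES",
    "fit_association",
    "fit_logistic_random_intercept",
    "run_model_grid",
    "stratified_models",
    "leave_one_out",
    "covariate_sensitivity",
    "join_analysis_table",
]

DEFAULT_COVARIATES: tuple[str, ...] = (
    "maternal_age", "race_ethnicity", "education", "parity", "child_sex",
)

#: outcome name -> model family
OUTCOME_FAMILIES: dict[str, str] = {
    "gestational_age": "linear",
    "birthweight": "linear",
    "birth_length": "linear",
    "bw_for_ga_z": "linear",
    "bw_for_ga_z_sex_only": "linear",
    "preterm": "logistic",
    "sga": "logistic",
    "lga": "logistic",
    "low_birthweight": "logistic",
}

CONTINUOUS_OUTCOMES = tuple(k for k, v in OUTCOME_FAMILIES.items() if v == "linear")[:4]
BINARY_OUTCOMES = tuple(k for k, v in OUTCOME_FAMILIES.items() if v == "logistic")


@dataclass(frozen=True)
class ModelSpec:
    """One exposure-outcome model definition."""

    outcome: str
    exposure_group: str
    timing: str = "pregnancy_average"          # or t1 / t2 / t3
    family: str | None = None                  # inferred from outcome if None
    covariates: tuple[str, ...] | None = None  # None -> default set
    strata_variable: str | None = None
    excluded_cohort: str | None = None
    extra_covariates: tuple[str, ...] = ()

    def resolved_family(self) -> str:
        if self.family is not None:
            return self.family
        try:
            return OUTCOME_FAMILIES[self.outcome]
        except KeyError:
            raise ValueError(f"unknown outcome {self.outcome!r}; give family explicitly")

    def resolved_covariates(self) -> tuple[str, ...]:
        if self.covariates is not None:
            cov = self.covariates
        else:
            cov = DEFAULT_COVARIATES
            if self.outcome.startswith("bw_for_ga_z"):
                cov = tuple(c for c in cov if c not in ("child_sex", "parity"))
        return cov + tuple(c for c in self.extra_covariates if c not in cov)

    @property
    def exposure_column(self) -> str:
        return f"log10_{self.timing}_{self.exposure_group}"


@dataclass
class ModelResult:
    """Adjusted coefficient (per log10-unit exposure increase) with Wald CI."""

    spec: ModelSpec
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_dyads: int
    n_cohorts: int
    converged: bool
    random_intercept_sd: float
    method: str
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def to_dict(self) -> dict:
        d = {
            "outcome": self.spec.outcome,
            "exposure_group": self.spec.exposure_group,
            "timing": self.spec.timing,
            "family": self.spec.resolved_family(),
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "n_dyads": self.n_dyads,
            "n_cohorts": self.n_cohorts,
            "converged": self.converged,
            "random_intercept_sd": self.random_intercept_sd,
            "method": self.method,
        }
        if self.spec.strata_variable:
            d["strata_variable"] = self.spec.strata_variable
        if self.spec.excluded_cohort:
            d["excluded_cohort"] = self.spec.excluded_cohort
        return d


def join_analysis_table(
    dyads: pd.DataFrame,
    exposure_summary: pd.DataFrame,
    derived_outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Join dyad covariates, derived outcomes, and wide exposure columns.

    Exposure columns are named ``log10_<timing>_<group>`` for timing in
    pregnancy_average / t1 / t2 / t3.
    """
    wide = exposure_summary.pivot(index="dyad_id", columns="group")
    cols = {}
    for timing in ("pregnancy_average", "t1", "t2", "t3"):
        src = f"log10_{timing}"
        if src in {c[0] for c in wide.columns}:
            for g in wide[src].columns:
                cols[f"log10_{timing}_{g}"] = wide[(src, g)]
    expo = pd.DataFrame(cols)
    out = dyads.merge(derived_outcomes, on="dyad_id", how="left")
    out = out.merge(expo, left_on="dyad_id", right_index=True, how="left")
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _encode_covariate(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if name == "maternal_age":
        return pd.DataFrame({"maternal_age": df["maternal_age"].astype(float)})
    if name == "race_ethnicity":
        r = df["race_ethnicity"].fillna("other")
        return pd.DataFrame(
            {
                "race_nh_black": (r == "nh_black").astype(float),
                "race_hispanic": (r == "hispanic").astype(float),
                "race_other": (r == "other").astype(float),
            }
        )
    if name == "education":
        e = df["education"].fillna("missing")
        low = e.isin(["less_than_hs", "hs_ged"])
        return pd.DataFrame(
            {
                "edu_hs_or_less": low.astype(float),
                "edu_missing": (e == "missing").astype(float),
            }
        )
    if name == "parity":
        p = df["parity"]
        return pd.DataFrame(
            {
                "parity_1": (p == 1).astype(float),
                "parity_2plus": (p >= 2).astype(float),
                "parity_missing": p.isna().astype(float),
            }
        )
    if name == "child_sex":
        return pd.DataFrame({"sex_female": (df["child_sex"] == "female").astype(float)})
    if name == "tobacco":
        t = df["tobacco"].fillna("missing")
        return pd.DataFrame(
            {
                "tobacco_yes": (t == "yes").astype(float),
                "tobacco_missing": (t == "missing").astype(float),
            }
        )
    # any other covariate: pass through as numeric
    return pd.DataFrame({name: pd.to_numeric(df[name], errors="coerce")})


def _build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Return (exog with intercept+exposure+covariates, endog, cohorts, names)."""
    xcol = spec.exposure_column
    if xcol not in data.columns:
        raise KeyError(f"exposure column {xcol!r} not in analysis table")
    df = data
    if spec.excluded_cohort is not None:
        df = df[df["cohort"] != spec.excluded_cohort]
    parts = [pd.DataFrame({"const": np.ones(len(df)), "exposure": df[xcol].astype(float)},
                          index=df.index)]
    for cov in spec.resolved_covariates():
        parts.append(_encode_covariate(df, cov).set_index(df.index))
    X = pd.concat(parts, axis=1)
    y = pd.to_numeric(df[spec.outcome], errors="coerce")
    ok = y.notna() & X.notna().all(axis=1)
    if "child_sex" in spec.resolved_covariates():
        ok &= df["child_sex"].notna()
    X, y = X[ok], y[ok]
    cohorts = df.loc[ok, "cohort"]
    # drop constant columns (empty levels) except the intercept
    keep = ["const", "exposure"] + [
        c for c in X.columns[2:] if X[c].nunique() > 1
    ]
    X = X[keep]
    return X, y.astype(float), cohorts, keep


# ---------------------------------------------------------------------------
# logistic GLMM by adaptive Gauss-Hermite maximum likelihood
# ---------------------------------------------------------------------------

class _AGQLogistic:
    """Marginal likelihood machinery for a random-intercept logistic model.

    One normal random intercept per cluster, integrated out with adaptive
    Gauss–Hermite quadrature (nodes recentred at each cluster's posterior
    mode and rescaled by its curvature). Gradient via the Fisher identity
    on the same nodes.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, n_quad: int = 25):
        self.X, self.y = X, y
        self.labels, self.idx = np.unique(groups, return_inverse=True)
        self.cluster_rows = [np.nonzero(self.idx == j)[0] for j in range(len(self.labels))]
        t, w = hermgauss(n_quad)
        self.t, self.logw = t, np.log(w)

    def _cluster_mode(self, eta0: np.ndarray, yj: np.ndarray, sigma: float) -> tuple[float, float]:
        u = 0.0
        for _ in range(50):
            p = expit(eta0 + sigma * u)
            g1 = sigma * np.sum(yj - p) - u
            g2 = -(sigma**2) * np.sum(p * (1.0 - p)) - 1.0
            step = g1 / g2
            u -= step
            if abs(step) < 1e-12:
                break
        p = expit(eta0 + sigma * u)
        g2 = -(sigma**2) * np.sum(p * (1.0 - p)) - 1.0
        return u, 1.0 / np.sqrt(-g2)

    def nll_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, sigma = theta[:-1], theta[-1]
        eta_all = self.X @ beta
        ll = 0.0
        grad = np.zeros_like(theta)
        for rows in self.cluster_rows:
            yj, Xj, eta0 = self.y[rows], self.X[rows], eta_all[rows]
            uhat, shat = self._cluster_mode(eta0, yj, sigma)
            u_k = uhat + np.sqrt(2.0) * shat * self.t          # (K,)
            eta_k = eta0[None, :] + sigma * u_k[:, None]        # (K, nj)
            # log joint at each node, + t^2 from the AGQ weight transform
            logp = -np.logaddexp(0.0, -eta_k)
            log1mp = -np.logaddexp(0.0, eta_k)
            g_k = (yj * logp + (1.0 - yj) * log1mp).sum(axis=1) - 0.5 * u_k**2
            a_k = self.logw + self.t**2 + g_k
            m = a_k.max()
            s = np.exp(a_k - m)
            denom = s.sum()
            ll += m + np.log(denom) + np.log(np.sqrt(2.0) * shat) - 0.5 * np.log(2.0 * np.pi)
            omega = s / denom
            resid_k = yj[None, :] - expit(eta_k)                # (K, nj)
            grad[:-1] += (omega[:, None] * (resid_k @ Xj)).sum(axis=0)
            grad[-1] += float(omega @ (resid_k.sum(axis=1) * u_k))
        return -ll, -grad

    def nll(self, theta: np.ndarray) -> float:
        return self.nll_grad(theta)[0]


def fit_logistic_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 25,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """ML fit of a logistic model with a normal cluster intercept.

    Returns ``(beta, se_beta, sigma, converged)`` where sigma is the fitted
    random-intercept SD. Standard errors come from the observed information
    (numerical Hessian of the marginal log-likelihood).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    start_model = sm.Logit(y, X)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = start_model.fit(disp=0, maxiter=200)
        beta0 = start.params
        if not start.mle_retvals.get("converged", True) or np.any(
            np.abs(beta0) > 50
        ):
            converged = False
    except Exception:  # separation or singular design
        beta0 = np.zeros(X.shape[1])
        converged = False

    agq = _AGQLogistic(X, y, groups, n_quad=n_quad)
    theta0 = np.concatenate([beta0, [0.3]])
    res = minimize(
        agq.nll_grad, theta0, jac=True, method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(0.0, None)],
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    if not res.success:
        # retry from the optimum with numerical gradients before flagging
        res2 = minimize(
            agq.nll, theta, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res2.fun <= res.fun:
            theta = res2.x
            theta[-1] = max(theta[-1], 0.0)
        converged = converged and res2.success
    sigma = float(theta[-1])

    # observed information; drop the sigma row when it sits on the boundary
    from statsmodels.tools.numdiff import approx_hess1
    free = theta.size if sigma > 1e-4 else theta.size - 1
    def nll_free(t_free: np.ndarray) -> float:
        t = np.concatenate([t_free, theta[free:]])
        return agq.nll(t)
    H = approx_hess1(theta[:free], nll_free)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))[: X.shape[1]]
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        converged = False
    if np.any(~np.isfinite(se)) or np.any(se == 0):
        converged = False
    return theta[: X.shape[1]], se, sigma, bool(converged)


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

Z95 = float(norm.ppf(0.975))


def fit_association(spec: ModelSpec, data: pd.DataFrame, n_quad: int = 25) -> ModelResult:
    """Fit one adjusted exposure-outcome association with a cohort random
    intercept; single-cohort data degrade to a fixed-intercept fit with a
    warning. Non-convergence is flagged on the result, never silent."""
    family = spec.resolved_family()
    X, y, cohorts, names = _build_design(data, spec)
    n = len(y)
    n_cohorts = cohorts.nunique()
    if n == 0:
        raise ValueError(f"no complete observations for {spec}")
    j = names.index("exposure")

    if n_cohorts < 2:
        logger.warning("single cohort: degrading to fixed-intercept fit for %s", spec.outcome)
        if family == "linear":
            fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
            beta, se, conv, sigma, method = fit.params[j], fit.bse[j], True, 0.0, "ols"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0)
            beta, se = fit.params[j], fit.bse[j]
            conv, sigma, method = bool(fit.mle_retvals["converged"]), 0.0, "logit"
    elif family == "linear":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y.to_numpy(), X.to_numpy(), groups=cohorts.to_numpy())
            fit = model.fit(reml=True)
        conv = bool(fit.converged)
        var_u = float(max(np.asarray(fit.cov_re)[0, 0], 0.0))
        sigma = float(np.sqrt(var_u))
        # an intercept variance indistinguishable from zero (ICC < 0.5%)
        # would only inject numerical noise through the GLS weights; the
        # model then reduces to an ordinary fixed-intercept fit
        if var_u / max(float(fit.scale), 1e-300) < 5e-3:
            ols = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
            beta, se = ols.params[j], ols.bse[j]
            method = "mixedlm_reml_degenerate_ols"
        else:
            beta, se = fit.params[j], fit.bse[j]
            method = "mixedlm_reml"
    elif family == "logistic":
        betas, ses, sigma, conv = fit_logistic_random_intercept(
            X.to_numpy(), y.to_numpy(), cohorts.to_numpy(), n_quad=n_quad
        )
        beta, se = betas[j], ses[j]
        method = "logistic_agq_ml"
    else:
        raise ValueError(f"unknown family {family!r}")

    beta, se = float(beta), float(se)
    lo, hi = beta - Z95 * se, beta + Z95 * se
    result = ModelResult(
        spec=spec, beta=beta, se=se, ci_low=lo, ci_high=hi,
        n_dyads=int(n), n_cohorts=int(n_cohorts), converged=conv,
        random_intercept_sd=float(sigma), method=method,
    )
    if family == "logistic":
        result.odds_ratio = float(np.exp(beta))
        result.or_ci_low = float(np.exp(lo))
        result.or_ci_high = float(np.exp(hi))
    return result


def run_model_grid(
    data: pd.DataFrame,
    exposure_groups: list[str],
    outcomes: list[str],
    timings: list[str] = ["pregnancy_average"],
    n_quad: int = 25,
) -> pd.DataFrame:
    """One adjusted model per (group x outcome x timing); tidy result table.

    Combinations whose exposure column is absent or entirely missing are
    skipped with a log entry (a group unavailable in every cohort).
    """
    rows = []
    for g in exposure_groups:
        for out in outcomes:
            for t in timings:
                spec = ModelSpec(outcome=out, exposure_group=g, timing=t)
                col = spec.exposure_column
                if col not in data.columns or data[col].notna().sum() == 0:
                    logger.info("skipping %s x %s x %s: exposure unavailable", g, out, t)
                    continue
                rows.append(fit_association(spec, data, n_quad=n_quad).to_dict())
    return pd.DataFrame(rows)


def stratified_models(
    spec: ModelSpec, data: pd.DataFrame, strata_variable: str, n_quad: int = 25
) -> pd.DataFrame:
    """Refit the model within each stratum of ``strata_variable``.

    Strata represented by fewer than two cohorts (or empty) are skipped with
    a log entry. No interaction terms are used — full stratification.
    """
    rows = []
    strata = data[strata_variable].dropna().unique()
    cov = tuple(c for c in spec.resolved_covariates() if c != strata_variable)
    for level in sorted(map(str, strata)):
        sub = data[data[strata_variable].astype(str) == level]
        if sub.empty or sub["cohort"].nunique() < 2:
            logger.info("stratum %s=%s skipped (fewer than 2 cohorts)", strata_variable, level)
            continue
        sspec = replace(spec, strata_variable=strata_variable, covariates=cov)
        rec = fit_association(sspec, sub, n_quad=n_quad).to_dict()
        rec["stratum"] = level
        rows.append(rec)
    return pd.DataFrame(rows)


def leave_one_out(
    spec: ModelSpec,
    data: pd.DataFrame,
    influence_fraction: float = 0.30,
    n_quad: int = 25,
) -> pd.DataFrame:
    """Refit excluding each cohort in turn; flag influential cohorts.

    A cohort is influential when its exclusion flips the estimate's sign or
    moves it by more than ``influence_fraction`` of the full-sample value.
    """
    if data["cohort"].nunique() < 3:
        raise ValueError("leave-one-out requires at least 3 cohorts")
    full = fit_association(spec, data, n_quad=n_quad)
    rows = []
    for cohort in sorted(data["cohort"].unique()):
        res = fit_association(replace(spec, excluded_cohort=str(cohort)), data, n_quad=n_quad)
        rec = res.to_dict()
        rec["full_beta"] = full.beta
        sign_flip = np.sign(res.beta) != np.sign(full.beta) and full.beta != 0
        if full.beta != 0:
            shift = abs(res.beta - full.beta) / abs(full.beta)
        else:
            shift = np.nan
        rec["relative_shift"] = shift
        rec["influential"] = bool(sign_flip or (np.isfinite(shift) and shift > influence_fraction))
        rows.append(rec)
    return pd.DataFrame(rows)


def percent_change(beta_base: float, beta_new: float) -> float | None:
    """|beta_new - beta_base| / |beta_base| x 100; None when the base is 0."""
    if beta_base == 0:
        return None
    return abs(beta_new - beta_base) / abs(beta_base) * 100.0


def covariate_sensitivity(
    spec: ModelSpec,
    data: pd.DataFrame,
    extra_covariate: str,
    threshold_percent: float = 15.0,
    n_quad: int = 25,
) -> dict:
    """Percent change in the exposure coefficient after adding a covariate.

    change% = |beta_new - beta_base| / |beta_base| * 100; flagged when it
    exceeds ``threshold_percent``. Undefined (None) when beta_base is 0.
    """
    base = fit_association(spec, data, n_quad=n_quad)
    extended = fit_association(
        replace(spec, extra_covariates=spec.extra_covariates + (extra_covariate,)),
        data, n_quad=n_quad,
    )
    change = percent_change(base.beta, extended.beta)
    flagged = change is not None and change > threshold_percent
    return {
        "outcome": spec.outcome,
        "exposure_group": spec.exposure_group,
        "extra_covariate": extra_covariate,
        "beta_base": base.beta,
        "beta_extended": extended.beta,
        "percent_change": change,
        "exceeds_threshold": flagged,
        "threshold_percent": threshold_percent,
    }
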