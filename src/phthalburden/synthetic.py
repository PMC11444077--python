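"""Synthetic multi-cohort pregnancy data and weighted survey samples.

Stands in for the two data sources the analysis chain consumes:

* a pooled multi-cohort pregnancy study — cohort-level baseline differences,
  log-normally distributed urinary metabolite concentrations censored at
  assay detection limits, urinary-dilution physics (creatinine or specific
  gravity), demographic covariates that confound both exposure and outcome,
  and configurable exposure effects on gestational age, birthweight, and
  preterm-birth odds;
* a nationally representative survey of exposure with positive sampling
  weights, from which the burden stage estimates population exposure
  percentiles.

Everything is driven by one integer seed through deterministic sub-seeding
(`numpy.random.SeedSequence`), so identical configs produce byte-identical
tables.

Gestational age is drawn from a two-component normal mixture (a bulk
term-delivery component plus a small early-delivery tail) rather than a
single normal: US birth data pair a mean near 38.8 weeks and SD near 1.8
with a preterm fraction near 8%, which no single normal can produce
simultaneously. Cohort, covariate and exposure effects shift the draw
additively, so linear-model slope recovery is unaffected by the skew.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exposure import GROUPS, METABOLITES, TRIMESTER_BREAKS

__all__ = ["SynthConfig", "SurveyConfig", "generate_cohort_dyads", "generate_survey_sample"]


# log10 ng/mL medians calibrated so that group molar-sum medians land near
# published pooled-cohort pregnancy values (LMW ~423, HMW ~155, DEHP ~101,
# phthalic acid ~220, DiNP ~28, DnOP ~9, DiDP ~5 nmol/L).
DEFAULT_LOG_MEANS: dict[str, float] = {
    "MEP": 1.583, "MnBP": 1.284, "MiBP": 1.043, "MBzP": 0.945,
    "MEHP": 0.224, "MEHHP": 0.792, "MEOHP": 0.643, "MECPP": 1.018,
    "MCPP": 0.108, "MCOP": 0.880, "MiNP": -0.083, "MCNP": 0.225,
    "MCHpP": -0.105, "PA": 1.562,
}

DEFAULT_COVARIATE_PREVALENCES: dict[str, dict[str, float]] = {
    "race_ethnicity": {
        "nh_white": 0.43, "nh_black": 0.24, "hispanic": 0.25, "other": 0.08,
    },
    "education": {
        "less_than_hs": 0.11, "hs_ged": 0.23, "some_college": 0.18,
        "bachelors": 0.25, "postgraduate": 0.22, "missing": 0.01,
    },
    "parity": {"0": 0.38, "1": 0.35, "2": 0.13, "3": 0.05, "4": 0.03, "missing": 0.06},
    "tobacco": {"yes": 0.06, "no": 0.74, "missing": 0.20},
    "child_sex": {"male": 0.505, "female": 0.495},
}

# Covariate effects on outcomes; directions and rough magnitudes follow
# published pooled-cohort covariate/outcome associations so that
# confounding-adjustment behaviour is exercised, not just noise.
DEFAULT_GA_EFFECTS: dict[str, float] = {          # weeks
    "nh_black": -0.375, "hispanic": -0.195, "other": -0.246,
    "higher_edu": 0.106, "parity_1": -0.150, "parity_2plus": -0.166,
    "age_per_year": -0.005,
}
DEFAULT_BW_EFFECTS: dict[str, float] = {          # grams
    "nh_black": -267.0, "hispanic": -126.0, "other": -142.0,
    "higher_edu": 121.0, "parity_1": 110.0, "parity_2plus": 105.0,
    "age_per_year": 9.5, "female": -123.0, "tobacco": -62.0,
}
DEFAULT_LOGIT_EFFECTS: dict[str, float] = {       # log-odds of preterm
    "nh_black": 0.49, "hispanic": 0.18, "other": 0.36, "higher_edu": -0.26,
}
# Demographic shifts of the dyad-level exposure propensity (log10 units);
# these make the covariates genuine confounders.
DEFAULT_EXPOSURE_SHIFTS: dict[str, float] = {
    "nh_black": 0.20, "hispanic": 0.08, "higher_edu": -0.17, "age_per_year": -0.012,
}

DEFAULT_DILUTION_MODEL: dict[str, dict[str, float]] = {
    "creatinine": {"median": 105.0, "log10_sd": 0.25},
    "specific_gravity": {"median_excess": 0.016, "log10_sd": 0.20},
}


def _check_probs(name: str, d: dict[str, float]) -> None:
    vals = list(d.values())
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-6:
        raise ValueError(f"{name}: prevalences must sum to 1 (got {sum(vals):.4f})")


@dataclass
class SynthConfig:
    """Configuration of the multi-cohort dyad generator.

    Exposure effects are per log10 unit of the (centered) true group molar
    sum: ``true_slopes_ga`` in weeks, ``true_slopes_bw`` in grams,
    ``true_log_or`` in log-odds of preterm birth. If ``true_log_or`` is
    non-empty the generator runs in binary-outcome mode: preterm status is
    drawn from the logistic model first, and gestational age from truncated
    normals conditional on it, so the derived <37-week flag carries exactly
    the configured odds ratios.
    """

    n_cohorts: int = 13
    dyads_per_cohort: int = 385
    cohort_intercept_sd: float = 0.30                    # weeks
    true_slopes_ga: dict[str, float] = field(default_factory=dict)
    true_slopes_bw: dict[str, float] = field(default_factory=dict)
    true_log_or: dict[str, float] = field(default_factory=dict)
    metabolite_log_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_MEANS)
    )
    metabolite_log_sd: dict[str, float] | float = 0.40   # between-dyad, log10
    within_sample_log_sd: float = 0.25                   # specimen-to-specimen
    lod: dict[str, float] = field(
        default_factory=lambda: {m: d.lod for m, d in METABOLITES.items()}
    )
    dilution_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DILUTION_MODEL.items()}
    )
    covariate_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PREVALENCES.items()}
    )
    maternal_age_mean: float = 28.5
    maternal_age_sd: float = 5.8
    ga_mean: float = 38.9
    ga_sd: float = 1.82
    ga_tail_prob: float = 0.055
    preterm_base_rate: float = 0.08
    bw_mean: float = 3312.0
    bw_per_week: float = 185.0
    bw_resid_sd: float = 430.0
    length_mean: float = 50.4
    length_per_week: float = 1.0
    length_resid_sd: float = 2.2
    covariate_effects_ga: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GA_EFFECTS))
    covariate_effects_bw: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BW_EFFECTS))
    covariate_effects_logit: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOGIT_EFFECTS))
    confounder_exposure_shifts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPOSURE_SHIFTS))
    twin_prob: float = 0.01
    missing_birthweight_prob: float = 0.005
    trimester_sample_prob: tuple[float, float, float] = (0.45, 0.75, 0.70)
    sample_count_probs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    include_urine: bool = True
    metabolites: tuple[str, ...] = tuple(DEFAULT_LOG_MEANS)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts < 1 or self.dyads_per_cohort < 1:
            raise ValueError("cohort and dyad counts must be >= 1")
        for name, v in [
            ("cohort_intercept_sd", self.cohort_intercept_sd),
            ("ga_sd", self.ga_sd), ("bw_resid_sd", self.bw_resid_sd),
            ("maternal_age_sd", self.maternal_age_sd),
            ("within_sample_log_sd", self.within_sample_log_sd),
        ]:
            if v <= 0 and name != "cohort_intercept_sd":
                raise ValueError(f"{name} must be > 0")
            if name == "cohort_intercept_sd" and v < 0:
                raise ValueError("cohort_intercept_sd must be >= 0")
        if isinstance(self.metabolite_log_sd, dict):
            if any(v <= 0 for v in self.metabolite_log_sd.values()):
                raise ValueError("metabolite_log_sd values must be > 0")
        elif self.metabolite_log_sd <= 0:
            raise ValueError("metabolite_log_sd must be > 0")
        if any(v <= 0 for v in self.lod.values()):
            raise ValueError("LODs must be > 0")
        if not 0.0 < self.preterm_base_rate < 1.0:
            raise ValueError("preterm_base_rate must be in (0, 1)")
        for cov, prevs in self.covariate_prevalences.items():
            _check_probs(cov, prevs)
        for p in (*self.trimester_sample_prob, self.twin_prob,
                  self.missing_birthweight_prob, self.ga_tail_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def sd_for(self, metabolite: str) -> float:
        if isinstance(self.metabolite_log_sd, dict):
            return self.metabolite_log_sd[metabolite]
        return float(self.metabolite_log_sd)


@dataclass
class SurveyConfig:
    """Configuration of the weighted survey exposure sample.

    ``quantile_targets`` maps group name to the (10th, 25th, 50th, 75th,
    90th) percentiles of log10 μM molar-sum exposure; when given, exposure
    is drawn by inverse transform through a piecewise-linear quantile
    function anchored at those points (linearly extrapolated tails), so the
    sample's weighted percentiles land on the targets at large n. Otherwise
    exposure is normal with ``exposure_log_mean``/``exposure_log_sd``.
    Weights are strictly positive log-normal draws (positive skew, as for
    complex-survey designs).
    """

    n_respondents: int = 2000
    weight_log10_sd: float = 0.35
    exposure_log_mean: dict[str, float] = field(default_factory=dict)
    exposure_log_sd: dict[str, float] = field(default_factory=dict)
    quantile_targets: dict[str, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.weight_log10_sd < 0:
            raise ValueError("weight_log10_sd must be >= 0")
        for g, q in self.quantile_targets.items():
            if len(q) != 5 or any(a > b for a, b in zip(q, q[1:])):
                raise ValueError(f"{g}: quantile targets must be 5 non-decreasing values")
        groups = set(self.exposure_log_mean) | set(self.quantile_targets)
        if not groups:
            raise ValueError("no exposure groups configured")


def _categorical(rng: np.random.Generator, prevs: dict[str, float], n: int) -> np.ndarray:
    labels = list(prevs)
    p = np.asarray([prevs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _covariate_vector(df: pd.DataFrame, effects: dict[str, float], age_center: float) -> np.ndarray:
    """Additive covariate contribution (shared parametrisation across outcomes)."""
    out = np.zeros(len(df))
    race = df["race_ethnicity"].to_numpy()
    out += np.where(race == "nh_black", effects.get("nh_black", 0.0), 0.0)
    out += np.where(race == "hispanic", effects.get("hispanic", 0.0), 0.0)
    out += np.where(race == "other", effects.get("other", 0.0), 0.0)
    higher = df["education"].isin(["some_college", "bachelors", "postgraduate"]).to_numpy()
    out += np.where(higher, effects.get("higher_edu", 0.0), 0.0)
    parity = df["parity"].to_numpy(dtype=float)
    out += np.where(parity == 1, effects.get("parity_1", 0.0), 0.0)
    out += np.where(parity >= 2, effects.get("parity_2plus", 0.0), 0.0)
    out += (df["maternal_age"].to_numpy() - age_center) * effects.get("age_per_year", 0.0)
    out += np.where(df["child_sex"].to_numpy() == "female", effects.get("female", 0.0), 0.0)
    out += np.where(df["tobacco"].to_numpy() == "yes", effects.get("tobacco", 0.0), 0.0)
    return out


def _draw_ga_mixture(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    """Skewed base gestational-age draw: bulk + early-delivery tail."""
    s = cfg.ga_sd
    bulk_sd, tail_sd = 0.58 * s, 1.04 * s
    tail_offset, p = -2.42 * s, cfg.ga_tail_prob
    bulk_offset = -tail_offset * p / (1.0 - p)  # zero-mean mixture
    tail = rng.random(n) < p
    draw = np.where(
        tail,
        cfg.ga_mean + tail_offset + tail_sd * rng.standard_normal(n),
        cfg.ga_mean + bulk_offset + bulk_sd * rng.standard_normal(n),
    )
    return draw


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, n: int) -> np.ndarray:
    """Inverse-CDF truncated normal using the generator's uniform stream."""
    from scipy.stats import norm
    a, b = norm.cdf((lo - mean) / sd), norm.cdf((hi - mean) / sd)
    u = rng.uniform(a, b, size=n)
    return mean + sd * norm.ppf(u)


def generate_cohort_dyads(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (dyad table, long-format urine measurement table).

    The dyad table carries, besides covariates and raw birth outcomes, the
    latent true per-group log10 molar-sum exposures (``true_log10_<group>``
    columns) used to generate the outcomes; they let effect-recovery studies
    skip the measurement pipeline when measurement noise is not the point.

    The urine table has one row per (specimen, metabolite) with columns
    ``dyad_id, cohort, trimester, collection_week, metabolite,
    concentration, below_lod, dilution_type, dilution_value``; for
    below-LOD rows the latent concentration is discarded (NaN), as in real
    assay output.
    """
    config.validate()
    n = config.n_cohorts * config.dyads_per_cohort
    ss = np.random.SeedSequence(config.seed)
    (r_cohort, r_cov, r_expo, r_out, r_urine) = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    cohorts = np.repeat([f"C{i + 1:02d}" for i in range(config.n_cohorts)],
                        config.dyads_per_cohort)
    u_cohort = r_cohort.normal(0.0, config.cohort_intercept_sd, config.n_cohorts)
    u = np.repeat(u_cohort, config.dyads_per_cohort)
    dilution_types = np.asarray(
        ["creatinine" if i % 2 == 0 else "specific_gravity" for i in range(config.n_cohorts)]
    )

    prev = config.covariate_prevalences
    parity_lab = _categorical(r_cov, prev["parity"], n)
    parity = pd.Series(parity_lab).replace("missing", np.nan).astype(float).to_numpy()
    dyads = pd.DataFrame(
        {
            "dyad_id": [f"D{i + 1:05d}" for i in range(n)],
            "cohort": cohorts,
            "maternal_age": np.clip(
                r_cov.normal(config.maternal_age_mean, config.maternal_age_sd, n), 16, 45
            ),
            "race_ethnicity": _categorical(r_cov, prev["race_ethnicity"], n),
            "education": _categorical(r_cov, prev["education"], n),
            "parity": parity,
            "tobacco": _categorical(r_cov, prev["tobacco"], n),
            "child_sex": _categorical(r_cov, prev["child_sex"], n),
        }
    )

    # dyad-level latent metabolite medians (log10 ng/mL), confounded by
    # demographics through a shared exposure-propensity shift
    shift = _covariate_vector(dyads, config.confounder_exposure_shifts, config.maternal_age_mean)
    mets = list(config.metabolites)
    latent = {}
    for m in mets:
        latent[m] = (
            config.metabolite_log_mean[m]
            + shift
            + config.sd_for(m) * r_expo.standard_normal(n)
        )

    # true group exposures: log10 of molar sums of the latent medians
    true_log10 = {}
    for g, members in GROUPS.items():
        if not set(members) <= set(mets):
            continue
        total = np.zeros(n)
        for m in members:
            total += 10.0 ** latent[m] / METABOLITES[m].molecular_weight * 1000.0
        true_log10[g] = np.log10(total)
        dyads[f"true_log10_{g}"] = true_log10[g]

    def effect_sum(slopes: dict[str, float]) -> np.ndarray:
        total = np.zeros(n)
        for g, b in slopes.items():
            if g not in true_log10:
                raise ValueError(f"slope configured for unavailable group {g!r}")
            centered = true_log10[g] - true_log10[g].mean()
            total += b * centered
        return total

    cov_ga = _covariate_vector(dyads, config.covariate_effects_ga, config.maternal_age_mean)
    binary_mode = any(v != 0.0 for v in config.true_log_or.values())
    if binary_mode:
        from scipy.special import expit, logit
        # in binary mode the cohort intercepts act on the log-odds scale
        eta = (
            logit(config.preterm_base_rate)
            + u
            + _covariate_vector(dyads, config.covariate_effects_logit, config.maternal_age_mean)
            + effect_sum(config.true_log_or)
        )
        preterm = r_out.random(n) < expit(eta)
        ga = np.where(
            preterm,
            _truncnorm(r_out, 35.3, 1.6, 23.0, 36.99, n),
            _truncnorm(r_out, config.ga_mean + 0.25, 0.58 * config.ga_sd, 37.0, 44.0, n),
        )
    else:
        ga = (
            _draw_ga_mixture(r_out, n, config)
            + u
            + cov_ga
            + effect_sum(config.true_slopes_ga)
        )
        ga = np.clip(ga, 22.0, 44.0)

    cov_bw = _covariate_vector(dyads, config.covariate_effects_bw, config.maternal_age_mean)
    bw = (
        config.bw_mean
        + config.bw_per_week * (ga - config.ga_mean)
        + cov_bw
        + effect_sum(config.true_slopes_bw)
        + r_out.normal(0.0, config.bw_resid_sd, n)
    )
    bw = np.clip(bw, 300.0, 6400.0)
    length = (
        config.length_mean
        + config.length_per_week * (ga - config.ga_mean)
        + r_out.normal(0.0, config.length_resid_sd, n)
    )
    dyads["gestational_age"] = ga
    dyads["birthweight"] = bw
    dyads["birth_length"] = np.clip(length, 30.0, 62.0)
    dyads["singleton"] = r_out.random(n) >= config.twin_prob
    missing_bw = r_out.random(n) < config.missing_birthweight_prob
    dyads.loc[missing_bw, "birthweight"] = np.nan

    if not config.include_urine:
        return dyads, pd.DataFrame(
            columns=["dyad_id", "cohort", "trimester", "collection_week", "metabolite",
                     "concentration", "below_lod", "dilution_type", "dilution_value"]
        )

    urine = _generate_urine(config, dyads, latent, dilution_types, r_urine)
    return dyads, urine


def _generate_urine(
    config: SynthConfig,
    dyads: pd.DataFrame,
    latent: dict[str, np.ndarray],
    dilution_types: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(dyads)
    mets = list(config.metabolites)
    t_lo = (5.0, TRIMESTER_BREAKS[0], TRIMESTER_BREAKS[1])
    t_hi = (TRIMESTER_BREAKS[0], TRIMESTER_BREAKS[1], 38.0)
    cohort_index = {c: i for i, c in enumerate(pd.unique(dyads["cohort"]))}

    # specimen schedule: per trimester, present with configured probability,
    # then 1-3 specimens; dyads with no specimen anywhere get one in T2
    counts = np.zeros((n, 3), dtype=int)
    n_choices = np.array([1, 2, 3])
    for t in range(3):
        present = rng.random(n) < config.trimester_sample_prob[t]
        k = rng.choice(n_choices, size=n, p=np.asarray(config.sample_count_probs))
        counts[:, t] = np.where(present, k, 0)
    none = counts.sum(axis=1) == 0
    counts[none, 1] = 1

    dil = config.dilution_model
    rows_dyad, rows_tri, rows_week, rows_dtype, rows_dval, spec_z = [], [], [], [], [], []
    dyad_ids = dyads["dyad_id"].to_numpy()
    dyad_cohorts = dyads["cohort"].to_numpy()
    for t in range(3):
        for k in range(1, counts[:, t].max() + 1 if counts[:, t].size else 0):
            idx = np.nonzero(counts[:, t] >= k)[0]
            if idx.size == 0:
                continue
            week = rng.uniform(t_lo[t], t_hi[t], idx.size)
            dtypes = dilution_types[[cohort_index[c] for c in dyad_cohorts[idx]]]
            is_cr = dtypes == "creatinine"
            cr = dil["creatinine"]["median"] * 10.0 ** (
                dil["creatinine"]["log10_sd"] * rng.standard_normal(idx.size)
            )
            sg = 1.0 + dil["specific_gravity"]["median_excess"] * 10.0 ** (
                dil["specific_gravity"]["log10_sd"] * rng.standard_normal(idx.size)
            )
            dval = np.where(is_cr, cr, sg)
            rows_dyad.append(idx)
            rows_tri.append(np.full(idx.size, t + 1))
            rows_week.append(week)
            rows_dtype.append(dtypes)
            rows_dval.append(dval)
            spec_z.append(rng.standard_normal((idx.size, len(mets))))

    idx_all = np.concatenate(rows_dyad)
    dval_all = np.concatenate(rows_dval)
    dtype_all = np.concatenate(rows_dtype)
    z_all = np.concatenate(spec_z, axis=0)
    is_cr_all = dtype_all == "creatinine"
    # dilution multiplier relative to the population median hydration
    factor = np.where(
        is_cr_all,
        dval_all / dil["creatinine"]["median"],
        (dval_all - 1.0) / dil["specific_gravity"]["median_excess"],
    )

    frames = []
    base = pd.DataFrame(
        {
            "dyad_id": dyad_ids[idx_all],
            "cohort": dyad_cohorts[idx_all],
            "trimester": np.concatenate(rows_tri),
            "collection_week": np.concatenate(rows_week),
            "dilution_type": dtype_all,
            "dilution_value": dval_all,
        }
    )
    for j, m in enumerate(mets):
        conc = 10.0 ** (
            latent[m][idx_all] + config.within_sample_log_sd * z_all[:, j]
        ) * factor
        below = conc < config.lod[m]
        f = base.copy()
        f["metabolite"] = m
        f["concentration"] = np.where(below, np.nan, conc)
        f["below_lod"] = below
        frames.append(f)
    urine = pd.concat(frames, ignore_index=True)
    urine = urine.sort_values(
        ["dyad_id", "trimester", "collection_week", "metabolite"], kind="mergesort"
    ).reset_index(drop=True)
    cols = ["dyad_id", "cohort", "trimester", "collection_week", "metabolite",
            "concentration", "below_lod", "dilution_type", "dilution_value"]
    return urine[cols]


def _quantile_function(targets: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    p = np.array([0.10, 0.25, 0.50, 0.75, 0.90])
    q = np.asarray(targets, dtype=float)
    # extend tails linearly at the slope of the outermost segments
    slope_lo = (q[1] - q[0]) / (p[1] - p[0])
    slope_hi = (q[-1] - q[-2]) / (p[-1] - p[-2])
    p_ext = np.concatenate([[0.001], p, [0.999]])
    q_ext = np.concatenate([[q[0] - slope_lo * (p[0] - 0.001)], q,
                            [q[-1] + slope_hi * (0.999 - p[-1])]])
    return p_ext, q_ext


def generate_survey_sample(config: SurveyConfig) -> pd.DataFrame:
    """Generate a weighted survey exposure table.

    Returns a DataFrame with ``respondent_id``, ``weight`` (strictly
    positive), and one ``log10_um_<group>`` column per configured group
    (log10 μM molar-sum exposure). Reproducible under the config seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_w, r_e = [np.random.default_rng(s) for s in ss.spawn(2)]
    n = config.n_respondents
    out = pd.DataFrame(
        {
            "respondent_id": [f"R{i + 1:05d}" for i in range(n)],
            "weight": 10.0 ** (config.weight_log10_sd * r_w.standard_normal(n)),
        }
    )
    groups = sorted(set(config.exposure_log_mean) | set(config.quantile_targets))
    for g in groups:
        if g in config.quantile_targets:
            p_ext, q_ext = _quantile_function(tuple(config.quantile_targets[g]))
            u = r_e.random(n)
            out[f"log10_um_{g}"] = np.interp(u, p_ext, q_ext)
        else:
            mu = config.exposure_log_mean[g]
            sd = config.exposure_log_sd.get(g, 0.0)
            out[f"log10_um_{g}"] = mu + sd * r_e.standard_normal(n)
    return out
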