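"""Attributable preterm-birth and cost engine.

The counterfactual construction: the national exposure distribution (log10
μM molar sums from a weighted survey) is cut at its 10th/25th/50th/75th/90th
percentiles; the lowest 10% of the population is treated as unexposed, the
10–24th percentile bin is the zero-effect reference, and every higher bin is
assigned the exposure at its own lower bound. Each effect bin's exposure
excess over the reference (the 10th percentile) is converted to either

* a gestational-age decrement (continuous path): d_b = slope × (x_b − x10),
  turned into a preterm-probability increment by shifting a normal
  gestational-age distribution, ΔP_b = Φ((T − μ + d_b)/σ) − Φ((T − μ)/σ)
  with T = 37 weeks, μ = 38.73, σ = 2.82; or
* a risk-ratio increment (logistic path): ΔP_b = p0 × (RR_b − 1), where p0
  is the baseline preterm probability. This increment form is inferred from
  the published tabulations, not stated by their source; p0 defaults to
  0.1002 (the 2018 US preterm rate) and is an explicit config field.

Bin population weights (0.25, 0.25, 0.15, 0.10 for the 25–49/50–74/75–90/
>90th bins; bins below the 25th percentile contribute zero) average the
increments, which multiply the annual births and the per-case cost. All
chains run at full precision; printed-style rounding is applied only by the
report helpers. Burdens are never summed across chemicals.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "PercentileProfile",
    "BIN_WEIGHTS",
    "BurdenConfig",
    "BurdenEstimate",
    "load_burden_inputs",
    "weighted_percentiles",
    "ga_decrement_per_bin",
    "preterm_increment_normal",
    "preterm_increment_rr",
    "weighted_mean_increment",
    "attributable_cases",
    "attributable_cost",
    "cpi_adjust",
    "run_burden",
]

BIN_LABELS = ("p25", "p50", "p75", "p90")
#: population fraction of each effect bin (sums to 0.75; the unexposed and
#: reference bins hold the remaining 0.25 and contribute no effect)
BIN_WEIGHTS: dict[str, float] = {"p25": 0.25, "p50": 0.25, "p75": 0.15, "p90": 0.10}
PERCENTILE_PROBS = (0.10, 0.25, 0.50, 0.75, 0.90)


@dataclass(frozen=True)
class PercentileProfile:
    """Survey exposure percentiles for one chemical group, log10 μM."""

    group: str
    x10: float
    x25: float
    x50: float
    x75: float
    x90: float

    def __post_init__(self) -> None:
        vals = (self.x10, self.x25, self.x50, self.x75, self.x90)
        if any(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError(f"{self.group}: percentiles must be non-decreasing")

    def bin_exposures(self) -> dict[str, float]:
        """Each effect bin's assigned exposure: its lower-bound percentile."""
        return {"p25": self.x25, "p50": self.x50, "p75": self.x75, "p90": self.x90}


@dataclass
class BurdenConfig:
    """National constants for the attributable-burden chain."""

    ga_mean: float = 38.73                # weeks
    ga_sd: float = 2.82                   # weeks
    preterm_threshold: float = 37.0       # weeks
    total_births: int = 3_664_651
    slope: float | None = None            # weeks lost per log10 unit
    per_bin_rr: dict[str, float] | None = None
    per_log10_or: float | None = None
    baseline_preterm_rate: float = 0.1002
    per_case_cost: float = 67_836.0       # USD per preterm birth
    cpi_ratio: float = 1.0
    floor_negative_rr: bool = False

    def validate(self) -> None:
        if self.ga_sd <= 0:
            raise ValueError("ga_sd must be > 0")
        if self.total_births <= 0:
            raise ValueError("total_births must be > 0")
        if not 0.0 < self.baseline_preterm_rate < 1.0:
            raise ValueError("baseline preterm rate must be in (0, 1)")
        if self.per_case_cost < 0:
            raise ValueError("per-case cost must be >= 0")


@dataclass
class BurdenEstimate:
    """Full per-bin burden chain for one chemical and path."""

    group: str
    path: str                                   # "continuous" or "logistic"
    per_bin_decrement: dict[str, float] | None  # weeks (continuous path)
    per_bin_rr: dict[str, float] | None         # (logistic path)
    per_bin_increment: dict[str, float]         # probability
    weighted_mean_increment: float              # probability
    attributable_cases: float                   # births (unrounded)
    attributable_cost: float                    # USD (unrounded)

    def to_table(self) -> pd.DataFrame:
        """Report-style table with the conventional rounding (weeks to 3
        decimals, percents to 2, cases to integer, cost to whole dollars)."""
        rows = []
        for b, label in zip(BIN_LABELS, ("25-49th", "50-74th", "75-90th", ">90th")):
            rows.append(
                {
                    "bin": f"{label} percentile",
                    "decrement_weeks": (
                        round(self.per_bin_decrement[b], 3) if self.per_bin_decrement else None
                    ),
                    "risk_ratio": (self.per_bin_rr[b] if self.per_bin_rr else None),
                    "increment_percent": round(100 * self.per_bin_increment[b], 2),
                }
            )
        rows.append({"bin": "weighted mean",
                     "increment_percent": round(100 * self.weighted_mean_increment, 2)})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        """Headline numbers with report rounding."""
        return {
            "weighted_mean_increment_pct": round(100 * self.weighted_mean_increment, 2),
            "attributable_preterm_births": round(self.attributable_cases),
            "attributable_cost_usd": round(self.attributable_cost),
            "attributable_cost_billions": self.cost_billions,
        }

    @property
    def cost_billions(self) -> float:
        return round(self.attributable_cost / 1e9, 2)


def load_burden_inputs() -> dict:
    """Load the shipped national burden-input constants (YAML)."""
    ref = importlib.resources.files("phthalburden") / "data" / "us_burden_inputs.yaml"
    return yaml.safe_load(ref.read_text())


def profile_from_inputs(inputs: dict, group: str) -> PercentileProfile:
    q = inputs["percentiles"][group]
    return PercentileProfile(group, *q)


def config_from_inputs(inputs: dict, group: str, cost_field: str = "per_case_cost_2018_usd") -> BurdenConfig:
    return BurdenConfig(
        ga_mean=inputs["ga_mean_weeks"],
        ga_sd=inputs["ga_sd_weeks"],
        preterm_threshold=inputs["preterm_threshold_weeks"],
        total_births=inputs["total_births"],
        slope=inputs["continuous_slope"].get(group),
        per_bin_rr=dict(zip(BIN_LABELS, inputs["per_bin_rr"][group])),
        per_log10_or=inputs["per_log10_or"].get(group),
        baseline_preterm_rate=inputs["baseline_preterm_rate"],
        per_case_cost=float(inputs[cost_field]),
    )


def weighted_percentiles(
    exposure: np.ndarray,
    weights: np.ndarray,
    probs: tuple[float, ...] = PERCENTILE_PROBS,
    group: str = "exposure",
) -> PercentileProfile:
    """Weighted quantiles by left-continuous CDF inversion.

    The p-quantile is the smallest sample value whose cumulative normalised
    weight is >= p (the survey-statistics step-function convention).
    Invariant to rescaling all weights.
    """
    x = np.asarray(exposure, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if np.unique(x).size < 5:
        logger.warning("fewer than 5 distinct exposure values: degenerate profile")
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) / ws.sum()
    qs = [float(xs[np.searchsorted(cum, p, side="left")]) for p in probs]
    return PercentileProfile(group, *qs)


def ga_decrement_per_bin(profile: PercentileProfile, slope: float) -> dict[str, float]:
    """Gestational-age decrement in each effect bin: slope × (x_b − x10).

    ``slope`` is expressed as weeks *lost* per log10 unit and must be >= 0;
    the reference bin's decrement is zero by construction.
    """
    if slope < 0:
        raise ValueError("slope must be expressed as weeks lost (>= 0)")
    out = {}
    for b, x in profile.bin_exposures().items():
        if x < profile.x10:
            raise ValueError(f"{b} percentile below the reference percentile")
        out[b] = slope * (x - profile.x10)
    return out


def preterm_increment_normal(decrement: float, config: BurdenConfig) -> float:
    """Preterm-probability increment from a gestational-age decrement.

    ΔP = Φ((T − (μ − d))/σ) − Φ((T − μ)/σ): the extra mass a normal
    gestational-age distribution pushes below the preterm threshold when its
    mean drops by ``decrement`` weeks. Exactly 0 for d = 0.
    """
    config.validate()
    if decrement < 0:
        raise ValueError("decrement must be >= 0")
    T, mu, s = config.preterm_threshold, config.ga_mean, config.ga_sd
    return float(norm.cdf((T - (mu - decrement)) / s) - norm.cdf((T - mu) / s))


def preterm_increment_rr(rr: float, p0: float, floor_negative: bool = False) -> float:
    """Preterm-probability increment from a bin risk ratio: p0 × (RR − 1).

    With ``floor_negative`` the increment is clipped at zero for RR < 1.
    """
    if rr < 0:
        raise ValueError("risk ratio must be >= 0")
    if not 0.0 < p0 < 1.0:
        raise ValueError("baseline probability must be in (0, 1)")
    inc = p0 * (rr - 1.0)
    return float(max(inc, 0.0)) if floor_negative else float(inc)


def weighted_mean_increment(
    increments: dict[str, float], weights: dict[str, float] = BIN_WEIGHTS
) -> float:
    """Population-weighted mean increment over the effect bins.

    Bins below the 25th percentile contribute zero (they are not in the
    weight map). Raises if the increments do not cover the weighted bins.
    """
    if set(weights) - set(increments):
        raise ValueError("missing increments for some weighted bins")
    return float(sum(weights[b] * increments[b] for b in weights))


def attributable_cases(mean_increment: float, total_births: int) -> float:
    """Attributable annual cases: weighted mean increment × total births."""
    if total_births <= 0:
        raise ValueError("total_births must be > 0")
    return float(mean_increment * total_births)


def attributable_cost(cases: float, per_case_cost: float) -> float:
    """Societal cost: attributable cases × per-case cost (USD)."""
    if cases < 0 or per_case_cost < 0:
        raise ValueError("inputs must be >= 0")
    return float(cases * per_case_cost)


def cpi_adjust(cost: float, cpi_ratio: float) -> float:
    """Inflate a cost between years with a consumer-price-index ratio."""
    if cpi_ratio <= 0:
        raise ValueError("CPI ratio must be > 0")
    return float(cost * cpi_ratio)


def rr_per_bin_from_or(profile: PercentileProfile, per_log10_or: float) -> dict[str, float]:
    """Log-linear scaling of a per-log10 odds ratio to per-bin risk ratios:
    RR_b = OR ** (x_b − x10). An alternative to directly tabulated bin RRs."""
    if per_log10_or <= 0:
        raise ValueError("per-log10 OR must be > 0")
    return {
        b: float(per_log10_or ** (x - profile.x10))
        for b, x in profile.bin_exposures().items()
    }


def run_burden(
    profile: PercentileProfile,
    config: BurdenConfig,
    path: str = "continuous",
    rr_source: str = "per_bin",
) -> BurdenEstimate:
    """Run the full chain for one chemical group and path.

    path="continuous" uses the gestational-age slope; path="logistic" uses
    per-bin risk ratios (``rr_source="per_bin"``) or the log-linear scaling
    of the per-log10 OR (``rr_source="per_log10_or"``).
    """
    config.validate()
    if path == "continuous":
        if config.slope is None:
            raise ValueError("continuous path requires a slope")
        dec = ga_decrement_per_bin(profile, config.slope)
        inc = {b: preterm_increment_normal(d, config) for b, d in dec.items()}
        rrs = None
    elif path == "logistic":
        if rr_source == "per_bin":
            if config.per_bin_rr is None:
                raise ValueError("logistic path requires per-bin risk ratios")
            rrs = dict(config.per_bin_rr)
        elif rr_source == "per_log10_or":
            if config.per_log10_or is None:
                raise ValueError("per_log10_or source requires the per-log10 OR")
            rrs = rr_per_bin_from_or(profile, config.per_log10_or)
        else:
            raise ValueError(f"unknown rr_source {rr_source!r}")
        inc = {
            b: preterm_increment_rr(r, config.baseline_preterm_rate, config.floor_negative_rr)
            for b, r in rrs.items()
        }
        dec = None
    else:
        raise ValueError(f"unknown path {path!r}")

    wm = weighted_mean_increment(inc)
    cases = attributable_cases(wm, config.total_births)
    cost = attributable_cost(cases, config.per_case_cost)
    if config.cpi_ratio != 1.0:
        cost = cpi_adjust(cost, config.cpi_ratio)
    return BurdenEstimate(
        group=profile.group, path=path, per_bin_decrement=dec, per_bin_rr=rrs,
        per_bin_increment=inc, weighted_mean_increment=wm,
        attributable_cases=cases, attributable_cost=cost,
    )
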