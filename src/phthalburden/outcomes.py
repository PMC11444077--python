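"""Birth-outcome derivation.

Continuous outcomes: gestational age at birth (completed weeks, fractional
accepted), birthweight (g), birth length (cm), and birthweight-for-
gestational-age z-scores standardised by child sex and parental parity
(nulliparous vs parous), with a sex-only variant for sensitivity analyses.

Dichotomous outcomes: preterm birth (<37 weeks), the finer term
categorisation (preterm / early term / term / late term), low birthweight
(<2500 g, overall and within preterm/term strata), and small/large for
gestational age (z below the reference 10th / above the 90th percentile).

The external US reference for the z-scores is not shipped; ``ZReference``
accepts any table with per-stratum means and SDs by completed gestational
week, and ``build_reference`` estimates one empirically from a designated
population (used for self-standardisation in simulation studies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "PRETERM_THRESHOLD_WEEKS",
    "ZReference",
    "build_reference",
    "classify_preterm",
    "classify_term_category",
    "classify_low_birthweight",
    "bw_for_ga_zscore",
    "classify_sga_lga",
    "derive_outcomes",
]

PRETERM_THRESHOLD_WEEKS = 37.0
#: z cut points for small/large-for-gestational-age under a normal reference
#: (the 10th and 90th percentiles of the reference population).
SGA_Z_CUTOFF = float(norm.ppf(0.10))
LGA_Z_CUTOFF = float(norm.ppf(0.90))

TERM_CATEGORIES = ("preterm", "early_term", "term", "late_term")


@dataclass
class ZReference:
    """Birthweight-for-gestational-age reference.

    ``table`` has columns ``sex, parous, week, mean, sd`` where ``week`` is
    the completed gestational week, ``parous`` is 0/1 (ignored when
    ``by_parity`` is False), and mean/sd are birthweight in grams. SDs must
    be positive everywhere.
    """

    table: pd.DataFrame
    by_parity: bool = True
    _lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if (self.table["sd"] <= 0).any():
            raise ValueError("reference SDs must be positive")
        keys = ["sex", "parous", "week"] if self.by_parity else ["sex", "week"]
        tab = self.table
        if not self.by_parity and "parous" in tab.columns:
            tab = tab.groupby(["sex", "week"], as_index=False).agg(
                mean=("mean", "mean"), sd=("sd", "mean")
            )
        self._lookup = {
            tuple(row[k] for k in keys): (row["mean"], row["sd"])
            for row in tab.to_dict("records")
        }

    def stats(self, sex: str, parous: int, week: int) -> tuple[float, float] | None:
        key = (sex, parous, week) if self.by_parity else (sex, week)
        return self._lookup.get(key)


def build_reference(
    dyads: pd.DataFrame, by_parity: bool = True, min_cell: int = 20
) -> ZReference:
    """Estimate a birthweight-for-GA reference from a population itself.

    Strata are child sex crossed (optionally) with a binary nulliparous vs
    parous indicator; cells with fewer than ``min_cell`` births are pooled
    with neighbouring weeks via a fallback to the sex-level week statistics.
    """
    df = dyads.dropna(subset=["birthweight", "gestational_age", "child_sex"]).copy()
    df["week"] = np.floor(df["gestational_age"]).astype(int)
    df["parous"] = (df["parity"].fillna(0) > 0).astype(int) if by_parity else 0
    keys = ["child_sex", "parous", "week"]
    g = df.groupby(keys)["birthweight"].agg(["mean", "std", "count"]).reset_index()
    # fall back to sex x week cells where the parity cell is thin
    fb = df.groupby(["child_sex", "week"])["birthweight"].agg(["mean", "std"]).reset_index()
    fb = fb.rename(columns={"mean": "fb_mean", "std": "fb_sd"})
    g = g.merge(fb, on=["child_sex", "week"], how="left")
    thin = (g["count"] < min_cell) | g["std"].isna() | (g["std"] <= 0)
    g.loc[thin, "mean"] = g.loc[thin, "fb_mean"]
    g.loc[thin, "std"] = g.loc[thin, "fb_sd"]
    g = g[g["std"] > 0]
    table = g.rename(columns={"child_sex": "sex", "std": "sd"})[
        ["sex", "parous", "week", "mean", "sd"]
    ]
    return ZReference(table=table, by_parity=by_parity)


def classify_preterm(gestational_age: float) -> bool | None:
    """Preterm birth: delivery before 37 completed weeks."""
    if gestational_age is None or (isinstance(gestational_age, float) and np.isnan(gestational_age)):
        return None
    return bool(gestational_age < PRETERM_THRESHOLD_WEEKS)


def classify_term_category(gestational_age: float) -> str | None:
    """Four-level birth-timing category.

    preterm <37.0; early term [37.0, 39.0); term [39.0, 41.0);
    late term >=41.0. Half-open intervals, so every valid gestational age
    maps to exactly one category.
    """
    ga = gestational_age
    if ga is None or (isinstance(ga, float) and np.isnan(ga)):
        return None
    if ga < 37.0:
        return "preterm"
    if ga < 39.0:
        return "early_term"
    if ga < 41.0:
        return "term"
    return "late_term"


def classify_low_birthweight(
    birthweight: float, preterm: bool | None
) -> tuple[bool | None, bool | None, bool | None]:
    """Low birthweight (<2500 g): overall, among-preterm, among-term flags.

    The stratum-specific flags are ``None`` outside their stratum.
    """
    if birthweight is None or (isinstance(birthweight, float) and np.isnan(birthweight)):
        return None, None, None
    low = bool(birthweight < 2500.0)
    if preterm is None:
        return low, None, None
    return low, (low if preterm else None), (low if not preterm else None)


def bw_for_ga_zscore(
    birthweight: float,
    gestational_age: float,
    sex: str,
    parity: float | None,
    reference: ZReference,
) -> float | None:
    """Birthweight-for-gestational-age z-score against a reference.

    z = (birthweight - ref mean) / ref sd for the (sex, parity stratum,
    completed week) cell. Returns ``None`` (with a warning) when the
    reference does not cover the cell.
    """
    if any(
        v is None or (isinstance(v, float) and np.isnan(v))
        for v in (birthweight, gestational_age)
    ) or sex is None:
        return None
    week = int(np.floor(gestational_age))
    parous = int((parity or 0) > 0)
    stats = reference.stats(sex, parous, week)
    if stats is None:
        logger.debug("z-score reference does not cover sex=%s parous=%d week=%d", sex, parous, week)
        return None
    mean, sd = stats
    return float((birthweight - mean) / sd)


def classify_sga_lga(
    z: float | None,
    lower: float = SGA_Z_CUTOFF,
    upper: float = LGA_Z_CUTOFF,
) -> tuple[bool | None, bool | None]:
    """Small/large-for-gestational-age flags from a z-score.

    SGA iff z < the reference 10th-percentile cut point, LGA iff z > the
    90th; mutually exclusive by construction.
    """
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return None, None
    return bool(z < lower), bool(z > upper)


def derive_outcomes(
    dyads: pd.DataFrame, reference: ZReference | None = None
) -> pd.DataFrame:
    """Derive every outcome for a dyad table.

    When ``reference`` is None, an empirical reference is built from the
    table itself (self-standardisation). Returns a DataFrame keyed by
    ``dyad_id`` with columns ``preterm, term_category, low_birthweight,
    low_birthweight_preterm, low_birthweight_term, bw_for_ga_z, bw_for_ga_z_sex_only,
    sga, lga``.
    """
    if reference is None:
        reference = build_reference(dyads, by_parity=True)
    ref_sex_only = (
        reference
        if not reference.by_parity
        else build_reference(dyads, by_parity=False)
    )
    records = []
    for row in dyads.to_dict("records"):
        ga = row.get("gestational_age")
        bw = row.get("birthweight")
        preterm = classify_preterm(ga)
        low, low_pt, low_term = classify_low_birthweight(bw, preterm)
        z = bw_for_ga_zscore(bw, ga, row.get("child_sex"), row.get("parity"), reference)
        z_sex = bw_for_ga_zscore(bw, ga, row.get("child_sex"), 0, ref_sex_only)
        sga, lga = classify_sga_lga(z)
        records.append(
            {
                "dyad_id": row["dyad_id"],
                "preterm": preterm,
                "term_category": classify_term_category(ga),
                "low_birthweight": low,
                "low_birthweight_preterm": low_pt,
                "low_birthweight_term": low_term,
                "bw_for_ga_z": z,
                "bw_for_ga_z_sex_only": z_sex,
                "sga": sga,
                "lga": lga,
            }
        )
    out = pd.DataFrame.from_records(records)
    n_missing_z = int(
        out["bw_for_ga_z"].isna().sum()
        - dyads[["birthweight", "gestational_age", "child_sex"]].isna().any(axis=1).sum()
    )
    if n_missing_z > 0:
        logger.warning(
            "%d dyads fall outside the z-score reference coverage", n_missing_z
        )
    return out
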