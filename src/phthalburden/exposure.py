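"""Urinary phthalate exposure processing.

Turns long-format urine measurement tables into per-dyad, per-group exposure
summaries on the scale the association models consume (log10 nmol/L).

The processing order is fixed by contract and must not be rearranged:

1. below-LOD substitution (LOD / sqrt(2)),
2. urinary-dilution standardization (Boeninger ratio method, anchored at the
   cohort-specific median creatinine or specific gravity),
3. molar conversion (ng/mL -> nmol/L via the metabolite molecular weight),
4. molar summation into chemical groups,
5. within-trimester averaging, then averaging of trimester means into a
   pregnancy average,
6. log10 transform.

Detection and eligibility filters operate on the raw table before step 4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteDefinition",
    "METABOLITES",
    "GROUPS",
    "impute_below_lod",
    "dilution_standardize",
    "to_molar",
    "molar_group_sum",
    "detection_filter",
    "eligibility_filter",
    "aggregate_exposure",
    "process_exposures",
]


@dataclass(frozen=True)
class MetaboliteDefinition:
    """One urinary metabolite: assay identity, molar mass, detection limit.

    Parameters
    ----------
    name : str
        Short metabolite code (e.g. ``"MEP"``).
    molecular_weight : float
        Molar mass in g/mol; used for the ng/mL -> nmol/L conversion.
    lod : float
        Assay limit of detection in ng/mL. Treated as a single per-metabolite
        constant here; batch-specific LODs can be supplied by overriding the
        table.
    """

    name: str
    molecular_weight: float
    lod: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular weight must be > 0")
        if self.lod <= 0:
            raise ValueError(f"{self.name}: LOD must be > 0")


# Standard monoester molar masses (g/mol); editable by passing a custom list.
METABOLITES: dict[str, MetaboliteDefinition] = {
    m.name: m
    for m in [
        MetaboliteDefinition("MEP", 194.18, 1.2),
        MetaboliteDefinition("MnBP", 222.24, 0.4),
        MetaboliteDefinition("MiBP", 222.24, 0.8),
        MetaboliteDefinition("MBzP", 256.25, 0.3),
        MetaboliteDefinition("MEHP", 278.34, 0.8),
        MetaboliteDefinition("MEHHP", 294.34, 0.4),
        MetaboliteDefinition("MEOHP", 292.33, 0.2),
        MetaboliteDefinition("MECPP", 308.33, 0.4),
        MetaboliteDefinition("MCPP", 252.22, 0.4),
        MetaboliteDefinition("MCOP", 322.35, 0.3),
        MetaboliteDefinition("MiNP", 292.40, 0.3),
        MetaboliteDefinition("MCNP", 336.40, 0.2),
        MetaboliteDefinition("MCHpP", 308.40, 0.4),
        MetaboliteDefinition("PA", 166.13, 0.5),
    ]
}

# Chemical groupings. DEHP metabolites are a subset of HMW by construction.
GROUPS: dict[str, tuple[str, ...]] = {
    "LMW": ("MEP", "MnBP", "MiBP"),
    "HMW": ("MCPP", "MECPP", "MEHHP", "MEOHP", "MEHP", "MBzP"),
    "DEHP": ("MEHP", "MEHHP", "MEOHP", "MECPP"),
    "DnOP": ("MCPP", "MCHpP"),
    "DiNP": ("MiNP", "MCOP"),
    "DiDP": ("MCNP",),
    "phthalic_acid": ("PA",),
}

assert set(GROUPS["DEHP"]) <= set(GROUPS["HMW"])

#: Gestational week cut points mapping collection week -> trimester.
#: T1 < 14 completed weeks, T2 14-<28, T3 >= 28.
TRIMESTER_BREAKS = (14.0, 28.0)


def trimester_of_week(week: float) -> int:
    """Map a gestational week of urine collection to trimester 1/2/3."""
    if week < TRIMESTER_BREAKS[0]:
        return 1
    if week < TRIMESTER_BREAKS[1]:
        return 2
    return 3


def impute_below_lod(
    concentration: float | np.ndarray,
    lod: float | np.ndarray,
    below_lod: bool | np.ndarray,
) -> float | np.ndarray:
    """Substitute below-detection values with LOD / sqrt(2).

    Detected values pass through unchanged. Vectorised over numpy arrays.

    Raises
    ------
    ValueError
        If any flagged record is missing its LOD.
    """
    lod_arr = np.asarray(lod, dtype=float)
    flag = np.asarray(below_lod, dtype=bool)
    if np.any(flag & ~(lod_arr > 0)):
        raise ValueError("below-LOD record without a positive LOD")
    sub = lod_arr / math.sqrt(2.0)
    out = np.where(flag, sub, np.asarray(concentration, dtype=float))
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def dilution_standardize(
    concentration: float | np.ndarray,
    dilution_type: str,
    dilution_value: float | np.ndarray,
    cohort_median_dilution: float,
) -> float | np.ndarray:
    """Boeninger ratio standardization to the cohort-median hydration level.

    creatinine:       c * median_cr / cr
    specific gravity: c * (median_sg - 1) / (sg - 1)

    A sample at exactly the cohort median is unchanged (fixed point).

    Raises
    ------
    ValueError
        On creatinine <= 0 or specific gravity <= 1 (physically invalid
        hydration measures); callers exclude such records with a warning.
    """
    c = np.asarray(concentration, dtype=float)
    v = np.asarray(dilution_value, dtype=float)
    if dilution_type == "creatinine":
        if np.any(v <= 0) or cohort_median_dilution <= 0:
            raise ValueError("creatinine must be > 0 mg/dL")
        out = c * (cohort_median_dilution / v)
    elif dilution_type == "specific_gravity":
        if np.any(v <= 1) or cohort_median_dilution <= 1:
            raise ValueError("specific gravity must be > 1")
        out = c * (cohort_median_dilution - 1.0) / (v - 1.0)
    else:
        raise ValueError(f"unknown dilution type: {dilution_type!r}")
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def to_molar(
    concentration: float | np.ndarray, molecular_weight: float
) -> float | np.ndarray:
    """Convert a mass concentration (ng/mL) to a molar one (nmol/L).

    nmol/L = ng/mL / (g/mol) * 1000.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    out = np.asarray(concentration, dtype=float) / molecular_weight * 1000.0
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def molar_group_sum(
    molar_values: dict[str, float], group: str, constituents: tuple[str, ...] | None = None
) -> float | None:
    """Sum constituent molar concentrations for one chemical group.

    Returns ``None`` when any constituent is absent: a cohort lacking a
    constituent assay cannot contribute that group (the cohort is excluded
    from that group's analyses, not from others).
    """
    members = constituents if constituents is not None else GROUPS[group]
    if not members:
        raise ValueError(f"group {group!r} has no constituents")
    vals = [molar_values.get(m) for m in members]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    return float(sum(vals))


def detection_filter(
    urine: pd.DataFrame,
    min_detect_fraction: float = 0.5,
    min_detected_participants: int = 1000,
) -> list[str]:
    """Eligible-metabolite screen.

    A metabolite is retained only if (a) it is detected in strictly more than
    ``min_detect_fraction`` of its specimens and (b) at least
    ``min_detected_participants`` distinct dyads have a detectable specimen.
    The specimen (not participant) denominator is used for (a).

    Returns the sorted list of retained metabolite names; exclusions are
    logged.
    """
    eligible = []
    for met, sub in urine.groupby("metabolite", sort=True):
        detected = ~sub["below_lod"].astype(bool)
        frac = float(detected.mean())
        n_participants = sub.loc[detected, "dyad_id"].nunique()
        if frac <= min_detect_fraction:
            logger.info(
                "excluding %s: detected in %.1f%% of specimens (need >%.0f%%)",
                met, 100 * frac, 100 * min_detect_fraction,
            )
        elif n_participants < min_detected_participants:
            logger.info(
                "excluding %s: %d participants with a detectable specimen (need >=%d)",
                met, n_participants, min_detected_participants,
            )
        else:
            eligible.append(str(met))
    return eligible


def eligibility_filter(dyads: pd.DataFrame, urine: pd.DataFrame) -> pd.DataFrame:
    """Apply the dyad inclusion criteria.

    Requires (a) at least one urine measurement during the pregnancy,
    (b) non-missing gestational age and birthweight, and (c) singleton
    delivery. Removal counts per criterion are logged.
    """
    dyads = dyads.copy()
    has_urine = dyads["dyad_id"].isin(urine["dyad_id"].unique())
    has_outcomes = dyads["gestational_age"].notna() & dyads["birthweight"].notna()
    singleton = dyads["singleton"].astype(bool)
    for name, mask in [
        ("no urinary phthalate measurement", ~has_urine),
        ("missing gestational age or birthweight", ~has_outcomes),
        ("non-singleton delivery", ~singleton),
    ]:
        n = int(mask.sum())
        if n:
            logger.info("eligibility: excluding %d dyads (%s)", n, name)
    return dyads[has_urine & has_outcomes & singleton].reset_index(drop=True)


def _standardize_table(urine: pd.DataFrame, metabolites: dict[str, MetaboliteDefinition]) -> pd.DataFrame:
    """LOD-substitute then dilution-standardize every specimen row.

    Cohort-specific median dilution values are computed per (cohort,
    dilution_type) over unique specimens. Rows with invalid hydration
    measures are dropped with a warning.
    """
    df = urine.copy()
    df["below_lod"] = df["below_lod"].astype(bool)
    lod = df["metabolite"].map({m: d.lod for m, d in metabolites.items()})
    if lod.isna().any():
        missing = sorted(df.loc[lod.isna(), "metabolite"].unique())
        raise ValueError(f"metabolites without definitions: {missing}")
    # conservative reading of assay output: unflagged but sub-LOD -> flagged
    silent = (~df["below_lod"]) & df["concentration"].notna() & (df["concentration"] < lod)
    if silent.any():
        logger.warning(
            "%d records below LOD without a flag; treating as below-LOD", int(silent.sum())
        )
        df.loc[silent, "below_lod"] = True
    df["concentration"] = impute_below_lod(
        df["concentration"].to_numpy(), lod.to_numpy(), df["below_lod"].to_numpy()
    )

    bad_cr = (df["dilution_type"] == "creatinine") & ~(df["dilution_value"] > 0)
    bad_sg = (df["dilution_type"] == "specific_gravity") & ~(df["dilution_value"] > 1)
    bad = bad_cr | bad_sg
    if bad.any():
        logger.warning("excluding %d records with invalid dilution values", int(bad.sum()))
        df = df[~bad]

    parts = []
    for (cohort, dtype), sub in df.groupby(["cohort", "dilution_type"], sort=False):
        med = float(sub["dilution_value"].median())
        sub = sub.copy()
        sub["concentration"] = dilution_standardize(
            sub["concentration"].to_numpy(), str(dtype), sub["dilution_value"].to_numpy(), med
        )
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def process_exposures(
    urine: pd.DataFrame,
    metabolites: dict[str, MetaboliteDefinition] | None = None,
    groups: dict[str, tuple[str, ...]] | None = None,
    min_detect_fraction: float = 0.5,
    min_detected_participants: int = 1000,
) -> pd.DataFrame:
    """Full exposure chain: raw urine table -> per-dyad group summaries.

    Parameters
    ----------
    urine : DataFrame
        Long format with columns ``dyad_id, cohort, trimester, metabolite,
        concentration, below_lod, dilution_type, dilution_value``
        (``concentration`` may be NaN for below-LOD rows).
    metabolites, groups
        Override the shipped constants tables.
    min_detect_fraction, min_detected_participants
        Detection-filter thresholds.

    Returns
    -------
    DataFrame
        Tidy summary with one row per (dyad, group): columns ``dyad_id,
        cohort, group, t1, t2, t3, pregnancy_average`` (nmol/L) and
        ``log10_t1 .. log10_pregnancy_average``. Groups unavailable for a
        dyad's cohort are absent.
    """
    metabolites = metabolites if metabolites is not None else METABOLITES
    groups = groups if groups is not None else GROUPS

    eligible = set(
        detection_filter(urine, min_detect_fraction, min_detected_participants)
    )
    df = urine[urine["metabolite"].isin(eligible)]
    if df.empty:
        return pd.DataFrame(
            columns=["dyad_id", "cohort", "group", "t1", "t2", "t3",
                     "pregnancy_average", "log10_t1", "log10_t2", "log10_t3",
                     "log10_pregnancy_average"]
        )
    df = _standardize_table(df, metabolites)

    mw = pd.Series({m: d.molecular_weight for m, d in metabolites.items()})
    df["molar"] = df["concentration"].to_numpy() / df["metabolite"].map(mw).to_numpy() * 1000.0

    # which metabolites does each cohort measure at all
    cohort_panel = df.groupby("cohort")["metabolite"].agg(lambda s: frozenset(s))

    # per dyad-trimester-metabolite mean molar concentration
    per_met = (
        df.groupby(["cohort", "dyad_id", "trimester", "metabolite"], sort=False)["molar"]
        .mean()
        .unstack("metabolite")
    )

    rows = []
    for gname, members in groups.items():
        members = tuple(m for m in members)
        if not set(members) <= eligible:
            logger.info("group %s unavailable: constituent failed detection filter", gname)
            continue
        ok_cohorts = {c for c, panel in cohort_panel.items() if set(members) <= panel}
        if not ok_cohorts:
            logger.info("group %s unavailable in every cohort", gname)
            continue
        sub = per_met[per_met.index.get_level_values("cohort").isin(ok_cohorts)]
        have = [m for m in members if m in sub.columns]
        if len(have) < len(members):
            continue
        gsum = sub[list(members)].sum(axis=1, skipna=False)
        gsum = gsum.dropna()
        tri = gsum.unstack("trimester")
        for t in (1, 2, 3):
            if t not in tri.columns:
                tri[t] = np.nan
        preg = tri[[1, 2, 3]].mean(axis=1)  # unweighted mean of available trimester means
        out = pd.DataFrame(
            {
                "cohort": tri.index.get_level_values("cohort"),
                "dyad_id": tri.index.get_level_values("dyad_id"),
                "group": gname,
                "t1": tri[1].to_numpy(),
                "t2": tri[2].to_numpy(),
                "t3": tri[3].to_numpy(),
                "pregnancy_average": preg.to_numpy(),
            }
        )
        rows.append(out[out["pregnancy_average"].notna()])
    if not rows:
        return pd.DataFrame(
            columns=["dyad_id", "cohort", "group", "t1", "t2", "t3",
                     "pregnancy_average", "log10_t1", "log10_t2", "log10_t3",
                     "log10_pregnancy_average"]
        )
    summary = pd.concat(rows, ignore_index=True)
    for col in ("t1", "t2", "t3", "pregnancy_average"):
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log10(summary[col].to_numpy(dtype=float))
        vals[~(summary[col].to_numpy(dtype=float) > 0)] = np.nan
        summary[f"log10_{col}"] = vals
    cols = ["dyad_id", "cohort", "group", "t1", "t2", "t3", "pregnancy_average",
            "log10_t1", "log10_t2", "log10_t3", "log10_pregnancy_average"]
    return summary[cols]


def aggregate_exposure(group_values: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-specimen group sums into trimester and pregnancy means.

    ``group_values`` has columns ``dyad_id, group, trimester, value`` (nmol/L,
    one row per specimen). Within-trimester arithmetic mean first, then the
    unweighted mean over available trimesters; log10 applied last.
    """
    tri = (
        group_values.groupby(["dyad_id", "group", "trimester"], sort=False)["value"]
        .mean()
        .unstack("trimester")
    )
    for t in (1, 2, 3):
        if t not in tri.columns:
            tri[t] = np.nan
    preg = tri[[1, 2, 3]].mean(axis=1)
    out = tri.rename(columns={1: "t1", 2: "t2", 3: "t3"}).reset_index()
    out["pregnancy_average"] = preg.to_numpy()
    for col in ("t1", "t2", "t3", "pregnancy_average"):
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log10(out[col].to_numpy(dtype=float))
        vals[~(out[col].to_numpy(dtype=float) > 0)] = np.nan
        out[f"log10_{col}"] = vals
    return out
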