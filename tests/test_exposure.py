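"""Exposure-processing chain: LOD substitution, dilution standardization,
molar conversion, group sums, filters, and aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phthalburden.exposure import (
    GROUPS,
    METABOLITES,
    MetaboliteDefinition,
    aggregate_exposure,
    detection_filter,
    dilution_standardize,
    eligibility_filter,
    impute_below_lod,
    molar_group_sum,
    process_exposures,
    to_molar,
    trimester_of_week,
)


class TestImputeBelowLod:
    @pytest.mark.parametrize(
        "conc, lod, flagged, expected",
        [
            (0.2, 1.0, True, 1.0 / math.sqrt(2)),
            (5.0, 1.0, False, 5.0),
            (0.9, 2.0, True, 2.0 / math.sqrt(2)),
        ],
    )
    def test_substitution(self, conc, lod, flagged, expected):
        assert impute_below_lod(conc, lod, flagged) == pytest.approx(expected, abs=1e-5)

    def test_flagged_without_lod_is_an_error(self):
        with pytest.raises(ValueError):
            impute_below_lod(0.2, np.nan, True)


class TestDilutionStandardize:
    def test_sample_at_cohort_median_is_fixed_point(self):
        assert dilution_standardize(10.0, "creatinine", 100.0, 100.0) == pytest.approx(10.0)
        assert dilution_standardize(7.0, "specific_gravity", 1.015, 1.015) == pytest.approx(7.0)

    @pytest.mark.parametrize(
        "conc, dtype, value, median, expected",
        [
            (10.0, "creatinine", 50.0, 100.0, 20.0),
            (8.0, "specific_gravity", 1.030, 1.015, 4.0),
        ],
    )
    def test_ratio_forms(self, conc, dtype, value, median, expected):
        assert dilution_standardize(conc, dtype, value, median) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dtype, value", [("creatinine", 0.0), ("creatinine", -5.0), ("specific_gravity", 1.0)]
    )
    def test_invalid_hydration_measures(self, dtype, value):
        with pytest.raises(ValueError):
            dilution_standardize(1.0, dtype, value, 100.0 if dtype == "creatinine" else 1.015)


class TestToMolar:
    @pytest.mark.parametrize(
        "conc, mw, expected",
        [(194.18, 194.18, 1000.0), (0.0, 278.34, 0.0), (27.8, 278.34, 99.88)],
    )
    def test_conversion(self, conc, mw, expected):
        assert to_molar(conc, mw) == pytest.approx(expected, abs=0.005)

    def test_rejects_nonpositive_molecular_weight(self):
        with pytest.raises(ValueError):
            to_molar(1.0, 0.0)


class TestGroupSums:
    def test_dehp_sum(self):
        vals = {"MEHP": 100.0, "MEHHP": 50.0, "MEOHP": 30.0, "MECPP": 20.0}
        assert molar_group_sum(vals, "DEHP") == pytest.approx(200.0)

    def test_missing_constituent_marks_group_unavailable(self):
        vals = {"MEHP": 100.0, "MEHHP": 50.0, "MECPP": 20.0}  # no MEOHP
        assert molar_group_sum(vals, "DEHP") is None

    def test_single_constituent_group_passes_through(self):
        assert molar_group_sum({"MCNP": 4.2}, "DiDP") == pytest.approx(4.2)

    def test_dehp_is_subset_of_hmw(self):
        assert set(GROUPS["DEHP"]) <= set(GROUPS["HMW"])

    @given(extra=st.floats(min_value=1e-6, max_value=1e4))
    def test_adding_positive_constituent_strictly_increases_sum(self, extra):
        base = {"MEHP": 10.0, "MEHHP": 5.0, "MEOHP": 3.0, "MECPP": 0.0}
        low = molar_group_sum(base, "DEHP")
        base["MECPP"] = extra
        assert molar_group_sum(base, "DEHP") > low


def _urine_frame(records):
    return pd.DataFrame(
        records,
        columns=["dyad_id", "cohort", "trimester", "metabolite", "concentration",
                 "below_lod", "dilution_type", "dilution_value"],
    )


class TestDetectionFilter:
    def _frame(self, met, n_detected, n_total, participants=None):
        """participants: number of distinct dyads among the detected rows."""
        participants = participants if participants is not None else n_detected
        rows = []
        for i in range(n_total):
            detected = i < n_detected
            dyad = f"P{i % participants}" if detected else f"Q{i}"
            rows.append((dyad, "C1", 2, met, 5.0 if detected else np.nan,
                         not detected, "creatinine", 100.0))
        return _urine_frame(rows)

    def test_below_half_detection_excluded(self):
        urine = self._frame("A", n_detected=980, n_total=2000)  # 49%
        assert detection_filter(urine, min_detected_participants=500) == []

    def test_too_few_detected_participants_excluded(self):
        urine = self._frame("B", n_detected=1600, n_total=2000, participants=900)
        assert detection_filter(urine, min_detected_participants=1000) == []

    def test_fully_detected_metabolite_retained(self):
        urine = self._frame("C", n_detected=2000, n_total=2000)
        assert detection_filter(urine, min_detected_participants=1000) == ["C"]


class TestEligibilityFilter:
    def test_criteria(self):
        dyads = pd.DataFrame(
            {
                "dyad_id": ["a", "b", "c", "d"],
                "gestational_age": [39.0, 39.0, np.nan, 40.0],
                "birthweight": [3300.0, 3200.0, 3100.0, 3400.0],
                "singleton": [True, False, True, True],
            }
        )
        urine = _urine_frame([("a", "C1", 1, "MEP", 5.0, False, "creatinine", 100.0),
                              ("b", "C1", 1, "MEP", 5.0, False, "creatinine", 100.0),
                              ("c", "C1", 1, "MEP", 5.0, False, "creatinine", 100.0)])
        kept = eligibility_filter(dyads, urine)
        # b: twin; c: missing gestational age; d: no urine sample
        assert list(kept["dyad_id"]) == ["a"]


class TestAggregation:
    def _frame(self, values):
        return pd.DataFrame(
            [("d1", "DEHP", t, v) for t, v in values],
            columns=["dyad_id", "group", "trimester", "value"],
        )

    def test_pregnancy_average_is_mean_of_trimester_means(self):
        out = aggregate_exposure(self._frame([(1, 100.0), (2, 200.0), (3, 300.0)]))
        assert out.loc[0, "pregnancy_average"] == pytest.approx(200.0)

    def test_single_trimester_two_samples(self):
        out = aggregate_exposure(self._frame([(2, 80.0), (2, 120.0)]))
        assert out.loc[0, "t2"] == pytest.approx(100.0)
        assert out.loc[0, "pregnancy_average"] == pytest.approx(100.0)

    def test_log10_applied_last(self):
        out = aggregate_exposure(self._frame([(1, 100.0)]))
        assert out.loc[0, "log10_pregnancy_average"] == pytest.approx(2.0)

    @given(
        t1=st.floats(min_value=0.1, max_value=1e4),
        t2=st.floats(min_value=0.1, max_value=1e4),
        t3=st.floats(min_value=0.1, max_value=1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_pregnancy_average_within_trimester_range(self, t1, t2, t3):
        out = aggregate_exposure(self._frame([(1, t1), (2, t2), (3, t3)]))
        avg = out.loc[0, "pregnancy_average"]
        assert min(t1, t2, t3) - 1e-9 <= avg <= max(t1, t2, t3) + 1e-9


class TestFullChain:
    def _single_sample(self, conc, flagged, scale=1.0):
        """One dyad, one specimen, DiDP (single constituent MCNP)."""
        lod = METABOLITES["MCNP"].lod * scale
        mets = {"MCNP": MetaboliteDefinition("MCNP", 336.40, lod)}
        urine = _urine_frame(
            [("d1", "C1", 2, "MCNP", conc, flagged, "creatinine", 50.0),
             ("d2", "C1", 2, "MCNP", 10.0 * scale, False, "creatinine", 200.0),
             ("d3", "C1", 2, "MCNP", 10.0 * scale, False, "creatinine", 100.0)]
        )
        return process_exposures(
            urine, metabolites=mets, groups={"DiDP": ("MCNP",)},
            min_detected_participants=1,
        )

    def test_order_of_operations(self):
        # LOD substitution happens before standardization and conversion:
        # flagged record -> lod/sqrt2, then x (median 100 / cr 50), then /MW x 1000
        out = self._single_sample(np.nan, True)
        lod = METABOLITES["MCNP"].lod
        expected = (lod / math.sqrt(2)) * (100.0 / 50.0) / 336.40 * 1000.0
        got = out.set_index("dyad_id").loc["d1", "pregnancy_average"]
        assert got == pytest.approx(expected, rel=1e-12)

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k):
        base = self._single_sample(2.0, False, scale=1.0)
        scaled = self._single_sample(2.0 * k, False, scale=k)
        b = base.set_index("dyad_id")["pregnancy_average"]
        s = scaled.set_index("dyad_id")["pregnancy_average"]
        assert s["d1"] == pytest.approx(k * b["d1"], rel=1e-9)
        assert s["d2"] == pytest.approx(k * b["d2"], rel=1e-9)

    def test_cohort_missing_constituent_drops_group_for_that_cohort_only(self):
        rows = []
        for dyad, cohort in [("d1", "C1"), ("d2", "C2")]:
            for met in ("MiNP", "MCOP", "MCNP"):
                if cohort == "C2" and met == "MCOP":
                    continue  # C2 never assays MCOP
                rows.append((dyad, cohort, 2, met, 5.0, False, "creatinine", 100.0))
        out = process_exposures(
            _urine_frame(rows),
            groups={"DiNP": ("MiNP", "MCOP"), "DiDP": ("MCNP",)},
            min_detected_participants=1,
        )
        key = out.set_index(["dyad_id", "group"]).index
        assert ("d1", "DiNP") in key and ("d2", "DiNP") not in key
        assert ("d1", "DiDP") in key and ("d2", "DiDP") in key

    def test_trimester_boundaries(self):
        assert trimester_of_week(13.9) == 1
        assert trimester_of_week(14.0) == 2
        assert trimester_of_week(27.9) == 2
        assert trimester_of_week(28.0) == 3
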