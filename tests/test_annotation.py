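import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from inhalttc.annotation import (
    ConfigurationError,
    UnrecognizedUnitError,
    adjust_for_duration,
    annotate_studies,
    classify_study_length,
    duration_to_days,
    filter_relevant,
    is_noec_type,
    normalize_species,
    remove_ambiguous,
    standardize_units,
)


class TestClassifyStudyLength:
    def test_chronic_by_duration(self):
        assert classify_study_length("repeat dose", 120, "days") == "chronic"

    def test_subchronic_lower_boundary(self):
        assert classify_study_length("repeat dose", 35, "days") == "subchronic"

    def test_reproductive_dominates_duration(self):
        assert classify_study_length("reproduction", 20, "days") == "reproductive"

    def test_week_conversion_to_subacute(self):
        # 4 weeks = 28 days < 35 -> subacute
        assert classify_study_length("repeat dose", 4, "weeks") == "subacute"

    def test_exactly_100_days_unclassified(self):
        # chronic needs > 100, subchronic needs < 100: the boundary is uncovered
        assert classify_study_length("repeat dose", 100, "days") == "unclassified"

    def test_chronic_token_wins_without_duration(self):
        assert classify_study_length("chronic toxicity", None, None) == "chronic"

    def test_subchronic_token_not_shadowed_by_chronic(self):
        assert classify_study_length("subchronic study", 200, "days") == "subchronic"

    def test_month_conversion(self):
        # 4 months = 121.76 days -> chronic
        assert classify_study_length("repeat dose", 4, "months") == "chronic"

    def test_unclassifiable(self):
        assert classify_study_length("repeat dose", None, None) == "unclassified"

    def test_negative_duration_raises(self):
        with pytest.raises(ValueError, match="negative"):
            classify_study_length("repeat dose", -5, "days")

    @pytest.mark.parametrize(
        "stype,expected",
        [
            ("multigeneration study", "multigenerational"),
            ("developmental toxicity", "developmental"),
            ("REPRODUCTION", "reproductive"),
        ],
    )
    def test_tokens_case_insensitive(self, stype, expected):
        assert classify_study_length(stype, None, None) == expected


class TestDurationToDays:
    @pytest.mark.parametrize(
        "value,units,expected",
        [(10, "days", 10.0), (2, "weeks", 14.0), (3, "wks", 21.0), (1, "month", 30.44), (2, "mo", 60.88)],
    )
    def test_conversions(self, value, units, expected):
        assert duration_to_days(value, units) == pytest.approx(expected)

    def test_missing(self):
        assert duration_to_days(None, "days") is None
        assert duration_to_days(5, None) is None


class TestStandardizeUnits:
    def test_ppm_with_mw_equal_molar_volume(self):
        mg, ppm = standardize_units(1.0, "ppm", mw=24.45)
        assert mg == pytest.approx(1.0)
        assert ppm == 1.0

    def test_g_m3_scaling(self):
        mg, _ = standardize_units(2.0, "g/m3", mw=100.0)
        assert mg == pytest.approx(2000.0)

    def test_ug_m3_scaling(self):
        mg, _ = standardize_units(500.0, "ug/m3", mw=100.0)
        assert mg == pytest.approx(0.5)

    def test_mg_l_identity(self):
        mg, _ = standardize_units(3.0, "mg/L", mw=None)
        assert mg == 3.0

    def test_ppm_arithmetic(self):
        mg, ppm = standardize_units(10.0, "ppm", mw=48.90)
        assert mg == pytest.approx(20.0)
        assert ppm == 10.0

    def test_missing_mw_leaves_track_missing(self):
        mg, ppm = standardize_units(10.0, "ppm", mw=None)
        assert mg is None and ppm == 10.0
        mg, ppm = standardize_units(10.0, "mg/m3", mw=None)
        assert mg == 10.0 and ppm is None

    def test_unit_spelling_variants(self):
        for spelling in ("mg/m3", "mg/m^3", "MG/M3", " mg/m3 ", "µg/m3", "ug/m3"):
            standardize_units(1.0, spelling, mw=50.0)

    def test_unrecognized_unit_raises(self):
        with pytest.raises(UnrecognizedUnitError):
            standardize_units(1.0, "furlongs", mw=50.0)

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=10.0, max_value=1000.0),
    )
    def test_round_trip_identity(self, value, mw):
        """mg/m3 -> ppm -> mg/m3 is the identity to >= 12 significant digits."""
        _, ppm = standardize_units(value, "mg/m3", mw=mw)
        mg_back, _ = standardize_units(ppm, "ppm", mw=mw)
        assert mg_back == pytest.approx(value, rel=1e-12)


class TestRemoveAmbiguous:
    def test_stated_rule(self):
        df = pd.DataFrame({"toxval_numeric": [1.2, 0, -999, 3]})
        cleaned, n = remove_ambiguous(df)
        assert cleaned["toxval_numeric"].tolist() == [1.2, 3]
        assert n == 2

    def test_all_positive_unchanged(self):
        df = pd.DataFrame({"toxval_numeric": [1.0, 2.0]})
        cleaned, n = remove_ambiguous(df)
        assert n == 0
        assert len(cleaned) == 2

    def test_degenerate_all_removed(self):
        df = pd.DataFrame({"toxval_numeric": [-999, -999]})
        cleaned, n = remove_ambiguous(df)
        assert cleaned.empty and n == 2

    def test_input_not_mutated(self):
        df = pd.DataFrame({"toxval_numeric": [1.2, 0]})
        remove_ambiguous(df)
        assert len(df) == 2

    def test_removes_exactly_injected_rows(self, messy_dataset):
        studies = messy_dataset["studies"]
        truth = messy_dataset["studies_truth"]
        cleaned, n = remove_ambiguous(studies)
        assert n == int(truth["is_ambiguous"].sum())
        kept_ids = set(cleaned["record_id"])
        flagged = set(truth.loc[truth["is_ambiguous"], "record_id"])
        assert kept_ids.isdisjoint(flagged)


class TestNormalizeSpecies:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Rat", "rodent"),
            ("Sprague-Dawley rat", "rodent"),
            ("mice", "rodent"),
            ("New Zealand rabbit", "rodent"),
            ("dog", "other"),
            ("monkey", "other"),
            (None, "other"),
        ],
    )
    def test_mapping(self, name, expected):
        assert normalize_species(name) == expected


class TestAdjustForDuration:
    def test_default_identity(self):
        assert adjust_for_duration(10.0, "chronic") == 10.0

    def test_configured_factor(self):
        assert adjust_for_duration(10.0, "subchronic", {"subchronic": 0.5}) == 5.0
        assert adjust_for_duration(0.2, "subacute", {"subacute": 0.25}) == pytest.approx(0.05)

    def test_missing_factor_raises(self):
        with pytest.raises(ConfigurationError):
            adjust_for_duration(1.0, "chronic", {"subchronic": 0.5})


class TestIsNoecType:
    @pytest.mark.parametrize("t", ["NOAEL", "NOAEC", "NOEL", "NOEC", "no(a)el", "NO(A)EC"])
    def test_accepted(self, t):
        assert is_noec_type(t)

    @pytest.mark.parametrize("t", ["LOAEL", "LOAEC", "BMD", "", None])
    def test_rejected(self, t):
        assert not is_noec_type(t)


class TestAnnotateAndFilter:
    def test_filter_branches(self, tiny_records, tiny_substances):
        annotated, rejects = annotate_studies(tiny_records, tiny_substances)
        assert rejects.empty
        kept, attrition = filter_relevant(annotated)
        assert len(kept) == 2
        assert set(kept["toxval_type"]) == {"NOAEC", "NOEC"}
        log = dict(zip(attrition["stage"], attrition["count"]))
        assert log["input"] == 5
        assert log["kept"] + log["dropped"] == log["input"]
        assert log["fail_route"] == 1
        assert log["fail_toxval_type"] == 1
        assert log["fail_species"] == 1

    def test_eq1_consistency_of_tracks(self, tiny_records, tiny_substances):
        annotated, _ = annotate_studies(tiny_records, tiny_substances)
        both = annotated.dropna(subset=["value_mg_m3", "value_ppm"])
        mw = tiny_substances.set_index("substance_id")["mw"]
        for _, row in both.iterrows():
            expected = row["value_ppm"] * mw[row["substance_id"]] / 24.45
            assert row["value_mg_m3"] == pytest.approx(expected, rel=1e-12)

    def test_unrecognized_units_routed_to_rejects(self, tiny_substances):
        records = pd.DataFrame(
            [
                ("S1", "chronic", 120, "days", "inhalation", "NOAEC", 5.0, "mol/L", "Rat"),
            ],
            columns=[
                "substance_id", "study_type", "study_duration_value", "study_duration_units",
                "exposure_route", "toxval_type", "toxval_numeric", "toxval_units", "species",
            ],
        )
        annotated, rejects = annotate_studies(records, tiny_substances)
        assert annotated.empty
        assert len(rejects) == 1
        assert "unrecognized" in rejects["reject_reason"].iloc[0]

    def test_filter_order_independence(self, messy_dataset):
        """Applying the four criteria jointly equals sequential application
        in any order (criteria are independent masks)."""
        from itertools import permutations

        studies, _ = remove_ambiguous(messy_dataset["studies"])
        annotated, _ = annotate_studies(studies, messy_dataset["substances"])
        joint, _ = filter_relevant(annotated)

        masks = {
            "route": annotated["exposure_route"].str.lower().str.contains("inhal"),
            "type": annotated["toxval_type"].map(is_noec_type),
            "species": annotated["species_group"] == "rodent",
            "length": annotated["study_length"].isin(
                ("subacute", "subchronic", "chronic", "reproductive", "developmental", "multigenerational")
            )
            | annotated["study_type"].str.lower().str.contains("repeat"),
        }
        for order in permutations(masks):
            df = annotated
            for key in order:
                df = df[masks[key].loc[df.index]]
            assert set(df.index) == set(joint.index)

    def test_annotate_does_not_mutate_input(self, tiny_records, tiny_substances):
        before = tiny_records.copy()
        annotate_studies(tiny_records, tiny_substances)
        pd.testing.assert_frame_equal(tiny_records, before)
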