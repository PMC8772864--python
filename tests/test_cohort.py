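"""Domain rules: BMI, weight-change, fiber categories; censoring; units."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scfa_assoc.cohort import (AcidProfile, Censored, DetectionLimits,
                               DomainError, SubjectRecord, categorize_bmi,
                               categorize_fiber, categorize_weight_change,
                               censor_concentration, compute_bmi,
                               extract_to_dry_mass, read_cohort,
                               write_cohort)


class TestComputeBmi:
    def test_worked_example(self):
        assert round(compute_bmi(70, 1.80), 1) == 21.6

    @given(st.floats(20, 200))
    @settings(derandomize=True)
    def test_unit_height_identity(self, w):
        assert compute_bmi(w, 1.0) == w

    @pytest.mark.parametrize("w,h", [(0, 1.7), (-5, 1.7), (70, 0), (70, -1)])
    def test_nonpositive_rejected(self, w, h):
        with pytest.raises(DomainError):
            compute_bmi(w, h)

    def test_cohort_extremes_representable(self):
        # a 40 kg / 1.70 m and a 120 kg / 1.80 m person bracket the
        # observed 13.8-37.1 kg/m2 cohort range
        assert compute_bmi(40, 1.70) < 13.9
        assert compute_bmi(120, 1.80) > 37.0


class TestBmiCategories:
    @pytest.mark.parametrize("bmi,cat", [
        (13.8, "underweight"), (18.49, "underweight"),
        (18.5, "normal"), (21.6, "normal"), (24.99, "normal"),
        (25.0, "excessive"), (37.1, "excessive"),
    ])
    def test_boundaries(self, bmi, cat):
        assert categorize_bmi(bmi) == cat

    @given(st.floats(0.1, 100, allow_nan=False))
    @settings(derandomize=True)
    def test_partition(self, bmi):
        """Every positive BMI maps to exactly one ordered category."""
        cat = categorize_bmi(bmi)
        assert cat in ("underweight", "normal", "excessive")
        if cat == "underweight":
            assert bmi < 18.5
        elif cat == "normal":
            assert 18.5 <= bmi <= 24.99
        else:
            assert bmi > 24.99

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            categorize_bmi(0.0)


class TestWeightChange:
    @pytest.mark.parametrize("pct,cat", [
        (-6.0, "loss"), (-5.0, "stable"), (0.0, "stable"),
        (5.0, "stable"), (5.1, "gain"),
    ])
    def test_boundaries(self, pct, cat):
        assert categorize_weight_change(pct) == cat

    @given(st.floats(5.0001, 60))
    @settings(derandomize=True)
    def test_antisymmetry_beyond_5pct(self, x):
        assert categorize_weight_change(-x) == "loss"
        assert categorize_weight_change(x) == "gain"


class TestFiber:
    @pytest.mark.parametrize("diet,cat", [
        ("low_fiber", "low"), ("easily_digestible", "low"),
        ("high_fiber", "high"), ("standard", "normal"), ("other", "normal"),
    ])
    def test_diet_type_mapping(self, diet, cat):
        assert categorize_fiber(diet) == cat

    @pytest.mark.parametrize("grams,cat", [
        (24.9, "low"), (25.0, "normal"), (27.0, "normal"),
        (30.0, "normal"), (30.5, "high"),
    ])
    def test_grams_per_day_override(self, grams, cat):
        # a reported intake overrides even a contradicting diet label
        assert categorize_fiber("high_fiber", grams_per_day=grams) == cat

    def test_unknown_diet_rejected(self):
        with pytest.raises(DomainError):
            categorize_fiber("keto")


class TestCensoring:
    limits = DetectionLimits(loq=26.0)

    def test_lod_is_third_of_loq(self):
        assert self.limits.lod == pytest.approx(26.0 / 3.0)

    def test_inconsistent_lod_rejected(self):
        with pytest.raises(DomainError):
            DetectionLimits(loq=26.0, lod=5.0)

    def test_above_loq_passes_through(self):
        assert censor_concentration(100.0, self.limits) == 100.0

    def test_between_lod_and_loq_flagged_retained(self):
        out = censor_concentration(10.0, self.limits)
        assert isinstance(out, Censored)
        assert out.bound == "below_loq"
        assert out.value == 10.0

    def test_below_lod_substituted_half_lod(self):
        out = censor_concentration(5.0, self.limits)
        assert out.bound == "below_lod"
        assert out.value == pytest.approx(26.0 / 6.0)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            censor_concentration(-1.0, self.limits)

    def test_bad_rsd_rejected(self):
        with pytest.raises(DomainError):
            DetectionLimits(loq=26.0, max_rsd=1.5)


class TestDryMassConversion:
    def test_loq_reproduced(self):
        # calibration floor 7.8 ug/mL, 1 mL extract, 0.3 g sample -> 26 ug/g
        assert extract_to_dry_mass(7.8, 1.0, 0.3) == pytest.approx(26.0)

    @pytest.mark.parametrize("x", [0.5, 3.7, 100.0])
    def test_identity(self, x):
        assert extract_to_dry_mass(x, 1.0, 1.0) == x

    def test_hand_example(self):
        assert extract_to_dry_mass(2.0, 3.0, 0.5) == pytest.approx(12.0)

    @given(st.floats(0.1, 50), st.floats(0.1, 5), st.floats(0.05, 2),
           st.floats(1.1, 4))
    @settings(derandomize=True)
    def test_linearity(self, conc, vol, mass, k):
        base = extract_to_dry_mass(conc, vol, mass)
        assert extract_to_dry_mass(k * conc, vol, mass) == pytest.approx(k * base)
        assert extract_to_dry_mass(conc, k * vol, mass) == pytest.approx(k * base)
        assert extract_to_dry_mass(conc, vol, k * mass) == pytest.approx(base / k)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            extract_to_dry_mass(7.8, 0.0, 0.3)


class TestSubjectRecord:
    def _record(self, **kw):
        base = dict(id="s1", group="UC", sex="male", age=30.0, bmi=22.0,
                    weight_change_pct=0.0, steroids=False, antibiotics=False,
                    immunosuppressants=False, asa5=False, anti_tnf=False,
                    other_meds=False, diet_type="standard")
        base.update(kw)
        return SubjectRecord(**base)

    def test_valid(self):
        assert self._record().group == "UC"

    @pytest.mark.parametrize("kw", [
        {"group": "ibs"}, {"sex": "x"}, {"bmi": -1.0},
        {"diet_type": "keto"}, {"ffq": {"pizza": "daily"}},
        {"ffq": {"legumes": "sometimes"}},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(DomainError):
            self._record(**kw)

    def test_underage_warns(self):
        with pytest.warns(UserWarning):
            self._record(age=17.0)


class TestCsvRoundTrip:
    def test_generated_cohort_round_trips(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(default_cohort, path)
        back = read_cohort(path)
        assert back == default_cohort

    def test_censored_and_missing_cells(self, tmp_path):
        rec = SubjectRecord(
            id="s1", group="CD", sex="female", age=40.0, bmi=20.0,
            weight_change_pct=None, steroids=True, antibiotics=False,
            immunosuppressants=False, asa5=True, anti_tnf=False,
            other_meds=False, diet_type="low_fiber",
            ffq={"legumes": "weekly"},
            acids=AcidProfile({"butyric": 100.0,
                               "valeric": Censored(26 / 6, "below_lod"),
                               "acetic": Censored(12.0, "below_loq")}))
        path = tmp_path / "one.csv"
        write_cohort([rec], path)
        back = read_cohort(path)
        assert back == [rec]
        assert back[0].acids.value("valeric") == pytest.approx(26 / 6)
        assert back[0].acids.value("propionic") is None

    def test_empty_cohort_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort([], path)
        assert len(path.read_text().strip().splitlines()) == 1
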