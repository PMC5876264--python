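import json
from importlib import resources

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hamscore.errors import ValidationError
from hamscore.rubric import (
    ComponentScores,
    InjuryRecord,
    Location,
    Muscle,
    Rubric,
    default_rubric,
    enumerate_score_range,
    score_injury,
)


def naive_component_scores(record):
    """Independent hand-coded application of the default scoring grid."""
    age = int(record.age)
    if age <= 25:
        age_s = 1
    elif age <= 31:
        age_s = 2
    else:
        age_s = 3
    if not record.mri_positive:
        return (age_s, 0, 0, 0, 0, 0, 0)
    muscles_s = min(record.n_muscles, 3)
    loc_s = {"proximal": 1, "middle": 2, "distal": 3}[record.location.value]
    ins_s = 2 if record.insertion_involved else 0
    t = record.transverse_pct
    tr_s = 0 if t < 25 else 1 if t < 50 else 2 if t < 75 else 3
    r = record.retraction_cm
    ret_s = 0 if r == 0 else 1 if r < 2 else 2
    s = record.sagittal_extent_cm
    sag_s = 0 if s == 0 else 1 if s < 5 else 2 if s < 10 else 3
    return (age_s, muscles_s, loc_s, ins_s, tr_s, ret_s, sag_s)


positive_records = st.builds(
    InjuryRecord,
    athlete_id=st.just("h"),
    age=st.integers(18, 50),
    mri_positive=st.just(True),
    n_muscles=st.integers(1, 4),
    primary_muscle=st.sampled_from(list(Muscle)),
    location=st.sampled_from(list(Location)),
    insertion_involved=st.booleans(),
    transverse_pct=st.floats(0, 100, allow_nan=False),
    retraction_cm=st.floats(0, 10, allow_nan=False),
    sagittal_extent_cm=st.floats(0.01, 40, allow_nan=False),
)

negative_records = st.builds(
    InjuryRecord,
    athlete_id=st.just("h"),
    age=st.integers(18, 50),
    mri_positive=st.just(False),
)

any_records = st.one_of(positive_records, negative_records)


class TestDefaultRubric:
    def test_age_bin_edges(self, rubric):
        for age, expected in [(25, 1), (26, 2), (31, 2), (32, 3), (18, 1), (50, 3)]:
            rec = InjuryRecord("a", age, mri_positive=False)
            assert score_injury(rec, rubric).age_score == expected

    def test_insertion_absent_scores_zero(self, rubric, make_record):
        assert score_injury(make_record(insertion_involved=False), rubric).insertion_score == 0
        assert score_injury(make_record(insertion_involved=True), rubric).insertion_score == 2

    def test_component_maxima(self, rubric):
        maxima = rubric.component_maxima()
        assert maxima == {
            "age_years": 3,
            "n_muscles": 3,
            "location": 3,
            "insertion": 2,
            "transverse_pct": 3,
            "retraction_cm": 2,
            "sagittal_cm": 3,
        }
        assert sum(maxima.values()) == 19

    def test_roundtrip_serialization(self, rubric, tmp_path):
        path = tmp_path / "rubric.json"
        rubric.dump(path)
        assert Rubric.load(path) == rubric

    def test_shipped_config_matches_default(self, rubric):
        shipped = json.loads(
            resources.files("hamscore.data").joinpath("default_rubric.json").read_text()
        )
        assert Rubric.from_dict(shipped) == rubric

    def test_invalid_points_rejected(self, rubric):
        d = rubric.to_dict()
        d["location"]["middle"] = 5
        with pytest.raises(ValidationError):
            Rubric.from_dict(d)

    def test_gappy_bins_rejected(self, rubric):
        d = rubric.to_dict()
        del d["transverse_pct"][1]  # leaves [25, 50) uncovered
        with pytest.raises(ValidationError):
            Rubric.from_dict(d)


class TestScoreInjury:
    def test_worked_example(self, rubric, make_record):
        # age 24, 1 muscle, middle, no insertion, 30%, 0 cm retraction, 12 cm
        scores = score_injury(make_record(), rubric)
        assert scores.as_tuple() == (1, 1, 2, 0, 1, 0, 3)
        assert scores.total == 8

    def test_mri_negative_scores_age_only(self, rubric):
        rec = InjuryRecord("neg", 20, mri_positive=False)
        scores = score_injury(rec, rubric)
        assert scores.total == 1
        assert scores.as_tuple() == (1, 0, 0, 0, 0, 0, 0)

    def test_all_top_bins_hits_enumerated_maximum(self, rubric, make_record):
        rec = make_record(
            age=39,
            n_muscles=3,
            location=Location.DISTAL,
            insertion_involved=True,
            transverse_pct=80.0,
            retraction_cm=3.0,
            sagittal_extent_cm=15.0,
        )
        assert score_injury(rec, rubric).total == enumerate_score_range(rubric, True).max_total

    @pytest.mark.parametrize("age", [17, 51, 10])
    def test_age_outside_eligibility_rejected(self, rubric, make_record, age):
        with pytest.raises(ValidationError) as exc:
            score_injury(make_record(age=age), rubric)
        assert exc.value.field == "age"

    def test_transverse_out_of_range_rejected(self, rubric, make_record):
        with pytest.raises(ValidationError) as exc:
            score_injury(make_record(transverse_pct=120.0), rubric)
        assert exc.value.field == "transverse_pct"

    def test_positive_record_needs_location(self, rubric, make_record):
        with pytest.raises(ValidationError):
            score_injury(make_record(location=None), rubric)

    def test_negative_record_rejects_injury_fields(self, rubric):
        rec = InjuryRecord("n", 25, mri_positive=False, n_muscles=1)
        with pytest.raises(ValidationError):
            score_injury(rec, rubric)

    def test_non_integer_age_floored(self, rubric, make_record):
        assert score_injury(make_record(age=25.9), rubric).age_score == 1

    def test_total_is_component_sum(self, rubric, make_record):
        s = score_injury(make_record(), rubric)
        assert s.total == sum(s.as_tuple())


class TestEnumerateScoreRange:
    def test_mri_negative_bounds(self, rubric):
        assert enumerate_score_range(rubric, False) == (1, 3)

    def test_mri_positive_bounds(self, rubric):
        assert enumerate_score_range(rubric, True) == (4, 19)


class TestProperties:
    @settings(max_examples=200, deadline=None)
    @given(record=any_records)
    def test_bin_lookup_matches_naive_grid(self, rubric, record):
        assert score_injury(record, rubric).as_tuple() == naive_component_scores(record)

    @settings(max_examples=100, deadline=None)
    @given(record=positive_records, bump=st.floats(0, 50, allow_nan=False))
    def test_monotone_in_size_variables(self, rubric, record, bump):
        import dataclasses

        base = score_injury(record, rubric).total
        for field_name, cap in [
            ("transverse_pct", 100.0),
            ("retraction_cm", None),
            ("sagittal_extent_cm", None),
        ]:
            value = getattr(record, field_name) + bump
            if cap is not None:
                value = min(value, cap)
            bigger = dataclasses.replace(record, **{field_name: value})
            assert score_injury(bigger, rubric).total >= base
        if record.n_muscles < 4:
            more = dataclasses.replace(record, n_muscles=record.n_muscles + 1)
            assert score_injury(more, rubric).total >= base

    @settings(max_examples=200, deadline=None)
    @given(record=any_records)
    def test_total_within_enumerated_range(self, rubric, record):
        lo, hi = enumerate_score_range(rubric, record.mri_positive)
        assert lo <= score_injury(record, rubric).total <= hi

    @settings(max_examples=50, deadline=None)
    @given(record=any_records)
    def test_deterministic(self, rubric, record):
        assert score_injury(record, rubric) == score_injury(record, rubric)

    def test_from_components_requires_seven(self):
        with pytest.raises(ValueError):
            ComponentScores.from_components(1, 2, 3)
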