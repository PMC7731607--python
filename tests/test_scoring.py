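"""Component scoring rules, boundary conventions, and score invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vbacscore import (AdmissionRecord, Indication, JohnsonParams,
                       RecordValidationError, ScoreBin, johnson_efw,
                       parse_indication, score_age, score_bin, score_bishop,
                       score_bmi, score_cohort, score_efw,
                       score_gestational_age, score_indication,
                       troyer_parisi_score, vbac_score)
from vbacscore.scoring import resolve_efw

from conftest import random_record_kwargs


@pytest.mark.parametrize("age,expected", [
    (22, 2), (28, 1), (33, 0),
    (25, 1), (30, 1), (18, 2), (35, 0), (24.9, 2), (30.1, 0),
])
def test_age_categories(age, expected):
    assert score_age(age) == expected


@pytest.mark.parametrize("ga,expected", [
    (38.5, 0), (39.0, 1), (41.2, 2),
    (37.0, 0), (40.9, 1), (41.0, 2),
])
def test_gestational_age_categories(ga, expected):
    assert score_gestational_age(ga) == expected


@pytest.mark.parametrize("ind,expected", [
    (Indication.NPOL_OR_OTHER, 0),
    (Indication.IUGR_OLIGO_APH, 1),
    (Indication.BREECH_OR_FETAL_DISTRESS, 2),
    ("breech", 2), ("oligohydramnios", 1), ("failed induction", 0),
])
def test_indication_categories(ind, expected):
    assert score_indication(ind) == expected


@pytest.mark.parametrize("bishop,expected", [
    (0, 0), (3, 0), (4, 1), (5, 1), (6, 2), (8, 2), (10, 2),
])
def test_bishop_categories(bishop, expected):
    assert score_bishop(bishop) == expected


@pytest.mark.parametrize("bmi,expected", [
    (23.0, 2), (27.5, 1), (31.0, 0),
    (24.99, 2), (25.0, 1), (29.5, 1), (30.0, 0),
])
def test_bmi_categories(bmi, expected):
    assert score_bmi(bmi) == expected


@pytest.mark.parametrize("efw,expected", [
    (2400, 2), (3000, 1), (3600, 0),
    (2500, 1), (3500, 1), (2499.9, 2), (3500.1, 0),
])
def test_efw_categories(efw, expected):
    assert score_efw(efw) == expected


@pytest.mark.parametrize("sfh,engaged,expected", [
    (34, False, 3410.0), (30, True, 2945.0), (20, False, 1240.0),
])
def test_johnson_formula(sfh, engaged, expected):
    assert johnson_efw(sfh, engaged) == pytest.approx(expected)


def test_johnson_strictly_increasing_in_sfh():
    heights = np.linspace(21, 49, 50)
    for engaged in (True, False):
        efws = [johnson_efw(h, engaged) for h in heights]
        assert np.all(np.diff(efws) > 0)


def test_johnson_params_must_be_positive():
    with pytest.raises(ValueError):
        JohnsonParams(gram_factor=-1)


@pytest.mark.parametrize("kwargs,total", [
    (dict(age=20, gestational_age=41.5, indication="BREECH_OR_FETAL_DISTRESS",
          bishop=8, bmi=23, efw_g=2400), 12),
    (dict(age=33, gestational_age=38, indication="NPOL_OR_OTHER",
          bishop=2, bmi=31, efw_g=3600), 0),
    (dict(age=22, gestational_age=39, indication="IUGR_OLIGO_APH",
          bishop=5, bmi=27, efw_g=3000), 7),
])
def test_total_score_worked_examples(kwargs, total):
    breakdown = vbac_score(AdmissionRecord(**kwargs))
    assert breakdown.total == total
    assert breakdown.total == sum([breakdown.age_pts, breakdown.ga_pts,
                                   breakdown.indication_pts, breakdown.bishop_pts,
                                   breakdown.bmi_pts, breakdown.efw_pts])


def test_bins_partition_all_totals():
    expected = {**{t: ScoreBin.B0_3 for t in range(4)},
                **{t: ScoreBin.B4_6 for t in range(4, 7)},
                **{t: ScoreBin.B7_9 for t in range(7, 10)},
                **{t: ScoreBin.B10_PLUS for t in range(10, 13)}}
    assert {t: score_bin(t) for t in range(13)} == expected
    for bad in (-1, 13, 5.5):
        with pytest.raises(ValueError):
            score_bin(bad)


@pytest.mark.parametrize("field,kwargs", [
    ("age", dict(age=17)),
    ("age", dict(age=36)),
    ("gestational_age", dict(gestational_age=36.5)),
    ("bishop", dict(bishop=11)),
    ("bmi", dict(bmi=-1)),
    ("efw_g", dict(efw_g=None)),
])
def test_validation_errors_name_the_field(field, kwargs):
    base = dict(age=25, gestational_age=39, indication="NPOL_OR_OTHER",
                bishop=5, bmi=24, efw_g=3000)
    base.update(kwargs)
    with pytest.raises(RecordValidationError) as err:
        AdmissionRecord(**base)
    assert err.value.field_name == field


def test_age_error_cites_inclusion_criterion():
    with pytest.raises(RecordValidationError, match="18-35"):
        AdmissionRecord(age=17, gestational_age=39, indication="NPOL_OR_OTHER",
                        bishop=5, bmi=24, efw_g=3000)


def test_unknown_indication_lists_categories():
    with pytest.raises(RecordValidationError) as err:
        parse_indication("placenta previa")
    for name in ("NPOL_OR_OTHER", "IUGR_OLIGO_APH", "BREECH_OR_FETAL_DISTRESS"):
        assert name in str(err.value)


def test_efw_direct_grams_take_precedence_with_warning():
    rec = AdmissionRecord(age=25, gestational_age=39, indication="NPOL_OR_OTHER",
                          bishop=5, bmi=24, efw_g=2000, sfh_cm=34, engaged=False)
    with pytest.warns(UserWarning, match="disagree"):
        assert resolve_efw(rec) == 2000
    rec2 = AdmissionRecord(age=25, gestational_age=39, indication="NPOL_OR_OTHER",
                           bishop=5, bmi=24, sfh_cm=34, engaged=False)
    assert resolve_efw(rec2) == pytest.approx(3410.0)


@pytest.mark.parametrize("flags,expected", [
    ((False, False, False, False), 0),
    ((True, True, True, True), 4),
    ((True, False, True, False), 2),
])
def test_troyer_parisi_counts_risk_factors(flags, expected):
    assert troyer_parisi_score(*flags) == expected


# --- invariants --------------------------------------------------------------

_record_strategy = st.fixed_dictionaries({
    "age": st.floats(18, 35),
    "gestational_age": st.floats(37, 43),
    "indication": st.sampled_from([m.value for m in Indication]),
    "bishop": st.integers(0, 10),
    "bmi": st.floats(16, 45),
    "efw_g": st.floats(1500, 4600),
})


@settings(max_examples=200, derandomize=True, database=None)
@given(_record_strategy)
def test_total_in_range_and_bin_consistent(kwargs):
    b = vbac_score(AdmissionRecord(**kwargs))
    assert 0 <= b.total <= 12
    assert b.bin == score_bin(b.total)


_IMPROVEMENTS = {
    "age": lambda v: max(18.0, v - 3.0),               # younger is favourable
    "gestational_age": lambda v: min(42.0, v + 0.5),   # later is favourable
    "bishop": lambda v: min(10, v + 1),
    "bmi": lambda v: max(16.0, v - 2.0),               # leaner is favourable
    "efw_g": lambda v: max(1500.0, v - 300.0),         # smaller is favourable
    "indication": lambda v: {
        "NPOL_OR_OTHER": "IUGR_OLIGO_APH",
        "IUGR_OLIGO_APH": "BREECH_OR_FETAL_DISTRESS",
        "BREECH_OR_FETAL_DISTRESS": "BREECH_OR_FETAL_DISTRESS"}[v],
}


@settings(max_examples=200, derandomize=True, database=None)
@given(_record_strategy, st.sampled_from(sorted(_IMPROVEMENTS)))
def test_more_favourable_covariate_never_lowers_total(kwargs, field):
    before = vbac_score(AdmissionRecord(**kwargs)).total
    improved = dict(kwargs)
    improved[field] = _IMPROVEMENTS[field](kwargs[field])
    after = vbac_score(AdmissionRecord(**improved)).total
    assert after >= before


def test_vectorised_cohort_scoring_matches_scalar(rng):
    rows = [random_record_kwargs(rng) for _ in range(300)]
    df = pd.DataFrame(rows)
    scored = score_cohort(df)
    for i, row in enumerate(rows):
        expected = vbac_score(AdmissionRecord(**row))
        assert scored.loc[i, "total"] == expected.total
        assert scored.loc[i, "bin"] == expected.bin.value


def test_vectorised_scoring_resolves_efw_via_johnson():
    df = pd.DataFrame([
        {"age": 25, "gestational_age": 39, "indication": "NPOL_OR_OTHER",
         "bishop": 5, "bmi": 24, "efw_g": np.nan, "sfh_cm": 34.0, "engaged": False},
    ])
    scored = score_cohort(df)
    assert scored.loc[0, "efw_resolved_g"] == pytest.approx(3410.0)
    assert scored.loc[0, "efw_pts"] == 1


def test_vectorised_scoring_rejects_out_of_range_rows(rng):
    df = pd.DataFrame([random_record_kwargs(rng) for _ in range(3)])
    df.loc[1, "age"] = 17.0
    with pytest.raises(RecordValidationError, match="age"):
        score_cohort(df)
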