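"""Unit conversions and cohort CSV round-tripping."""

import math

import pytest

from glycendo import (FastingSample, SubjectRecord, ValidationError, compute_panel,
                      convert_glucose, convert_insulin, insulin_pmol_to_uiu,
                      read_cohort, write_cohort)
from glycendo.cohort import Cohort, record_from_row


@pytest.mark.parametrize("value,unit,expected", [
    (126.0, "mg_dL", 7.0),
    (0.0, "mg_dL", 0.0),
    (90.0, "mg_dL", 5.0),
    (5.1, "mmol_L", 5.1),
])
def test_convert_glucose(value, unit, expected):
    assert convert_glucose(value, unit) == pytest.approx(expected)


@pytest.mark.parametrize("value,unit,expected", [
    (10.0, "uIU_mL", 69.45),
    (0.0, "uIU_mL", 0.0),
    (97.2, "pmol_L", 97.2),
])
def test_convert_insulin(value, unit, expected):
    assert convert_insulin(value, unit) == pytest.approx(expected)


def test_insulin_inverse_conversion():
    assert insulin_pmol_to_uiu(97.2) == pytest.approx(97.2 / 6.945)
    assert insulin_pmol_to_uiu(convert_insulin(13.0, "uIU_mL")) == pytest.approx(13.0)


@pytest.mark.parametrize("converter", [convert_glucose, convert_insulin])
def test_negative_concentration_rejected(converter):
    with pytest.raises(ValueError):
        converter(-1.0)


def test_unknown_unit_rejected():
    with pytest.raises(ValueError):
        convert_glucose(5.0, "mol_L")


@pytest.mark.parametrize("kwargs", [
    {"glucose": 0.5, "insulin": 100.0},     # below glucose plausibility bound
    {"glucose": 60.0, "insulin": 100.0},    # above glucose plausibility bound
    {"glucose": 5.0, "insulin": 5000.0},    # insulin out of range
    {"glucose": 5.0, "insulin": 100.0, "hba1c": 25.0},
])
def test_implausible_fasting_values_rejected(kwargs):
    with pytest.raises(ValidationError):
        FastingSample(**kwargs)


def _write_csv(path, rows, header=None):
    header = header or ("subject_id,group,sex,age,bmi,glucose,glucose_unit,"
                        "insulin,insulin_unit,hba1c,haptoglobin,crp,ab_positive,"
                        "age_dm_dx,meds,hurley,sahs,exacerbations,regions,"
                        "fistulae,nodules,abscesses")
    path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")


def test_read_cohort_roundtrip(tmp_path):
    p = tmp_path / "c.csv"
    _write_csv(p, [
        "s1,HS,female,41,31.1,5.1,mmol_L,97.2,pmol_L,5.6,210.3,5.4,,,metformin;sitagliptin,2,7,0,3,4,2,0",
        "s2,control,male,40,27.4,4.9,mmol_L,69.0,pmol_L,,,,,,,,0,0,0,0,0,0",
        "s3,HS,male,52,36.2,6.28,mmol_L,145.8,pmol_L,6.8,256.6,11.4,false,48,metformin,3,9,2,5,8,4,1",
    ])
    cohort = read_cohort(p)
    assert len(cohort) == 3 and not cohort.rejected_rows
    s1 = cohort.subjects[0]
    assert s1.antidiabetic_medications == {"metformin", "sitagliptin"}
    assert cohort.subjects[1].sample.hba1c is None
    out = tmp_path / "out.csv"
    write_cohort(cohort, out)
    again = read_cohort(out)
    for a, b in zip(cohort, again):
        assert a.sample == b.sample
        assert a.antidiabetic_medications == b.antidiabetic_medications
        assert a.hurley == b.hurley and a.haptoglobin == b.haptoglobin


def test_invalid_rows_rejected_with_row_numbers(tmp_path):
    p = tmp_path / "c.csv"
    _write_csv(p, [
        "s1,HS,female,41,31.1,5.1,mmol_L,97.2,pmol_L,,,,,,,,,,,,,",
        "s2,HS,male,40,28.0,-1,mmol_L,80.0,pmol_L,,,,,,,,,,,,,",
    ])
    cohort = read_cohort(p)
    assert len(cohort) == 1
    assert [row for row, _ in cohort.rejected_rows] == [3]


def test_missing_mandatory_column_is_hard_error(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("subject_id,group,sex\ns1,HS,female\n", encoding="utf-8")
    with pytest.raises(ValidationError, match="mandatory"):
        read_cohort(p)


def test_duplicate_subject_ids_rejected():
    s = FastingSample(glucose=5.0, insulin=60.0)
    rec = dict(group="HS", sex="male", age=40.0, bmi=30.0, sample=s)
    with pytest.raises(ValidationError, match="duplicate"):
        Cohort([SubjectRecord(subject_id="a", **rec),
                SubjectRecord(subject_id="a", **rec)])


def test_unit_invariance_of_downstream_panel(tmp_path):
    """The same physiology in conventional vs SI units gives identical indices."""
    si = tmp_path / "si.csv"
    conv = tmp_path / "conv.csv"
    # 91.8 mg/dL = 5.1 mmol/L; 14 µIU/mL = 97.23 pmol/L
    _write_csv(si, ["s1,HS,female,41,31.1,5.1,mmol_L,97.23,pmol_L,,,,,,,,,,,,,"])
    _write_csv(conv, ["s1,HS,female,41,31.1,91.8,mg_dL,14.0,uIU_mL,,,,,,,,,,,,,"])
    p_si = compute_panel(read_cohort(si).subjects[0].sample)
    p_conv = compute_panel(read_cohort(conv).subjects[0].sample)
    for name, v in p_si.as_dict().items():
        w = p_conv.value(name)
        assert math.isclose(v, w, rel_tol=1e-9), name


def test_complete_case_filter_is_per_variable_set():
    s_full = SubjectRecord(subject_id="a", group="HS", sex="male", age=40, bmi=30,
                           sample=FastingSample(5.0, 60.0, hba1c=5.5), haptoglobin=200.0)
    s_nohp = SubjectRecord(subject_id="b", group="HS", sex="male", age=40, bmi=30,
                           sample=FastingSample(5.0, 60.0))
    cohort = Cohort([s_full, s_nohp])
    assert len(cohort.complete_cases(["glucose", "insulin"])) == 2
    assert len(cohort.complete_cases(["hba1c", "haptoglobin"])) == 1


def test_per_row_units_override_defaults():
    row = {"subject_id": "x", "group": "HS", "sex": "female", "age": "40",
           "bmi": "30", "glucose": "126", "glucose_unit": "mg_dL",
           "insulin": "10", "insulin_unit": "uIU_mL"}
    rec = record_from_row(row, glucose_unit="mmol_L", insulin_unit="pmol_L")
    assert rec.sample.glucose == pytest.approx(7.0)
    assert rec.sample.insulin == pytest.approx(69.45)
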