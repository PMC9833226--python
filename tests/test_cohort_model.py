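import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from fhscreen import (
    Analyte,
    CohortConfig,
    GeneticTestRecord,
    LabMeasurement,
    PatientRecord,
    Sex,
    derive_diabetes,
    derive_hypertension,
    read_cohort,
    write_cohort,
)
from fhscreen.cohort_model import LABS_COLUMNS, REGISTRY_COLUMNS


def _patient(**kw) -> PatientRecord:
    base = dict(
        patient_id="P1",
        sex=Sex.MALE,
        birth_date=dt.date(1970, 1, 1),
        cad_date=dt.date(2012, 6, 1),
        max_stenosis_pct=80.0,
    )
    base.update(kw)
    return PatientRecord(**base)


def _hba1c(value: float, pid: str = "P1") -> LabMeasurement:
    return LabMeasurement(
        patient_id=pid, date=dt.date(2010, 1, 1), analyte=Analyte.HBA1C,
        value=value, unit="mmol/mol",
    )


class TestRecordInvariants:
    def test_birth_after_cad_rejected(self):
        with pytest.raises(ValidationError):
            _patient(birth_date=dt.date(2015, 1, 1))

    def test_stenosis_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            _patient(max_stenosis_pct=120.0)

    @pytest.mark.parametrize(
        "analyte,unit,ok",
        [
            (Analyte.LDL, "mmol/l", True),
            (Analyte.LDL, "mg/dl", False),
            (Analyte.HBA1C, "mmol/mol", True),
            (Analyte.HBA1C, "mmol/l", False),
            (Analyte.TSH, "mU/l", True),
            (Analyte.TSH, "mmol/l", False),
        ],
    )
    def test_lab_unit_must_be_canonical(self, analyte, unit, ok):
        make = lambda: LabMeasurement(
            patient_id="P1", date=dt.date(2010, 1, 1), analyte=analyte,
            value=5.0, unit=unit,
        )
        if ok:
            assert make().unit == unit
        else:
            with pytest.raises(ValidationError):
                make()

    def test_genetic_result_requires_test(self):
        with pytest.raises(ValidationError):
            GeneticTestRecord(tested=False, result="negative")

    def test_age_at_cad_fractional_years(self):
        p = _patient(birth_date=dt.date(1970, 1, 1), cad_date=dt.date(2012, 6, 1))
        days = (dt.date(2012, 6, 1) - dt.date(1970, 1, 1)).days
        assert p.age_at_cad == pytest.approx(days / 365.25)


class TestConfig:
    def test_defaults_match_screening_rules(self):
        cfg = CohortConfig()
        assert (cfg.male_age_cutoff, cfg.female_age_cutoff) == (55.0, 60.0)
        assert (cfg.tc_threshold, cfg.ldl_threshold) == (8.0, 5.0)
        assert cfg.lab_window_start == dt.date(2000, 1, 1)
        assert cfg.friedewald_era_end == dt.date(2017, 3, 30)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(tsh_cutoff=0.0)

    def test_yaml_overlay_keeps_defaults(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("ldl_threshold: 4.0\nthreshold_inclusive: false\n")
        cfg = CohortConfig.from_yaml(path)
        assert cfg.ldl_threshold == 4.0
        assert not cfg.threshold_inclusive
        assert cfg.tc_threshold == 8.0


class TestReadWrite:
    def test_roundtrip_identity(self, tmp_path):
        from fhscreen import SimParams, simulate_cohort

        patients, labs, _ = simulate_cohort(SimParams(n_patients=60, seed=7))
        reg, lab = tmp_path / "registry.csv", tmp_path / "labs.csv"
        write_cohort(patients, labs, reg, lab)
        back_p, back_l, report = read_cohort(reg, lab)
        assert report.n_rejected == 0
        assert back_p == patients
        assert back_l == labs

    def test_bad_rows_rejected_with_reason_and_conserved(self, tmp_path):
        reg = tmp_path / "registry.csv"
        lab = tmp_path / "labs.csv"
        good = _patient()
        write_cohort([good], [], reg, lab)
        # append a registry row with birth after CAD and a lab row in mg/dl
        with open(reg, "a") as fh:
            row = reg.read_text().strip().split("\n")[1].split(",")
            row[0], row[2], row[3] = "P2", "2015-01-01", "2012-06-01"
            fh.write(",".join(row) + "\n")
        lab.write_text(
            ",".join(LABS_COLUMNS)
            + "\nP1,2010-01-01,LDL,5.4,mmol/l,direct\nP1,2010-01-02,LDL,140,mg/dl,direct\n"
        )
        patients, labs, report = read_cohort(reg, lab)
        assert len(patients) == 1 and len(labs) == 1
        assert report.registry_rows == 2 and report.labs_rows == 2
        # conservation: accepted + rejected == input rows
        assert len(patients) + len(labs) + report.n_rejected == 4
        reasons = {r.source: r.reason for r in report.rejections}
        assert "birth_date" in reasons["registry"]
        assert "unit" in reasons["labs"] or "mg/dl" in reasons["labs"]

    def test_missing_column_is_hard_error(self, tmp_path):
        reg = tmp_path / "registry.csv"
        lab = tmp_path / "labs.csv"
        reg.write_text(",".join(REGISTRY_COLUMNS[:-1]) + "\n")
        lab.write_text(",".join(LABS_COLUMNS) + "\n")
        with pytest.raises(ValueError, match="cascade_referred"):
            read_cohort(reg, lab)


class TestRiskFactors:
    @pytest.mark.parametrize(
        "dx,treat,hba1c,expected",
        [
            (False, False, 43.0, True),   # HbA1c above 42 mmol/mol
            (False, False, 42.0, False),  # boundary: strictly above
            (True, False, None, True),    # prior diagnosis alone
            (False, True, None, True),    # treatment alone
            (False, False, None, False),
        ],
    )
    def test_derive_diabetes(self, dx, treat, hba1c, expected):
        p = _patient(diabetes_dx=dx, diabetes_treatment=treat)
        labs = [_hba1c(hba1c)] if hba1c is not None else []
        assert derive_diabetes(p, labs) is expected

    @pytest.mark.parametrize(
        "sbp,dbp,dx,meds,expected",
        [
            (150.0, None, False, False, True),
            (140.0, 90.0, False, False, False),  # strict inequalities
            (None, 95.0, False, False, True),
            (None, None, True, False, True),
            (None, None, False, True, True),
            (None, None, False, False, False),
        ],
    )
    def test_derive_hypertension(self, sbp, dbp, dx, meds, expected):
        p = _patient(sbp=sbp, dbp=dbp, hypertension_dx=dx, antihypertensive_meds=meds)
        assert derive_hypertension(p) is expected

    @given(
        dx=st.booleans(), treat=st.booleans(),
        hba1c=st.floats(min_value=20, max_value=120),
    )
    @settings(max_examples=50, deadline=None)
    def test_diabetes_monotone_in_facts(self, dx, treat, hba1c):
        """Adding a qualifying fact never flips a positive call negative."""
        base = derive_diabetes(_patient(diabetes_dx=dx, diabetes_treatment=treat),
                               [_hba1c(hba1c)])
        stronger = derive_diabetes(
            _patient(diabetes_dx=True, diabetes_treatment=treat), [_hba1c(hba1c)]
        )
        assert stronger or not base
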