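"""Event datasets: dialect round-trip, ratio rules, analysis-set rules."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from ratiopkpd import (ADULT_ASSAY, PAEDIATRIC_ASSAY, AdultDesign,
                       DoseEvent, Observation, PaediatricDesign,
                       StudyDataset, SubjectRecord, TruthSpec,
                       apply_adult_inclusion_rules,
                       apply_paediatric_exclusion_rules, compute_ratio,
                       generate_adult_study, generate_paediatric_study,
                       read_dataset, time_since_last_dose, write_dataset)
from ratiopkpd.datasets import DatasetError


def _toy_csv(tmp_path, text):
    p = tmp_path / "toy.csv"
    p.write_text(text)
    return p


class TestReadWrite:
    def test_toy_csv_parses_doses_and_censoring(self, tmp_path):
        p = _toy_csv(tmp_path, "\n".join([
            "ID,TIME,EVID,AMT,DVID,DV,CENS,LIMIT",
            "1,0,1,20000,.,.,.,.",
            "1,1.0,0,.,1,5.2,0,.",
            "1,24,0,.,1,0.70,1,0",
        ]) + "\n")
        ds = read_dataset(p, population="adult")
        assert len(ds.subjects) == 1
        s = ds.subjects[0]
        assert len(s.doses) == 1 and s.doses[0].amount == 20000
        assert len(s.observations) == 2
        cens = [ob for ob in s.observations if ob.censored]
        assert len(cens) == 1 and cens[0].value == 0.70

    def test_censored_row_without_limit_column_is_an_error(self, tmp_path):
        p = _toy_csv(tmp_path, "\n".join([
            "ID,TIME,EVID,AMT,DVID,DV,CENS",
            "1,0,1,20000,.,.,.",
            "1,24,0,.,1,0.70,1",
        ]) + "\n")
        with pytest.raises(DatasetError, match="LIMIT"):
            read_dataset(p, population="adult")

    def test_unknown_dvid_is_a_schema_error(self, tmp_path):
        p = _toy_csv(tmp_path, "ID,TIME,EVID,AMT,DVID,DV,CENS,LIMIT\n"
                               "1,1,0,.,9,5.0,0,.\n")
        with pytest.raises(DatasetError, match="DVID"):
            read_dataset(p, population="adult")

    def test_negative_time_is_a_validation_error(self, tmp_path):
        p = _toy_csv(tmp_path, "ID,TIME,EVID,AMT,DVID,DV,CENS,LIMIT\n"
                               "1,-1,0,.,1,5.0,0,.\n")
        with pytest.raises(DatasetError, match="negative time"):
            read_dataset(p, population="adult")

    def test_round_trip_preserves_generated_adult_study(self, tmp_path,
                                                        adult_truth):
        ds = generate_adult_study(AdultDesign(), adult_truth, seed=7)
        path = tmp_path / "adult.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.population == "adult"
        assert [s.id for s in back.subjects] == [s.id for s in ds.subjects]
        okey = lambda ob: (ob.time, ob.analyte, ob.value)  # noqa: E731
        for s0, s1 in zip(ds.subjects, back.subjects):
            assert s0.doses == s1.doses
            assert sorted(s0.observations, key=okey) == \
                sorted(s1.observations, key=okey)
            for key in ("age", "weight", "bmi", "sex"):
                assert s0.covariates[key] == pytest.approx(
                    s1.covariates[key])


class TestComputeRatio:
    def test_substitution_below_paediatric_lloq(self):
        # ANG II below 22.3 pg/mL is replaced by LLOQ/2 = 11.15
        res = compute_ratio(10.0, 111.5, PAEDIATRIC_ASSAY)
        assert res.substituted and not res.excluded
        assert res.value == pytest.approx(11.15 / 111.5)
        assert res.value == pytest.approx(0.1)

    def test_equal_quantifiable_analytes_give_unity(self):
        res = compute_ratio(50.0, 50.0, PAEDIATRIC_ASSAY)
        assert not res.substituted
        assert res.value == pytest.approx(1.0)

    def test_both_blq_is_excluded_without_a_ratio(self):
        res = compute_ratio(5.0, 10.0, PAEDIATRIC_ASSAY)
        assert res.excluded and res.value is None

    def test_ang1_unit_harmonisation(self):
        # adult ANG I reported in ug/L: 0.5 ug/L = 500 pg/mL
        res = compute_ratio(50.0, 0.5, ADULT_ASSAY, ang1_units="ug/L")
        assert res.value == pytest.approx(0.1)

    def test_zero_ang1_not_flagged_blq_is_an_error(self):
        with pytest.raises(DatasetError, match="undefined"):
            compute_ratio(50.0, 0.0, PAEDIATRIC_ASSAY, ang1_blq=False)

    @hsettings(derandomize=True, max_examples=50)
    @given(st.floats(0.05, 0.95), st.floats(30, 1500))
    def test_ratio_invariant_to_consistent_unit_rescaling(self, r, ang1):
        ang2 = r * ang1
        a = compute_ratio(ang2, ang1, PAEDIATRIC_ASSAY)
        b = compute_ratio(ang2 / 1000.0, ang1 / 1000.0, PAEDIATRIC_ASSAY,
                          ang2_units="ug/L", ang1_units="ug/L")
        assert a.substituted == b.substituted
        assert a.excluded == b.excluded
        if a.value is not None:
            assert a.value == pytest.approx(b.value, rel=1e-12)


class TestAdultInclusionRules:
    def test_design_faithful_study_yields_printed_counts(self,
                                                         adult_study_n9):
        out, audit = apply_adult_inclusion_rules(adult_study_n9)
        assert audit["included_pk"] == 288
        assert audit["included_ratio"] == 99
        assert audit["excluded_predose_pk"] == 9
        assert audit["excluded_ratio_gt24h"] == 18

    def test_idempotent(self, adult_study_n9):
        once, audit1 = apply_adult_inclusion_rules(adult_study_n9)
        twice, audit2 = apply_adult_inclusion_rules(once)
        assert audit2["included_pk"] == audit1["included_pk"]
        assert audit2["included_ratio"] == audit1["included_ratio"]
        assert twice == once

    def test_counts_partition_the_input(self, adult_study_n9):
        n_in = len([ob for ob in adult_study_n9.observations()
                    if ob.analyte in ("ENALAPRILAT", "RATIO")])
        _, a = apply_adult_inclusion_rules(adult_study_n9)
        assert (a["included_pk"] + a["included_ratio"]
                + a["excluded_predose_pk"]
                + a["excluded_ratio_gt24h"]) == n_in

    def test_blq_values_become_interval_censored(self, adult_study_n9):
        out, audit = apply_adult_inclusion_rules(adult_study_n9)
        lloq = ADULT_ASSAY.limits["ENALAPRILAT"].lloq
        for ob in out.observations("ENALAPRILAT"):
            if ob.censored:
                assert ob.value == lloq and ob.lower == 0.0
            else:
                assert ob.value >= lloq

    def test_empty_dataset_passes_with_zero_counts(self):
        ds = StudyDataset("adult", (), ADULT_ASSAY)
        out, audit = apply_adult_inclusion_rules(ds)
        assert all(v == 0 for v in audit.values())

    def test_population_mismatch_is_an_error(self, paed_study_n27):
        with pytest.raises(DatasetError, match="non-adult"):
            apply_adult_inclusion_rules(paed_study_n27)


class TestPaediatricExclusionRules:
    def test_study_fixture_gives_printed_accounting(self, paed_study_n27):
        out, audit = apply_paediatric_exclusion_rules(paed_study_n27)
        assert audit["included"] == 54
        assert (audit["predose_first"], audit["post_first"],
                audit["post_repeated"]) == (16, 12, 26)
        assert audit["ANGI_ULOQ"] == 10
        assert audit["THERAPY_STOPPED"] == 10
        assert audit["STOP_UNCLEAR"] == 8
        assert audit["BOTH_BLQ"] == 2
        assert audit["GT24H"] == 1
        assert audit["OTHER"] == 2

    def test_untagged_recent_records_pass_unchanged(self,
                                                    paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=10),
                                       paediatric_truth, seed=3)
        out, audit = apply_paediatric_exclusion_rules(ds)
        assert sum(audit[t] for t in ("ANGI_ULOQ", "THERAPY_STOPPED",
                                      "STOP_UNCLEAR", "BOTH_BLQ",
                                      "OTHER")) == 0
        assert out.observations() == ds.observations()

    def test_unknown_tag_is_a_validation_error(self):
        s = SubjectRecord("P1", {}, (DoseEvent("P1", 0.0, 100.0),),
                          (Observation("P1", 4.0, "RATIO", 0.1,
                                       excluded="MYSTERY"),))
        ds = StudyDataset("paediatric", (s,), PAEDIATRIC_ASSAY)
        with pytest.raises(DatasetError, match="MYSTERY"):
            apply_paediatric_exclusion_rules(ds)

    def test_counts_partition_records(self, paed_study_n27):
        # records = distinct (subject, time) observation groups
        n_rec = sum(len({ob.time for ob in s.observations})
                    for s in paed_study_n27.subjects)
        _, a = apply_paediatric_exclusion_rules(paed_study_n27)
        excl = sum(a[t] for t in ("ANGI_ULOQ", "THERAPY_STOPPED",
                                  "STOP_UNCLEAR", "BOTH_BLQ", "GT24H",
                                  "OTHER"))
        assert a["included"] + excl == n_rec


class TestTimeSinceLastDose:
    def test_two_doses(self):
        s = SubjectRecord("x", {}, (DoseEvent("x", 0.0, 1.0),
                                    DoseEvent("x", 12.0, 1.0)))
        assert time_since_last_dose(s, 16.0) == pytest.approx(4.0)

    def test_single_dose(self):
        s = SubjectRecord("x", {}, (DoseEvent("x", 0.0, 1.0),))
        assert time_since_last_dose(s, 4.0) == pytest.approx(4.0)

    def test_no_prior_dose_is_an_error(self):
        s = SubjectRecord("x", {}, (DoseEvent("x", 10.0, 1.0),))
        with pytest.raises(DatasetError):
            time_since_last_dose(s, 5.0)

    def test_bid_diary_scan(self, paediatric_truth):
        # generated twice-daily diary: 2 h after any morning dose is 2 h
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=5),
                                       paediatric_truth, seed=9)
        s = next(sub for sub in ds.subjects if len(sub.doses) > 4)
        last = s.doses[-2].time
        expected = last + 2.0 - max(d.time for d in s.doses
                                    if d.time <= last + 2.0)
        assert time_since_last_dose(s, last + 2.0) == pytest.approx(
            expected) == pytest.approx(2.0)
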