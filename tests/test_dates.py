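"""Study-day convention, offsets, age derivation, season retention."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

import trialdeid as td
from trialdeid.dates import ReferenceDateSpec
from trialdeid.study import parse_iso_date


class TestStudyDay:
    @pytest.mark.parametrize(
        "date,ref,expected",
        [
            ("2020-03-01", "2020-03-01", 1),   # day 1 is the reference itself
            ("2020-03-05", "2020-03-01", 5),
            ("2020-02-28", "2020-03-01", -2),  # no day 0
            ("2020-03-02", "2020-03-01", 2),
            ("2020-02-29", "2020-03-01", -1),
        ],
    )
    def test_sdtm_convention(self, date, ref, expected):
        assert td.study_day(date, ref) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        d=st.dates(dt.date(1990, 1, 1), dt.date(2030, 12, 31)),
        r=st.dates(dt.date(1990, 1, 1), dt.date(2030, 12, 31)),
    )
    def test_never_zero_and_monotone(self, d, r):
        day = td.study_day(d, r)
        assert day != 0
        assert td.study_day(d + dt.timedelta(days=1), r) > day

    def test_partial_date_rejected(self):
        with pytest.raises(td.StudyError, match="partial"):
            td.study_day("2020-03", "2020-03-01")


class TestDeriveAge:
    @pytest.mark.parametrize(
        "dob,ref,expected",
        [
            ("1950-06-15", "2020-06-14", 69),  # birthday not yet reached
            ("1950-06-15", "2020-06-15", 70),  # birthday boundary
            ("1950-06-15", "2020-06-16", 70),
            ("2000-02-29", "2021-02-28", 21),  # leap-day birthday reached Feb 28
            ("2000-02-29", "2021-02-27", 20),
            ("2000-02-29", "2020-02-29", 20),
        ],
    )
    def test_completed_years(self, dob, ref, expected):
        assert td.derive_age(dob, ref) == expected

    def test_dob_after_reference_is_error(self):
        with pytest.raises(td.StudyError):
            td.derive_age("2021-01-01", "2020-01-01")

    @settings(max_examples=200, derandomize=True)
    @given(
        dob=st.dates(dt.date(1920, 1, 1), dt.date(2000, 12, 31)),
        ref=st.dates(dt.date(2002, 1, 1), dt.date(2030, 12, 31)),
    )
    def test_age_increases_by_at_most_one_per_year(self, dob, ref):
        a_now = td.derive_age(dob, ref)
        a_prev = td.derive_age(dob, ref.replace(year=ref.year - 1) if not
                               (ref.month == 2 and ref.day == 29)
                               else dt.date(ref.year - 1, 2, 28))
        assert a_now - a_prev in (0, 1)
        assert a_now >= 0


class TestApplyStudyDays:
    def test_values_and_renaming(self, tiny_study):
        spec = ReferenceDateSpec(table="DM", variable="RFSTDTC")
        out = td.apply_study_days(
            tiny_study, spec, {"AE": ["AESTDTC"], "DM": ["RFSTDTC"]}
        )
        assert "AESTDY" in out.tables["AE"].variables
        assert "AESTDTC" not in out.tables["AE"].variables
        # P001 ref 2020-01-10, event 2020-01-20 -> day 11
        assert out.tables["AE"].values("AESTDY")[0] == "11"
        # the reference variable itself becomes constant day 1
        assert set(out.tables["DM"].values("RFSTDY")) == {"1"}

    def test_no_date_variables_is_identity(self, tiny_study):
        spec = ReferenceDateSpec(table="DM", variable="RFSTDTC")
        out = td.apply_study_days(tiny_study, spec, {})
        assert out.equals(tiny_study)

    def test_no_residual_iso_dates(self, gen_study_50):
        study, _ = gen_study_50
        spec = ReferenceDateSpec(table="DM", variable="RFSTDTC")
        targets = {
            "DM": ["RFSTDTC"], "AE": ["AESTDTC", "AEENDTC"],
            "VS": ["VSDTC"], "LB": ["LBDTC"], "DS": ["DSSTDTC"],
        }
        out = td.apply_study_days(study, spec, targets)
        for tname, variables in targets.items():
            for var in variables:
                new = var[:-3] + "DY"
                assert var not in out.tables[tname].variables
                hits = [v for v in out.tables[tname].values(new)
                        if parse_iso_date(v) is not None]
                assert hits == []

    def test_partial_date_policies(self, tiny_study):
        study = tiny_study.copy()
        vals = study.tables["AE"].values("AESTDTC")
        vals[1] = "2020-01"  # partial
        study.tables["AE"].df["AESTDTC"] = vals
        spec = ReferenceDateSpec(table="DM", variable="RFSTDTC")

        log = []
        out = td.apply_study_days(study, spec, {"AE": ["AESTDTC"]},
                                  partial_policy="none", log=log)
        assert out.tables["AE"].values("AESTDY")[1] == ""
        assert log[0]["dropped_values"] == 1

        out = td.apply_study_days(study, spec, {"AE": ["AESTDTC"]},
                                  partial_policy="month-midpoint")
        # imputed to 2020-01-15; P002 reference 2020-02-01 -> -17
        assert out.tables["AE"].values("AESTDY")[1] == "-17"

    def test_missing_reference_error_policy(self, tiny_study):
        study = tiny_study.copy()
        vals = study.tables["DM"].values("RFSTDTC")
        vals[0] = ""
        study.tables["DM"].df["RFSTDTC"] = vals
        spec = ReferenceDateSpec(table="DM", variable="RFSTDTC", fallback="error")
        with pytest.raises(td.StudyError, match="reference"):
            td.apply_study_days(study, spec, {"AE": ["AESTDTC"]})
        spec = ReferenceDateSpec(table="DM", variable="RFSTDTC",
                                 fallback="drop-subject-dates")
        out = td.apply_study_days(study, spec, {"AE": ["AESTDTC"]})
        assert out.tables["AE"].values("AESTDY")[0] == ""  # P001 blanked


class TestOffsetDates:
    def test_shift_preserves_intervals(self, tiny_study):
        out, plan = td.offset_dates(
            tiny_study, seed=4, bounds=(-30, 30), date_variables={"AE": ["AESTDTC"]}
        )
        k = plan.offsets["P002"]
        orig = [parse_iso_date(v) for s, v in
                zip(tiny_study.tables["AE"].values("SUBJID"),
                    tiny_study.tables["AE"].values("AESTDTC")) if s == "P002"]
        new = [parse_iso_date(v) for s, v in
               zip(out.tables["AE"].values("SUBJID"),
                   out.tables["AE"].values("AESTDTC")) if s == "P002"]
        assert all((n - o).days == k for o, n in zip(orig, new))
        assert (new[1] - new[0]) == (orig[1] - orig[0])

    def test_deterministic_given_seed(self, gen_study_50):
        study, _ = gen_study_50
        targets = {"AE": ["AESTDTC", "AEENDTC"], "VS": ["VSDTC"]}
        _, p1 = td.offset_dates(study, 9, (-30, 30), targets)
        _, p2 = td.offset_dates(study, 9, (-30, 30), targets)
        assert p1.offsets == p2.offsets

    def test_nonzero_offsets_by_default(self, gen_study_50):
        study, _ = gen_study_50
        _, plan = td.offset_dates(study, 2, (-3, 3), {"VS": ["VSDTC"]})
        assert all(k != 0 for k in plan.offsets.values())

    def test_constrained_offsets_stay_in_trial_range(self):
        gen_study, _ = td.generate_study(100, 5, seed=8)
        targets = {"AE": ["AESTDTC", "AEENDTC"], "VS": ["VSDTC"], "LB": ["LBDTC"],
                   "DS": ["DSSTDTC"], "DM": ["RFSTDTC"]}
        all_orig = [parse_iso_date(v)
                    for t, vs in targets.items() for var in vs
                    for v in gen_study.tables[t].values(var) if parse_iso_date(v)]
        lo, hi = min(all_orig), max(all_orig)
        out, plan = td.offset_dates(
            gen_study, 13, (-30, 30), targets, constrain_to_trial_range=True,
            ref=ReferenceDateSpec(table="DM", variable="RFSTDTC"),
        )
        shifted_ok = 0
        for t, vs in targets.items():
            for var in vs:
                for subj, v in zip(out.tables[t].values("SUBJID"),
                                   out.tables[t].values(var)):
                    d = parse_iso_date(v)
                    if d is None:
                        continue
                    if subj in plan.offsets:
                        assert lo <= d <= hi
                        shifted_ok += 1
        assert shifted_ok > 0
        # every subject is either shifted within range or logged as fallback
        assert set(plan.offsets) | set(plan.fallback_subjects) >= {
            s for s in gen_study.subjects
        }

    def test_infeasible_bounds_error(self, tiny_study):
        with pytest.raises(td.StudyError, match="empty"):
            td.offset_dates(tiny_study, 1, (5, -5), {"AE": ["AESTDTC"]})


class TestRetainSeason:
    @pytest.mark.parametrize(
        "value,granularity,expected",
        [
            ("2020-07-14", "month", "7"),
            ("2020-07-14", "season", "JJA"),
            ("2020-12-01", "season", "DJF"),
            ("2020-07", "month", "7"),  # month recoverable from partial date
        ],
    )
    def test_derivation(self, tiny_study, value, granularity, expected):
        study = tiny_study.copy()
        vals = study.tables["AE"].values("AESTDTC")
        vals[0] = value
        study.tables["AE"].df["AESTDTC"] = vals
        out = td.retain_season(study, "AE", "AESTDTC", granularity)
        derived = f"AESTDTC_{granularity.upper()}"
        assert out.tables["AE"].values(derived)[0] == expected
        assert out.tables["AE"].values("AESTDTC")[0] == value  # raw date untouched

    def test_unknown_variable_error(self, tiny_study):
        with pytest.raises(td.StudyError):
            td.retain_season(tiny_study, "AE", "NOPE", "month")
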