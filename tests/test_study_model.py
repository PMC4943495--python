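"""Data model: lossless CSV round trips, invariants, structural diff."""

import pandas as pd
import pytest

import trialdeid as td
from trialdeid.study import is_partial_date, parse_iso_date

from conftest import make_study


def _write_csvs(tmp_path, files):
    paths = []
    for name, text in files.items():
        p = tmp_path / f"{name}.csv"
        p.write_text(text, "utf-8")
        paths.append(p)
    return paths


class TestReadStudy:
    def test_two_domains(self, tmp_path):
        paths = _write_csvs(
            tmp_path,
            {
                "DM": "SUBJID,BRTHDTC,SEX\nP001,1950-06-15,F\nP002,1980-01-01,M\n",
                "AE": "SUBJID,AESTDTC,AETERM\nP001,2020-01-20,headache\n",
            },
        )
        study = td.read_study(paths, {"subject_key": "SUBJID"})
        assert set(study.tables) == {"DM", "AE"}
        assert study.subject_key == "SUBJID"
        assert study.tables["DM"].n_records == 2

    def test_header_only_file(self, tmp_path):
        paths = _write_csvs(
            tmp_path,
            {"DM": "SUBJID,SEX\nP001,F\n", "AE": "SUBJID,AESTDTC,AETERM\n"},
        )
        study = td.read_study(paths, {"subject_key": "SUBJID"})
        assert study.tables["AE"].n_records == 0
        assert len(study.tables["AE"].variables) == 3

    def test_invalid_date_kept_as_text_with_warning(self, tmp_path):
        paths = _write_csvs(
            tmp_path, {"DM": "SUBJID,BRTHDTC\nP001,2010-02-30\nP002,2010-02-28\n"}
        )
        warnings_out = []
        study = td.read_study(
            paths,
            {"subject_key": "SUBJID",
             "domains": {"DM": {"kinds": {"BRTHDTC": "calendar-date"}}}},
            warnings_out=warnings_out,
        )
        # independent calendar-validity check over every loaded cell
        bad = [
            (v, val)
            for v in study.tables["DM"].variables
            if study.tables["DM"].kinds[v] == "calendar-date"
            for val in study.tables["DM"].values(v)
            if val and parse_iso_date(val) is None
        ]
        assert study.tables["DM"].values("BRTHDTC") == ["2010-02-30", "2010-02-28"]
        assert len(warnings_out) == len(bad) == 1
        assert "2010-02-30" in warnings_out[0]

    def test_missing_subject_key_is_hard_error(self, tmp_path):
        paths = _write_csvs(tmp_path, {"DM": "ID,SEX\nP001,F\n"})
        with pytest.raises(td.StudyError, match="DM"):
            td.read_study(paths, {"subject_key": "SUBJID"})

    def test_orphan_subject_in_event_table(self, tmp_path):
        paths = _write_csvs(
            tmp_path,
            {"DM": "SUBJID\nP001\n", "AE": "SUBJID,AETERM\nP999,headache\n"},
        )
        with pytest.raises(td.StudyError, match="P999"):
            td.read_study(paths, {"subject_key": "SUBJID"})


class TestWriteStudy:
    def test_round_trip_identity(self, tiny_study, tmp_path):
        paths = td.write_study(tiny_study, tmp_path)
        again = td.read_study(paths, {"subject_key": "SUBJID"})
        assert tiny_study.equals(again)

    def test_quoting_preserved(self, tmp_path):
        study = make_study(
            [{"SUBJID": "P001", "NOTE": 'contains, a comma and a "quote"'}],
            reference=None,
        )
        paths = td.write_study(study, tmp_path)
        again = td.read_study(paths, {"subject_key": "SUBJID"})
        assert again.tables["DM"].values("NOTE") == ['contains, a comma and a "quote"']

    def test_zero_record_table_writes_header(self, tmp_path):
        study = make_study(
            [{"SUBJID": "P001"}],
            ae_rows=pd.DataFrame(columns=["SUBJID", "AETERM"]).to_dict("records"),
            reference=None,
        )
        study.tables["AE"] = td.Table("AE", pd.DataFrame(columns=["SUBJID", "AETERM"]))
        td.write_study(study, tmp_path)
        assert (tmp_path / "AE.csv").read_text().strip() == "SUBJID,AETERM"

    def test_refuses_overwrite(self, tiny_study, tmp_path):
        td.write_study(tiny_study, tmp_path)
        with pytest.raises(td.StudyError, match="overwrite"):
            td.write_study(tiny_study, tmp_path)

    def test_generated_study_round_trips(self, gen_study_50, tmp_path):
        study, _ = gen_study_50
        paths = td.write_study(study, tmp_path)
        again = td.read_study(paths, {"subject_key": "SUBJID", "site_key": "SITEID"})
        assert study.equals(again)


class TestDiffStudies:
    def test_identical_studies_empty_diff(self, tiny_study):
        assert td.diff_studies(tiny_study, tiny_study.copy()) == []

    def test_removed_variable(self, tiny_study):
        after = tiny_study.copy()
        after.tables["DM"].df.drop(columns=["BRTHDTC"], inplace=True)
        assert td.diff_studies(tiny_study, after) == [
            td.ChangeRecord("DM", "BRTHDTC", "removed")
        ]

    def test_value_change_matches_cellwise_oracle(self, tiny_study):
        after = tiny_study.copy()
        mapping = {"P001": "X1", "P002": "X2", "P003": "X3"}
        for tab in after.tables.values():
            tab.df["SUBJID"] = [mapping[v] for v in tab.values("SUBJID")]
        diff = td.diff_studies(tiny_study, after)
        # oracle: cell-by-cell comparison loop over every shared variable
        expected = set()
        for name in tiny_study.tables:
            b, a = tiny_study.tables[name], after.tables[name]
            for var in b.variables:
                if any(x != y for x, y in zip(b.values(var), a.values(var))):
                    expected.add((name, var))
        assert {(c.table, c.variable) for c in diff} == expected
        assert all(c.kind == "unchanged-values-differ" for c in diff)

    def test_mismatched_domains_error(self, tiny_study):
        after = tiny_study.copy()
        del after.tables["AE"]
        with pytest.raises(td.StudyError, match="AE"):
            td.diff_studies(tiny_study, after)

    @pytest.mark.parametrize("mutation", ["remove", "add", "edit"])
    def test_single_mutation_yields_single_entry(self, tiny_study, mutation):
        after = tiny_study.copy()
        if mutation == "remove":
            after.tables["AE"].df.drop(columns=["AETERM"], inplace=True)
            target = ("AE", "AETERM")
        elif mutation == "add":
            after.tables["AE"].df["NEW"] = ""
            target = ("AE", "NEW")
        else:
            vals = after.tables["AE"].values("AETERM")
            vals[1] = "changed"
            after.tables["AE"].df["AETERM"] = vals
            target = ("AE", "AETERM")
        diff = td.diff_studies(tiny_study, after)
        assert len(diff) == 1 and (diff[0].table, diff[0].variable) == target


def test_partial_date_recognition():
    assert is_partial_date("2020") and is_partial_date("2020-07")
    assert not is_partial_date("2020-13")  # impossible month
    assert not is_partial_date("2020-07-14")  # complete date, not partial
    assert parse_iso_date("2020-07-14") is not None
    assert parse_iso_date("2020-02-30") is None
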