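"""Equivalence classes, k-anonymity and small-cell flags vs brute force."""

import itertools

import pandas as pd
import pytest

import trialdeid as td

from conftest import make_study


def _qi_study(tuples):
    """Subjects with given (ageband, sex) attribute pairs."""
    rows = [
        {"SUBJID": f"P{i}", "AGEBAND": a, "SEX": s} for i, (a, s) in enumerate(tuples)
    ]
    return make_study(rows, reference=None)


def brute_force_classes(study, variables):
    """Independent oracle: plain group-by loop over subject tuples."""
    dm = study.tables["DM"]
    groups = {}
    for i, subj in enumerate(dm.values("SUBJID")):
        key = tuple(dm.values(v)[i] if dm.values(v)[i] != "" else "<missing>"
                    for v in variables)
        groups.setdefault(key, []).append(subj)
    return sorted(len(g) for g in groups.values())


class TestEquivalenceClasses:
    def test_worked_example(self):
        study = _qi_study([("A", "M"), ("A", "M"), ("A", "F"), ("B", "M"), ("B", "M")])
        qi = td.QuasiIdentifierSet([("DM", "AGEBAND"), ("DM", "SEX")])
        assert td.equivalence_classes(study, qi) == [1, 2, 2]

    def test_empty_qi_is_vacuous_partition(self):
        study = _qi_study([("A", "M")] * 5)
        assert td.equivalence_classes(study, td.QuasiIdentifierSet([])) == [5]

    def test_constant_attributes_single_class(self):
        study = _qi_study([("A", "M")] * 7)
        qi = td.QuasiIdentifierSet([("DM", "AGEBAND"), ("DM", "SEX")])
        assert td.equivalence_classes(study, qi) == [7]

    def test_missing_is_its_own_category(self):
        study = _qi_study([("A", "M"), ("", "M"), ("", "M")])
        qi = td.QuasiIdentifierSet([("DM", "AGEBAND")])
        assert td.equivalence_classes(study, qi) == [1, 2]

    def test_event_level_variable_without_reduction_errors(self, tiny_study):
        qi = td.QuasiIdentifierSet([("AE", "AETERM")])
        with pytest.raises(td.StudyError, match="reduction|event-level"):
            td.equivalence_classes(tiny_study, qi)

    def test_conservation_and_agreement_with_oracle_random_studies(self):
        """Agreement with the brute-force group-by on 200 random studies."""
        import numpy as np

        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(1, 201))
            rows = [
                {
                    "SUBJID": f"P{i}",
                    "A": str(rng.integers(0, 4)),
                    "B": str(rng.integers(0, 3)),
                    "C": str(rng.integers(0, 2)),
                }
                for i in range(n)
            ]
            study = make_study(rows, reference=None)
            for k in (1, 2, 3):
                variables = ["A", "B", "C"][:k]
                qi = td.QuasiIdentifierSet([("DM", v) for v in variables])
                sizes = td.equivalence_classes(study, qi)
                assert sizes == brute_force_classes(study, variables)
                assert sum(sizes) == n
                assert td.k_anonymity(study, qi) == min(sizes)


class TestKAnonymity:
    def test_min_of_class_sizes(self):
        study = _qi_study([("A", "M"), ("A", "M"), ("A", "F"), ("B", "M"), ("B", "M")])
        qi = td.QuasiIdentifierSet([("DM", "AGEBAND"), ("DM", "SEX")])
        assert td.k_anonymity(study, qi) == 1

    def test_single_subject(self):
        study = _qi_study([("A", "M")])
        assert td.k_anonymity(study, td.QuasiIdentifierSet([("DM", "SEX")])) == 1

    def test_refinement_never_increases_k(self):
        import numpy as np

        rng = np.random.default_rng(29)
        for trial in range(30):
            n = int(rng.integers(2, 120))
            rows = [
                {"SUBJID": f"P{i}", "A": str(rng.integers(0, 3)),
                 "B": str(rng.integers(0, 3))}
                for i in range(n)
            ]
            study = make_study(rows, reference=None)
            k1 = td.k_anonymity(study, td.QuasiIdentifierSet([("DM", "A")]))
            k2 = td.k_anonymity(
                study, td.QuasiIdentifierSet([("DM", "A"), ("DM", "B")])
            )
            assert k2 <= k1

    def test_zero_subjects_error(self):
        study = td.Study(
            {"DM": td.Table("DM", pd.DataFrame(columns=["SUBJID"]))},
            subject_key="SUBJID",
        )
        with pytest.raises(td.StudyError):
            td.k_anonymity(study, td.QuasiIdentifierSet([]))


class TestFlagSmallCells:
    def _events_study(self, n_subjects, term_counts):
        dm = [{"SUBJID": f"P{i}", "SEX": "F"} for i in range(n_subjects)]
        ae, i = [], 0
        for term, count in term_counts.items():
            for j in range(count):
                ae.append({"SUBJID": f"P{j}", "AEDECOD": term})
        return make_study(dm, ae, reference=None)

    def test_denominator_boundary(self):
        study = self._events_study(99, {})
        qi = td.QuasiIdentifierSet([("DM", "SEX")])
        flags = td.flag_small_cells(study, qi)
        assert [f.kind for f in flags] == ["denominator"]
        assert flags[0].observed == 99 and flags[0].threshold == 100

        study = self._events_study(100, {})
        assert td.flag_small_cells(study, qi) == []

    @pytest.mark.parametrize("count,flagged", [(1, True), (2, True), (3, False)])
    def test_numerator_boundary(self, count, flagged):
        study = self._events_study(200, {"Stevens-Johnson syndrome": count})
        qi = td.QuasiIdentifierSet([])
        flags = td.flag_small_cells(study, qi, [("AE", "AEDECOD")])
        numer = [f for f in flags if f.kind == "numerator"]
        assert bool(numer) == flagged
        if flagged:
            assert numer[0].observed == count

    def test_numerator_counts_subjects_not_rows(self):
        dm = [{"SUBJID": f"P{i}", "SEX": "F"} for i in range(150)]
        ae = [{"SUBJID": "P0", "AEDECOD": "Rash"}] * 5  # 5 rows, 1 subject
        study = make_study(dm, ae, reference=None)
        flags = td.flag_small_cells(
            study, td.QuasiIdentifierSet([]), [("AE", "AEDECOD")]
        )
        numer = [f for f in flags if f.kind == "numerator"]
        assert len(numer) == 1 and numer[0].observed == 1

    def test_threshold_one_flags_nothing(self):
        study = self._events_study(10, {"Rash": 2})
        flags = td.flag_small_cells(
            study, td.QuasiIdentifierSet([("DM", "SEX")]), [("AE", "AEDECOD")],
            denom_threshold=1, numer_threshold=1,
        )
        assert flags == []

    def test_threshold_above_n_flags_every_category(self):
        study = _qi_study([("A", "M"), ("A", "F"), ("B", "M")])
        qi = td.QuasiIdentifierSet([("DM", "AGEBAND"), ("DM", "SEX")])
        flags = td.flag_small_cells(study, qi, denom_threshold=4)
        assert len(flags) == 3  # every combination is below n+1


def test_risk_report_invariants(gen_study_50):
    study, _ = gen_study_50
    qi = td.QuasiIdentifierSet([("DM", "SEX"), ("DM", "SITEID")])
    report = td.build_risk_report(study, qi, [("AE", "AEDECOD")])
    assert sum(report.class_sizes) == report.n_subjects == 50
    assert report.k == min(report.class_sizes)
    assert report.uniques == sum(1 for s in report.class_sizes if s == 1)
    d = report.to_dict()
    assert d["k_anonymity"] == report.k
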