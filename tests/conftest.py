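import pandas as pd
import pytest

import trialdeid as td


def make_study(dm_rows, ae_rows=None, site_key=None, reference=("DM", "RFSTDTC")):
    """Build a small two-domain study from row dicts."""
    tables = {"DM": td.Table("DM", pd.DataFrame(dm_rows))}
    if ae_rows is not None:
        tables["AE"] = td.Table("AE", pd.DataFrame(ae_rows))
    ref = reference if reference and reference[1] in tables["DM"].variables else None
    study = td.Study(
        tables=tables,
        subject_key="SUBJID",
        subject_table="DM",
        site_key=site_key,
        reference_date=ref,
    )
    study.validate()
    return study


@pytest.fixture
def tiny_study():
    dm = [
        {"SUBJID": "P001", "BRTHDTC": "1950-06-15", "SEX": "F", "RFSTDTC": "2020-01-10"},
        {"SUBJID": "P002", "BRTHDTC": "1980-01-01", "SEX": "M", "RFSTDTC": "2020-02-01"},
        {"SUBJID": "P003", "BRTHDTC": "1995-12-31", "SEX": "F", "RFSTDTC": "2020-03-05"},
    ]
    ae = [
        {"SUBJID": "P001", "AESTDTC": "2020-01-20", "AETERM": "mild headache",
         "AEDECOD": "Headache"},
        {"SUBJID": "P002", "AESTDTC": "2020-01-28", "AETERM": "nausea after dosing",
         "AEDECOD": "Nausea"},
        {"SUBJID": "P002", "AESTDTC": "2020-02-15", "AETERM": "dizzy spells",
         "AEDECOD": "Dizziness"},
    ]
    return make_study(dm, ae)


@pytest.fixture(scope="session")
def gen_study_50():
    """One 50-subject generated trial shared across tests (read-only)."""
    return td.generate_study(50, 5, seed=11)


@pytest.fixture(scope="session")
def gen_study_500():
    """Larger fixture for the statistical property checks."""
    return td.generate_study(500, 12, seed=23)
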