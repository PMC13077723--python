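import pandas as pd
import pytest

import faersig as fs
from faersig import faers_io

TARGET_SYNONYMS = ("TORADOL", "KETOROLAC", "KETOROLAC TROMETHAMINE")


@pytest.fixture(scope="session")
def small_config():
    return fs.GeneratorConfig(
        n_reports=1000, seed=7, duplicate_fraction=0.2,
        injected_signals=(fs.SignalSpec(0, 0, 10.0),))


@pytest.fixture(scope="session")
def small_set(small_config):
    return fs.generate_reports(small_config)


@pytest.fixture(scope="session")
def quarter_dir(small_set, tmp_path_factory):
    d = tmp_path_factory.mktemp("quarter")
    fs.write_faers_ascii(small_set, d, "17Q4")
    return d


@pytest.fixture(scope="session")
def ingested_cases(quarter_dir):
    return fs.build_cases(fs.read_quarter(quarter_dir))


def cases_in_memory(report_set) -> faers_io.CaseData:
    """Run typing + dedup on a generated set without touching disk."""
    raw = faers_io.RawTables(**{k.lower(): v for k, v in report_set.raw.items()})
    return faers_io.build_cases(raw)


def make_case_data(case_specs) -> faers_io.CaseData:
    """Tiny hand-built CaseData: [(pid, [(drugname, role)], [pts]), ...]."""
    demo = pd.DataFrame({
        "caseid": [pid for pid, _, _ in case_specs],
        "caseversion": 1,
        "fda_dt": pd.Timestamp("2017-01-01"),
        "event_dt": pd.Timestamp("2017-01-01"),
        "sex": "F", "age_yr": 50.0, "weight_kg": 70.0,
        "reporter": "consumer", "country": "US", "tto_days": 0,
    }, index=pd.Index([pid for pid, _, _ in case_specs], name="primaryid"))
    drugs = pd.DataFrame(
        [(pid, i + 1, role, name, "ORAL")
         for pid, dr, _ in case_specs for i, (name, role) in enumerate(dr)],
        columns=["primaryid", "drug_seq", "role_cod", "drugname", "route"])
    reac = pd.DataFrame(
        [(pid, pt) for pid, _, pts in case_specs for pt in pts],
        columns=["primaryid", "pt"])
    empty = pd.DataFrame(columns=["primaryid"])
    return faers_io.CaseData(demo=demo, drugs=drugs, reactions=reac,
                             outcomes=empty.assign(outcome=None), ther=empty)
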