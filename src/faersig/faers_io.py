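"""Ingestion of FAERS-style quarterly ASCII tables.

Covers the standard spontaneous-report preprocessing workflow: parse the
$-delimited DEMO/DRUG/REAC/OUTC/RPSR/THER files, collapse case versions to
one record per case, classify drug roles, normalize ages and weights, and
attach time-to-onset.  The missing token is the empty field.

Deduplication keeps, per ``caseid``, the row maximizing
``(caseversion, fda_dt, primaryid)`` lexicographically — i.e. the latest
submitted version, ties broken by the latest receipt date and then the
largest primaryid — which is the common practice for FAERS case-version
collapse.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IngestionError, ParseError

log = logging.getLogger(__name__)

FILE_PREFIXES = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER")

#: age-unit code -> factor converting to years
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
}

WEIGHT_UNIT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}

OCCP_LABELS = {
    "CN": "consumer",
    "MD": "physician",
    "OT": "other health professional",
    "PH": "pharmacist",
    "LW": "lawyer",
    "RN": "registered nurse",
}

OUTCOME_LABELS = {
    "HO": "hospitalization",
    "OT": "other serious",
    "LT": "life threatening",
    "DE": "death",
    "DS": "disability",
    "RI": "required intervention",
    "CA": "congenital anomaly",
}

ROLE_CODES = ("PS", "SS", "C", "I")


@dataclass
class RawTables:
    """String-valued quarterly tables, one DataFrame per file prefix."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    ther: pd.DataFrame
    malformed: dict[str, list[int]] = field(default_factory=dict)

    def __getitem__(self, prefix: str) -> pd.DataFrame:
        return getattr(self, prefix.lower())


@dataclass
class CaseData:
    """Deduplicated cases with their drug, reaction, outcome and therapy rows.

    ``demo`` has one row per case (index ``primaryid``) with typed columns:
    caseid, caseversion, fda_dt, event_dt, sex, age_yr, weight_kg,
    reporter, country, tto_days.  The long tables are restricted to the
    retained primaryids; reaction PTs are unique within a case.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    ther: pd.DataFrame
    n_raw_demo_rows: int = 0
    n_versions_dropped: int = 0
    n_implausible_tto: int = 0

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    def subset(self, primaryids: pd.Index) -> "CaseData":
        keep = self.demo.index.isin(primaryids)
        demo = self.demo.loc[keep]
        sel = lambda t: t.loc[t["primaryid"].isin(demo.index)]  # noqa: E731
        return CaseData(demo=demo, drugs=sel(self.drugs),
                        reactions=sel(self.reactions), outcomes=sel(self.outcomes),
                        ther=sel(self.ther),
                        n_raw_demo_rows=self.n_raw_demo_rows,
                        n_versions_dropped=self.n_versions_dropped,
                        n_implausible_tto=self.n_implausible_tto)

    def to_csv(self, path) -> None:
        """Audit export of the per-case table."""
        out = self.demo.copy()
        for col in ("fda_dt", "event_dt"):
            out[col] = out[col].dt.strftime("%Y%m%d")
        out.to_csv(path, lineterminator="\n")


def _read_dollar_file(path: Path, tolerance: float) -> tuple[pd.DataFrame, list[int]]:
    """Parse one $-delimited file; returns (frame, malformed row numbers)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        nfields = len(header)
        rows, bad = [], []
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != nfields:
                bad.append(lineno)
            else:
                rows.append(rec)
    total = len(rows) + len(bad)
    if bad:
        log.warning("%s: %d of %d rows malformed (e.g. line %d)",
                    path.name, len(bad), total, bad[0])
    if total and len(bad) / total > tolerance:
        raise ParseError(
            f"{path}: {len(bad)}/{total} malformed rows exceeds tolerance "
            f"{tolerance:.2%}; first offending lines {bad[:10]}")
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    return frame, bad


def read_quarter(directory, tolerance: float = 0.01) -> RawTables:
    """Read one quarter's DEMO/DRUG/REAC/OUTC/RPSR/THER files.

    Files are located by prefix (``DEMO*.txt`` etc.); a missing file is an
    ingestion error.  Rows with the wrong field count are logged and
    skipped; parsing fails if their fraction exceeds ``tolerance``.
    """
    directory = Path(directory)
    frames, malformed = {}, {}
    for prefix in FILE_PREFIXES:
        matches = sorted(directory.glob(f"{prefix}*.txt"))
        if not matches:
            raise IngestionError(f"no {prefix}*.txt file found in {directory}")
        parts = []
        for path in matches:
            frame, bad = _read_dollar_file(path, tolerance)
            parts.append(frame)
            if bad:
                malformed.setdefault(prefix, []).extend(bad)
        frames[prefix.lower()] = pd.concat(parts, ignore_index=True)
    return RawTables(**frames, malformed=malformed)


def _num(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def _date(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="%Y%m%d", errors="coerce")


def normalize_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Convert (value, unit-code) ages to years; unparseable -> missing."""
    factor = age_cod.str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    return _num(age) * factor


def normalize_weight_kg(wt: pd.Series, wt_cod: pd.Series) -> pd.Series:
    factor = wt_cod.str.strip().str.upper().map(WEIGHT_UNIT_TO_KG)
    return _num(wt) * factor


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse case versions: one row per caseid.

    The retained row maximizes (caseversion, fda_dt, primaryid)
    lexicographically.  Returns (deduplicated frame sorted by caseid,
    number of versions dropped).  Accepts either raw string-valued or
    typed frames; requires caseid, caseversion, fda_dt columns and
    primaryid as column or index.
    """
    if demo.empty:
        return demo.copy(), 0
    work = demo.reset_index() if "primaryid" not in demo.columns else demo.copy()
    order = work.assign(
        _ver=_num(work["caseversion"]),
        _dt=_date(work["fda_dt"]) if work["fda_dt"].dtype == object else work["fda_dt"],
    ).sort_values(["caseid", "_ver", "_dt", "primaryid"], kind="mergesort",
                  na_position="first")
    kept = order.drop_duplicates(subset="caseid", keep="last")
    kept = kept.drop(columns=["_ver", "_dt"]).sort_values("caseid", kind="mergesort")
    return kept.reset_index(drop=True), len(demo) - len(kept)


def compute_tto(therapy_start, event_date):
    """Days from therapy start to event onset; missing if undeterminable.

    Negative intervals (event before therapy start) are implausible and
    reported as missing rather than clamped to zero, so they cannot
    inflate the earliest onset bucket.
    """
    start = pd.to_datetime(therapy_start, format="%Y%m%d", errors="coerce")
    event = pd.to_datetime(event_date, format="%Y%m%d", errors="coerce")
    if pd.isna(start) or pd.isna(event):
        return None
    days = (event - start).days
    return None if days < 0 else int(days)


def _tto_series(ther: pd.DataFrame, event_dt: pd.Series) -> tuple[pd.Series, int]:
    """Vectorized time-to-onset per case (earliest therapy start)."""
    start = _date(ther["start_dt"]).groupby(ther["primaryid"]).min()
    start = start.reindex(event_dt.index)
    days = (event_dt - start).dt.days
    implausible = int((days < 0).sum())
    if implausible:
        log.warning("%d cases with event date before therapy start; "
                    "time-to-onset set to missing", implausible)
    return days.where(days >= 0), implausible


def build_cases(raw: RawTables) -> CaseData:
    """Type, deduplicate and assemble one ReportCase record per caseid."""
    demo = raw.demo.copy()
    n_raw = len(demo)
    demo["caseversion"] = _num(demo["caseversion"]).fillna(1).astype(int)
    kept, dropped = deduplicate(demo)
    kept = kept.set_index("primaryid")

    typed = pd.DataFrame(index=kept.index)
    typed["caseid"] = kept["caseid"]
    typed["caseversion"] = kept["caseversion"]
    typed["fda_dt"] = _date(kept["fda_dt"])
    typed["event_dt"] = _date(kept.get("event_dt", pd.Series("", index=kept.index)))
    typed["sex"] = kept["sex"].where(kept["sex"].isin(["F", "M"]))
    typed["age_yr"] = normalize_age_years(kept["age"], kept["age_cod"])
    typed["weight_kg"] = normalize_weight_kg(kept["wt"], kept["wt_cod"])
    typed["reporter"] = kept["occp_cod"].str.strip().str.upper().map(OCCP_LABELS)
    typed["country"] = kept["reporter_country"].replace("", np.nan)

    ids = typed.index
    drugs = raw.drug.loc[raw.drug["primaryid"].isin(ids)].copy()
    drugs["role_cod"] = drugs["role_cod"].str.strip().str.upper()
    unknown_roles = ~drugs["role_cod"].isin(ROLE_CODES)
    if unknown_roles.any():
        log.warning("%d drug rows with unknown role code dropped",
                    int(unknown_roles.sum()))
        drugs = drugs.loc[~unknown_roles]
    drugs["drug_seq"] = _num(drugs["drug_seq"])

    reac = raw.reac.loc[raw.reac["primaryid"].isin(ids)].copy()
    reac["pt"] = reac["pt"].str.strip()
    reac = reac.loc[reac["pt"] != ""].drop_duplicates(subset=["primaryid", "pt"])

    outc = raw.outc.loc[raw.outc["primaryid"].isin(ids)].copy()
    outc["outcome"] = outc["outc_cod"].str.strip().str.upper().map(OUTCOME_LABELS)
    outc = outc.dropna(subset=["outcome"]).drop_duplicates(
        subset=["primaryid", "outcome"])

    ther = raw.ther.loc[raw.ther["primaryid"].isin(ids)].copy()
    tto, implausible = _tto_series(ther, typed["event_dt"])
    typed["tto_days"] = tto

    return CaseData(demo=typed.sort_index(), drugs=drugs.reset_index(drop=True),
                    reactions=reac.reset_index(drop=True),
                    outcomes=outc.reset_index(drop=True),
                    ther=ther.reset_index(drop=True),
                    n_raw_demo_rows=n_raw, n_versions_dropped=dropped,
                    n_implausible_tto=implausible)


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim, collapse inner whitespace."""
    return " ".join(str(name).upper().split())


def filter_primary_suspect(cases: CaseData, drug_synonyms) -> CaseData:
    """Cases with >=1 primary-suspect drug row matching the synonym set.

    Matching is exact on normalized names (no fuzzy matching), which keeps
    the inclusion rule fully reproducible.
    """
    synonyms = {normalize_drug_name(s) for s in drug_synonyms}
    synonyms.discard("")
    if not synonyms:
        raise ConfigurationError("drug synonym set must be non-empty")
    d = cases.drugs
    hit = d.loc[(d["role_cod"] == "PS")
                & d["drugname"].map(normalize_drug_name).isin(synonyms),
                "primaryid"]
    return cases.subset(pd.Index(hit.unique()))
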