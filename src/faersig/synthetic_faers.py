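"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of FAERS quarterly data: one demographic row per
case *version*, multiple drug rows with role codes (PS/SS/C/I), multiple
MedDRA preferred-term reaction rows, outcome codes, reporter occupations
and therapy dates.  Drug–event associations of known relative risk can be
injected, together with duplicate case versions and field-level
missingness, so that every downstream stage (ingestion, deduplication,
primary-suspect filtering, contingency building, disproportionality
statistics) can be tested against an exact generative ledger.

The generative model for reactions is one independent Bernoulli draw per
(report, event): event ``e`` occurs with probability ``base_rate[e]``,
multiplied by ``relative_risk`` when the report's primary-suspect drug is
the paired drug of an injected signal (capped at 1).  Reports with no
event are redrawn, i.e. the emitted set is the model conditioned on at
least one reaction per case.  This keeps the marginal odds ratio of an
injected pair available in closed form (:func:`analytic_odds_ratio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LookupError_

ROLE_CODES = ("PS", "SS", "C", "I")

OCCP_CODES = {
    "consumer": "CN",
    "physician": "MD",
    "other health professional": "OT",
    "pharmacist": "PH",
    "lawyer": "LW",
    "registered nurse": "RN",
}

OUTCOME_CODES = {
    "hospitalization": "HO",
    "other serious": "OT",
    "life threatening": "LT",
    "death": "DE",
    "disability": "DS",
    "required intervention": "RI",
    "congenital anomaly": "CA",
}

#: Non-US country codes sampled for the "Other" reporting-country class.
_OTHER_COUNTRIES = ("GB", "CA", "JP", "FR", "DE", "AU")

# Default categorical marginals. These follow the profile of a published
# ketorolac (Toradol) spontaneous-report case series: mostly female
# reports, a median age near 50, consumer-heavy reporting, US-dominant
# geography, and onset concentrated in the first week of therapy.
_DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"F": 242 / 355, "M": 113 / 355},
    "age_band": {
        "<18": 9 / 260,
        "18-45": 89 / 260,
        "45-65": 88 / 260,
        "65-75": 32 / 260,
        ">=75": 42 / 260,
    },
    "weight_band": {"<60": 27 / 137, "60-80": 55 / 137, ">=80": 55 / 137},
    "reporter": {
        "consumer": 106 / 310,
        "physician": 79 / 310,
        "other health professional": 76 / 310,
        "pharmacist": 45 / 310,
        "lawyer": 3 / 310,
        "registered nurse": 1 / 310,
    },
    "country": {"US": 120 / 154, "OTHER": 34 / 154},
    "route": {
        "OTHER": 176 / 355,
        "INTRAMUSCULAR": 69 / 355,
        "INTRAVENOUS": 65 / 355,
        "ORAL": 45 / 355,
    },
    "outcome": {
        "hospitalization": 143 / 374,
        "other serious": 108 / 374,
        "life threatening": 46 / 374,
        "death": 33 / 374,
        "disability": 24 / 374,
        "required intervention": 19 / 374,
        "congenital anomaly": 1 / 374,
    },
}

_DEFAULT_TTO = {"<7": 144 / 166, "7-28": 12 / 166, "28-60": 5 / 166, ">=60": 5 / 166}

_DEFAULT_MISSINGNESS = {
    "sex": 0.058,
    "age": 0.268,
    "weight": 0.614,
    "reporter": 0.127,
    "country": 0.566,
    "route": 0.058,
    "tto": 0.157,
    "outcome": 0.008,
}

# (low, high) sampling ranges for the age and weight bands.
_AGE_RANGES = {"<18": (1.0, 18.0), "18-45": (18.0, 45.0), "45-65": (45.0, 65.0),
               "65-75": (65.0, 75.0), ">=75": (75.0, 95.0)}
_WT_RANGES = {"<60": (40.0, 60.0), "60-80": (60.0, 80.0), ">=80": (80.0, 120.0)}

# Day weights within the first-week onset band (day 0 dominates: most
# reported reactions start on the day of administration); later bands are
# uniform.
_TTO_WEEK_WEIGHTS = np.array([0.60, 0.10, 0.08, 0.06, 0.06, 0.05, 0.05])

_EPOCH = np.datetime64("2004-01-01")
_EPOCH_DAYS = 5113  # days spanned by 2004-01-01 .. 2017-12-31


@dataclass(frozen=True)
class SignalSpec:
    """One injected drug–event association.

    ``relative_risk`` multiplies the event's base reporting probability in
    reports where ``drug_id`` is the primary-suspect drug (capped at 1).
    """

    drug_id: int
    event_id: int
    relative_risk: float


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic reporting system."""

    n_reports: int = 5000
    n_drugs: int = 25
    n_events: int = 40
    drug_prevalence: float | Sequence[float] = 0.05
    event_base_rate: float | Sequence[float] = 0.04
    injected_signals: Sequence[SignalSpec] = ()
    duplicate_fraction: float = 0.1
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    demographic_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MARGINALS.items()})
    tto_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TTO))
    drug_synonyms: Mapping[int, Sequence[str]] = field(
        default_factory=lambda: {0: ("TORADOL", "KETOROLAC", "KETOROLAC TROMETHAMINE")})
    seed: int = 0

    # -- derived views -------------------------------------------------
    def drug_prevalence_array(self) -> np.ndarray:
        return _as_prob_array(self.drug_prevalence, self.n_drugs, "drug_prevalence")

    def event_base_rate_array(self) -> np.ndarray:
        return _as_prob_array(self.event_base_rate, self.n_events, "event_base_rate")

    def drug_name(self, drug_id: int) -> str:
        """Canonical (first-synonym) name of a drug id."""
        syns = self.drug_synonyms.get(drug_id)
        return syns[0] if syns else f"DRUG{drug_id:03d}"

    def pt_name(self, event_id: int) -> str:
        return f"PT_{event_id:03d}"

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        if self.n_drugs < 1 or self.n_events < 1:
            raise ConfigurationError("n_drugs and n_events must be >= 1")
        prev = self.drug_prevalence_array()
        base = self.event_base_rate_array()
        if prev.sum() <= 0:
            raise ConfigurationError("drug_prevalence must have positive mass")
        if base.sum() <= 0:
            raise ConfigurationError("event_base_rate must have positive mass")
        if not 0 <= self.duplicate_fraction < 1:
            raise ConfigurationError("duplicate_fraction must lie in [0, 1)")
        for name, p in self.missingness.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"missingness[{name!r}] must lie in [0, 1]")
        for spec in self.injected_signals:
            if not 0 <= spec.drug_id < self.n_drugs:
                raise ConfigurationError(f"injected_signals: drug_id {spec.drug_id} out of range")
            if not 0 <= spec.event_id < self.n_events:
                raise ConfigurationError(f"injected_signals: event_id {spec.event_id} out of range")
            if spec.relative_risk < 0:
                raise ConfigurationError("injected_signals: relative_risk must be >= 0")
        for name, marg in {**dict(self.demographic_marginals),
                           "tto": self.tto_distribution}.items():
            total = sum(marg.values())
            if any(p < 0 for p in marg.values()):
                raise ConfigurationError(f"demographic_marginals[{name!r}] has negative mass")
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"demographic_marginals[{name!r}] must sum to 1 (got {total!r})")

    # -- (de)serialization, used by the CLI -----------------------------
    def to_dict(self) -> dict:
        d = {
            "n_reports": self.n_reports,
            "n_drugs": self.n_drugs,
            "n_events": self.n_events,
            "drug_prevalence": _plain(self.drug_prevalence),
            "event_base_rate": _plain(self.event_base_rate),
            "injected_signals": [
                {"drug_id": s.drug_id, "event_id": s.event_id,
                 "relative_risk": s.relative_risk}
                for s in self.injected_signals],
            "duplicate_fraction": self.duplicate_fraction,
            "missingness": dict(self.missingness),
            "demographic_marginals": {k: dict(v) for k, v in self.demographic_marginals.items()},
            "tto_distribution": dict(self.tto_distribution),
            "drug_synonyms": {int(k): list(v) for k, v in self.drug_synonyms.items()},
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "injected_signals" in d:
            d["injected_signals"] = tuple(
                SignalSpec(**s) if isinstance(s, Mapping) else SignalSpec(*s)
                for s in d["injected_signals"])
        if "drug_synonyms" in d:
            d["drug_synonyms"] = {int(k): tuple(v) for k, v in d["drug_synonyms"].items()}
        return cls(**d)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _plain(x):
    return list(np.asarray(x).tolist()) if not np.isscalar(x) else float(x)


def _as_prob_array(x, n: int, name: str) -> np.ndarray:
    arr = np.full(n, float(x)) if np.isscalar(x) else np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise ConfigurationError(f"{name} must be scalar or length {n}")
    if ((arr < 0) | (arr > 1)).any():
        raise ConfigurationError(f"{name} values must lie in [0, 1]")
    return arr


@dataclass
class ReportSet:
    """A generated corpus: ground-truth ledger plus raw FAERS-style tables.

    ``cases`` holds one row per true (pre-duplication) case with the
    unmasked field values; ``raw`` holds the observed $-delimited tables
    (one DEMO row per case *version*, missingness applied) exactly as
    :func:`write_faers_ascii` will serialize them.
    """

    config: GeneratorConfig
    cases: pd.DataFrame        # index caseid; truth, one row per case
    drugs: pd.DataFrame        # caseid, drug_seq, drug_id, role, drugname
    reactions: pd.DataFrame    # caseid, event_id, pt
    versions: pd.DataFrame     # caseid, caseversion, primaryid, fda_dt
    raw: dict[str, pd.DataFrame]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def ps_cases_of(self, drug_id: int) -> pd.Index:
        """caseids whose primary-suspect drug is ``drug_id``."""
        return self.cases.index[self.cases["ps_drug"] == drug_id]


def generate_reports(config: GeneratorConfig) -> ReportSet:
    """Draw a full report set from the generative model. Deterministic per seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_drug, rng_event, rng_demo, rng_date, rng_dup, rng_miss = (
        np.random.default_rng(s) for s in streams)

    n, n_drugs, n_events = config.n_reports, config.n_drugs, config.n_events
    prev = config.drug_prevalence_array()
    base = config.event_base_rate_array()

    # --- drug mentions and roles ---------------------------------------
    mention = rng_drug.random((n, n_drugs)) < prev
    no_drug = ~mention.any(axis=1)
    if no_drug.any():  # every case needs >=1 drug row
        forced = rng_drug.choice(n_drugs, size=int(no_drug.sum()), p=prev / prev.sum())
        mention[np.nonzero(no_drug)[0], forced] = True
    score = rng_drug.random((n, n_drugs))
    score[~mention] = -1.0
    ps = score.argmax(axis=1)  # uniform among mentioned drugs

    # --- reactions ------------------------------------------------------
    p_event = np.broadcast_to(base, (n, n_events)).copy()
    for spec in config.injected_signals:
        rows = ps == spec.drug_id
        p_event[rows, spec.event_id] = min(1.0, spec.relative_risk * base[spec.event_id])
    present = rng_event.random((n, n_events)) < p_event
    for _ in range(10_000):  # condition on >=1 reaction per case
        empty = ~present.any(axis=1)
        if not empty.any():
            break
        idx = np.nonzero(empty)[0]
        present[idx] = rng_event.random((idx.size, n_events)) < p_event[idx]
    else:  # pragma: no cover - prevented by validate()
        raise ConfigurationError("event_base_rate too small to populate reactions")

    # --- demographics ---------------------------------------------------
    marg = config.demographic_marginals
    sex = _cat(rng_demo, marg["sex"], n)
    age_band = _cat(rng_demo, marg["age_band"], n)
    lo, hi = _range_arrays(age_band, _AGE_RANGES)
    age_yr = np.round(lo + rng_demo.random(n) * (hi - lo), 1)
    wt_band = _cat(rng_demo, marg["weight_band"], n)
    lo, hi = _range_arrays(wt_band, _WT_RANGES)
    weight_kg = np.round(lo + rng_demo.random(n) * (hi - lo), 1)
    reporter = _cat(rng_demo, marg["reporter"], n)
    country_cls = _cat(rng_demo, marg["country"], n)
    country = np.where(country_cls == "US", "US",
                       rng_demo.choice(_OTHER_COUNTRIES, size=n))
    route = _cat(rng_demo, marg["route"], n)
    outcome = _cat(rng_demo, marg["outcome"], n)

    tto_band = _cat(rng_demo, config.tto_distribution, n)
    tto = np.zeros(n, dtype=int)
    for band, days in (("<7", None), ("7-28", (7, 28)), ("28-60", (28, 60))):
        m = tto_band == band
        if band == "<7":
            tto[m] = rng_demo.choice(7, size=int(m.sum()), p=_TTO_WEEK_WEIGHTS)
        else:
            tto[m] = rng_demo.integers(days[0], days[1], size=int(m.sum()))
    m = tto_band == ">=60"
    tto[m] = 60 + rng_demo.geometric(0.05, size=int(m.sum())) - 1

    # --- dates and identifiers ------------------------------------------
    fda_offset = rng_date.integers(0, _EPOCH_DAYS + 1, size=n)
    fda_dt = _EPOCH + fda_offset.astype("timedelta64[D]")
    event_dt = fda_dt - rng_date.integers(0, 31, size=n).astype("timedelta64[D]")
    ther_start = event_dt - tto.astype("timedelta64[D]")
    caseid = np.char.add("9", np.char.zfill(np.arange(1, n + 1).astype(str), 7))

    cases = pd.DataFrame({
        "ps_drug": ps, "sex": sex, "age_yr": age_yr, "weight_kg": weight_kg,
        "reporter": reporter, "country": country, "route": route,
        "outcome": outcome, "tto_days": tto,
        "fda_dt": fda_dt, "event_dt": event_dt, "ther_start": ther_start,
    }, index=pd.Index(caseid, name="caseid"))

    # --- long drug / reaction tables ------------------------------------
    row_idx, col_idx = np.nonzero(mention)
    is_ps = col_idx == ps[row_idx]
    roles = np.where(is_ps, "PS",
                     rng_drug.choice(["SS", "C", "I"], size=row_idx.size,
                                     p=[0.40, 0.45, 0.15]))
    names = np.array([config.drug_name(d) for d in range(n_drugs)],
                     dtype=object)[col_idx]
    for d, syns in config.drug_synonyms.items():
        if len(syns) > 1:
            m = col_idx == d
            names[m] = rng_drug.choice(list(syns), size=int(m.sum()))
    drugs = pd.DataFrame({
        "caseid": caseid[row_idx], "drug_id": col_idx, "role": roles, "drugname": names,
    })
    drugs["drug_seq"] = drugs.groupby("caseid").cumcount() + 1

    r_row, r_col = np.nonzero(present)
    reactions = pd.DataFrame({
        "caseid": caseid[r_row], "event_id": r_col,
        "pt": np.array([config.pt_name(e) for e in range(n_events)])[r_col],
    })

    # --- case versions (duplicates) -------------------------------------
    dup = rng_dup.random(n) < config.duplicate_fraction
    v1 = pd.DataFrame({"caseid": caseid, "caseversion": 1,
                       "primaryid": np.char.add(caseid, "1"), "fda_dt": fda_dt})
    lag = rng_dup.integers(1, 61, size=int(dup.sum())).astype("timedelta64[D]")
    v2 = pd.DataFrame({"caseid": caseid[dup], "caseversion": 2,
                       "primaryid": np.char.add(caseid[dup], "2"),
                       "fda_dt": fda_dt[dup] + lag})
    versions = (pd.concat([v1, v2], ignore_index=True)
                .sort_values(["caseid", "caseversion"], ignore_index=True))

    miss = {f: rng_miss.random(n) < q for f, q in config.missingness.items()}
    raw = _build_raw_tables(config, cases, drugs, reactions, versions, miss)
    return ReportSet(config=config, cases=cases, drugs=drugs,
                     reactions=reactions, versions=versions, raw=raw)


def _cat(rng, marginal: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(marginal)
    p = np.asarray([marginal[k] for k in labels], dtype=float)
    return rng.choice(labels, size=n, p=p / p.sum())


def _range_arrays(bands: np.ndarray, ranges: Mapping[str, tuple]) -> tuple:
    lo = np.empty(bands.size)
    hi = np.empty(bands.size)
    for band, (a, b) in ranges.items():
        m = bands == band
        lo[m], hi[m] = a, b
    return lo, hi


def _fmt_date(s: pd.Series) -> pd.Series:
    s = pd.Series(s)
    ymd = s.dt.year * 10000 + s.dt.month * 100 + s.dt.day
    return ymd.astype("Int64").astype(str).mask(s.isna(), "")


def _build_raw_tables(config, cases, drugs, reactions, versions, miss) -> dict:
    """Assemble the observed $-delimited tables (string-valued, '' = missing)."""
    caseids = cases.index.to_numpy()
    pos = pd.Series(np.arange(len(caseids)), index=caseids)

    def masked(values: pd.Series, field: str) -> pd.Series:
        out = values.astype(str).copy()
        if field in miss:
            out[miss[field][pos[out.index].to_numpy()]] = ""
        return out

    demo_case = pd.DataFrame(index=cases.index)
    demo_case["event_dt"] = _fmt_date(cases["event_dt"])
    demo_case["sex"] = masked(cases["sex"], "sex")
    demo_case["age"] = masked(cases["age_yr"].map("{:.1f}".format), "age")
    demo_case["age_cod"] = np.where(demo_case["age"] == "", "", "YR")
    demo_case["wt"] = masked(cases["weight_kg"].map("{:.1f}".format), "weight")
    demo_case["wt_cod"] = np.where(demo_case["wt"] == "", "", "KG")
    occp = cases["reporter"].map(OCCP_CODES)
    demo_case["occp_cod"] = masked(occp, "reporter")
    demo_case["reporter_country"] = masked(cases["country"], "country")

    demo = versions.merge(demo_case, left_on="caseid", right_index=True)
    demo["fda_dt"] = _fmt_date(demo["fda_dt"])
    demo = demo[["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
                 "sex", "age", "age_cod", "wt", "wt_cod", "occp_cod",
                 "reporter_country"]].astype(str)

    route_case = masked(cases["route"], "route")
    drug_obs = drugs.copy()
    drug_obs["route"] = route_case[drug_obs["caseid"].to_numpy()].to_numpy()
    drug_raw = (versions[["caseid", "primaryid"]]
                .merge(drug_obs, on="caseid")
                .rename(columns={"role": "role_cod"}))
    drug_raw = drug_raw[["primaryid", "caseid", "drug_seq", "role_cod",
                         "drugname", "route"]].astype(str)

    reac_raw = versions[["caseid", "primaryid"]].merge(reactions, on="caseid")
    reac_raw = reac_raw[["primaryid", "caseid", "pt"]].astype(str)

    outc_case = masked(cases["outcome"].map(OUTCOME_CODES), "outcome")
    outc_raw = versions[["caseid", "primaryid"]].copy()
    outc_raw["outc_cod"] = outc_case[outc_raw["caseid"].to_numpy()].to_numpy()
    outc_raw = outc_raw[outc_raw["outc_cod"] != ""]
    outc_raw = outc_raw[["primaryid", "caseid", "outc_cod"]].astype(str)

    rpsr_case = np.where(occp.isna() | (demo_case["occp_cod"] == ""), "OTH",
                         np.where(cases["reporter"] == "consumer", "CSM", "HP"))
    rpsr_raw = versions[["caseid", "primaryid"]].copy()
    rpsr_raw["rpsr_cod"] = pd.Series(rpsr_case, index=cases.index)[
        rpsr_raw["caseid"].to_numpy()].to_numpy()
    rpsr_raw = rpsr_raw[["primaryid", "caseid", "rpsr_cod"]].astype(str)

    start_case = masked(_fmt_date(cases["ther_start"]), "tto")
    ps_seq = drugs.loc[drugs["role"] == "PS"].set_index("caseid")["drug_seq"]
    ther_raw = versions[["caseid", "primaryid"]].copy()
    ther_raw["dsg_drug_seq"] = ps_seq[ther_raw["caseid"].to_numpy()].to_numpy()
    ther_raw["start_dt"] = start_case[ther_raw["caseid"].to_numpy()].to_numpy()
    ther_raw["end_dt"] = ""
    ther_raw = ther_raw[ther_raw["start_dt"] != ""]
    ther_raw = ther_raw[["primaryid", "caseid", "dsg_drug_seq", "start_dt",
                         "end_dt"]].astype(str)

    return {"DEMO": demo.reset_index(drop=True), "DRUG": drug_raw,
            "REAC": reac_raw, "OUTC": outc_raw.reset_index(drop=True),
            "RPSR": rpsr_raw, "THER": ther_raw.reset_index(drop=True)}


def true_contingency(report_set: ReportSet, drug_id: int, event_id: int):
    """2x2 counts for (drug, event) from the pre-duplication ledger.

    Counts reports (cases): exposure = the drug is the case's primary
    suspect, outcome = the event's PT is present.  This bypasses file I/O
    and deduplication entirely and serves as the brute-force oracle for
    the contingency module.
    """
    from .contingency import ContingencyTable

    cfg = report_set.config
    if not 0 <= drug_id < cfg.n_drugs:
        raise LookupError_(f"unknown drug_id {drug_id}")
    if not 0 <= event_id < cfg.n_events:
        raise LookupError_(f"unknown event_id {event_id}")
    n = report_set.n_cases
    if n == 0:
        return ContingencyTable(0, 0, 0, 0)
    exposed = report_set.cases["ps_drug"].to_numpy() == drug_id
    with_event = np.zeros(n, dtype=bool)
    hits = report_set.reactions.loc[
        report_set.reactions["event_id"] == event_id, "caseid"]
    with_event[report_set.cases.index.get_indexer(hits.unique())] = True
    a = int((exposed & with_event).sum())
    b = int((exposed & ~with_event).sum())
    c = int((~exposed & with_event).sum())
    d = int((~exposed & ~with_event).sum())
    return ContingencyTable(a, b, c, d)


def analytic_odds_ratio(config: GeneratorConfig, drug_id: int, event_id: int) -> float:
    """Closed-form marginal odds ratio of a pair under the generative model.

    Conditioning on >=1 reaction per case scales every event probability
    within an exposure class by 1/P(>=1 event | class), which changes the
    per-class event odds; both classes are handled exactly here.
    """
    base = config.event_base_rate_array()
    p1 = base.copy()  # event probabilities when ps == drug_id
    for spec in config.injected_signals:
        if spec.drug_id == drug_id:
            p1[spec.event_id] = min(1.0, spec.relative_risk * base[spec.event_id])
    p0 = base  # all other cases (no other signal shares the drug by assumption)
    none1 = np.prod(1.0 - p1)
    none0 = np.prod(1.0 - p0)
    q1 = p1[event_id] / (1.0 - none1)  # P(event | exposed, >=1 reaction)
    q0 = p0[event_id] / (1.0 - none0)
    return (q1 / (1.0 - q1)) / (q0 / (1.0 - q0))


def write_faers_ascii(report_set: ReportSet, directory, quarter_label: str = "17Q4") -> dict:
    """Serialize the observed tables as $-delimited quarterly ASCII files.

    Returns a manifest mapping file path to row count (header excluded).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for prefix, frame in report_set.raw.items():
        path = directory / f"{prefix}{quarter_label}.txt"
        try:
            frame.to_csv(path, sep="$", index=False, lineterminator="\n")
        except OSError as exc:  # pragma: no cover - environment dependent
            raise IOError(f"cannot write {path}: {exc}") from exc
        manifest[str(path)] = len(frame)
    return manifest


def write_ledger(report_set: ReportSet, directory) -> dict:
    """Write the ground-truth ledger (pre-duplication view) as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    cases = report_set.cases.copy()
    for col in ("fda_dt", "event_dt", "ther_start"):
        cases[col] = _fmt_date(cases[col])
    for name, frame in (("cases", cases.reset_index()), ("drugs", report_set.drugs),
                        ("reactions", report_set.reactions),
                        ("versions", report_set.versions.assign(
                            fda_dt=_fmt_date(report_set.versions["fda_dt"])))):
        path = directory / f"ledger_{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        out[str(path)] = len(frame)
    return out
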