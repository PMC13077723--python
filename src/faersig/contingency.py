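"""2x2 contingency tables for (target drug, event) pairs.

The unit of counting is the report (case): for a given event, a case
contributes at most 1 to each cell.

====================  ====================  =============
\\                     reports w/ the event  all other AEs
target drug is PS     a                     b
all other reports     c                     d
====================  ====================  =============

``a+b`` (number of primary-suspect cases for the target drug) and ``n``
are constant across events at a given aggregation level; the comparator
is every other case in the ingested corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .faers_io import CaseData, filter_primary_suspect
from .meddra_map import PtSocTable


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _event_frame(cases: CaseData, level: str, mapping: PtSocTable | None) -> pd.DataFrame:
    """(primaryid, event) pairs, unique per case, at PT or SOC level."""
    pairs = cases.reactions[["primaryid", "pt"]]
    if level == "pt":
        return pairs.rename(columns={"pt": "event"})
    if level == "soc":
        if mapping is None:
            raise ConfigurationError("SOC-level tables require a PT->SOC mapping")
        soc = mapping.primary_soc()
        out = pairs.assign(event=pairs["pt"].map(soc).fillna("UNMAPPED"))
        return out[["primaryid", "event"]].drop_duplicates()
    raise ConfigurationError(f"level must be 'pt' or 'soc', got {level!r}")


def build_tables(cases: CaseData, target_drug_synonyms, level: str = "pt",
                 mapping: PtSocTable | None = None,
                 ) -> list[tuple[str, ContingencyTable]]:
    """One 2x2 table per event label observed in the corpus.

    ``cases`` must already be deduplicated (one record per caseid).
    Returns (event_label, table) pairs sorted by label; every table
    satisfies a+b+c+d == number of cases.
    """
    events = _event_frame(cases, level, mapping)
    n = cases.n_cases
    exposed = filter_primary_suspect(cases, target_drug_synonyms)
    exposed_ids = set(exposed.demo.index)
    n_exposed = len(exposed_ids)

    with_event = events.groupby("event")["primaryid"].nunique()
    a_counts = (events.loc[events["primaryid"].isin(exposed_ids)]
                .groupby("event")["primaryid"].nunique()
                .reindex(with_event.index, fill_value=0))

    out = []
    for event in sorted(with_event.index):
        a = int(a_counts[event])
        c = int(with_event[event]) - a
        b = n_exposed - a
        d = n - n_exposed - c
        out.append((event, ContingencyTable(a, b, c, d)))
    return out


def tables_to_frame(tables) -> pd.DataFrame:
    """(event, a, b, c, d) frame for CSV export."""
    return pd.DataFrame(
        [(e, t.a, t.b, t.c, t.d) for e, t in tables],
        columns=["event", "a", "b", "c", "d"])
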