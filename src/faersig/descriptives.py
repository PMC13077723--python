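"""Descriptive summaries of a spontaneous-report case series.

Produces count-(percent) tables per categorical variable, median (Q1, Q3)
rows for age and time-to-onset, and the banded age/weight/onset
groupings.  Percentages are computed over the sum of the *displayed*
categories (cases missing a variable are excluded unless an explicit
Unknown row is shown, as is conventional for age, weight, reporter and
onset summaries) and rounded half-up to two decimals.

Band boundaries are lower-inclusive / upper-exclusive: an age of exactly
45 years falls in the 45-65 band, an onset of exactly 7 days in the 7-28
band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .faers_io import CaseData

log = logging.getLogger(__name__)

UNKNOWN = "Unknown"

AGE_BAND_EDGES = (18.0, 45.0, 65.0, 75.0)
AGE_BAND_LABELS = ("<18", "18-45", "45-65", "65-75", ">=75")
WEIGHT_BAND_EDGES = (60.0, 80.0)
WEIGHT_BAND_LABELS = ("<60", "60-80", ">=80")
TTO_BAND_EDGES = (7, 28, 60)
TTO_BAND_LABELS = ("<7", "7-28", "28-60", ">=60")

#: variables an explicit Unknown row is displayed for by default
_UNKNOWN_SHOWN = {"age_band", "weight_band", "reporter", "tto_band"}

VARIABLES = ("year", "sex", "age_band", "weight_band", "reporter", "country",
             "route", "outcome", "tto_band")


def percent_half_up(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to 2 decimals (exact rational)."""
    q = (Decimal(100) * Decimal(count) / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class SummaryTable:
    """One variable's categorical summary: (label, count, percent) rows.

    The denominator is the sum of displayed counts, so the percents are
    always recomputable as round(100*count/denominator, 2) and sum to
    100 up to rounding slack.
    """

    variable: str
    rows: list[tuple[str, int, float]]
    denominator: int

    @classmethod
    def from_counts(cls, variable: str, counts: Sequence[tuple[str, int]],
                    ) -> "SummaryTable":
        denom = sum(c for _, c in counts)
        rows = [(label, int(c), percent_half_up(int(c), denom))
                for label, c in counts]
        return cls(variable=variable, rows=rows, denominator=denom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "count", "percent"])

    def to_markdown_lines(self) -> list[str]:
        lines = [f"**{self.variable}** (n = {self.denominator})", ""]
        lines += ["| Category | Count (%) |", "| --- | --- |"]
        lines += [f"| {label} | {count} ({pct:.2f}) |"
                  for label, count, pct in self.rows]
        return lines


def _band(value: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    if value < 0:
        log.warning("negative value %r banded as %s", value, UNKNOWN)
        return UNKNOWN
    return labels[int(np.searchsorted(edges, value, side="right"))]


def age_band(age_years) -> str:
    """Half-open age bands [0,18), [18,45), [45,65), [65,75), [75,inf)."""
    return _band(age_years, AGE_BAND_EDGES, AGE_BAND_LABELS)


def weight_band(weight_kg) -> str:
    return _band(weight_kg, WEIGHT_BAND_EDGES, WEIGHT_BAND_LABELS)


def tto_band(tto_days) -> str:
    """Half-open onset bands [0,7), [7,28), [28,60), [60,inf)."""
    return _band(tto_days, TTO_BAND_EDGES, TTO_BAND_LABELS)


def median_iqr(values) -> tuple[float, float, float] | None:
    """(median, Q1, Q3) by linear interpolation between order statistics.

    Missing values are excluded; all-missing input yields None.  Values
    are returned unrounded; display rounding is the caller's concern.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        return None
    q50, q25, q75 = np.percentile(arr, [50, 25, 75])  # type-7 interpolation
    return float(q50), float(q25), float(q75)


def _variable_series(cases: CaseData, variable: str) -> pd.Series:
    demo = cases.demo
    if variable == "year":
        return demo["fda_dt"].dt.year.astype("Int64").astype(str).replace("<NA>", None)
    if variable == "sex":
        return demo["sex"].map({"F": "Female", "M": "Male"})
    if variable == "age_band":
        return demo["age_yr"].map(age_band)
    if variable == "weight_band":
        return demo["weight_kg"].map(weight_band)
    if variable == "reporter":
        return demo["reporter"].str.capitalize()
    if variable == "country":
        return pd.Series(np.where(demo["country"].isna(), None,
                                  np.where(demo["country"] == "US",
                                           "United States", "Other")),
                         index=demo.index, dtype=object)
    if variable == "route":
        d = cases.drugs
        route = (d.loc[(d["role_cod"] == "PS") & (d["route"].fillna("") != ""),
                       ["primaryid", "route"]]
                 .drop_duplicates("primaryid").set_index("primaryid")["route"])
        return route.str.capitalize().reindex(demo.index)
    if variable == "outcome":
        # counting unit is the outcome entry, not the case
        return cases.outcomes["outcome"].str.capitalize()
    if variable == "tto_band":
        return demo["tto_days"].map(tto_band)
    raise ConfigurationError(f"unknown summary variable {variable!r}")


def summarize_categorical(cases: CaseData, variable: str,
                          category_order: Sequence[str] | None = None,
                          include_unknown: bool | None = None) -> SummaryTable:
    """Count-(percent) table of one variable over the displayed categories.

    ``include_unknown`` appends an Unknown row counting cases with the
    variable missing; default per-variable convention (shown for age,
    weight, reporter and onset bands).  ``category_order`` fixes the row
    order; otherwise rows are sorted by descending count then label.
    """
    if variable not in VARIABLES:
        raise ConfigurationError(f"unknown summary variable {variable!r}")
    if include_unknown is None:
        include_unknown = variable in _UNKNOWN_SHOWN
    series = _variable_series(cases, variable)
    series = series.replace(UNKNOWN, None) if series.dtype == object else series
    counts = series.dropna().value_counts()
    if category_order is not None:
        ordered = [(c, int(counts.get(c, 0))) for c in category_order
                   if c != UNKNOWN]
    elif variable == "year":
        ordered = [(c, int(counts[c])) for c in sorted(counts.index)]
    else:
        ordered = [(c, int(counts[c]))
                   for c in counts.sort_values(ascending=False).index]
    if include_unknown:
        n_unknown = int(series.isna().sum())
        ordered.append((UNKNOWN, n_unknown))
    return SummaryTable.from_counts(variable, ordered)


def demographic_report(cases: CaseData) -> list[SummaryTable]:
    """The full set of per-variable summaries for a case series."""
    return [summarize_categorical(cases, v) for v in VARIABLES]


def report_markdown(cases: CaseData) -> str:
    """Combined report: every categorical block plus median (Q1, Q3) rows."""
    lines = ["# Case series summary", ""]
    for table in demographic_report(cases):
        lines += table.to_markdown_lines() + [""]
        if table.variable == "age_band":
            lines += _median_lines("Age, years", cases.demo["age_yr"])
        if table.variable == "tto_band":
            lines += _median_lines("Time to onset, days", cases.demo["tto_days"])
    return "\n".join(lines)


def _median_lines(label: str, values: pd.Series) -> list[str]:
    stats = median_iqr(values)
    if stats is None:
        return []
    med, q1, q3 = stats
    return [f"{label}: median {med:.2f} (Q1 {q1:.2f}, Q3 {q3:.2f})", ""]
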