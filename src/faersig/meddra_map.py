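"""PT -> system organ class mapping.

MedDRA is multi-axial: a preferred term may belong to several SOCs but has
exactly one *primary* SOC.  MedDRA itself is licensed, so this module works
from a plain two-column CSV surrogate ``(pt, soc, is_primary)`` with the
same semantics.  The 26 rows of a licensed distribution per term are out of
scope; only the PT->SOC axis is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"

#: The 21 MedDRA system organ classes used for SOC-level aggregation.
SOC_NAMES = (
    "Immune system disorders",
    "Renal and urinary disorders",
    "Gastrointestinal disorders",
    "Vascular disorders",
    "Respiratory, thoracic, and mediastinal disorders",
    "Ear and labyrinth disorders",
    "Blood and lymphatic system disorders",
    "Skin and subcutaneous tissue disorders",
    "Nervous system disorders",
    "Psychiatric disorders",
    "Musculoskeletal and connective tissue disorders",
    "Pregnancy, puerperium, and perinatal conditions",
    "Investigations",
    "Reproductive system and breast disorders",
    "Cardiac disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Metabolism and nutrition disorders",
    "Injury, poisoning, and procedural complications",
    "Eye disorders",
    "Infections and infestations",
)


@dataclass
class PtSocTable:
    """Validated PT->SOC mapping with one primary SOC per term."""

    frame: pd.DataFrame  # columns pt, soc, is_primary (bool)

    def __post_init__(self) -> None:
        f = self.frame
        dup = f.duplicated(subset=["pt", "soc"])
        if dup.any():
            rows = (f.index[dup] + 1).tolist()
            raise ValidationError(f"duplicate (pt, soc) pairs at rows {rows}")
        n_primary = f.groupby("pt")["is_primary"].sum()
        bad = n_primary[n_primary != 1]
        if not bad.empty:
            raise ValidationError(
                "each pt needs exactly one primary SOC; violated by: "
                + ", ".join(f"{pt} ({int(k)} primaries)" for pt, k in bad.items()))

    @property
    def pts(self) -> set[str]:
        return set(self.frame["pt"])

    def primary_soc(self) -> pd.Series:
        """Series pt -> primary SOC."""
        f = self.frame
        return f.loc[f["is_primary"]].set_index("pt")["soc"]

    def save(self, path) -> None:
        out = self.frame.copy()
        out["is_primary"] = out["is_primary"].astype(int)
        out.to_csv(path, index=False, lineterminator="\n")


def load_mapping(path) -> PtSocTable:
    """Load and validate a (pt, soc, is_primary) CSV mapping file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"mapping file not found: {path}")
    frame = pd.read_csv(path, dtype={"pt": str, "soc": str})
    required = {"pt", "soc", "is_primary"}
    if not required.issubset(frame.columns):
        raise ConfigurationError(
            f"mapping file {path} must have columns {sorted(required)}")
    frame["is_primary"] = frame["is_primary"].astype(int).astype(bool)
    return PtSocTable(frame.reset_index(drop=True))


def soc_of(pt: str, table: PtSocTable, policy: str = "primary_only"):
    """SOC(s) of a preferred term.

    ``primary_only`` returns the single primary SOC (a string); ``all``
    returns every mapped SOC as a list.  Unmapped terms yield the
    ``UNMAPPED`` sentinel (in a one-element list under ``all``) with a
    logged warning.
    """
    if policy not in ("primary_only", "all"):
        raise ConfigurationError(f"unknown policy {policy!r}")
    rows = table.frame.loc[table.frame["pt"] == pt]
    if rows.empty:
        log.warning("preferred term %r has no SOC mapping", pt)
        return UNMAPPED if policy == "primary_only" else [UNMAPPED]
    if policy == "primary_only":
        return rows.loc[rows["is_primary"], "soc"].iloc[0]
    return rows["soc"].tolist()


def synthetic_mapping(n_events: int, pt_name=None) -> PtSocTable:
    """Round-robin mapping of n synthetic PTs onto the 21 SOC names.

    Companion to the report generator: PT ``i`` gets primary SOC
    ``SOC_NAMES[i % 21]``.  Synthetic stand-in for a licensed MedDRA
    distribution, usable anywhere a :class:`PtSocTable` is expected.
    """
    if pt_name is None:
        pt_name = lambda e: f"PT_{e:03d}"  # noqa: E731 - mirrors generator naming
    frame = pd.DataFrame({
        "pt": [pt_name(e) for e in range(n_events)],
        "soc": [SOC_NAMES[e % len(SOC_NAMES)] for e in range(n_events)],
        "is_primary": True,
    })
    return PtSocTable(frame)
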