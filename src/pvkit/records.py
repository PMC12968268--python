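"""Core record types for Individual Case Safety Reports (ICSRs).

A spontaneous-report database stores one or more *versions* of each case;
every version carries demographics, the suspect/concomitant drug list and
the MedDRA Preferred Terms (PTs) coded for the event.  Dates are kept in
the raw ``YYYYMMDD`` digit form used by FAERS extracts so that partial
dates (``YYYYMM`` or ``YYYY``) survive round trips and are never silently
promoted to full precision.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OCCUPATION_CODES = frozenset({"MD", "CN", "PH", "HP", "OT", "LW"})

#: fields whose absence is counted when deduplication breaks ties
COMPLETENESS_FIELDS = ("age", "weight", "sex", "occupation", "country", "event_date")

LB_TO_KG = 0.453592
#: weights above this (kg) are treated as data-entry errors
MAX_PLAUSIBLE_WEIGHT_KG = 650.0


@dataclass(slots=True)
class DrugEntry:
    """One drug row of a report: normalized name, role code, therapy start."""

    name: str
    role: str
    start_date: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role!r}")


@dataclass(slots=True)
class IcsrRecord:
    """One case-version of a spontaneous safety report."""

    caseid: str
    version: int
    fda_dt: str | None
    age_value: float | None = None
    age_unit: str | None = None
    weight_value: float | None = None
    weight_unit: str | None = None
    sex: str | None = None
    occupation: str | None = None
    reporter_country: str | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    event_date: str | None = None

    def __post_init__(self) -> None:
        if not self.caseid:
            raise ValueError("caseid must be non-empty")

    # -- derived views -------------------------------------------------

    def age_years(self) -> float | None:
        """Age normalized to years (DEC x10, MON /12, DY /365.25)."""
        if self.age_value is None or self.age_value < 0:
            return None
        unit = (self.age_unit or "YR").upper()
        factor = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}.get(unit)
        if factor is None:
            return None
        return self.age_value * factor

    def weight_kg(self) -> float | None:
        """Weight in kg; pounds converted; implausible entries -> None."""
        if self.weight_value is None:
            return None
        unit = (self.weight_unit or "KG").upper()
        if unit in ("KG", "KGS"):
            kg = self.weight_value
        elif unit in ("LBS", "LB"):
            kg = self.weight_value * LB_TO_KG
        else:
            return None
        if kg <= 0 or kg > MAX_PLAUSIBLE_WEIGHT_KG:
            return None
        return kg

    def ps_drugs(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.role == "PS"]

    def n_missing_core_fields(self) -> int:
        """How many of the dedup tie-break fields are absent."""
        missing = 0
        missing += self.age_years() is None
        missing += self.weight_kg() is None
        missing += not self.sex
        missing += not self.occupation
        missing += not self.reporter_country
        missing += full_date(self.event_date) is None
        return missing


def full_date(raw: str | None) -> _dt.date | None:
    """Parse a FAERS ``YYYYMMDD`` string; partial or malformed dates -> None."""
    if not raw or len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


def to_faers_date(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


DEFAULT_SALT_SUFFIXES = (
    "HYDROCHLORIDE",
    "HCL",
    "SODIUM",
    "SULFATE",
    "SULPHATE",
    "ACETATE",
    "TARTRATE",
    "MESYLATE",
    "MALEATE",
    "CITRATE",
    "BESYLATE",
)


def normalize_drug_name(name: str, salt_suffixes: tuple[str, ...] = DEFAULT_SALT_SUFFIXES) -> str:
    """Uppercase, trim, collapse whitespace, strip a trailing salt qualifier.

    No ingredient-dictionary mapping is attempted; two brand names of the
    same active substance remain distinct strings.
    """
    norm = " ".join(name.upper().split())
    for suffix in salt_suffixes:
        if norm.endswith(" " + suffix):
            norm = norm[: -len(suffix) - 1]
            break
    return norm
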