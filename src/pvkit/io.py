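"""Reading FAERS-dialect quarterly files and building the analysis cohort.

The quarterly extract dialect is ``$``-delimited ASCII with one header
row per table.  DEMO defines the case versions; DRUG, REAC and THER are
joined to it by the per-report primary key.  Deduplication follows the
agency's case-version guidance: one record survives per CASEID, chosen
by highest version, then latest FDA receipt date, then completeness.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from .records import (
    DrugEntry,
    IcsrRecord,
    full_date,
    normalize_drug_name,
)

logger = logging.getLogger(__name__)

DEFAULT_PT_TARGETS = frozenset({"ABORTION SPONTANEOUS", "ABORTION"})

#: progestogens and related formulations excluded to avoid protopathic bias
#: (drugs prescribed *for* threatened miscarriage)
DEFAULT_DRUG_EXCLUSIONS = frozenset(
    {
        "MEDROXYPROGESTERONE",
        "PROGESTERONE",
        "INTRAUTERINE CONTRACEPTIVE DEVICE",
        "ETHINYLESTRADIOL/ETONOGESTREL",
        "ETONOGESTREL",
        "LEVONORGESTREL",
        "ETHINYLESTRADIOL/NORELGESTROMIN",
        "ULIPRISTAL",
    }
)

#: healthcare professionals plus consumers; lawyer and unknown dropped by
#: default but configurable (public extracts still tabulate LW reports)
DEFAULT_OCCUPATIONS_KEPT = frozenset({"MD", "CN", "PH", "HP", "OT"})


class FaersFormatError(ValueError):
    """A quarterly file is missing a mandatory table or column."""


@dataclass(frozen=True)
class CohortFilter:
    window: tuple[str, str] = ("2005Q1", "2024Q4")
    roles_kept: frozenset[str] = frozenset({"PS"})
    occupations_kept: frozenset[str] = DEFAULT_OCCUPATIONS_KEPT
    pt_targets: frozenset[str] = DEFAULT_PT_TARGETS
    drug_exclusions: frozenset[str] = DEFAULT_DRUG_EXCLUSIONS

    def __post_init__(self) -> None:
        if not self.pt_targets:
            raise ValueError("pt_targets must be non-empty")
        unknown = set(self.roles_kept) - {"PS", "SS", "C", "I"}
        if unknown:
            raise ValueError(f"unknown role codes {sorted(unknown)}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_MANDATORY = {
    "DEMO": ("primaryid", "caseid", "caseversion", "fda_dt"),
    "DRUG": ("primaryid", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
}


def _read_table(path: Path) -> list[dict[str, str]]:
    with open(path, "r", encoding="ascii", newline="") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            return []
        rows = [dict(zip(header, row)) for row in reader]
    return rows


def _locate(directory: Path, prefix: str) -> Path | None:
    hits = sorted(
        p for p in directory.iterdir() if p.name.upper().startswith(prefix) and p.is_file()
    )
    return hits[0] if hits else None


def parse_quarter(directory) -> list[IcsrRecord]:
    """Parse one quarter's DEMO/DRUG/REAC/THER files into ICSR records.

    DEMO and DRUG are mandatory; a missing REAC or THER file is only
    warned about.  One record is produced per DEMO row; unparseable
    dates are carried through verbatim (they surface as partial/missing
    downstream, never as fabricated full dates).
    """
    directory = Path(directory)
    tables: dict[str, list[dict[str, str]]] = {}
    for name in ("DEMO", "DRUG", "REAC", "THER"):
        path = _locate(directory, name)
        if path is None:
            if name in ("DEMO", "DRUG"):
                raise FaersFormatError(f"mandatory {name} file not found in {directory}")
            logger.warning("optional %s file not found in %s", name, directory)
            tables[name] = []
            continue
        rows = _read_table(path)
        if rows:
            missing = [c for c in _MANDATORY[name] if c not in rows[0]]
            if missing:
                raise FaersFormatError(
                    f"{path.name}: missing mandatory column(s) {missing}"
                )
        tables[name] = rows

    drug_by_pid: dict[str, list[dict[str, str]]] = {}
    for row in tables["DRUG"]:
        drug_by_pid.setdefault(row["primaryid"], []).append(row)
    reac_by_pid: dict[str, list[str]] = {}
    for row in tables["REAC"]:
        reac_by_pid.setdefault(row["primaryid"], []).append(row["pt"])
    start_by_pid_seq: dict[tuple[str, str], str] = {}
    for row in tables["THER"]:
        if row["start_dt"]:
            start_by_pid_seq[(row["primaryid"], row["dsg_drug_seq"])] = row["start_dt"]

    records: list[IcsrRecord] = []
    n_drugless = 0
    n_skipped = 0
    for row in tables["DEMO"]:
        if not row.get("caseid"):
            n_skipped += 1
            continue
        pid = row["primaryid"]
        drugs = []
        for drow in drug_by_pid.get(pid, ()):
            seq = drow.get("drug_seq", "")
            drugs.append(
                DrugEntry(
                    name=drow["drugname"],
                    role=drow["role_cod"],
                    start_date=start_by_pid_seq.get((pid, seq)),
                )
            )
        if not drugs:
            n_drugless += 1
        records.append(
            IcsrRecord(
                caseid=row["caseid"],
                version=int(row["caseversion"] or 1),
                fda_dt=row["fda_dt"] or None,
                age_value=float(row["age"]) if row.get("age") else None,
                age_unit=row.get("age_cod") or None,
                weight_value=float(row["wt"]) if row.get("wt") else None,
                weight_unit=row.get("wt_cod") or None,
                sex=row.get("sex") or None,
                occupation=row.get("occp_cod") or None,
                reporter_country=row.get("reporter_country") or None,
                drugs=drugs,
                reactions=reac_by_pid.get(pid, []),
                event_date=row.get("event_dt") or None,
            )
        )
    if n_drugless:
        logger.info("parse_quarter: %d drugless DEMO rows", n_drugless)
    if n_skipped:
        logger.info("parse_quarter: %d DEMO rows without caseid skipped", n_skipped)
    return records


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate(records: Sequence[IcsrRecord]) -> list[IcsrRecord]:
    """Keep exactly one version per CASEID.

    Selection order: highest version, then most recent FDA_DT, then the
    fewest missing core fields; remaining ties keep the last-seen input
    record (deterministic in input order).  Idempotent.
    """
    best: dict[str, tuple[tuple, IcsrRecord]] = {}
    order: list[str] = []
    for pos, rec in enumerate(records):
        fda = full_date(rec.fda_dt)
        key = (
            rec.version,
            fda.toordinal() if fda else -1,
            -rec.n_missing_core_fields(),
            pos,
        )
        if rec.caseid not in best:
            order.append(rec.caseid)
            best[rec.caseid] = (key, rec)
        elif key >= best[rec.caseid][0]:
            best[rec.caseid] = (key, rec)
    return [best[cid][1] for cid in order]


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------


def match_miscarriage(record: IcsrRecord, pt_targets: Iterable[str] = DEFAULT_PT_TARGETS) -> bool:
    """True iff any reaction PT equals a target PT after trim + case-fold.

    Exact term match only — "ABORTION INDUCED" does not match "ABORTION".
    """
    targets = {t.strip().casefold() for t in pt_targets}
    return any(pt.strip().casefold() in targets for pt in record.reactions)


def _year_quarter(raw: str | None) -> str | None:
    d = full_date(raw)
    if d is None:
        return None
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def filter_cohort(
    records: Sequence[IcsrRecord], cohort_filter: CohortFilter = CohortFilter()
) -> tuple[list[IcsrRecord], list[IcsrRecord]]:
    """Split deduplicated records into (cases, background).

    Background: reports inside the year-quarter window (records with an
    unparseable FDA_DT are retained), passing the occupation filter,
    carrying at least one kept-role drug not on the exclusion list.
    Cases: the background subset whose PTs match the miscarriage targets.
    """
    lo, hi = cohort_filter.window
    background: list[IcsrRecord] = []
    cases: list[IcsrRecord] = []
    for rec in records:
        yq = _year_quarter(rec.fda_dt)
        if yq is not None and not (lo <= yq <= hi):
            continue
        if rec.occupation not in cohort_filter.occupations_kept:
            continue
        kept = [
            d
            for d in rec.drugs
            if d.role in cohort_filter.roles_kept
            and normalize_drug_name(d.name) not in cohort_filter.drug_exclusions
        ]
        if not kept:
            continue
        background.append(rec)
        if match_miscarriage(rec, cohort_filter.pt_targets):
            cases.append(rec)
    if not background:
        raise ValueError(
            "empty background cohort: no report passed the filters; "
            "consider widening the year-quarter window"
        )
    return cases, background


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching tabular presentation conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _continuous_summary(values: list[float], cutpoint: float, labels: tuple[str, str]):
    below = sum(v < cutpoint for v in values)
    above = len(values) - below
    known = below + above
    out = {
        "median": None,
        "min": None,
        "max": None,
        "strata": {},
        "n_known": known,
    }
    if values:
        svals = sorted(values)
        mid = len(svals) // 2
        median = svals[mid] if len(svals) % 2 else (svals[mid - 1] + svals[mid]) / 2
        out.update(median=median, min=svals[0], max=svals[-1])
    for label, count in zip(labels, (below, above)):
        pct = round_half_up(100.0 * count / known) if known else None
        out["strata"][label] = {"n": count, "pct": pct}
    return out


def summarize_demographics(
    cohort: Sequence[IcsrRecord],
    age_cut: float = 35.0,
    weight_cut: float = 70.0,
) -> dict:
    """Table-1-style summary of a cohort.

    Continuous variables report median [min, max] and a dichotomy (age at
    35 years, weight at 70 kg); categorical variables report stratum
    counts with percentages over the known-value denominator.  Missing
    values are counted separately and never enter a denominator.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    n = len(cohort)

    ages = [a for rec in cohort if (a := rec.age_years()) is not None]
    weights = [w for rec in cohort if (w := rec.weight_kg()) is not None]
    summary = {
        "n": n,
        "age": _continuous_summary(ages, age_cut, (f"<{age_cut:g} years", f">={age_cut:g} years")),
        "weight": _continuous_summary(
            weights, weight_cut, (f"<{weight_cut:g} kg", f">={weight_cut:g} kg")
        ),
    }
    summary["age"]["missing"] = n - len(ages)
    summary["weight"]["missing"] = n - len(weights)

    for key, getter in (
        ("occupation", lambda r: r.occupation),
        ("country", lambda r: r.reporter_country),
    ):
        counts: dict[str, int] = {}
        missing = 0
        for rec in cohort:
            v = getter(rec)
            if v:
                counts[v] = counts.get(v, 0) + 1
            else:
                missing += 1
        known = sum(counts.values())
        summary[key] = {
            "strata": {
                c: {"n": cnt, "pct": round_half_up(100.0 * cnt / known) if known else None}
                for c, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            },
            "missing": missing,
            "n_known": known,
        }
    return summary
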