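"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of FAERS quarterly extracts: versioned duplicate
case reports, drug role codes, MedDRA PT strings, heavily and
non-randomly missing demographics, reporter occupations and countries,
therapy-start/event dates, and drug-event associations with configurable
injected relative risks and per-drug Weibull time-to-onset distributions.

The event model is deliberately simple so that the implied 2x2 cell
probabilities are available in closed form for oracle tests: each report
is exposed to each configured drug independently with ``use_prob`` (as
primary suspect), and the miscarriage event fires with probability
``event_base_rate`` multiplied by the injected relative risk of every
exposed drug, capped at 1.  Reports exposed to no configured drug are
assigned one background filler drug so every report has a primary
suspect and the screening background is well defined.
"""

from __future__ import annotations

import math
import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import DrugEntry, IcsrRecord, to_faers_date

TARGET_PTS = ("ABORTION SPONTANEOUS", "ABORTION")

#: PTs used for non-case reports (opaque strings; no MedDRA hierarchy implied)
NOISE_PTS = (
    "HEADACHE",
    "NAUSEA",
    "FATIGUE",
    "PYREXIA",
    "RASH",
    "DIZZINESS",
    "ARTHRALGIA",
    "DIARRHOEA",
)

N_BACKGROUND_DRUGS = 20

_EPOCH = _dt.date(2005, 1, 1)
_WINDOW_DAYS = (_dt.date(2024, 12, 31) - _EPOCH).days


class ConfigError(ValueError):
    """A synthetic-cohort configuration value is out of range."""


@dataclass(slots=True)
class DrugSpec:
    """One simulated drug: exposure prevalence, injected effect, TTO law."""

    name: str
    use_prob: float = 0.05
    injected_rr: float = 1.0
    tto_shape: float = 0.73
    tto_scale: float = 480.67


# Occupation mix and missingness defaults follow the reporting patterns of
# large public pharmacovigilance extracts: age absent in roughly half the
# reports, weight in three quarters, and healthcare professionals
# submitting about two thirds of those with a known reporter type.
DEFAULT_OCCUPATION_MIX = {
    "MD": 0.308,
    "CN": 0.3125,
    "PH": 0.0213,
    "HP": 0.0846,
    "OT": 0.2213,
    "LW": 0.0063,
    "missing": 0.046,
}


@dataclass(slots=True)
class SyntheticConfig:
    n_reports: int = 10_000
    drugs: list[DrugSpec] = field(default_factory=lambda: [DrugSpec("DRUG A")])
    event_base_rate: float = 0.02
    duplicate_rate: float = 0.1
    missing_age_rate: float = 0.45
    missing_weight_rate: float = 0.78
    missing_date_rate: float = 0.30
    age_dist: tuple[str, dict] = ("normal", {"mean": 32.0, "sd": 9.0})
    weight_dist: tuple[str, dict] = ("normal", {"mean": 68.0, "sd": 16.0})
    occupation_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPATION_MIX)
    )
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_reports, int) and self.n_reports > 0):
            raise ConfigError("n_reports must be a positive integer")
        if not self.drugs:
            raise ConfigError("drugs must be non-empty")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigError("drugs must have unique names")
        for d in self.drugs:
            if not (math.isfinite(d.use_prob) and 0.0 <= d.use_prob <= 1.0):
                raise ConfigError(f"use_prob out of [0,1] for drug {d.name!r}")
            if not (math.isfinite(d.injected_rr) and d.injected_rr > 0):
                raise ConfigError(f"injected_rr must be > 0 for drug {d.name!r}")
            if not (math.isfinite(d.tto_shape) and d.tto_shape > 0):
                raise ConfigError(f"tto_shape must be > 0 for drug {d.name!r}")
            if not (math.isfinite(d.tto_scale) and d.tto_scale > 0):
                raise ConfigError(f"tto_scale must be > 0 for drug {d.name!r}")
        for name in (
            "event_base_rate",
            "missing_age_rate",
            "missing_weight_rate",
            "missing_date_rate",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} out of [0,1]")
        if not (math.isfinite(self.duplicate_rate) and 0.0 <= self.duplicate_rate < 1.0):
            raise ConfigError("duplicate_rate out of [0,1)")
        total = sum(self.occupation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"occupation_mix sums to {total}, expected 1")
        if any(p < 0 for p in self.occupation_mix.values()):
            raise ConfigError("occupation_mix probabilities must be >= 0")


@dataclass(slots=True)
class GroundTruth:
    """What the generator actually injected, keyed by configured drug name."""

    injected_rr: dict[str, float]
    tto_params: dict[str, tuple[float, float]]
    n_unique_cases: int
    n_duplicate_versions: int
    n_exposed: dict[str, int]


def _draw(dist: tuple[str, dict], rng: np.random.Generator, n: int) -> np.ndarray:
    family, params = dist
    if family == "normal":
        return rng.normal(params["mean"], params["sd"], size=n)
    if family == "lognormal":
        return rng.lognormal(params["mean"], params["sd"], size=n)
    if family == "uniform":
        return rng.uniform(params["low"], params["high"], size=n)
    raise ConfigError(f"unknown distribution family {family!r}")


def generate_cohort(config: SyntheticConfig) -> tuple[list[IcsrRecord], GroundTruth]:
    """Draw a cohort of case reports plus the ground truth behind it.

    Identical config (including seed) yields a bitwise-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    k = len(config.drugs)

    exposed = rng.random((n, k)) < np.array([d.use_prob for d in config.drugs])
    rr = np.array([d.injected_rr for d in config.drugs])
    p_event = config.event_base_rate * np.where(exposed, rr, 1.0).prod(axis=1)
    np.clip(p_event, 0.0, 1.0, out=p_event)
    is_case = rng.random(n) < p_event

    # demographics (drawn for everyone, then masked to emulate missingness)
    ages = np.clip(_draw(config.age_dist, rng, n), 0.0, 95.0).round(1)
    weights = np.clip(_draw(config.weight_dist, rng, n), 30.0, 250.0).round(1)
    age_missing = rng.random(n) < config.missing_age_rate
    weight_missing = rng.random(n) < config.missing_weight_rate
    occ_codes = list(config.occupation_mix)
    occ_idx = rng.choice(len(occ_codes), size=n, p=list(config.occupation_mix.values()))
    countries = np.array(["US", "CA", "UK", "DE", "FR", "JP", "BR", "IT", "OTHER"])
    country_idx = rng.choice(
        len(countries), size=n, p=[0.36, 0.11, 0.08, 0.06, 0.05, 0.02, 0.02, 0.02, 0.28]
    )

    fda_offsets = rng.integers(0, _WINDOW_DAYS + 1, size=n)
    start_offsets = rng.integers(0, _WINDOW_DAYS - 400, size=n)
    date_missing = rng.random(n) < config.missing_date_rate
    date_partial = rng.random(n) < 0.5  # half of "unreliable" dates are partial

    # per-drug Weibull TTO for event-positive exposed reports (first exposed
    # drug's law), rounded up to whole days >= 1
    first_exposed = np.where(exposed.any(axis=1), exposed.argmax(axis=1), -1)
    shapes = np.array([d.tto_shape for d in config.drugs])
    scales = np.array([d.tto_scale for d in config.drugs])
    tto_raw = rng.weibull(np.where(first_exposed >= 0, shapes[first_exposed], 1.0))
    tto_days = np.maximum(np.ceil(tto_raw * np.where(first_exposed >= 0, scales[first_exposed], 1.0)), 1.0)

    noise_drug_idx = rng.integers(0, N_BACKGROUND_DRUGS, size=n)
    noise_pt_idx = rng.integers(0, len(NOISE_PTS), size=n)
    target_pt_idx = rng.random(n) < 0.85  # True -> "ABORTION SPONTANEOUS"

    background_names = [f"BACKGROUND DRUG {i:02d}" for i in range(N_BACKGROUND_DRUGS)]
    drug_names = [d.name for d in config.drugs]

    records: list[IcsrRecord] = []
    for i in range(n):
        caseid = f"{10_000_000 + i}"
        has_tto = is_case[i] and first_exposed[i] >= 0
        start = _EPOCH + _dt.timedelta(days=int(start_offsets[i]))
        start_str: str | None = to_faers_date(start)
        if has_tto:
            event = start + _dt.timedelta(days=int(tto_days[i]))
            event_str: str | None = to_faers_date(event)
        else:
            event_str = to_faers_date(start + _dt.timedelta(days=int(rng.integers(1, 365)))) if is_case[i] else None
        if date_missing[i]:
            # unreliable exposure timing: drop or truncate the start date
            start_str = start_str[:6] if date_partial[i] else None

        entries: list[DrugEntry] = []
        row = exposed[i]
        if row.any():
            for j in np.flatnonzero(row):
                entries.append(DrugEntry(drug_names[j], "PS", start_str))
        else:
            entries.append(DrugEntry(background_names[noise_drug_idx[i]], "PS", start_str))

        if is_case[i]:
            pts = [TARGET_PTS[0] if target_pt_idx[i] else TARGET_PTS[1]]
        else:
            pts = [NOISE_PTS[noise_pt_idx[i]]]

        occ = occ_codes[occ_idx[i]]
        records.append(
            IcsrRecord(
                caseid=caseid,
                version=1,
                fda_dt=to_faers_date(_EPOCH + _dt.timedelta(days=int(fda_offsets[i]))),
                age_value=None if age_missing[i] else float(ages[i]),
                age_unit=None if age_missing[i] else "YR",
                weight_value=None if weight_missing[i] else float(weights[i]),
                weight_unit=None if weight_missing[i] else "KG",
                sex="F",
                occupation=None if occ == "missing" else occ,
                reporter_country=str(countries[country_idx[i]]),
                drugs=entries,
                reactions=pts,
                event_date=event_str,
            )
        )

    # re-emitted case versions: a fraction of cases appears again, either as a
    # higher caseversion, as the same version received later by the agency
    # (FDA_DT shifted forward 1-90 days), or as an identical version that
    # fills one formerly-missing field — so each dedup tie-break is exercised
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_indices = np.flatnonzero(dup_mask)
    dup_kind = rng.choice(3, size=dup_indices.size, p=[0.5, 0.3, 0.2])
    dup_fda_shift = rng.integers(1, 91, size=dup_indices.size)
    fill_ages = np.clip(_draw(config.age_dist, rng, dup_indices.size), 0.0, 95.0).round(1)
    for pos, i in enumerate(dup_indices):
        base = records[i]
        kind = dup_kind[pos]
        dup = IcsrRecord(
            caseid=base.caseid,
            version=base.version + 1 if kind == 0 else base.version,
            fda_dt=base.fda_dt if kind == 2 else _shift_date(base.fda_dt, int(dup_fda_shift[pos])),
            age_value=base.age_value,
            age_unit=base.age_unit,
            weight_value=base.weight_value,
            weight_unit=base.weight_unit,
            sex=base.sex,
            occupation=base.occupation,
            reporter_country=base.reporter_country,
            drugs=list(base.drugs),
            reactions=list(base.reactions),
            event_date=base.event_date,
        )
        if kind == 2:
            if dup.age_value is None:
                dup.age_value = float(fill_ages[pos])
                dup.age_unit = "YR"
            elif dup.weight_value is None:
                dup.weight_value = float(np.clip(fill_ages[pos] + 40.0, 35.0, 250.0))
                dup.weight_unit = "KG"
        records.append(dup)

    truth = GroundTruth(
        injected_rr={d.name: d.injected_rr for d in config.drugs},
        tto_params={d.name: (d.tto_shape, d.tto_scale) for d in config.drugs},
        n_unique_cases=n,
        n_duplicate_versions=int(dup_indices.size),
        n_exposed={
            d.name: int(exposed[:, j].sum()) for j, d in enumerate(config.drugs)
        },
    )
    return records, truth


def _shift_date(raw: str | None, days: int) -> str | None:
    if raw is None:
        return None
    d = _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8])) + _dt.timedelta(days=days)
    return to_faers_date(d)


def config_from_dict(data: dict) -> SyntheticConfig:
    """Build a config from a YAML/JSON-style mapping mirroring the field names."""
    data = dict(data)
    drugs = [DrugSpec(**d) for d in data.pop("drugs", [])]
    if "age_dist" in data:
        data["age_dist"] = tuple(data["age_dist"])
    if "weight_dist" in data:
        data["weight_dist"] = tuple(data["weight_dist"])
    cfg = SyntheticConfig(drugs=drugs or SyntheticConfig().drugs, **data)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# FAERS-dialect writer ("$"-delimited ASCII quarter)
# ---------------------------------------------------------------------------

DEMO_COLUMNS = (
    "primaryid",
    "caseid",
    "caseversion",
    "fda_dt",
    "age",
    "age_cod",
    "wt",
    "wt_cod",
    "sex",
    "occp_cod",
    "reporter_country",
    "event_dt",
)
DRUG_COLUMNS = ("primaryid", "caseid", "drug_seq", "role_cod", "drugname")
REAC_COLUMNS = ("primaryid", "caseid", "pt")
THER_COLUMNS = ("primaryid", "caseid", "dsg_drug_seq", "start_dt")


def write_faers_quarter(records: Sequence[IcsrRecord], directory) -> dict[str, str]:
    """Write DEMO/DRUG/REAC/THER ``$``-delimited files for one quarter.

    Returns the mapping of table name to written path.  ``parse_quarter``
    on the output reproduces the records field-exactly.  The join key is
    an ISR-style running report id, unique per emitted case version (two
    transmissions of the same caseid+caseversion stay distinguishable).
    """
    if not records:
        raise ValueError("records must be non-empty")
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {}
    demo_rows, drug_rows, reac_rows, ther_rows = [], [], [], []
    for idx, rec in enumerate(records):
        pid = f"{90_000_000 + idx}"
        demo_rows.append(
            [
                pid,
                rec.caseid,
                str(rec.version),
                rec.fda_dt or "",
                "" if rec.age_value is None else repr(rec.age_value),
                rec.age_unit or "",
                "" if rec.weight_value is None else repr(rec.weight_value),
                rec.weight_unit or "",
                rec.sex or "",
                rec.occupation or "",
                rec.reporter_country or "",
                rec.event_date or "",
            ]
        )
        for seq, drug in enumerate(rec.drugs, start=1):
            drug_rows.append([pid, rec.caseid, str(seq), drug.role, drug.name])
            if drug.start_date is not None:
                ther_rows.append([pid, rec.caseid, str(seq), drug.start_date])
        for pt in rec.reactions:
            reac_rows.append([pid, rec.caseid, pt])

    for name, header, rows in (
        ("DEMO", DEMO_COLUMNS, demo_rows),
        ("DRUG", DRUG_COLUMNS, drug_rows),
        ("REAC", REAC_COLUMNS, reac_rows),
        ("THER", THER_COLUMNS, ther_rows),
    ):
        path = os.path.join(directory, f"{name}.txt")
        with open(path, "w", encoding="ascii") as fh:
            fh.write("$".join(header) + "\n")
            for row in rows:
                fh.write("$".join(row) + "\n")
        paths[name] = path
    return paths
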