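"""Stratified disproportionality by age and body weight.

Reports are partitioned strictly at a cutpoint (below vs at-or-above;
records missing the variable are excluded and counted), and the ROR
arithmetic of the main analysis is applied within each stratum against
the within-stratum non-case background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import DEFAULT_PT_TARGETS, match_miscarriage
from .records import IcsrRecord
from .signals import ContingencyTable, build_contingency, ror

#: drugs with fewer case reports than this are not sub-stratified
#: ("overall signal only" policy for rare drugs)
DEFAULT_MIN_REPORTS_SUBGROUP = 100

#: minimum within-stratum case count to report a stratum estimate
MIN_STRATUM_A = 3


@dataclass
class StratumResult:
    drug: str
    stratum: str
    table: ContingencyTable | None
    ror: float
    ror_lo: float
    ror_hi: float
    p_value: float
    n_reports: int


def stratify(
    cohort: Sequence[IcsrRecord], variable: str, cutpoint: float
) -> tuple[list[IcsrRecord], list[IcsrRecord], int]:
    """Split a cohort at ``cutpoint`` of age (years) or weight (kg).

    Returns (below, at-or-above, n_missing); the boundary value goes to
    the upper stratum.
    """
    if variable == "age":
        getter = IcsrRecord.age_years
    elif variable == "weight":
        getter = IcsrRecord.weight_kg
    else:
        raise ValueError(f"unknown stratification variable {variable!r}")
    below: list[IcsrRecord] = []
    above: list[IcsrRecord] = []
    n_missing = 0
    for rec in cohort:
        v = getter(rec)
        if v is None:
            n_missing += 1
        elif v < cutpoint:
            below.append(rec)
        else:
            above.append(rec)
    return below, above, n_missing


def stratum_signal(
    stratum: Sequence[IcsrRecord],
    drug: str,
    label: str = "",
    pt_targets=DEFAULT_PT_TARGETS,
    min_a: int = MIN_STRATUM_A,
) -> StratumResult:
    """ROR for one drug inside one stratum (within-stratum comparator).

    Cases are the stratum reports matching the miscarriage PTs; the
    comparator is the stratum's non-case remainder.  Fewer than
    ``min_a`` exposed cases (or a drug absent from the stratum) yields
    an undefined-marker row, not an exception.
    """
    cases = [r for r in stratum if match_miscarriage(r, pt_targets)]
    nan = math.nan
    if not stratum:
        return StratumResult(drug, label, None, nan, nan, nan, nan, 0)
    table = build_contingency(cases, list(stratum), drug)
    if table.drug_absent or table.a < min_a:
        return StratumResult(drug, label, table, nan, nan, nan, nan, table.a + table.b)
    est, lo, hi, p = ror(table)
    return StratumResult(drug, label, table, est, lo, hi, p, table.a + table.b)


def analyze_subgroups(
    cohort: Sequence[IcsrRecord],
    drugs: Sequence[str],
    variable: str,
    cutpoint: float,
    pt_targets=DEFAULT_PT_TARGETS,
    min_reports_subgroup: int = DEFAULT_MIN_REPORTS_SUBGROUP,
) -> list[StratumResult]:
    """Per-drug stratified RORs for one variable.

    Drugs whose total case-report count is below ``min_reports_subgroup``
    are skipped (they keep their overall signal only).
    """
    below, above, _ = stratify(cohort, variable, cutpoint)
    labels = (f"<{cutpoint:g}", f">={cutpoint:g}")
    all_cases = [r for r in cohort if match_miscarriage(r, pt_targets)]
    results: list[StratumResult] = []
    for drug in drugs:
        overall = build_contingency(all_cases, list(cohort), drug)
        if overall.a < min_reports_subgroup:
            continue
        for stratum, label in zip((below, above), labels):
            results.append(stratum_signal(stratum, drug, label, pt_targets))
    return results


def compare_strata(results: Sequence[StratumResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy cross-stratum comparison: per drug the log2 ratio of RORs,
    each stratum's -log10 p, and a flag for drugs significant (CI
    excluding 1) in exactly one stratum.

    Drugs undefined in either stratum are excluded from the ratio table
    (they remain in the per-stratum listing).
    """
    by_drug: dict[str, dict[str, StratumResult]] = {}
    for r in results:
        by_drug.setdefault(r.drug, {})[r.stratum] = r
    rows = []
    for drug, strata in sorted(by_drug.items()):
        if len(strata) != 2:
            continue
        (lab1, r1), (lab2, r2) = sorted(strata.items())
        if math.isnan(r1.ror) or math.isnan(r2.ror):
            continue
        sig1 = r1.ror_lo > 1 or r1.ror_hi < 1
        sig2 = r2.ror_lo > 1 or r2.ror_hi < 1
        rows.append(
            {
                "drug": drug,
                "stratum_low": lab1,
                "stratum_high": lab2,
                "ror_low": r1.ror,
                "ror_high": r2.ror,
                "log2_ror_ratio": math.log2(r1.ror / r2.ror),
                "neglog10_p_low": -math.log10(r1.p_value) if r1.p_value > 0 else math.inf,
                "neglog10_p_high": -math.log10(r2.p_value) if r2.p_value > 0 else math.inf,
                "significant_one_stratum_only": sig1 != sig2,
            }
        )
    return pd.DataFrame(rows)


def strata_to_frame(results: Sequence[StratumResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "drug": r.drug,
                "stratum": r.stratum,
                "a": t.a if t else 0,
                "b": t.b if t else 0,
                "c": t.c if t else 0,
                "d": t.d if t else 0,
                "ror": r.ror,
                "ror_lo": r.ror_lo,
                "ror_hi": r.ror_hi,
                "p_value": r.p_value,
                "n_reports": r.n_reports,
            }
        )
    return pd.DataFrame(rows)
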