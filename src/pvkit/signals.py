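"""Disproportionality statistics on 2x2 contingency tables.

For one drug-event pair over a background of spontaneous reports the
table is::

                 target event   other events
    target drug        a             b
    other drugs        c             d

with N = a+b+c+d and E = (a+b)(a+c)/N the count expected in cell *a*
under independence.  Four classical methods are computed:

* **ROR** — reporting odds ratio ``ad/bc`` with a Woolf (log-normal)
  95% interval ``exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
  the Pearson chi-square (df=1, no continuity correction).
* **BCPNN IC** — information component ``log2[(a+0.5)/(E+0.5)]`` with
  the asymptotic lower credibility bound
  ``IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2)``.
* **MGPS EBGM/EB05** — empirical-Bayes geometric mean of the posterior
  relative reporting rate under a two-gamma mixture prior fitted by
  marginal maximum likelihood, and its 5th posterior percentile.

A signal is declared when at least two methods, always including the
ROR, exceed their conventional thresholds.

Zero-cell policy: when any cell is 0 the Haldane-Anscombe correction
(+0.5 on all four cells) is applied to ROR/PRR point estimates and
intervals only; the chi-square is always computed on the raw cells.
Undefined situations (an empty margin) yield NaN markers, never
exceptions, and NaN statistics never flag.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import optimize, special, stats

from .records import IcsrRecord, normalize_drug_name

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.N == 0:
            raise ValueError("table is empty (N = 0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N

    @property
    def drug_absent(self) -> bool:
        return self.a + self.b == 0

    @property
    def event_absent(self) -> bool:
        return self.a + self.c == 0


def build_contingency(
    cases: Sequence[IcsrRecord],
    background: Sequence[IcsrRecord],
    drug: str,
) -> ContingencyTable:
    """Count the 2x2 for one (normalized) drug as primary suspect.

    ``cases`` must be a subset of ``background``; exposure means the
    drug appears with role PS on the report.
    """
    target = normalize_drug_name(drug)

    def exposed(rec: IcsrRecord) -> bool:
        return any(normalize_drug_name(d.name) == target for d in rec.ps_drugs())

    case_ids = {r.caseid for r in cases}
    a = sum(1 for r in cases if exposed(r))
    c = len(cases) - a
    b = sum(1 for r in background if r.caseid not in case_ids and exposed(r))
    d = len(background) - len(cases) - b
    table = ContingencyTable(a, b, c, d)
    if table.drug_absent:
        logger.warning("drug %r absent from background (a+b=0)", drug)
    return table


def build_all_tables(
    cases: Sequence[IcsrRecord],
    background: Sequence[IcsrRecord],
    drugs: Sequence[str],
) -> dict[str, ContingencyTable]:
    """Single-pass equivalent of ``build_contingency`` over many drugs."""
    targets = {normalize_drug_name(d): d for d in drugs}
    case_ids = {r.caseid for r in cases}
    n_cases, n_background = len(cases), len(background)
    a_counts = dict.fromkeys(targets, 0)
    b_counts = dict.fromkeys(targets, 0)
    for rec in background:
        is_case = rec.caseid in case_ids
        seen = {normalize_drug_name(d.name) for d in rec.ps_drugs()}
        for norm in seen:
            if norm in targets:
                if is_case:
                    a_counts[norm] += 1
                else:
                    b_counts[norm] += 1
    out = {}
    for norm, original in targets.items():
        a, b = a_counts[norm], b_counts[norm]
        out[original] = ContingencyTable(
            a, b, n_cases - a, n_background - n_cases - b
        )
    return out


# ---------------------------------------------------------------------------
# frequentist methods
# ---------------------------------------------------------------------------


class RorResult(NamedTuple):
    estimate: float
    ci_lo: float
    ci_hi: float
    p_value: float


class PrrResult(NamedTuple):
    estimate: float
    chi2: float
    p_value: float


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float]:
    cells = (t.a, t.b, t.c, t.d)
    if 0 in cells:
        return tuple(v + 0.5 for v in cells)  # type: ignore[return-value]
    return tuple(float(v) for v in cells)  # type: ignore[return-value]


def pearson_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (df=1, uncorrected) and its p-value on raw cells."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.N
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan, math.nan
    chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


def ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio with Woolf 95% CI and chi-square p-value."""
    if table.drug_absent or table.event_absent:
        return RorResult(math.nan, math.nan, math.nan, math.nan)
    a, b, c, d = _corrected_cells(table)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    _, p = pearson_chi2(table)
    return RorResult(est, est * math.exp(-_Z95 * se), est * math.exp(_Z95 * se), p)


def prr(table: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio with Pearson chi-square."""
    if table.drug_absent or table.event_absent:
        chi2, p = pearson_chi2(table)
        return PrrResult(math.nan, chi2, p)
    a, b, c, d = _corrected_cells(table)
    if c + d == 0:
        return PrrResult(math.nan, math.nan, math.nan)
    est = (a / (a + b)) / (c / (c + d))
    chi2, p = pearson_chi2(table)
    return PrrResult(est, chi2, p)


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------


class IcResult(NamedTuple):
    ic: float
    ic025: float


def bcpnn_ic(table: ContingencyTable) -> IcResult:
    """Closed-form IC with 0.5 continuity terms and asymptotic lower bound."""
    if table.drug_absent or table.event_absent:
        return IcResult(math.nan, math.nan)
    a_star = table.a + 0.5
    ic = math.log2(a_star / (table.E + 0.5))
    ic025 = ic - 3.3 * a_star ** -0.5 - 2.0 * a_star ** -1.5
    return IcResult(ic, ic025)


# ---------------------------------------------------------------------------
# MGPS: two-gamma mixture prior and posterior summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GpsPrior:
    """Hyperparameters of the two-gamma mixture prior on the relative
    reporting rate lambda: P Ga(alpha1, beta1) + (1-P) Ga(alpha2, beta2)
    (shape/rate parameterization)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixture weight p must be in [0, 1]")


#: customary initialization for gamma-Poisson shrinkage fits
DEFAULT_GPS_PRIOR = GpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p=1.0 / 3.0)


class GpsFitError(RuntimeError):
    def __init__(self, message: str, best_prior: GpsPrior, diagnostics: dict):
        super().__init__(message)
        self.best_prior = best_prior
        self.diagnostics = diagnostics


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # marginal of Poisson(lambda*E) with Ga(alpha, beta) prior on lambda:
    # NB with size alpha and success prob beta/(beta+E)
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    p = special.expit(theta[4])
    l1 = _nb_logpmf(a, a1, b1, e) + np.log(p + 1e-300)
    l2 = _nb_logpmf(a, a2, b2, e) + np.log(1 - p + 1e-300)
    return float(np.logaddexp(l1, l2).sum())


def fit_gps_prior(
    tables: Iterable[ContingencyTable],
    init: GpsPrior = DEFAULT_GPS_PRIOR,
    n_restarts: int = 5,
    seed: int = 0,
    min_tables: int = 50,
) -> GpsPrior:
    """Fit the mixture prior by maximizing the marginal likelihood of the
    observed a-counts given their expected counts.

    Uses bounded quasi-Newton (L-BFGS-B) on log-transformed gamma
    parameters (logit for the weight), with random restarts jittered
    around the documented initialization.  Fewer than ``min_tables``
    usable tables returns the default prior with a warning.
    """
    usable = [(t.a, t.E) for t in tables if t.E > 0]
    if len(usable) < min_tables:
        warnings.warn(
            f"only {len(usable)} tables with E > 0 (< {min_tables}); "
            "returning default prior",
            stacklevel=2,
        )
        return init
    a = np.array([u[0] for u in usable], dtype=float)
    e = np.array([u[1] for u in usable], dtype=float)

    theta0 = np.array(
        [
            math.log(init.alpha1),
            math.log(init.beta1),
            math.log(init.alpha2),
            math.log(init.beta2),
            special.logit(init.p),
        ]
    )
    rng = np.random.default_rng(seed)
    best = None
    diagnostics: dict = {"restarts": []}
    for r in range(n_restarts + 1):
        start = theta0 if r == 0 else theta0 + rng.normal(0, 0.5, size=5)
        res = optimize.minimize(
            lambda th: -_mixture_loglik(th, a, e),
            start,
            method="L-BFGS-B",
            bounds=[(-10, 10)] * 4 + [(-12, 12)],
            options={"ftol": 1e-8 / max(abs(_mixture_loglik(start, a, e)), 1.0), "maxiter": 500},
        )
        diagnostics["restarts"].append({"fun": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    a1, b1, a2, b2 = np.exp(best.x[:4])
    prior = GpsPrior(float(a1), float(b1), float(a2), float(b2), float(special.expit(best.x[4])))
    if not any(d["success"] for d in diagnostics["restarts"]):
        raise GpsFitError("MGPS prior fit did not converge", prior, diagnostics)
    return prior


class EbgmResult(NamedTuple):
    ebgm: float
    eb05: float


def ebgm(table: ContingencyTable, prior: GpsPrior = DEFAULT_GPS_PRIOR) -> EbgmResult:
    """Posterior EBGM and EB05 under the fitted mixture prior.

    The posterior on lambda is ``Q Ga(alpha1+a, beta1+E) +
    (1-Q) Ga(alpha2+a, beta2+E)`` with Q the posterior component weight;
    EBGM is the geometric mean ``2^{E[log2 lambda]}`` and EB05 the 5th
    percentile found by monotone root-finding on the posterior CDF.
    """
    e = table.E
    if e <= 0:
        return EbgmResult(math.nan, math.nan)
    a = table.a
    # posterior weight via the marginal NB likelihood of each component
    if prior.p in (0.0, 1.0):
        q = prior.p
    else:
        l1 = math.log(prior.p) + float(_nb_logpmf(np.array([a]), prior.alpha1, prior.beta1, np.array([e]))[0])
        l2 = math.log(1 - prior.p) + float(_nb_logpmf(np.array([a]), prior.alpha2, prior.beta2, np.array([e]))[0])
        q = math.exp(l1 - np.logaddexp(l1, l2))
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    mean_log = q * (special.digamma(s1) - math.log(r1)) + (1 - q) * (
        special.digamma(s2) - math.log(r2)
    )
    geo_mean = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    hi = max(stats.gamma.ppf(0.999, s1, scale=1 / r1), stats.gamma.ppf(0.999, s2, scale=1 / r2))
    lo = 1e-12
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-8, rtol=1e-12))
    return EbgmResult(geo_mean, eb05)


# ---------------------------------------------------------------------------
# thresholds, consensus, multiplicity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalThresholds:
    """Conventional per-method signal criteria, all configurable."""

    ror_min_count: int = 3
    ror_ci_lo: float = 1.0
    prr_min: float = 2.0
    prr_chi2_min: float = 4.0
    prr_min_count: int = 3
    ic025_min: float = 0.0
    eb05_min: float = 2.0


DEFAULT_THRESHOLDS = SignalThresholds()


@dataclass
class SignalResult:
    drug: str
    table: ContingencyTable
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    eb05: float = math.nan
    p_value: float = math.nan
    q_value: float = math.nan
    flags: dict[str, bool] = field(default_factory=dict)
    consensus: bool = False


def apply_thresholds(
    result: SignalResult, thresholds: SignalThresholds = DEFAULT_THRESHOLDS
) -> SignalResult:
    """Set per-method flags and the >=2-method (ROR-anchored) consensus.

    NaN statistics never flag.  The consensus requires the ROR criterion
    plus at least one of the other three.
    """
    t = result.table
    flags = {
        "ror": bool(
            t.a >= thresholds.ror_min_count
            and not math.isnan(result.ror_lo)
            and result.ror_lo > thresholds.ror_ci_lo
        ),
        "prr": bool(
            t.a >= thresholds.prr_min_count
            and not math.isnan(result.prr)
            and result.prr >= thresholds.prr_min
            and not math.isnan(result.chi2)
            and result.chi2 >= thresholds.prr_chi2_min
        ),
        "bcpnn": bool(not math.isnan(result.ic025) and result.ic025 > thresholds.ic025_min),
        "mgps": bool(not math.isnan(result.eb05) and result.eb05 >= thresholds.eb05_min),
    }
    result.flags = flags
    result.consensus = flags["ror"] and (flags["prr"] or flags["bcpnn"] or flags["mgps"])
    return result


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserving).

    ``q_i = min_{j >= rank(i)} m p_(j) / j``, capped at 1.  NaN inputs
    propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, math.nan)
    pf = p[finite]
    m = pf.size
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[finite] = out
    return q


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def screen_signals(
    cases: Sequence[IcsrRecord],
    background: Sequence[IcsrRecord],
    drugs: Sequence[str] | None = None,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    prior: GpsPrior | None = None,
    min_case_count: int = 1,
    seed: int = 0,
) -> list[SignalResult]:
    """Run all four methods plus consensus and BH-FDR for every drug.

    When ``drugs`` is None the screening universe is every PS drug with
    at least ``min_case_count`` case reports.  The MGPS prior, unless
    supplied, is fitted on the full universe of drug-event tables.
    """
    if drugs is None:
        counts: dict[str, int] = {}
        for rec in cases:
            for d in {normalize_drug_name(x.name) for x in rec.ps_drugs()}:
                counts[d] = counts.get(d, 0) + 1
        drugs = sorted(d for d, cnt in counts.items() if cnt >= min_case_count)

    tables = build_all_tables(cases, background, drugs)
    if prior is None:
        try:
            prior = fit_gps_prior(tables.values(), seed=seed)
        except GpsFitError as exc:
            logger.warning("MGPS prior fit failed (%s); using best-so-far", exc)
            prior = exc.best_prior

    results = []
    for d in drugs:
        t = tables[d]
        res = SignalResult(drug=d, table=t)
        res.ror, res.ror_lo, res.ror_hi, res.p_value = ror(t)
        res.prr, res.chi2, _ = prr(t)
        res.ic, res.ic025 = bcpnn_ic(t)
        res.ebgm, res.eb05 = ebgm(t, prior)
        apply_thresholds(res, thresholds)
        results.append(res)
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def signals_to_frame(results: Sequence[SignalResult]):
    """Tidy one-row-per-drug DataFrame of all statistics and flags."""
    import pandas as pd

    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "drug": r.drug,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "expected": t.E,
                "ror": r.ror,
                "ror_lo": r.ror_lo,
                "ror_hi": r.ror_hi,
                "prr": r.prr,
                "chi2": r.chi2,
                "ic": r.ic,
                "ic025": r.ic025,
                "ebgm": r.ebgm,
                "eb05": r.eb05,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "flag_ror": r.flags.get("ror", False),
                "flag_prr": r.flags.get("prr", False),
                "flag_bcpnn": r.flags.get("bcpnn", False),
                "flag_mgps": r.flags.get("mgps", False),
                "consensus": r.consensus,
            }
        )
    return pd.DataFrame(rows)
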