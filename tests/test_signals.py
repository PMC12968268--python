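import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from pvkit.signals import (
    DEFAULT_GPS_PRIOR,
    ContingencyTable,
    GpsPrior,
    SignalResult,
    apply_thresholds,
    bcpnn_ic,
    bh_fdr,
    build_all_tables,
    build_contingency,
    ebgm,
    fit_gps_prior,
    prr,
    ror,
    screen_signals,
)
from pvkit.io import deduplicate, filter_cohort
from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_or_by_expansion(a, b, c, d):
    """Cross-product odds ratio via literal expansion into unit records."""
    units = (
        [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d
    )  # (exposed, case)
    n11 = sum(1 for e, y in units if e and y)
    n10 = sum(1 for e, y in units if e and not y)
    n01 = sum(1 for e, y in units if not e and y)
    n00 = sum(1 for e, y in units if not e and not y)
    return (n11 * n00) / (n10 * n01)


def oracle_chi2(a, b, c, d):
    """Textbook Pearson statistic: sum over 4 cells of (O-E)^2/E."""
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if 0 in rows or 0 in cols:
        return math.nan
    total = 0.0
    for (i, j), obs in (((0, 0), a), ((0, 1), b), ((1, 0), c), ((1, 1), d)):
        exp = rows[i] * cols[j] / n
        total += (obs - exp) ** 2 / exp
    return total


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def test_table_invariants():
    t = ContingencyTable(2, 1, 0, 1)
    assert t.N == 4
    assert t.E == pytest.approx(3 * 2 / 4)
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 1)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 0)


def test_build_contingency_toy_cohort():
    exposed_case = [
        make_record(caseid=str(i), drugs=(("DRUG X", "PS", None),)) for i in range(2)
    ]
    exposed_noncase = [
        make_record(caseid="10", drugs=(("DRUG X", "PS", None),), reactions=["HEADACHE"])
    ]
    unexposed_noncase = [
        make_record(caseid="11", drugs=(("DRUG Y", "PS", None),), reactions=["HEADACHE"])
    ]
    background = exposed_case + exposed_noncase + unexposed_noncase
    t = build_contingency(exposed_case, background, "DRUG X")
    assert (t.a, t.b, t.c, t.d) == (2, 1, 0, 1)


def test_build_contingency_matches_brute_force_scan(planted_cohort):
    cfg, records, _ = planted_cohort
    cases, background = filter_cohort(deduplicate(records))
    drug = cfg.drugs[0].name
    t = build_contingency(cases, background, drug)
    # brute force recount
    def exposed(r):
        return any(d.name == drug and d.role == "PS" for d in r.drugs)

    case_ids = {r.caseid for r in cases}
    a = sum(exposed(r) for r in cases)
    b = sum(exposed(r) for r in background if r.caseid not in case_ids)
    assert (t.a, t.b) == (a, b)
    assert t.N == len(background)
    assert build_all_tables(cases, background, [drug])[drug] == t


def test_drug_absent_table_flagged():
    t = ContingencyTable(0, 0, 5, 5)
    assert t.drug_absent
    assert math.isnan(ror(t).estimate)
    assert math.isnan(prr(t).estimate)
    assert math.isnan(bcpnn_ic(t).ic)


# ---------------------------------------------------------------------------
# ROR / PRR / chi2
# ---------------------------------------------------------------------------


def test_ror_hand_values():
    est, lo, hi, p = ror(ContingencyTable(10, 90, 100, 9900))
    assert est == pytest.approx(11.0)
    est, lo, hi, _ = ror(ContingencyTable(10, 10, 10, 10))
    assert est == pytest.approx(1.0)
    assert lo == pytest.approx(math.exp(-1.959963984540054 * math.sqrt(0.4)), rel=1e-6)
    assert hi == pytest.approx(math.exp(1.959963984540054 * math.sqrt(0.4)), rel=1e-6)


def test_zero_cell_policy_haldane_correction():
    est, lo, hi, p = ror(ContingencyTable(0, 5, 3, 1000))
    expected = (0.5 * 1000.5) / (5.5 * 3.5)
    assert est == pytest.approx(expected)
    assert math.isfinite(est) and math.isfinite(lo) and math.isfinite(hi)
    # a genuine reporting deficit does come out below 1
    assert ror(ContingencyTable(0, 1000, 50, 1000)).estimate < 1
    # chi-square stays on the raw cells
    assert prr(ContingencyTable(0, 5, 3, 1000)).chi2 == pytest.approx(
        oracle_chi2(0, 5, 3, 1000)
    )


def test_prr_hand_values():
    assert prr(ContingencyTable(10, 90, 100, 9900)).estimate == pytest.approx(10.0)
    res = prr(ContingencyTable(5, 45, 50, 450))
    assert res.estimate == pytest.approx(1.0)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_grid_oracle_equivalence_small_tables():
    """ROR, PRR, chi-square and IC match independent evaluation on an
    exhaustive grid of tables with cells <= 6."""
    for a, b, c, d in itertools.product(range(7), repeat=4):
        if a + b + c + d == 0:
            continue
        t = ContingencyTable(a, b, c, d)
        chi2 = prr(t).chi2
        oc = oracle_chi2(a, b, c, d)
        assert (math.isnan(chi2) and math.isnan(oc)) or chi2 == pytest.approx(oc, abs=1e-9)
        if min(a, b, c, d) > 0 and not (t.drug_absent or t.event_absent):
            assert ror(t).estimate == pytest.approx(oracle_or_by_expansion(a, b, c, d))
            assert prr(t).estimate == pytest.approx((a / (a + b)) / (c / (c + d)))
        if not (t.drug_absent or t.event_absent):
            assert bcpnn_ic(t).ic == pytest.approx(math.log2((a + 0.5) / (t.E + 0.5)))


def test_chi2_matches_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a, b, c, d = rng.integers(1, 13, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        expected = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert prr(t).chi2 == pytest.approx(expected.statistic)
        assert ror(t).p_value == pytest.approx(expected.pvalue)


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------


def test_ic_zero_when_observed_equals_expected():
    # (a,b,c,d) = (8,8,8,8): E = 16*16/32 = 8 = a
    t = ContingencyTable(8, 8, 8, 8)
    assert bcpnn_ic(t).ic == pytest.approx(0.0)


def test_ic_hand_value_at_e_one():
    t = ContingencyTable(10, 90, 0, 900)  # E = 100*10/1000 = 1
    ic, ic025 = bcpnn_ic(t)
    assert ic == pytest.approx(math.log2(10.5 / 1.5), abs=1e-9)
    assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(10.5) - 2 / 10.5**1.5, abs=1e-9)
    assert ic025 == pytest.approx(1.7302, abs=1e-4)


def test_ic_negative_when_zero_observed():
    t = ContingencyTable(0, 40, 50, 910)  # E = 40*50/1000 = 2
    assert bcpnn_ic(t).ic < 0


# ---------------------------------------------------------------------------
# MGPS
# ---------------------------------------------------------------------------


def test_gps_prior_validation():
    with pytest.raises(ValueError):
        GpsPrior(0.0, 1.0, 1.0, 1.0, 0.5)
    with pytest.raises(ValueError):
        GpsPrior(1.0, 1.0, 1.0, 1.0, 1.5)


def test_negative_binomial_marginal_closed_form():
    """Single component alpha=beta=1, E=1: P(a=0) = (beta/(beta+E))^alpha = 0.5."""
    from pvkit.signals import _nb_logpmf

    mass = math.exp(float(_nb_logpmf(np.array([0]), 1.0, 1.0, np.array([1.0]))[0]))
    assert mass == pytest.approx(0.5, abs=1e-12)


def test_gps_fit_falls_back_on_tiny_input():
    with pytest.warns(UserWarning, match="default prior"):
        prior = fit_gps_prior([ContingencyTable(1, 1, 1, 1)])
    assert prior == DEFAULT_GPS_PRIOR


def test_ebgm_closed_form_single_component():
    t = ContingencyTable(5, 95, 95, 9805)  # E = 1 exactly
    res = ebgm(t, GpsPrior(1.0, 1.0, 1.0, 1.0, 1.0))
    assert res.ebgm == pytest.approx(math.exp(special.digamma(6) - math.log(2)), abs=1e-6)
    assert res.eb05 == pytest.approx(stats.gamma.ppf(0.05, 6) / 2, abs=1e-6)


def test_ebgm_shrinkage_vanishes_for_large_counts():
    # a=1000, E=100: shrinkage is negligible, EBGM within 5% of a/E = 10
    t = ContingencyTable(1000, 9000, 9000, 981000)
    assert t.E == pytest.approx(100.0)
    res = ebgm(t, DEFAULT_GPS_PRIOR)
    assert res.ebgm == pytest.approx(10.0, rel=0.05)


def test_ebgm_monotone_in_a_and_ordering():
    prior = DEFAULT_GPS_PRIOR
    last = -math.inf
    for a in (1, 3, 10, 30, 100):
        t = ContingencyTable(a, 1000 - a, 2000, 97000)
        res = ebgm(t, prior)
        assert res.eb05 < res.ebgm
        assert res.ebgm > last
        last = res.ebgm
    ic_res = bcpnn_ic(ContingencyTable(20, 80, 100, 9800))
    assert ic_res.ic025 < ic_res.ic


def test_large_count_consistency_all_methods():
    """On tables with all cells >= 1000 drawn at true RR r, all four point
    statistics land within 10% of r."""
    rng = np.random.default_rng(99)
    r_true = 3.0
    n_exposed, n_unexposed = 20_000, 2_000_000  # rare exposure, rare event
    p0 = 0.02
    a = int(rng.binomial(n_exposed, p0 * r_true))
    c = int(rng.binomial(n_unexposed, p0))
    t = ContingencyTable(a, n_exposed - a, c, n_unexposed - c)
    assert min(t.a, t.b, t.c, t.d) >= 1000
    assert ror(t).estimate == pytest.approx(r_true, rel=0.1)
    assert prr(t).estimate == pytest.approx(r_true, rel=0.1)
    assert 2 ** bcpnn_ic(t).ic == pytest.approx(r_true, rel=0.1)
    assert ebgm(t, DEFAULT_GPS_PRIOR).ebgm == pytest.approx(r_true, rel=0.1)


# ---------------------------------------------------------------------------
# thresholds and consensus
# ---------------------------------------------------------------------------


def _result(a=10, ror_lo=2.0, prr_val=3.0, chi2=10.0, ic025=1.0, eb05=3.0):
    t = ContingencyTable(a, 100, 50, 5000)
    res = SignalResult(drug="X", table=t, ror=3.0, ror_lo=ror_lo, ror_hi=4.0,
                       prr=prr_val, chi2=chi2, ic=1.5, ic025=ic025, ebgm=3.5, eb05=eb05)
    return apply_thresholds(res)


def test_consensus_requires_ror_plus_one():
    res = _result(ic025=1.0, prr_val=0.5, chi2=1.0, eb05=0.5)
    assert res.flags == {"ror": True, "prr": False, "bcpnn": True, "mgps": False}
    assert res.consensus


def test_consensus_false_without_ror_flag():
    res = _result(ror_lo=0.8)  # PRR and MGPS flag, ROR does not
    assert res.flags["prr"] and res.flags["mgps"] and not res.flags["ror"]
    assert not res.consensus


def test_minimum_count_gate_blocks_huge_ror():
    res = _result(a=2)
    assert not res.flags["ror"] and not res.consensus


def test_undefined_statistics_never_flag():
    t = ContingencyTable(0, 0, 5, 100)
    res = SignalResult(drug="X", table=t)
    res = apply_thresholds(res)
    assert not any(res.flags.values()) and not res.consensus


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------


def test_bh_hand_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
def test_bh_matches_statsmodels_step_up(pvals):
    from statsmodels.stats.multitest import multipletests

    ours = bh_fdr(pvals)
    _, theirs, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(ours, theirs, atol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
def test_bh_matches_literal_step_up_definition(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    expected = [math.nan] * m
    for rank_pos, i in enumerate(order):
        q = min(
            m * pvals[order[j]] / (j + 1) for j in range(rank_pos, m)
        )
        expected[i] = min(q, 1.0)
    assert np.allclose(bh_fdr(pvals), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def test_screen_signals_flags_planted_drug(planted_cohort):
    cfg, records, _ = planted_cohort
    cases, background = filter_cohort(deduplicate(records))
    results = screen_signals(
        cases, background, drugs=[d.name for d in cfg.drugs], prior=DEFAULT_GPS_PRIOR
    )
    by_drug = {r.drug: r for r in results}
    planted = by_drug["PLANTED DRUG"]
    assert planted.consensus
    assert planted.q_value < 0.05
    assert planted.ror == pytest.approx(4.0, rel=0.35)
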