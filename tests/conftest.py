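import pytest

from pvkit.records import DrugEntry, IcsrRecord
from pvkit.synthetic import DrugSpec, SyntheticConfig, generate_cohort


def make_record(
    caseid="100",
    version=1,
    fda_dt="20200115",
    drugs=(("ADALIMUMAB", "PS", "20200101"),),
    reactions=("ABORTION SPONTANEOUS",),
    age=30.0,
    weight=65.0,
    occupation="MD",
    country="US",
    event_date="20200301",
    sex="F",
):
    """Terse builder for hand fixtures."""
    return IcsrRecord(
        caseid=caseid,
        version=version,
        fda_dt=fda_dt,
        age_value=age,
        age_unit="YR" if age is not None else None,
        weight_value=weight,
        weight_unit="KG" if weight is not None else None,
        sex=sex,
        occupation=occupation,
        reporter_country=country,
        drugs=[DrugEntry(n, r, s) for n, r, s in drugs],
        reactions=list(reactions),
        event_date=event_date,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """20k-report cohort with one RR=4 drug and three null drugs."""
    cfg = SyntheticConfig(
        n_reports=20_000,
        drugs=[DrugSpec("PLANTED DRUG", use_prob=0.08, injected_rr=4.0)]
        + [DrugSpec(f"NULL DRUG {i}", use_prob=0.08, injected_rr=1.0) for i in range(3)],
        event_base_rate=0.02,
        duplicate_rate=0.15,
        seed=11,
    )
    records, truth = generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Duplicate-free cohort for exposure bookkeeping checks."""
    cfg = SyntheticConfig(
        n_reports=10_000,
        drugs=[
            DrugSpec("DRUG ALPHA", use_prob=0.10, injected_rr=2.0),
            DrugSpec("DRUG BETA", use_prob=0.05, injected_rr=1.0),
        ],
        event_base_rate=0.05,
        duplicate_rate=0.0,
        seed=23,
    )
    records, truth = generate_cohort(cfg)
    return cfg, records, truth
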