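import math

import numpy as np
import pytest

from pvkit.risk import (
    FeatureMatrix,
    auc,
    build_feature_matrix,
    cross_validate,
    gain_importance,
    select_top_drugs,
    shap_ranking,
    train_booster,
)
from conftest import make_record


# ---------------------------------------------------------------------------
# drug selection and matrix construction
# ---------------------------------------------------------------------------


def test_select_top_drugs_matches_brute_force(clean_cohort):
    cfg, records, truth = clean_cohort
    top = select_top_drugs(records, k=2)
    # brute force recount
    counts = {}
    for r in records:
        for name in {d.name for d in r.drugs if d.role == "PS"}:
            counts[name] = counts.get(name, 0) + 1
    expected = sorted(counts, key=lambda n: (-counts[n], n))[:2]
    assert top == expected
    assert top[0] == "DRUG ALPHA"  # highest use_prob


def test_select_top_drugs_k_larger_than_universe(caplog):
    recs = [make_record(drugs=(("ONLY DRUG", "PS", None),))]
    with caplog.at_level("WARNING"):
        top = select_top_drugs(recs, k=5)
    assert top == ["ONLY DRUG"]
    assert "available" in caplog.text


def test_select_top_drugs_tie_breaks_lexicographically():
    recs = [
        make_record(caseid="1", drugs=(("ZETA", "PS", None),)),
        make_record(caseid="2", drugs=(("ALPHA", "PS", None),)),
    ]
    assert select_top_drugs(recs, k=2) == ["ALPHA", "ZETA"]


def test_feature_matrix_hand_fixture():
    recs = [
        make_record(caseid="1", drugs=(("A", "PS", None),), reactions=["ABORTION"]),
        make_record(caseid="2", drugs=(("A", "PS", None), ("B", "PS", None)),
                    reactions=["HEADACHE"]),
        make_record(caseid="3", drugs=(("C", "PS", None),), reactions=["ABORTION"]),
    ]
    m = build_feature_matrix(recs, ["A", "B"])
    assert m.X.tolist() == [[1.0, 0.0], [1.0, 1.0]]
    assert m.y.tolist() == [1, 0]
    assert m.n_dropped_all_zero == 1  # the C-only report


def test_feature_matrix_column_sums_match_ground_truth(clean_cohort):
    cfg, records, truth = clean_cohort
    drugs = [d.name for d in cfg.drugs]
    m = build_feature_matrix(records, drugs)
    for j, d in enumerate(drugs):
        assert int(m.X[:, j].sum()) == truth.n_exposed[d]


def test_empty_matrix_rejected():
    recs = [make_record(drugs=(("A", "PS", None),))]
    with pytest.raises(ValueError):
        build_feature_matrix(recs, ["UNSEEN DRUG"])


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def test_auc_hand_value():
    assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)


def test_auc_pure_ties_and_symmetry():
    assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)
    scores = [0.9, 0.2, 0.7, 0.4, 0.4]
    labels = [1, 0, 1, 0, 1]
    assert auc(scores, labels) == pytest.approx(1 - auc(scores, [1 - y for y in labels]))


def test_auc_single_class_undefined():
    assert math.isnan(auc([0.1, 0.2], [1, 1]))


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.integers(0, 2, size=50)
        if len(np.unique(y)) < 2:
            continue
        s = rng.choice([0.1, 0.3, 0.5, 0.7], size=50)  # ties included
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _random_matrix(n, k, p_outcome, seed, informative=False):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, k)) < 0.3).astype(np.float32)
    if k > 1:
        X[X.sum(axis=1) == 0, 0] = 1.0
    if informative:
        y = X[:, 0].astype(np.int32)
    else:
        y = (rng.random(n) < p_outcome).astype(np.int32)
    return FeatureMatrix(X=X, y=y, caseids=[str(i) for i in range(n)],
                         drugs=[f"D{j}" for j in range(k)])


def test_separable_matrix_gives_perfect_auc():
    m = _random_matrix(2_000, 3, 0.5, seed=1, informative=True)
    metrics = cross_validate(m, n_folds=5, seed=0)
    assert metrics.mean_auc == pytest.approx(1.0, abs=1e-9)


def test_null_matrix_auc_near_half():
    m = _random_matrix(20_000, 5, 0.2, seed=2)
    metrics = cross_validate(m, n_folds=5, seed=0)
    assert 0.45 <= metrics.mean_auc <= 0.55


def test_cross_validate_deterministic_and_partitioned():
    m = _random_matrix(1_000, 4, 0.3, seed=3, informative=True)
    m1 = cross_validate(m, n_folds=5, seed=9)
    m2 = cross_validate(m, n_folds=5, seed=9)
    assert m1.fold_aucs == m2.fold_aucs
    assert m1.accuracy == m2.accuracy
    assert np.array_equal(m1.fold_assignments, m2.fold_assignments)
    # every row in exactly one test fold, folds cover all rows
    assert set(np.unique(m1.fold_assignments)) == set(range(5))
    assert m1.fold_assignments.size == 1_000


def test_single_class_outcome_rejected():
    m = _random_matrix(100, 2, 0.0, seed=4)
    m.y[:] = 0
    with pytest.raises(ValueError, match="both outcome classes"):
        cross_validate(m)


# ---------------------------------------------------------------------------
# explainability
# ---------------------------------------------------------------------------


def test_shap_additivity_and_single_feature_rank():
    m = _random_matrix(1_000, 1, 0.3, seed=5, informative=True)
    booster = train_booster(m, seed=0)
    ranking = shap_ranking(booster, m)  # additivity enforced internally
    assert ranking.iloc[0]["drug"] == "D0"
    assert ranking.iloc[0]["rank"] == 1


def test_shap_planted_signal_ranks_first():
    rng = np.random.default_rng(6)
    n, k = 30_000, 6
    X = (rng.random((n, k)) < 0.3).astype(np.float32)
    X[X.sum(axis=1) == 0, 1] = 1.0
    p = np.where(X[:, 0] == 1, 0.10, 0.02)  # drug 0 carries RR 5
    y = (rng.random(n) < p).astype(np.int32)
    m = FeatureMatrix(X=X, y=y, caseids=[str(i) for i in range(n)],
                      drugs=[f"D{j}" for j in range(k)])
    booster = train_booster(m, seed=0)
    assert shap_ranking(booster, m).iloc[0]["drug"] == "D0"
    gain = gain_importance(booster)
    assert gain.iloc[0]["drug"] == "D0"


def test_shap_feature_mismatch_rejected():
    m1 = _random_matrix(500, 2, 0.3, seed=7, informative=True)
    m2 = _random_matrix(500, 3, 0.3, seed=8, informative=True)
    booster = train_booster(m1, seed=0)
    with pytest.raises(ValueError, match="match"):
        shap_ranking(booster, m2)


def test_gain_importance_single_and_unused_feature():
    m = _random_matrix(1_000, 1, 0.3, seed=9, informative=True)
    booster = train_booster(m, seed=0)
    gain = gain_importance(booster)
    assert gain["gain_share"].iloc[0] == pytest.approx(1.0)

    # add a constant (hence unused) second feature
    X = np.hstack([m.X, np.zeros((1_000, 1), dtype=np.float32)])
    m2 = FeatureMatrix(X=X, y=m.y, caseids=m.caseids, drugs=["D0", "UNUSED"])
    booster2 = train_booster(m2, seed=0)
    gain2 = gain_importance(booster2).set_index("drug")
    assert gain2.loc["UNUSED", "gain_share"] == 0.0
    assert gain2.loc["D0", "gain_share"] == pytest.approx(1.0)
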