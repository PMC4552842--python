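"""Molecular score, ROC/AUC, threshold derivation, and grade prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from ckdms import (
    DataError,
    GradeThresholds,
    MolecularScoreClassifier,
    ParameterError,
    compute_fold_change,
    derive_thresholds,
    generate_cohort,
    grade_dichotomization_auc,
    molecular_score,
    predict_grade_category,
    roc_auc,
    validate_cohort,
)
from ckdms.scoring import MolecularScore

from conftest import clean_params, fc_from_ratios, null_params


def _score_fc(ratio_rows, genes=("G1",), probes_per_gene=None):
    """Build a FoldChangeProfile + annotation from per-probe ratio lists."""
    n_probes = len(ratio_rows)
    probes = [f"m{i}" for i in range(n_probes)]
    n_samples = len(ratio_rows[0])
    ratios = pd.DataFrame(
        np.asarray(ratio_rows, dtype=float),
        index=probes,
        columns=[f"s{i}" for i in range(n_samples)],
    )
    if probes_per_gene is None:
        gene_of = {p: genes[i % len(genes)] for i, p in enumerate(probes)}
    else:
        gene_of = dict(zip(probes, probes_per_gene))
    annotation = pd.Series(gene_of)
    return fc_from_ratios(ratios), annotation


# --- molecular score ----------------------------------------------------------

def test_unit_fold_changes_give_score_one():
    fc, ann = _score_fc([[1.0], [1.0], [1.0]])
    score = molecular_score(fc, ann, ("G1",))
    assert score.scores.iloc[0] == pytest.approx(1.0)


def test_two_probe_closed_form():
    fc, ann = _score_fc([[2.0], [8.0]])
    score = molecular_score(fc, ann, ("G1",))
    assert score.scores.iloc[0] == pytest.approx(4.0)


def test_five_probe_log_domain_oracle():
    values = [1.5, 2.0, 4.0, 0.5, 3.0]
    fc, ann = _score_fc([[v] for v in values])
    score = molecular_score(fc, ann, ("G1",))
    oracle = float(np.prod(values) ** (1 / 5))  # product-root form
    assert score.scores.iloc[0] == pytest.approx(oracle, abs=1e-12)


def test_marker_gene_without_detectable_probe_is_named():
    fc, ann = _score_fc([[2.0], [3.0]], probes_per_gene=["G1", "G2"])
    fc.detectable.loc["m1"] = False  # G2's only probe
    with pytest.raises(DataError, match="G2"):
        molecular_score(fc, ann, ("G1", "G2"))


def test_all_marker_probes_are_used(small_cohort, small_fold_change):
    score = molecular_score(small_fold_change, small_cohort.annotation)
    assert set(score.marker_probes) == small_cohort.truth.marker_probe_ids


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=10_000),
    st.floats(min_value=0.01, max_value=100.0),
)
def test_score_homogeneity(seed, c):
    rng = np.random.default_rng(seed)
    rows = rng.lognormal(0, 1, size=(4, 3))
    fc, ann = _score_fc(rows.tolist())
    base = molecular_score(fc, ann, ("G1",)).scores
    fc2, _ = _score_fc((rows * c).tolist())
    scaled = molecular_score(fc2, ann, ("G1",)).scores
    assert np.allclose(scaled, c * base, rtol=1e-9)


# --- ROC / AUC -----------------------------------------------------------------

def _pairwise_auc(scores, labels):
    """Exhaustive positive-negative pair counting, ties credited 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_separation_gives_auc_one():
    r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert r.auc == 1.0


def test_complete_ties_give_auc_half():
    r = roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1])
    assert r.auc == pytest.approx(0.5)


def test_auc_matches_exhaustive_pair_oracle_with_ties():
    scores = [1, 2, 2, 3, 3, 3, 4, 5]
    labels = [0, 0, 1, 0, 1, 1, 0, 1]
    r = roc_auc(scores, labels)
    assert r.auc == pytest.approx(_pairwise_auc(scores, labels), abs=1e-12)


def test_roc_curve_endpoints():
    r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert r.sensitivity[0] == 0.0 and r.one_minus_specificity[0] == 0.0
    assert r.sensitivity[-1] == 1.0 and r.one_minus_specificity[-1] == 1.0


def test_single_class_is_an_error():
    with pytest.raises(ParameterError, match="class"):
        roc_auc([1.0, 2.0], [1, 1])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_auc_invariant_under_increasing_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=12)
    labels = rng.integers(0, 2, size=12)
    if labels.all() or not labels.any():
        labels[0], labels[1] = 0, 1
    assert roc_auc(scores, labels).auc == pytest.approx(
        roc_auc(np.exp(scores), labels).auc, abs=1e-12
    )


# --- grade dichotomization AUC ---------------------------------------------------

def _score_and_meta(scores, fib, tub):
    ids = [f"s{i}" for i in range(len(scores))]
    ms = MolecularScore(
        scores=pd.Series(scores, index=ids, dtype=float),
        marker_genes=(),
        marker_probes=(),
    )
    meta = pd.DataFrame(
        {
            "disease": ["iga"] * len(ids),
            "fibrosis_grade": fib,
            "tubular_damage_grade": tub,
            "role": ["discovery"] * len(ids),
        },
        index=ids,
    )
    return ms, meta


def test_dichotomization_aucs_match_pair_oracle():
    scores = [1.0, 2.0, 3.0, 4.0, 2.5, 3.5]
    fib = [1, 1, 2, 3, 4, 4]
    tub = [1, 2, 2, 3, 3, 4]
    ms, meta = _score_and_meta(scores, fib, tub)
    table = grade_dichotomization_auc(ms, meta)
    for _, row in table.iterrows():
        cut = row["cut"]
        if row["endpoint"] == "fibrosis":
            grades, s = np.array(fib), np.array(scores)
        elif row["endpoint"] == "tubular":
            grades, s = np.array(tub), np.array(scores)
        else:
            grades = np.concatenate([fib, tub])
            s = np.concatenate([scores, scores])
        labels = grades > cut
        if labels.all() or not labels.any():
            assert np.isnan(row["auc"])
        else:
            assert row["auc"] == pytest.approx(_pairwise_auc(s, labels), abs=1e-12)


def test_empty_class_reports_nan_not_error():
    ms, meta = _score_and_meta([1.0, 2.0, 3.0], [2, 2, 2], [2, 3, 3])
    table = grade_dichotomization_auc(ms, meta, cuts=[1, 2, 3])
    fib_rows = table[table["endpoint"] == "fibrosis"]
    assert fib_rows["auc"].isna().all()  # fibrosis grades all equal -> undefined


def test_null_cohort_aucs_center_on_half():
    aucs = []
    for seed in (50, 51, 52, 53, 54):
        cohort = generate_cohort(null_params(seed, n_probes=200, n_discovery=48))
        fc = compute_fold_change(cohort.matrix, cohort.control)
        ms = molecular_score(fc, cohort.annotation)
        table = grade_dichotomization_auc(ms, cohort.metadata)
        aucs.extend(table["auc"].dropna().tolist())
    assert abs(float(np.mean(aucs)) - 0.5) < 0.1


# --- thresholds ------------------------------------------------------------------

def _youden_scan_oracle(scores, labels):
    """Independent exhaustive scan over midpoints (rule: score > t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    uniq = np.sort(np.unique(scores))
    best_t, best_j = None, -np.inf
    for t in (uniq[:-1] + uniq[1:]) / 2:
        tpr = ((scores > t) & labels).sum() / labels.sum()
        fpr = ((scores > t) & ~labels).sum() / (~labels).sum()
        if tpr - fpr > best_j:
            best_j, best_t = tpr - fpr, t
    return best_t, best_j


def test_separable_scores_give_perfect_training_threshold():
    scores = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
    fib = [1, 1, 2, 3, 4, 4]
    tub = [1, 2, 2, 3, 4, 4]
    ms, meta = _score_and_meta(scores, fib, tub)
    th = derive_thresholds(ms, meta)
    assert 3.0 < th.threshold_I < 10.0
    # all grade >=3 samples above the threshold, all <=2 below it
    preds = [predict_grade_category(s, th)[0] for s in scores]
    assert preds == ["<=2", "<=2", "<=2", ">=3", ">=3", ">=3"]


def test_youden_matches_exhaustive_scan_oracle():
    rng = np.random.default_rng(8)
    scores = np.round(rng.lognormal(1, 0.8, size=10), 2)
    grades = rng.integers(1, 5, size=10)
    ms, meta = _score_and_meta(scores, grades, grades)
    th = derive_thresholds(ms, meta, endpoint="tubular")
    oracle_t1, _ = _youden_scan_oracle(scores, grades > 2)
    oracle_t2, _ = _youden_scan_oracle(scores, grades > 3)
    assert th.threshold_I == pytest.approx(oracle_t1)
    assert th.threshold_II == pytest.approx(max(oracle_t1, oracle_t2))


def test_thresholds_ordered_on_synthetic_discovery():
    cohort = generate_cohort(clean_params(seed=23, n_probes=300))
    fc = compute_fold_change(cohort.matrix, cohort.control)
    ms = molecular_score(fc, cohort.annotation)
    th = derive_thresholds(ms, cohort.metadata)
    assert th.threshold_II >= th.threshold_I > 0


def test_threshold_derivation_is_deterministic():
    rng = np.random.default_rng(12)
    scores = rng.lognormal(1, 1, size=20)
    grades = rng.integers(1, 5, size=20)
    ms, meta = _score_and_meta(scores, grades, grades)
    a = derive_thresholds(ms, meta)
    b = derive_thresholds(ms, meta)
    assert (a.threshold_I, a.threshold_II) == (b.threshold_I, b.threshold_II)


def test_degenerate_single_class_cut_is_an_error():
    ms, meta = _score_and_meta([1.0, 2.0, 3.0], [1, 1, 2], [1, 2, 2])
    with pytest.raises(DataError, match="class"):
        derive_thresholds(ms, meta)


# --- prediction rule ---------------------------------------------------------------

def test_score_above_both_thresholds():
    th = GradeThresholds(threshold_I=2.0, threshold_II=5.0)
    assert predict_grade_category(7.0, th) == (">=3", ">=4")


def test_score_below_both_thresholds():
    th = GradeThresholds(threshold_I=2.0, threshold_II=5.0)
    assert predict_grade_category(1.0, th) == ("<=2", "<=3")


def test_boundary_equality_falls_in_lower_category():
    th = GradeThresholds(threshold_I=2.0, threshold_II=5.0)
    assert predict_grade_category(2.0, th) == ("<=2", "<=3")
    assert predict_grade_category(5.0, th) == (">=3", "<=3")


def test_threshold_ordering_enforced():
    with pytest.raises(ParameterError, match="threshold_II"):
        GradeThresholds(threshold_I=5.0, threshold_II=2.0)


# --- validation cohort ----------------------------------------------------------------

def test_empty_validation_set_returns_empty_table(small_cohort, small_fold_change):
    th = GradeThresholds(threshold_I=2.0, threshold_II=5.0)
    table = validate_cohort(
        small_fold_change, small_cohort.annotation, th, small_cohort.metadata,
        sample_ids=[],
    )
    assert len(table) == 0


def test_concordance_definition_at_grade_three():
    """A grade-3 sample is Threshold-I concordant iff predicted '>=3'."""
    fc, ann = _score_fc([[10.0, 1.0]])
    meta = pd.DataFrame(
        {
            "disease": ["iga", "iga"],
            "fibrosis_grade": [3, 3],
            "tubular_damage_grade": [3, 3],
            "role": ["validation", "validation"],
        },
        index=["s0", "s1"],
    )
    th = GradeThresholds(threshold_I=2.0, threshold_II=20.0)
    table = validate_cohort(fc, ann, th, meta, marker_probes=["m0"])
    assert bool(table.loc["s0", "concordant_I_tubular"]) is True  # 10 > 2 -> ">=3"
    assert bool(table.loc["s1", "concordant_I_tubular"]) is False  # 1 < 2 -> "<=2"


def test_probe_set_mismatch_is_an_error(small_cohort, small_fold_change):
    th = GradeThresholds(threshold_I=2.0, threshold_II=5.0)
    with pytest.raises(DataError, match="missing"):
        validate_cohort(
            small_fold_change, small_cohort.annotation, th, small_cohort.metadata,
            marker_probes=["NOT_A_PROBE"],
        )


def test_validation_concordance_on_synthetic_cohort():
    cohort = generate_cohort(clean_params(seed=31, n_probes=300))
    fc = compute_fold_change(cohort.matrix, cohort.control,
                             cohort_samples=cohort.discovery_ids())
    ms = molecular_score(fc, cohort.annotation)
    th = derive_thresholds(
        ms, cohort.metadata,
        sample_ids=[s for s in ms.scores.index if s in set(cohort.discovery_ids())],
    )
    table = validate_cohort(fc, cohort.annotation, th, cohort.metadata,
                            marker_probes=ms.marker_probes)
    assert len(table) == 5
    assert table["concordant_I_tubular"].sum() >= 4


# --- sklearn estimator -------------------------------------------------------------

def test_classifier_fit_predict_consistent_with_functions():
    rng = np.random.default_rng(4)
    grades = rng.integers(1, 5, size=30)
    X = rng.lognormal(0.5 * grades[:, None], 0.3, size=(30, 6))
    clf = MolecularScoreClassifier().fit(X, np.column_stack([grades, grades]))
    scores = clf.decision_function(X)
    assert np.allclose(scores, np.exp(np.log(X).mean(axis=1)))
    labels = clf.predict(X)
    assert set(labels) <= {"<=2", "3", ">=4"}
    assert clf.threshold_II_ >= clf.threshold_I_
    # strict ">" rule at the fitted thresholds
    assert ((scores > clf.threshold_I_) == (labels != "<=2")).all()
    assert ((scores > clf.threshold_II_) == (labels == ">=4")).all()


def test_classifier_is_cloneable_and_validates_y():
    clf = MolecularScoreClassifier(method="youden", lower_cut=2, upper_cut=3)
    clone(clf)  # sklearn get_params/set_params contract
    with pytest.raises(ParameterError):
        clf.fit(np.ones((4, 2)) * 2.0, np.ones((4, 3)))
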