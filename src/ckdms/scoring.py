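"""Marker-panel molecular score, ROC evaluation, and grade thresholds.

The molecular score of a sample is the geometric mean of its unlogged fold
changes (versus the control kidney profile) across *all* probes mapping to the
marker-gene panel (default HAVCR1/KIM-1, LCN2/NGAL, SOX9, WFDC2, NKX6-2).
It is evaluated by ROC/AUC over dichotomizations of the two ordinal
histopathology grades; two operating cutoffs are derived on the discovery set:

* Threshold I  — separates grade ≤ 2 from grade ≥ 3,
* Threshold II — separates grade ≤ 3 from grade ≥ 4,

each placed at the Youden-optimal midpoint between adjacent observed scores.
A new sample is called ≥3 (resp. ≥4) when its score strictly exceeds the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import (
    MARKER_GENES,
    DataError,
    FoldChangeProfile,
    ParameterError,
)

__all__ = [
    "MolecularScore",
    "ROCResult",
    "GradeThresholds",
    "molecular_score",
    "roc_auc",
    "grade_dichotomization_auc",
    "derive_thresholds",
    "predict_grade_category",
    "validate_cohort",
    "MolecularScoreClassifier",
]


# ---------------------------------------------------------------------------
# molecular score
# ---------------------------------------------------------------------------

def _geometric_mean_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean, computed in log space for stability."""
    if np.any(X <= 0):
        raise DataError("geometric mean requires strictly positive fold changes")
    return np.exp(np.log(X).mean(axis=1))


@dataclass
class MolecularScore:
    """Per-sample composite score over a marker-gene panel."""

    scores: pd.Series
    marker_genes: tuple[str, ...]
    marker_probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.scores <= 0).any():
            raise DataError("molecular scores must be strictly positive")


def molecular_score(
    fc: FoldChangeProfile,
    annotation: pd.Series,
    marker_genes=MARKER_GENES,
) -> MolecularScore:
    """Geometric-mean fold-change score over all detectable marker probes.

    Every marker gene must contribute at least one detectable probe; a gene
    with none is reported by name.
    """
    marker_genes = tuple(marker_genes)
    if not marker_genes:
        raise ParameterError("marker_genes must be nonempty")
    detectable = set(fc.detectable_probes())
    probes: list[str] = []
    for gene in marker_genes:
        gene_probes = [
            p for p in annotation.index[annotation == gene] if p in detectable
        ]
        if not gene_probes:
            raise DataError(f"marker gene {gene!r} has no detectable probe")
        probes.extend(gene_probes)
    X = fc.ratios.loc[probes].to_numpy(dtype=float).T  # samples x probes
    scores = pd.Series(_geometric_mean_rows(X), index=fc.sample_ids, name="score")
    return MolecularScore(scores=scores, marker_genes=marker_genes, marker_probes=tuple(probes))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC curve with tie-corrected (Mann-Whitney) AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    endpoint: str = ""
    dichotomization: str = ""


def roc_auc(scores, labels, endpoint: str = "", dichotomization: str = "") -> ROCResult:
    """ROC curve and AUC of ``scores`` against binary ``labels``.

    The AUC is the Mann-Whitney probability that a positive outscores a
    negative, ties credited 1/2; it equals the trapezoidal area under the
    empirical curve. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels have mismatched lengths")
    if labels.all() or not labels.any():
        raise ParameterError("both classes must be present to compute an ROC curve")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        one_minus_specificity=fpr,
        auc=auc,
        endpoint=endpoint,
        dichotomization=dichotomization,
    )


def _dichotomize(grades: np.ndarray, cut: int) -> np.ndarray:
    """Binary label: grade strictly above ``cut`` (low = ≤cut, high = >cut)."""
    return np.asarray(grades) > cut


def grade_dichotomization_auc(
    score: MolecularScore,
    metadata: pd.DataFrame,
    cuts=None,
    sample_ids=None,
) -> pd.DataFrame:
    """AUCs of the score for every endpoint × grade dichotomization.

    For each cut ``g`` the classes are grade ≤ g versus grade > g; for the
    typical grade-1–4 discovery cohort the default cuts {1, 2, 3} reproduce
    the 1 vs 2–4, 1–2 vs 3–4, and 1–3 vs 4 splits. Besides the two per-endpoint
    rows, a ``composite`` row pools the labels of both endpoints (each sample
    contributes one labeled instance per endpoint, the score duplicated).
    Cells where a class is empty carry AUC = NaN rather than raising.
    """
    if sample_ids is None:
        sample_ids = [s for s in score.scores.index if s in metadata.index
                      and metadata.loc[s, "role"] == "discovery"]
    s = score.scores.loc[sample_ids].to_numpy(dtype=float)
    fib = metadata.loc[sample_ids, "fibrosis_grade"].to_numpy()
    tub = metadata.loc[sample_ids, "tubular_damage_grade"].to_numpy()
    if cuts is None:
        lo = int(min(fib.min(), tub.min()))
        hi = int(max(fib.max(), tub.max()))
        cuts = list(range(lo, hi))
    rows = []
    for cut in cuts:
        name = f"<= {cut} vs > {cut}"
        for endpoint, grades, values in (
            ("fibrosis", fib, s),
            ("tubular", tub, s),
            ("composite", np.concatenate([fib, tub]), np.concatenate([s, s])),
        ):
            labels = _dichotomize(grades, cut)
            if labels.all() or not labels.any():
                auc = np.nan
            else:
                auc = roc_auc(values, labels).auc
            rows.append({"endpoint": endpoint, "cut": cut,
                         "dichotomization": name, "auc": auc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thresholds and prediction
# ---------------------------------------------------------------------------

def _youden_threshold(scores: np.ndarray, labels: np.ndarray, method: str) -> float:
    """Cutoff maximizing Youden's J (or accuracy) under the rule score > t.

    Candidate cutoffs are the midpoints between adjacent distinct observed
    scores; ties in the objective resolve to the lowest candidate (highest
    sensitivity).
    """
    if labels.all() or not labels.any():
        raise DataError("threshold derivation needs both classes populated")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise DataError("threshold derivation needs at least two distinct scores")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_t, best_obj = None, -np.inf
    for t in candidates:
        pred = scores > t
        tpr = (pred & labels).sum() / n_pos
        fpr = (pred & ~labels).sum() / n_neg
        if method == "youden":
            obj = tpr - fpr
        elif method == "max-accuracy":
            obj = ((pred == labels).sum()) / labels.size
        else:
            raise ParameterError(f"invalid threshold method: {method!r}")
        if obj > best_obj:
            best_obj, best_t = obj, float(t)
    return best_t


@dataclass
class GradeThresholds:
    """Operating cutoffs for the two grade categories, with provenance."""

    threshold_I: float
    threshold_II: float
    method: str = "youden"
    endpoint: str = "pooled"
    sample_ids: tuple[str, ...] = ()
    clipped: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.threshold_I <= 0 or self.threshold_II <= 0:
            raise ParameterError("thresholds must be positive scores")
        if self.threshold_II < self.threshold_I:
            raise ParameterError("threshold_II must be >= threshold_I")


def derive_thresholds(
    score: MolecularScore,
    metadata: pd.DataFrame,
    method: str = "youden",
    endpoint: str = "pooled",
    sample_ids=None,
    lower_cut: int = 2,
    upper_cut: int = 3,
) -> GradeThresholds:
    """Derive Threshold I (grade ≤lower_cut vs >) and II (≤upper_cut vs >).

    ``endpoint`` chooses the grades used for the labels: ``"pooled"``
    (default; each sample contributes one labeled instance per endpoint),
    ``"fibrosis"`` or ``"tubular"``. Monotonicity (II ≥ I) is enforced; if it
    binds, II is clipped to I and the fact is recorded.
    """
    if sample_ids is None:
        sample_ids = [s for s in score.scores.index if s in metadata.index
                      and metadata.loc[s, "role"] == "discovery"]
    s = score.scores.loc[sample_ids].to_numpy(dtype=float)
    fib = metadata.loc[sample_ids, "fibrosis_grade"].to_numpy()
    tub = metadata.loc[sample_ids, "tubular_damage_grade"].to_numpy()
    if endpoint == "pooled":
        values = np.concatenate([s, s])
        grades = np.concatenate([fib, tub])
    elif endpoint == "fibrosis":
        values, grades = s, fib
    elif endpoint == "tubular":
        values, grades = s, tub
    else:
        raise ParameterError(f"invalid endpoint: {endpoint!r}")

    t1 = _youden_threshold(values, _dichotomize(grades, lower_cut), method)
    t2 = _youden_threshold(values, _dichotomize(grades, upper_cut), method)
    clipped = False
    if t2 < t1:
        t2, clipped = t1, True
    return GradeThresholds(
        threshold_I=t1,
        threshold_II=t2,
        method=method,
        endpoint=endpoint,
        sample_ids=tuple(sample_ids),
        clipped=clipped,
    )


def predict_grade_category(score: float, thresholds: GradeThresholds) -> tuple[str, str]:
    """Map a score to its two grade categories by the strict-``>`` rule.

    Returns ``(category_I, category_II)`` with category_I in {"<=2", ">=3"}
    and category_II in {"<=3", ">=4"}; a score exactly equal to a threshold
    falls in the lower category.
    """
    cat1 = ">=3" if score > thresholds.threshold_I else "<=2"
    cat2 = ">=4" if score > thresholds.threshold_II else "<=3"
    return cat1, cat2


def validate_cohort(
    fc: FoldChangeProfile,
    annotation: pd.Series,
    thresholds: GradeThresholds,
    metadata: pd.DataFrame,
    marker_probes=None,
    marker_genes=MARKER_GENES,
    sample_ids=None,
) -> pd.DataFrame:
    """Score held-out samples and check concordance with observed grades.

    ``marker_probes`` must be the exact probe set used on the discovery set
    (a mismatch is an error — the score is only comparable across cohorts when
    computed from the same probes against the same control). A sample is
    concordant for Threshold I when its observed grade falls in the predicted
    category (≥3 vs ≤2), and likewise for Threshold II; concordance is checked
    against each endpoint separately. An empty sample set returns an empty
    table.
    """
    if sample_ids is None:
        sample_ids = [s for s in fc.sample_ids if s in metadata.index
                      and metadata.loc[s, "role"] == "validation"]
    if marker_probes is not None:
        missing = set(marker_probes) - set(fc.probe_ids)
        if missing:
            raise DataError(
                f"marker probes from discovery missing in this cohort: {sorted(missing)}"
            )
        X = fc.ratios.loc[list(marker_probes), sample_ids].to_numpy(dtype=float).T
        scores = pd.Series(
            _geometric_mean_rows(X) if len(sample_ids) else np.empty(0),
            index=sample_ids, name="score", dtype=float,
        )
    else:
        scores = molecular_score(fc, annotation, marker_genes).scores.loc[sample_ids]

    rows = []
    for sid in sample_ids:
        s = float(scores.loc[sid])
        cat1, cat2 = predict_grade_category(s, thresholds)
        fib = int(metadata.loc[sid, "fibrosis_grade"])
        tub = int(metadata.loc[sid, "tubular_damage_grade"])
        rows.append(
            {
                "sample_id": sid,
                "score": s,
                "category_I": cat1,
                "category_II": cat2,
                "fibrosis_grade": fib,
                "tubular_damage_grade": tub,
                "concordant_I_fibrosis": (fib >= 3) == (cat1 == ">=3"),
                "concordant_I_tubular": (tub >= 3) == (cat1 == ">=3"),
                "concordant_II_fibrosis": (fib >= 4) == (cat2 == ">=4"),
                "concordant_II_tubular": (tub >= 4) == (cat2 == ">=4"),
            }
        )
    columns = [
        "sample_id", "score", "category_I", "category_II",
        "fibrosis_grade", "tubular_damage_grade",
        "concordant_I_fibrosis", "concordant_I_tubular",
        "concordant_II_fibrosis", "concordant_II_tubular",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("sample_id")


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class MolecularScoreClassifier(BaseEstimator):
    """Geometric-mean panel score with Youden-derived grade thresholds.

    Fit on X (samples × marker-probe unlogged fold changes) and y (ordinal
    grades: shape (n,) for a single endpoint or (n, 2) to pool fibrosis and
    tubular labels). Fitted attributes: ``scores_`` (training scores),
    ``threshold_I_`` (grade ≤lower_cut vs >) and ``threshold_II_``
    (≤upper_cut vs >).

    ``predict`` returns one of ``"<=2"``, ``"3"``, ``">=4"`` by combining the
    two strict-``>`` threshold calls; ``decision_function`` returns the score.
    """

    def __init__(self, method: str = "youden", lower_cut: int = 2, upper_cut: int = 3):
        self.method = method
        self.lower_cut = lower_cut
        self.upper_cut = upper_cut

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True, dtype=float)
        y = np.asarray(y)
        scores = _geometric_mean_rows(X)
        if y.ndim == 1:
            values, grades = scores, y
        elif y.ndim == 2 and y.shape[1] == 2:
            values = np.concatenate([scores, scores])
            grades = np.concatenate([y[:, 0], y[:, 1]])
        else:
            raise ParameterError("y must be (n,) or (n, 2) ordinal grades")
        if y.shape[0] != X.shape[0]:
            raise ParameterError("X and y have mismatched lengths")
        t1 = _youden_threshold(values, _dichotomize(grades, self.lower_cut), self.method)
        t2 = _youden_threshold(values, _dichotomize(grades, self.upper_cut), self.method)
        self.clipped_ = t2 < t1
        self.scores_ = scores
        self.threshold_I_ = t1
        self.threshold_II_ = max(t1, t2)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_I_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return _geometric_mean_rows(X)

    def predict(self, X):
        scores = self.decision_function(X)
        labels = np.full(scores.shape, f"<={self.lower_cut}", dtype=object)
        labels[scores > self.threshold_I_] = str(self.lower_cut + 1)
        labels[scores > self.threshold_II_] = f">={self.upper_cut + 1}"
        return labels
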