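"""Association of probe expression with ordinal histopathology grades.

Each candidate probe's per-sample fold change is tested against the
tubulointerstitial-fibrosis grade and (separately) the tubular-cell-damage
grade with the Kruskal-Wallis rank test, each observed grade forming its own
group. A probe is selected when it is significant (raw P < alpha) for *both*
endpoints; no multiple-testing correction is applied by default, with an
optional Benjamini-Hochberg adjustment.

The H statistic uses midranks with the standard tie correction and the
chi-square approximation with k−1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .containers import (
    DEFAULT_DISEASE_SUBSET,
    DataError,
    FoldChangeProfile,
    ParameterError,
)

__all__ = [
    "kruskal_wallis",
    "kruskal_wallis_many",
    "subset_by_disease",
    "AssociationResult",
    "dual_endpoint_selection",
    "DualEndpointSelector",
]


def _group_indicator(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordered unique labels and an indicator matrix (n_obs × k)."""
    labels, inverse = np.unique(np.asarray(groups), return_inverse=True)
    indicator = np.zeros((groups.shape[0], labels.shape[0]))
    indicator[np.arange(groups.shape[0]), inverse] = 1.0
    return labels, indicator


def _tie_correction(ranked_rows: np.ndarray) -> np.ndarray:
    """Per-row tie factor 1 - sum(t^3 - t) / (n^3 - n) from midranks."""
    n = ranked_rows.shape[1]
    out = np.empty(ranked_rows.shape[0])
    for i, row in enumerate(np.sort(ranked_rows, axis=1)):
        _, counts = np.unique(row, return_counts=True)
        out[i] = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return out


def kruskal_wallis_many(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Kruskal-Wallis over the rows of ``values``.

    ``values`` is (n_tests × n_obs); ``groups`` labels the n_obs columns.
    Returns per-row (H, P). Rows where every value is tied give H=0, P=1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    groups = np.asarray(groups)
    if values.shape[1] != groups.shape[0]:
        raise ParameterError("values and groups have mismatched lengths")
    labels, indicator = _group_indicator(groups)
    k = labels.shape[0]
    if k < 2:
        raise ParameterError("Kruskal-Wallis requires at least 2 groups")
    n = values.shape[1]
    if n < 3:
        raise ParameterError("Kruskal-Wallis requires at least 3 observations")

    ranks = stats.rankdata(values, axis=1)
    n_per_group = indicator.sum(axis=0)
    rank_sums = ranks @ indicator
    h = 12.0 / (n * (n + 1)) * ((rank_sums**2) / n_per_group[None, :]).sum(axis=1) - 3 * (n + 1)
    correction = _tie_correction(ranks)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(correction > 0, h / correction, 0.0)
    h = np.maximum(h, 0.0)  # guard tiny negative round-off
    p = np.where(correction > 0, stats.chi2.sf(h, k - 1), 1.0)
    return h, p


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H and P for one variable against ordinal group labels.

    All-values-tied inputs return (0.0, 1.0); a single group is an error.
    """
    values = np.asarray(values, dtype=float)
    h, p = kruskal_wallis_many(values[None, :], np.asarray(groups))
    return float(h[0]), float(p[0])


def subset_by_disease(metadata: pd.DataFrame, categories) -> list[str]:
    """Discovery samples whose primary disease is in ``categories`` (order kept)."""
    categories = set(categories)
    if not categories:
        raise ParameterError("categories must be a nonempty set of disease codes")
    mask = (metadata["role"] == "discovery") & metadata["disease"].isin(categories)
    subset = list(metadata.index[mask])
    if not subset:
        raise DataError(f"no discovery samples with diseases in {sorted(categories)}")
    return subset


@dataclass
class AssociationResult:
    """Dual-endpoint Kruskal-Wallis results for candidate probes.

    ``table`` columns: ``H_fibrosis``, ``P_fibrosis``, ``H_tubular``,
    ``P_tubular``, ``selected`` (both raw P < alpha).
    """

    table: pd.DataFrame
    alpha: float
    sample_ids: tuple[str, ...]

    @property
    def fibrosis_significant(self) -> pd.Index:
        return self.table.index[self.table["P_fibrosis"] < self.alpha]

    @property
    def tubular_significant(self) -> pd.Index:
        return self.table.index[self.table["P_tubular"] < self.alpha]

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def dual_endpoint_selection(
    fc: FoldChangeProfile,
    metadata: pd.DataFrame,
    candidates=None,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
    adjust: str | None = None,
) -> AssociationResult:
    """Select probes associated with both histopathology endpoints.

    Parameters
    ----------
    candidates:
        Probe ids to test (typically the up-regulated set); default: all
        detectable probes.
    sample_ids:
        The samples to test on — normally the disease-restricted discovery
        subset from :func:`subset_by_disease`. Default: all discovery samples
        present in both ``fc`` and ``metadata``.
    adjust:
        ``None`` (raw P, matching the P < 0.05 convention) or ``"bh"`` for a
        Benjamini-Hochberg adjustment of each endpoint's P values.
    """
    if not 0 <= alpha <= 1:
        raise ParameterError(f"invalid alpha: {alpha!r} not in [0, 1]")
    if adjust not in (None, "bh"):
        raise ParameterError(f"invalid adjust: {adjust!r} (use None or 'bh')")
    if sample_ids is None:
        discovery = metadata.index[metadata["role"] == "discovery"]
        sample_ids = [s for s in fc.sample_ids if s in set(discovery)]
    if candidates is None:
        candidates = list(fc.detectable_probes())
    candidates = list(candidates)
    missing = set(candidates) - set(fc.probe_ids)
    if missing:
        raise DataError(f"candidate probes absent from fold changes: {sorted(missing)[:10]}")

    values = fc.ratios.loc[candidates, sample_ids].to_numpy(dtype=float)
    table = pd.DataFrame(index=pd.Index(candidates, name="probe_id"))
    for endpoint, column in (
        ("fibrosis", "fibrosis_grade"),
        ("tubular", "tubular_damage_grade"),
    ):
        grades = metadata.loc[sample_ids, column].to_numpy()
        if np.unique(grades).size < 2:
            raise DataError(
                f"{endpoint} endpoint has fewer than 2 distinct grades in the subset"
            )
        h, p = kruskal_wallis_many(values, grades)
        if adjust == "bh":
            p = multipletests(p, method="fdr_bh")[1]
        table[f"H_{endpoint}"] = h
        table[f"P_{endpoint}"] = p
    table["selected"] = (table["P_fibrosis"] < alpha) & (table["P_tubular"] < alpha)
    return AssociationResult(table=table, alpha=alpha, sample_ids=tuple(sample_ids))


class DualEndpointSelector(BaseEstimator):
    """Feature selector keeping probes Kruskal-Wallis-significant for both grades.

    Fit on X (samples × probes fold changes) and y (samples × 2 integer grades:
    fibrosis, tubular). ``support_`` marks probes with both raw P < alpha.
    """

    def __init__(self, alpha: float = 0.05, adjust: str | None = None):
        self.alpha = alpha
        self.adjust = adjust

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True, dtype=float)
        y = check_array(y, ensure_2d=True, dtype=None)
        if y.shape != (X.shape[0], 2):
            raise ParameterError("y must be (n_samples, 2): fibrosis and tubular grades")
        if not 0 <= self.alpha <= 1:
            raise ParameterError(f"invalid alpha: {self.alpha!r} not in [0, 1]")
        pvals = np.empty((X.shape[1], 2))
        stats_h = np.empty((X.shape[1], 2))
        for j in range(2):
            h, p = kruskal_wallis_many(X.T, y[:, j])
            if self.adjust == "bh":
                p = multipletests(p, method="fdr_bh")[1]
            stats_h[:, j], pvals[:, j] = h, p
        self.statistic_ = stats_h
        self.pvalues_ = pvals
        self.support_ = (pvals < self.alpha).all(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return X[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
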