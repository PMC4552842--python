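"""Differential expression by z-scored cohort-mean fold change.

Each detectable probe gets one z-score: its log2 cohort-mean ratio to control,
standardized across all detectable probes (sample standard deviation). Probes
with z beyond ±cutoff (default 2.0) are called up-/down-regulated. This is a
gene-wise standardization across the profile, not a per-probe test across
samples: one z exists per probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import DataError, FoldChangeProfile, ParameterError

__all__ = ["DEGResult", "zscore_fold_changes", "select_deg", "collapse_to_genes",
           "ZScoreDEGSelector"]


def _zscore(values: np.ndarray) -> np.ndarray:
    """Standardize with the (n-1)-denominator sample SD."""
    if values.size < 3:
        raise DataError("z-scoring requires at least 3 detectable probes")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance across probes; z-scores are undefined")
    return (values - values.mean()) / sd


def _directions(z: np.ndarray, cutoff: float) -> np.ndarray:
    direction = np.full(z.shape, "unchanged", dtype=object)
    direction[z > cutoff] = "up"
    direction[z < -cutoff] = "down"
    return direction


@dataclass
class DEGResult:
    """Per-probe differential-expression summary.

    ``table`` columns: ``mean_ratio`` (unlogged cohort-mean fold change),
    ``value`` (the standardized scale: log2 ratio by default), ``z``, and
    ``direction`` in {up, down, unchanged} at ``cutoff``.
    """

    table: pd.DataFrame
    cutoff: float
    scale: str

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]


def zscore_fold_changes(
    fc: FoldChangeProfile, cutoff: float = 2.0, scale: str = "log2"
) -> DEGResult:
    """z-score the cohort-mean fold changes across detectable probes.

    ``scale`` chooses what is standardized: ``"log2"`` (default; ratios are
    right-skewed so the symmetric log scale is the sensible basis) or
    ``"linear"`` for the raw ratios.
    """
    if cutoff < 0:
        raise ParameterError(f"invalid cutoff: {cutoff!r} must be >= 0")
    if scale not in ("log2", "linear"):
        raise ParameterError(f"invalid scale: {scale!r} (use 'log2' or 'linear')")
    probes = fc.detectable_probes()
    mean_ratio = fc.cohort_mean.loc[probes].to_numpy(dtype=float)
    values = np.log2(mean_ratio) if scale == "log2" else mean_ratio
    z = _zscore(values)
    table = pd.DataFrame(
        {
            "mean_ratio": mean_ratio,
            "value": values,
            "z": z,
            "direction": _directions(z, cutoff),
        },
        index=probes,
    )
    return DEGResult(table=table, cutoff=cutoff, scale=scale)


def select_deg(
    result: DEGResult, cutoff: float | None = None
) -> tuple[list[str], list[str]]:
    """Up- and down-regulated probe lists, each sorted by |z| descending."""
    cutoff = result.cutoff if cutoff is None else cutoff
    if cutoff < 0:
        raise ParameterError(f"invalid cutoff: {cutoff!r} must be >= 0")
    z = result.table["z"]
    order = result.table.reindex(z.abs().sort_values(ascending=False).index)
    up = list(order.index[order["z"] > cutoff])
    down = list(order.index[order["z"] < -cutoff])
    return up, down


def collapse_to_genes(result: DEGResult, annotation: pd.Series) -> pd.DataFrame:
    """Collapse probe-level calls to genes via the maximum-|z| probe per gene."""
    table = result.table.copy()
    table["gene"] = annotation.reindex(table.index)
    if table["gene"].isna().any():
        missing = table.index[table["gene"].isna()][:10]
        raise DataError(f"annotation does not cover probes: {list(missing)}")
    idx = table.groupby("gene")["z"].apply(lambda s: s.abs().idxmax())
    collapsed = table.loc[idx.to_numpy()].copy()
    collapsed["probe_id"] = collapsed.index
    return collapsed.set_index("gene")


class ZScoreDEGSelector(BaseEstimator):
    """Feature selector flagging up/down probes by across-probe z-score.

    Fit on a samples × probes matrix of unlogged fold changes; the cohort
    mean is taken across rows, log2-transformed (``scale="log2"``) and
    standardized across probes. ``transform`` keeps probes with |z| > cutoff.
    """

    def __init__(self, cutoff: float = 2.0, scale: str = "log2"):
        self.cutoff = cutoff
        self.scale = scale

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        if np.any(X <= 0):
            raise DataError("fold changes must be strictly positive")
        if self.scale not in ("log2", "linear"):
            raise ParameterError(f"invalid scale: {self.scale!r}")
        self.mean_ratio_ = X.mean(axis=0)
        values = np.log2(self.mean_ratio_) if self.scale == "log2" else self.mean_ratio_
        self.z_ = _zscore(values)
        self.direction_ = _directions(self.z_, self.cutoff)
        self.support_ = np.abs(self.z_) > self.cutoff
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, direction: str | None = None) -> np.ndarray:
        check_is_fitted(self, "support_")
        if direction is None:
            return self.support_
        return self.direction_ == direction

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return X[:, self.support_]
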