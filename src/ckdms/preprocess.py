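"""Array preprocessing: bad-spot handling, median normalization,
background-significance detectability filtering, and fold change versus the
control kidney profile.

The stages follow standard one-color array practice: flagged features are
removed before normalization, each array is rescaled multiplicatively so its
intensity median matches a common target, features are kept only where the
signal significantly exceeds the local background, and expression is summarized
as the unlogged ratio to a single control profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import DataError, ExpressionMatrix, FoldChangeProfile, ParameterError

__all__ = [
    "flag_and_drop_bad_spots",
    "median_normalize",
    "filter_detectable",
    "compute_fold_change",
    "DetectabilityMask",
    "MedianNormalizer",
    "DetectabilityFilter",
]


# ---------------------------------------------------------------------------
# core numerics (sample-major numpy arrays, shared by functions and estimators)
# ---------------------------------------------------------------------------

def _median_scale_factors(X: np.ndarray, target: float) -> np.ndarray:
    """Per-row factors bringing each row's median to ``target``."""
    medians = np.nanmedian(X, axis=1)
    if np.any(~np.isfinite(medians)) or np.any(medians <= 0):
        raise DataError("every sample needs at least one positive intensity")
    return target / medians


def _detectable_cells(
    X: np.ndarray, bg_mean: np.ndarray, bg_sd: np.ndarray, alpha: float
) -> np.ndarray:
    """Boolean samples × probes mask of background-significant signals.

    A cell is detectable when the signal exceeds the feature background *and*
    the one-sided z statistic ``(signal - bg_mean) / bg_sd`` exceeds the
    upper-``alpha`` standard-normal quantile.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"invalid alpha: {alpha!r} not in (0, 1)")
    zcrit = stats.norm.ppf(1 - alpha)
    with np.errstate(invalid="ignore"):
        z = (X - bg_mean[None, :]) / bg_sd[None, :]
    return (X > bg_mean[None, :]) & (z > zcrit)


# ---------------------------------------------------------------------------
# spec-facing operations on ExpressionMatrix
# ---------------------------------------------------------------------------

def flag_and_drop_bad_spots(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.2
) -> ExpressionMatrix:
    """Remove flagged cells, drop gappy probes, impute the rest.

    Flagged cells become missing; probes missing in more than
    ``max_missing_fraction`` of samples are dropped entirely; remaining
    missing cells are imputed with the probe's median across samples (a
    rank-preserving choice — downstream tests are rank-based).
    """
    if not 0 <= max_missing_fraction < 1:
        raise ParameterError(
            f"invalid max_missing_fraction: {max_missing_fraction!r} not in [0, 1)"
        )
    if matrix.bad_spots is None:
        return matrix.copy()

    values = matrix.intensities.where(~matrix.bad_spots)
    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= max_missing_fraction
    if not keep.any():
        raise DataError("all probes were dropped by the bad-spot rule")
    values = values.loc[keep]
    medians = values.median(axis=1)
    gaps = values.isna()
    if gaps.to_numpy().any():
        fill = np.broadcast_to(medians.to_numpy()[:, None], values.shape)
        values = values.where(~gaps, pd.DataFrame(fill, index=values.index, columns=values.columns))
    return ExpressionMatrix(
        intensities=values,
        bad_spots=None,
        background=None if matrix.background is None else matrix.background.loc[keep].copy(),
    )


def median_normalize(
    matrix: ExpressionMatrix, target: float | str = "global"
) -> ExpressionMatrix:
    """Rescale each sample so its median intensity equals ``target``.

    ``target="global"`` uses the grand median of the per-sample medians, so a
    second application is an exact no-op.
    """
    X = matrix.intensities.to_numpy(dtype=float).T  # samples x probes
    if isinstance(target, str):
        if target != "global":
            raise ParameterError(f"invalid target: {target!r}")
        target_value = float(np.median(np.nanmedian(X, axis=1)))
    else:
        target_value = float(target)
        if not np.isfinite(target_value) or target_value <= 0:
            raise ParameterError(f"invalid target: {target!r} must be positive")
    factors = _median_scale_factors(X, target_value)
    scaled = matrix.intensities.mul(pd.Series(factors, index=matrix.sample_ids), axis=1)
    return ExpressionMatrix(
        intensities=scaled,
        bad_spots=None if matrix.bad_spots is None else matrix.bad_spots.copy(),
        background=None if matrix.background is None else matrix.background.copy(),
    )


class DetectabilityMask:
    """Per-cell and per-probe result of the detectability filter."""

    def __init__(self, per_cell: pd.DataFrame, min_fraction: float):
        self.per_cell = per_cell
        self.min_fraction = min_fraction
        self.per_probe = per_cell.mean(axis=1) >= min_fraction

    def detectable_probes(self) -> pd.Index:
        return self.per_cell.index[self.per_probe.to_numpy()]


def filter_detectable(
    matrix: ExpressionMatrix, alpha: float = 0.05, min_fraction: float = 0.5
) -> DetectabilityMask:
    """Mark probes whose signal significantly exceeds the feature background.

    A probe is retained overall when it is detectable (signal above background
    with one-sided z beyond the upper-``alpha`` normal quantile) in at least
    ``min_fraction`` of the samples.
    """
    if matrix.background is None:
        raise DataError("background_mean/background_sd are required for detectability")
    X = matrix.intensities.to_numpy(dtype=float).T
    cells = _detectable_cells(
        X,
        matrix.background["bg_mean"].to_numpy(dtype=float),
        matrix.background["bg_sd"].to_numpy(dtype=float),
        alpha,
    )
    per_cell = pd.DataFrame(cells.T, index=matrix.probe_ids, columns=matrix.sample_ids)
    return DetectabilityMask(per_cell, min_fraction)


def compute_fold_change(
    matrix: ExpressionMatrix,
    control: pd.Series,
    floor: float | None = None,
    detectable: pd.Series | None = None,
    cohort_samples: list[str] | None = None,
) -> FoldChangeProfile:
    """Unlogged per-sample ratios to the control profile plus cohort means.

    The denominator is ``max(control, floor)``; by default the floor is the
    1st percentile of the control intensities, which keeps near-zero control
    signals from blowing up the ratio. ``cohort_samples`` (default: all
    columns) selects the samples entering the cohort-mean ratio.
    """
    missing = matrix.probe_ids.difference(control.index)
    if len(missing):
        raise DataError(f"control profile is missing probes: {list(missing[:10])}")
    control = control.loc[matrix.probe_ids].astype(float)
    if (control <= 0).any():
        raise DataError("control intensities must be strictly positive")
    if floor is None:
        floor = float(np.percentile(control.to_numpy(), 1))
    if floor <= 0:
        raise ParameterError(f"invalid floor: {floor!r} must be positive")
    denom = np.maximum(control.to_numpy(), floor)
    ratios = matrix.intensities.div(pd.Series(denom, index=matrix.probe_ids), axis=0)
    if cohort_samples is None:
        cohort_samples = list(matrix.sample_ids)
    cohort_mean = ratios[cohort_samples].mean(axis=1)
    if detectable is None:
        detectable = pd.Series(True, index=matrix.probe_ids)
    return FoldChangeProfile(
        ratios=ratios,
        cohort_mean=cohort_mean,
        control=control,
        floor=floor,
        detectable=detectable,
        cohort_samples=tuple(cohort_samples),
    )


# ---------------------------------------------------------------------------
# scikit-learn estimators (samples as rows, probes as columns)
# ---------------------------------------------------------------------------

class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Rescale each sample (row) so its median matches a common target.

    Parameters
    ----------
    target : "global" or positive float, default "global"
        "global" targets the grand median of the per-row medians seen at fit
        time; a float targets that value directly.
    """

    def __init__(self, target: float | str = "global"):
        self.target = target

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        if isinstance(self.target, str):
            if self.target != "global":
                raise ParameterError(f"invalid target: {self.target!r}")
            self.target_ = float(np.median(np.median(X, axis=1)))
        else:
            if not np.isfinite(self.target) or self.target <= 0:
                raise ParameterError(f"invalid target: {self.target!r} must be positive")
            self.target_ = float(self.target)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "target_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return X * _median_scale_factors(X, self.target_)[:, None]


class DetectabilityFilter(BaseEstimator):
    """Feature selector keeping probes significantly above background.

    ``background_mean`` and ``background_sd`` are per-feature arrays supplied
    at construction (they describe the array platform, not the cohort).
    """

    def __init__(self, background_mean, background_sd, alpha: float = 0.05,
                 min_fraction: float = 0.5):
        self.background_mean = background_mean
        self.background_sd = background_sd
        self.alpha = alpha
        self.min_fraction = min_fraction

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        bg_mean = np.asarray(self.background_mean, dtype=float)
        bg_sd = np.asarray(self.background_sd, dtype=float)
        if bg_mean.shape[0] != X.shape[1] or bg_sd.shape[0] != X.shape[1]:
            raise DataError("background arrays must have one entry per probe")
        cells = _detectable_cells(X, bg_mean, bg_sd, self.alpha)
        self.detectable_fraction_ = cells.mean(axis=0)
        self.support_ = self.detectable_fraction_ >= self.min_fraction
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return X[:, self.support_]
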