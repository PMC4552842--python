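"""Shared data containers and cohort-level constants.

The pipeline moves three tabular objects between stages:

* :class:`ExpressionMatrix` — probe × sample fluorescence intensities with
  optional per-cell bad-spot flags and per-probe background statistics,
  mirroring what a one-color array feature-extraction export contains.
* a sample-metadata table (plain :class:`pandas.DataFrame`) with one row per
  sample: primary disease, the two ordinal histopathology grades
  (tubulointerstitial fibrosis and tubular cell damage, both on the 0–5
  area-of-lesion scale), and the cohort role.
* :class:`FoldChangeProfile` — per-probe, per-sample unlogged ratios to the
  control kidney profile, plus the cohort-mean ratio used for differential
  expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Marker-gene panel used for the molecular score. HAVCR1 is also known as
#: KIM-1 and LCN2 as NGAL; both are established tubular-injury markers.
MARKER_GENES: tuple[str, ...] = ("HAVCR1", "LCN2", "SOX9", "WFDC2", "NKX6-2")

#: Primary-disease categories (short code -> descriptive name).
DISEASES: dict[str, str] = {
    "iga": "IgA nephropathy",
    "mn": "membranous nephropathy",
    "mcns": "minimal change nephrotic syndrome",
    "mpgn": "membranoproliferative glomerulonephropathy",
    "dn": "diabetic nephropathy",
    "lupus": "lupus nephritis",
    "amyloidosis": "amyloidosis",
    "anca": "ANCA-related glomerulonephropathy",
    "other": "other nephropathy",
}

#: Primary glomerulonephritis + diabetic nephropathy subset used for the
#: grade-association analysis.
DEFAULT_DISEASE_SUBSET: tuple[str, ...] = ("iga", "mn", "mcns", "mpgn", "dn")

#: Disease frequencies of a typical 48-patient CKD biopsy discovery cohort.
#: The five categories in DEFAULT_DISEASE_SUBSET sum to 31.
DISCOVERY_DISEASE_COUNTS: dict[str, int] = {
    "iga": 15,
    "mn": 7,
    "mcns": 4,
    "mpgn": 3,
    "dn": 2,
    "lupus": 6,
    "amyloidosis": 3,
    "anca": 2,
    "other": 6,
}

GRADE_MIN, GRADE_MAX = 0, 5
ROLES: tuple[str, ...] = ("discovery", "validation", "control")
METADATA_COLUMNS: tuple[str, ...] = (
    "disease",
    "fibrosis_grade",
    "tubular_damage_grade",
    "role",
)


class DataError(ValueError):
    """Raised when an input table violates a structural contract."""


class ParameterError(ValueError):
    """Raised when a user-supplied parameter is out of range."""


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it unchanged.

    Expects the index to hold unique sample identifiers and the columns of
    ``METADATA_COLUMNS``. Grades must be integers in [0, 5] and roles one of
    ``ROLES``.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise DataError(f"metadata is missing columns: {missing}")
    if metadata.index.duplicated().any():
        dups = metadata.index[metadata.index.duplicated()].tolist()
        raise DataError(f"duplicate sample ids in metadata: {dups}")
    for col in ("fibrosis_grade", "tubular_damage_grade"):
        grades = metadata[col]
        if not np.array_equal(grades, grades.astype(int)):
            raise DataError(f"{col} must be integer-valued")
        if grades.min() < GRADE_MIN or grades.max() > GRADE_MAX:
            raise DataError(f"{col} outside the 0-5 area-of-lesion scale")
    bad_roles = set(metadata["role"]) - set(ROLES)
    if bad_roles:
        raise DataError(f"unknown cohort roles: {sorted(bad_roles)}")
    return metadata


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity matrix with optional QC side tables.

    Parameters
    ----------
    intensities:
        DataFrame of positive fluorescence intensities, probes as the index,
        samples as columns. Missing cells (after bad-spot removal) are NaN.
    bad_spots:
        Optional boolean DataFrame of the same shape flagging unreliable
        features (scratches, saturated pixels, ...).
    background:
        Optional per-probe DataFrame with columns ``bg_mean`` and ``bg_sd``,
        the local-background statistics used by the detectability filter.
    """

    intensities: pd.DataFrame
    bad_spots: pd.DataFrame | None = None
    background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.duplicated().any():
            raise DataError("duplicate probe ids in expression matrix")
        if cols.duplicated().any():
            raise DataError("duplicate sample ids in expression matrix")
        values = self.intensities.to_numpy(dtype=float)
        if np.any(values[~np.isnan(values)] <= 0):
            raise DataError("expression intensities must be strictly positive")
        if self.bad_spots is not None:
            if self.bad_spots.shape != self.intensities.shape:
                raise DataError("bad_spots shape does not match intensities")
            self.bad_spots = self.bad_spots.astype(bool)
            self.bad_spots.index = idx
            self.bad_spots.columns = cols
        if self.background is not None:
            for col in ("bg_mean", "bg_sd"):
                if col not in self.background.columns:
                    raise DataError(f"background table is missing '{col}'")
            if not self.background.index.equals(idx):
                self.background = self.background.reindex(idx)
                if self.background[["bg_mean", "bg_sd"]].isna().any().any():
                    raise DataError("background table does not cover all probes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def subset_probes(self, probes) -> "ExpressionMatrix":
        """Return a copy restricted to ``probes`` (order as given)."""
        return ExpressionMatrix(
            intensities=self.intensities.loc[probes].copy(),
            bad_spots=None if self.bad_spots is None else self.bad_spots.loc[probes].copy(),
            background=None if self.background is None else self.background.loc[probes].copy(),
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=self.intensities.copy(),
            bad_spots=None if self.bad_spots is None else self.bad_spots.copy(),
            background=None if self.background is None else self.background.copy(),
        )


@dataclass
class FoldChangeProfile:
    """Unlogged per-sample expression ratios to the control kidney profile.

    ``cohort_mean`` is the arithmetic mean of the per-sample ratios across the
    cohort samples (for a single control column this equals the ratio of mean
    signals to the control signal). ``detectable`` marks probes that passed
    the background-significance filter; downstream stages restrict themselves
    to detectable probes.
    """

    ratios: pd.DataFrame
    cohort_mean: pd.Series
    control: pd.Series
    floor: float
    detectable: pd.Series = field(default=None)  # type: ignore[assignment]
    cohort_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.detectable is None:
            self.detectable = pd.Series(True, index=self.ratios.index)
        self.detectable = self.detectable.reindex(self.ratios.index, fill_value=False).astype(bool)
        values = self.ratios.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise DataError("fold-change ratios must be finite and strictly positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.ratios.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ratios.columns

    def detectable_probes(self) -> pd.Index:
        return self.ratios.index[self.detectable.to_numpy()]
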