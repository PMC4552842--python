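"""Synthetic renal-biopsy cohort generator.

Emulates the statistical structure of a one-color microarray study of CKD
biopsies: tens of thousands of probes, a discovery set (~48 biopsies) plus a
small validation set, and a single normal-kidney control profile. A small
panel of marker genes is planted whose log2 expression ratio to control rises
linearly with the tubular-cell-damage grade; the tubulointerstitial-fibrosis
grade is generated as a correlated ordinal through a Gaussian copula. A
configurable fraction of non-marker probes receives grade-independent up/down
shifts (disease effects unrelated to grade), and bad spots / near-background
probes are planted so the preprocessing filters have real work to do.

Everything is reproducible from ``SimulationParams.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    DISCOVERY_DISEASE_COUNTS,
    GRADE_MAX,
    GRADE_MIN,
    MARKER_GENES,
    METADATA_COLUMNS,
    ExpressionMatrix,
    ParameterError,
    validate_metadata,
)

CONTROL_ID = "CONTROL"

_COHORT_FILES = {
    "expression": "expression.tsv",
    "control": "control.tsv",
    "background": "background.tsv",
    "flags": "flags.tsv",
    "metadata": "metadata.tsv",
    "annotation": "annotation.tsv",
    "truth": "truth.json",
}


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-generator settings.

    Defaults reproduce the study conditions the pipeline is designed for:
    48 discovery + 5 validation biopsies over 20 000 probes, five marker
    genes with two probes each whose log2 fold change grows by
    ``effect_slope_log2`` per grade unit, log-normal multiplicative noise,
    and two histopathology grades with rank correlation ~0.8 drawn uniformly
    from grades 1–4.
    """

    n_probes: int = 20000
    n_marker_genes: int = 5
    probes_per_marker_gene: int = 2
    n_discovery: int = 48
    n_validation: int = 5
    grade_range: tuple[int, int] = (1, 4)
    effect_slope_log2: float = 0.8
    background_de_fraction: float = 0.02
    noise_sd_log2: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    bad_spot_fraction: float = 0.01
    undetectable_fraction: float = 0.15
    grade_correlation: float = 0.8
    seed: int = 0

    def validate(self) -> "SimulationParams":
        def _require(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ParameterError(f"invalid {name}: {why}")

        _require(self.n_probes >= 1, "n_probes", "must be a positive integer")
        _require(self.n_marker_genes >= 1, "n_marker_genes", "must be a positive integer")
        _require(
            self.probes_per_marker_gene >= 1,
            "probes_per_marker_gene",
            "must be a positive integer",
        )
        _require(
            self.n_marker_genes * self.probes_per_marker_gene <= self.n_probes,
            "n_marker_genes",
            "marker probes cannot exceed n_probes",
        )
        _require(self.n_discovery >= 1, "n_discovery", "must be a positive integer")
        _require(self.n_validation >= 0, "n_validation", "must be non-negative")
        lo, hi = self.grade_range
        _require(
            GRADE_MIN <= lo <= hi <= GRADE_MAX,
            "grade_range",
            f"must be an ordered pair within [{GRADE_MIN}, {GRADE_MAX}]",
        )
        _require(self.effect_slope_log2 >= 0, "effect_slope_log2", "must be >= 0")
        _require(
            0 <= self.background_de_fraction < 1,
            "background_de_fraction",
            "must lie in [0, 1)",
        )
        _require(self.noise_sd_log2 > 0, "noise_sd_log2", "must be > 0")
        _require(self.baseline_log2_sd >= 0, "baseline_log2_sd", "must be >= 0")
        _require(0 <= self.bad_spot_fraction < 1, "bad_spot_fraction", "must lie in [0, 1)")
        _require(
            0 <= self.undetectable_fraction < 1,
            "undetectable_fraction",
            "must lie in [0, 1)",
        )
        _require(0 <= self.grade_correlation <= 1, "grade_correlation", "must lie in [0, 1]")
        return self


@dataclass
class SyntheticTruth:
    """Record of the structure planted by :func:`generate_cohort`."""

    marker_probe_ids: set[str]
    grade_independent_up: set[str]
    grade_independent_down: set[str]
    undetectable_probe_ids: set[str]
    per_sample_grades: dict[str, tuple[int, int]]  # (fibrosis, tubular)
    marker_genes: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        shifted = self.grade_independent_up | self.grade_independent_down
        if self.marker_probe_ids & shifted:
            raise ParameterError("marker probes overlap grade-independent sets")

    def to_json(self) -> str:
        payload = {
            "marker_probe_ids": sorted(self.marker_probe_ids),
            "grade_independent_up": sorted(self.grade_independent_up),
            "grade_independent_down": sorted(self.grade_independent_down),
            "undetectable_probe_ids": sorted(self.undetectable_probe_ids),
            "per_sample_grades": {k: list(v) for k, v in self.per_sample_grades.items()},
            "marker_genes": list(self.marker_genes),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(
            marker_probe_ids=set(payload["marker_probe_ids"]),
            grade_independent_up=set(payload["grade_independent_up"]),
            grade_independent_down=set(payload["grade_independent_down"]),
            undetectable_probe_ids=set(payload["undetectable_probe_ids"]),
            per_sample_grades={
                k: (int(v[0]), int(v[1])) for k, v in payload["per_sample_grades"].items()
            },
            marker_genes=tuple(payload["marker_genes"]),
            seed=int(payload["seed"]),
        )


@dataclass
class Cohort:
    """Bundle returned by :func:`generate_cohort`."""

    matrix: ExpressionMatrix
    control: pd.Series
    metadata: pd.DataFrame
    annotation: pd.Series  # probe_id -> gene symbol
    truth: SyntheticTruth

    def discovery_ids(self) -> list[str]:
        return list(self.metadata.index[self.metadata["role"] == "discovery"])

    def validation_ids(self) -> list[str]:
        return list(self.metadata.index[self.metadata["role"] == "validation"])


def _marker_gene_names(n: int) -> tuple[str, ...]:
    names = list(MARKER_GENES[:n])
    names += [f"MARKER{i + 1}" for i in range(len(names), n)]
    return tuple(names)


def _discretized_corr(rho: float, levels: int) -> float:
    """Population correlation of two uniform ordinals from a Gaussian copula.

    With uniform margins and average-rank ties, the Spearman correlation of
    the discretized grades equals their Pearson correlation (midranks are
    affine in the level index), so this is the quantity the generator must
    calibrate against.
    """
    cuts = stats.norm.ppf(np.linspace(0, 1, levels + 1))
    cdf = np.empty((levels + 1, levels + 1))
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    for i, a in enumerate(cuts):
        for j, b in enumerate(cuts):
            if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                cdf[i, j] = 0.0
            elif np.isinf(a) and np.isinf(b):
                cdf[i, j] = 1.0
            elif np.isinf(a):
                cdf[i, j] = stats.norm.cdf(b)
            elif np.isinf(b):
                cdf[i, j] = stats.norm.cdf(a)
            else:
                cdf[i, j] = mvn.cdf([a, b])
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    g = np.arange(levels, dtype=float)
    mu = g.mean()
    var = ((g - mu) ** 2).mean()
    if var == 0:
        return 1.0
    cov = float(np.outer(g - mu, g - mu).ravel() @ cell.ravel())
    return cov / var


@lru_cache(maxsize=None)
def _latent_rho(target: float, levels: int) -> float:
    """Latent copula correlation whose discretized-grade correlation is ``target``."""
    if levels <= 1 or target >= 1.0:
        return 1.0
    if target <= 0.0:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _discretized_corr(mid, levels) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_grades(
    rng: np.random.Generator, n: int, grade_range: tuple[int, int], rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (fibrosis, tubular) ordinal grades via a Gaussian copula.

    Both margins are uniform over the inclusive grade range. The latent
    bivariate-normal correlation is chosen so that the *discretized* grades
    have (population) Spearman correlation ``rho``, compensating for the
    attenuation introduced by binning.
    """
    lo, hi = grade_range
    levels = hi - lo + 1
    latent = _latent_rho(round(float(rho), 6), levels)
    z_t = rng.standard_normal(n)
    z_f = latent * z_t + np.sqrt(max(0.0, 1 - latent**2)) * rng.standard_normal(n)
    u_t = stats.norm.cdf(z_t)
    u_f = stats.norm.cdf(z_f)
    tubular = lo + np.minimum((u_t * levels).astype(int), levels - 1)
    fibrosis = lo + np.minimum((u_f * levels).astype(int), levels - 1)
    return fibrosis, tubular


def _assign_diseases(rng: np.random.Generator, n: int) -> list[str]:
    """Disease labels with the frequencies of the 48-patient reference cohort.

    For n == 48 the exact counts are used (shuffled); otherwise labels are
    drawn from the corresponding categorical distribution.
    """
    codes = list(DISCOVERY_DISEASE_COUNTS)
    counts = np.array([DISCOVERY_DISEASE_COUNTS[c] for c in codes], dtype=float)
    if n == int(counts.sum()):
        labels = np.repeat(codes, counts.astype(int))
        rng.shuffle(labels)
        return list(labels)
    probs = counts / counts.sum()
    return list(rng.choice(codes, size=n, p=probs))


def generate_cohort(params: SimulationParams) -> Cohort:
    """Generate a synthetic biopsy cohort with planted grade-driven markers.

    The tubular-cell-damage grade drives marker expression: a marker probe's
    expected log2 ratio to the control profile is
    ``effect_slope_log2 × tubular_damage_grade``. The fibrosis grade is a
    correlated ordinal. Non-marker probes are null except for a
    ``background_de_fraction`` given grade-independent shifts.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_probes = params.n_probes
    probe_ids = np.array([f"P{i:06d}" for i in range(n_probes)], dtype=object)
    genes = _marker_gene_names(params.n_marker_genes)

    # Marker probes come first and are named after their gene so annotation is
    # self-describing; remaining probes map to a synthetic per-probe gene id.
    n_marker_probes = params.n_marker_genes * params.probes_per_marker_gene
    marker_probe_ids = []
    annotation = {}
    for gi, gene in enumerate(genes):
        for pi in range(params.probes_per_marker_gene):
            pid = f"{gene}_p{pi + 1}"
            marker_probe_ids.append(pid)
            annotation[pid] = gene
    probe_ids[:n_marker_probes] = marker_probe_ids
    for pid in probe_ids[n_marker_probes:]:
        annotation[pid] = f"GENE_{pid}"
    annotation = pd.Series(annotation, name="gene").loc[probe_ids]
    annotation.index.name = "probe_id"

    # Samples and grades.
    sample_ids = [f"D{i + 1:03d}" for i in range(params.n_discovery)] + [
        f"V{i + 1:02d}" for i in range(params.n_validation)
    ]
    n_samples = len(sample_ids)
    fibrosis, tubular = _draw_grades(
        rng, n_samples, params.grade_range, params.grade_correlation
    )
    diseases = _assign_diseases(rng, params.n_discovery)
    diseases += list(
        rng.choice(list(DISCOVERY_DISEASE_COUNTS), size=params.n_validation)
    )
    roles = ["discovery"] * params.n_discovery + ["validation"] * params.n_validation
    metadata = pd.DataFrame(
        {
            "disease": diseases,
            "fibrosis_grade": fibrosis,
            "tubular_damage_grade": tubular,
            "role": roles,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # The control is a normal kidney pool: 0% lesion area on both scales.
    metadata.loc[CONTROL_ID] = {
        "disease": "other",
        "fibrosis_grade": 0,
        "tubular_damage_grade": 0,
        "role": "control",
    }
    metadata["fibrosis_grade"] = metadata["fibrosis_grade"].astype(int)
    metadata["tubular_damage_grade"] = metadata["tubular_damage_grade"].astype(int)
    validate_metadata(metadata)

    # Per-probe baselines and background statistics.
    baseline = params.baseline_log2_mean + params.baseline_log2_sd * rng.standard_normal(
        n_probes
    )
    # Markers must stay comfortably detectable, otherwise the score is moot.
    baseline[:n_marker_probes] = np.maximum(
        baseline[:n_marker_probes], params.baseline_log2_mean
    )
    bg_mean = 2.0 ** (5.0 + 0.3 * rng.standard_normal(n_probes))
    bg_sd = 0.25 * bg_mean

    # Planted near-background probes: expression sits at the local background
    # level so the detectability z-test should reject them.
    n_undetectable = int(round(params.undetectable_fraction * (n_probes - n_marker_probes)))
    undetectable_idx = n_marker_probes + rng.choice(
        n_probes - n_marker_probes, size=n_undetectable, replace=False
    )
    baseline[undetectable_idx] = np.log2(bg_mean[undetectable_idx])

    # Grade-independent disease effects on a fraction of the remaining nulls.
    eligible = np.setdiff1d(
        np.arange(n_marker_probes, n_probes), undetectable_idx, assume_unique=False
    )
    n_shift = int(round(params.background_de_fraction * eligible.size))
    shifted_idx = rng.choice(eligible, size=n_shift, replace=False) if n_shift else np.array([], int)
    shift_log2 = rng.uniform(0.5, 2.0, size=n_shift) * rng.choice([-1.0, 1.0], size=n_shift)

    # Expected log2 expression per probe per column (samples + control).
    expected = np.tile(baseline[:, None], (1, n_samples + 1))
    expected[:n_marker_probes, :n_samples] += (
        params.effect_slope_log2 * tubular[None, :]
    )
    if n_shift:
        expected[shifted_idx, :n_samples] += shift_log2[:, None]

    noise = params.noise_sd_log2 * rng.standard_normal(expected.shape)
    log2_intensity = expected + noise
    intensities = 2.0**log2_intensity

    columns = sample_ids + [CONTROL_ID]
    pidx = pd.Index(probe_ids, name="probe_id")
    full = pd.DataFrame(intensities, index=pidx, columns=columns)
    control = full[CONTROL_ID].rename(CONTROL_ID)
    expr = full[sample_ids]

    flags = None
    if params.bad_spot_fraction > 0:
        flags = pd.DataFrame(
            rng.random((n_probes, n_samples)) < params.bad_spot_fraction,
            index=pidx,
            columns=sample_ids,
        )
    background = pd.DataFrame({"bg_mean": bg_mean, "bg_sd": bg_sd}, index=pidx)

    matrix = ExpressionMatrix(intensities=expr, bad_spots=flags, background=background)
    truth = SyntheticTruth(
        marker_probe_ids=set(marker_probe_ids),
        grade_independent_up=set(probe_ids[shifted_idx[shift_log2 > 0]]) if n_shift else set(),
        grade_independent_down=set(probe_ids[shifted_idx[shift_log2 < 0]]) if n_shift else set(),
        undetectable_probe_ids=set(probe_ids[undetectable_idx]),
        per_sample_grades={
            s: (int(f), int(t)) for s, f, t in zip(sample_ids, fibrosis, tubular)
        },
        marker_genes=genes,
        seed=params.seed,
    )
    return Cohort(
        matrix=matrix, control=control, metadata=metadata, annotation=annotation, truth=truth
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as the standard tab-delimited file set plus truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _COHORT_FILES.items()}

    expr = cohort.matrix.intensities.copy()
    expr.index.name = "probe_id"
    expr.to_csv(paths["expression"], sep="\t")

    control = cohort.control.to_frame(name="intensity")
    control.index.name = "probe_id"
    control.to_csv(paths["control"], sep="\t")

    bg = cohort.matrix.background
    if bg is not None:
        bg = bg.copy()
        bg.index.name = "probe_id"
        bg.to_csv(paths["background"], sep="\t")

    if cohort.matrix.bad_spots is not None:
        flags = cohort.matrix.bad_spots.astype(int).copy()
        flags.index.name = "probe_id"
        flags.to_csv(paths["flags"], sep="\t")

    meta = cohort.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(paths["metadata"], sep="\t")

    ann = cohort.annotation.to_frame(name="gene")
    ann.index.name = "probe_id"
    ann.to_csv(paths["annotation"], sep="\t")

    paths["truth"].write_text(cohort.truth.to_json())
    return paths


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (optional files may be absent)."""
    directory = Path(directory)
    required = ["expression", "control", "metadata"]
    for key in required + ["truth", "annotation"]:
        path = directory / _COHORT_FILES[key]
        if key in required and not path.exists():
            raise FileNotFoundError(f"cohort directory is missing {path.name}: {path}")

    expr = pd.read_csv(directory / _COHORT_FILES["expression"], sep="\t", index_col="probe_id")
    control = pd.read_csv(
        directory / _COHORT_FILES["control"], sep="\t", index_col="probe_id"
    )["intensity"].rename(CONTROL_ID)

    bg_path = directory / _COHORT_FILES["background"]
    background = (
        pd.read_csv(bg_path, sep="\t", index_col="probe_id") if bg_path.exists() else None
    )
    flags_path = directory / _COHORT_FILES["flags"]
    flags = (
        pd.read_csv(flags_path, sep="\t", index_col="probe_id").astype(bool)
        if flags_path.exists()
        else None
    )
    metadata = pd.read_csv(directory / _COHORT_FILES["metadata"], sep="\t", index_col="sample_id")
    validate_metadata(metadata)

    ann_path = directory / _COHORT_FILES["annotation"]
    if ann_path.exists():
        annotation = pd.read_csv(ann_path, sep="\t", index_col="probe_id")["gene"]
    else:
        annotation = pd.Series(expr.index, index=expr.index, name="gene")

    truth_path = directory / _COHORT_FILES["truth"]
    if truth_path.exists():
        truth = SyntheticTruth.from_json(truth_path.read_text())
    else:
        truth = SyntheticTruth(set(), set(), set(), set(), {}, (), seed=-1)

    matrix = ExpressionMatrix(intensities=expr, bad_spots=flags, background=background)
    return Cohort(matrix=matrix, control=control, metadata=metadata, annotation=annotation, truth=truth)


def params_with(params: SimulationParams, **overrides) -> SimulationParams:
    """Return a copy of ``params`` with fields replaced."""
    return dataclasses.replace(params, **overrides).validate()
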