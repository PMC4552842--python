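"""End-to-end orchestration: simulate/read → preprocess → DEG → grade
association → molecular score → thresholds → validation predictions.

A single :class:`PipelineConfig` drives the run; every stage writes its table
under the output directory and the run finishes with a machine-readable
``report.json`` whose content is fully determined by the config and seed
(no timestamps), so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import dual_endpoint_selection, subset_by_disease
from .containers import (
    DEFAULT_DISEASE_SUBSET,
    MARKER_GENES,
    DataError,
    FoldChangeProfile,
    ParameterError,
)
from .deg import collapse_to_genes, select_deg, zscore_fold_changes
from .preprocess import (
    compute_fold_change,
    filter_detectable,
    flag_and_drop_bad_spots,
    median_normalize,
)
from .scoring import (
    derive_thresholds,
    grade_dichotomization_auc,
    molecular_score,
    validate_cohort,
)
from .simulate import CONTROL_ID, Cohort, SimulationParams, generate_cohort, read_cohort

logger = logging.getLogger("ckdms")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "write_fold_change", "read_fold_change"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run.

    ``input_dir`` reads a cohort written in the standard tab-delimited layout;
    when it is None a synthetic cohort is generated from ``simulation`` (with
    ``seed`` overriding the simulation seed so one value controls the run).
    """

    input_dir: str | None = None
    simulation: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0
    # preprocessing
    max_missing_fraction: float = 0.2
    detect_alpha: float = 0.05
    detect_quorum: float = 0.5
    fc_floor: float | None = None
    # DEG selection
    z_cutoff: float = 2.0
    z_scale: str = "log2"
    # grade association
    diseases: tuple[str, ...] = DEFAULT_DISEASE_SUBSET
    alpha: float = 0.05
    adjust: str | None = None
    # scoring
    marker_genes: tuple[str, ...] = MARKER_GENES
    markers_from_selection: bool = False
    threshold_method: str = "youden"
    threshold_endpoint: str = "pooled"
    lower_cut: int = 2
    upper_cut: int = 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["grade_range"] = list(self.simulation.grade_range)
        d["diseases"] = list(self.diseases)
        d["marker_genes"] = list(self.marker_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            if "grade_range" in sim:
                sim["grade_range"] = tuple(sim["grade_range"])
            sim = SimulationParams(**sim)
        for key in ("diseases", "marker_genes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(simulation=sim, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_fold_change(fc: FoldChangeProfile, directory: str | Path) -> None:
    """Write ``fold_change.tsv`` and ``detectability.tsv``."""
    directory = Path(directory)
    table = fc.ratios.copy()
    table.insert(0, "cohort_mean_ratio", fc.cohort_mean)
    table.index.name = "probe_id"
    table.to_csv(directory / "fold_change.tsv", sep="\t")
    det = fc.detectable.astype(int).to_frame("detectable")
    det.index.name = "probe_id"
    det.to_csv(directory / "detectability.tsv", sep="\t")


def read_fold_change(
    directory: str | Path, cohort_samples: list[str] | None = None
) -> FoldChangeProfile:
    """Read the tables written by :func:`write_fold_change`.

    The control column and floor are not persisted (the ratios already embed
    them); placeholders are used so the profile supports downstream stages.
    """
    directory = Path(directory)
    table = pd.read_csv(directory / "fold_change.tsv", sep="\t", index_col="probe_id")
    cohort_mean = table.pop("cohort_mean_ratio")
    det_path = directory / "detectability.tsv"
    detectable = (
        pd.read_csv(det_path, sep="\t", index_col="probe_id")["detectable"].astype(bool)
        if det_path.exists()
        else pd.Series(True, index=table.index)
    )
    return FoldChangeProfile(
        ratios=table,
        cohort_mean=cohort_mean,
        control=pd.Series(np.nan, index=table.index),
        floor=float("nan"),
        detectable=detectable,
        cohort_samples=tuple(cohort_samples or []),
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (DataError, ParameterError, FileNotFoundError) as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("input")
def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.input_dir is not None:
        return read_cohort(config.input_dir)
    params = dataclasses.replace(config.simulation, seed=config.seed)
    return generate_cohort(params)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, write all outputs under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }

    cohort = _load_cohort(config)
    meta = cohort.metadata
    discovery = cohort.discovery_ids()
    validation = cohort.validation_ids()
    logger.info("stage=input probes=%d samples=%d discovery=%d validation=%d",
                cohort.matrix.shape[0], cohort.matrix.shape[1], len(discovery), len(validation))
    report["stages"]["input"] = {
        "n_probes": int(cohort.matrix.shape[0]),
        "n_samples": int(cohort.matrix.shape[1]),
        "n_discovery": len(discovery),
        "n_validation": len(validation),
    }

    # --- preprocessing: bad spots -> joint median normalization -> filter ----
    @_stage("preprocess")
    def _preprocess():
        from .containers import ExpressionMatrix

        joint = cohort.matrix.intensities.copy()
        joint[CONTROL_ID] = cohort.control
        flags = None
        if cohort.matrix.bad_spots is not None:
            flags = cohort.matrix.bad_spots.copy()
            flags[CONTROL_ID] = False
        matrix = ExpressionMatrix(joint, bad_spots=flags, background=cohort.matrix.background)
        matrix = flag_and_drop_bad_spots(matrix, config.max_missing_fraction)
        matrix = median_normalize(matrix, "global")
        control = matrix.intensities[CONTROL_ID]
        samples_only = ExpressionMatrix(
            intensities=matrix.intensities.drop(columns=[CONTROL_ID]),
            background=matrix.background,
        )
        mask = filter_detectable(samples_only, config.detect_alpha, config.detect_quorum)
        fc = compute_fold_change(
            samples_only,
            control,
            floor=config.fc_floor,
            detectable=mask.per_probe,
            cohort_samples=[s for s in samples_only.sample_ids if s in set(discovery)],
        )
        return fc

    fc = _preprocess()
    write_fold_change(fc, outdir)
    n_detectable = int(fc.detectable.sum())
    logger.info("stage=preprocess probes_kept=%d detectable=%d", fc.ratios.shape[0], n_detectable)
    report["stages"]["preprocess"] = {
        "n_probes_after_bad_spots": int(fc.ratios.shape[0]),
        "n_detectable": n_detectable,
        "fold_change_floor": float(fc.floor),
    }

    # --- DEG selection ------------------------------------------------------
    @_stage("deg_selection")
    def _deg():
        result = zscore_fold_changes(fc, cutoff=config.z_cutoff, scale=config.z_scale)
        up, down = select_deg(result)
        return result, up, down

    deg_result, up, down = _deg()
    table = deg_result.table.copy()
    table["gene"] = cohort.annotation.reindex(table.index)
    table.index.name = "probe_id"
    table.to_csv(outdir / "deg.tsv", sep="\t")
    genes = collapse_to_genes(deg_result, cohort.annotation)
    n_up_genes = int((genes["direction"] == "up").sum())
    n_down_genes = int((genes["direction"] == "down").sum())
    logger.info("stage=deg up=%d down=%d up_genes=%d down_genes=%d",
                len(up), len(down), n_up_genes, n_down_genes)
    report["stages"]["deg_selection"] = {
        "z_cutoff": config.z_cutoff,
        "n_up_probes": len(up),
        "n_down_probes": len(down),
        "n_up_genes": n_up_genes,
        "n_down_genes": n_down_genes,
    }

    # --- grade association on the disease-restricted subset -----------------
    @_stage("grade_association")
    def _associate():
        subset = subset_by_disease(meta, config.diseases)
        subset = [s for s in subset if s in set(fc.sample_ids)]
        if not up:
            return None, subset
        assoc = dual_endpoint_selection(
            fc, meta, candidates=up, alpha=config.alpha,
            sample_ids=subset, adjust=config.adjust,
        )
        return assoc, subset

    assoc, subset = _associate()
    if assoc is None:
        report["warnings"].append(
            "no up-regulated probes; grade association skipped, configured markers used"
        )
        selected_probes: list[str] = []
        n_fib = n_tub = 0
    else:
        out = assoc.table.copy()
        out["gene"] = cohort.annotation.reindex(out.index)
        out.to_csv(outdir / "association.tsv", sep="\t")
        selected_probes = list(assoc.selected)
        n_fib = len(assoc.fibrosis_significant)
        n_tub = len(assoc.tubular_significant)
        if not selected_probes:
            report["warnings"].append("no probe passed dual-endpoint selection")
    selected_genes = sorted(set(cohort.annotation.reindex(selected_probes))) if selected_probes else []
    logger.info("stage=associate subset=%d candidates=%d fib=%d tub=%d selected=%d",
                len(subset), len(up), n_fib, n_tub, len(selected_probes))
    report["stages"]["grade_association"] = {
        "n_subset_samples": len(subset),
        "n_candidates": len(up),
        "n_fibrosis_significant": n_fib,
        "n_tubular_significant": n_tub,
        "n_selected_probes": len(selected_probes),
        "selected_genes": selected_genes,
    }

    # --- molecular score, thresholds, validation ----------------------------
    @_stage("scoring")
    def _score():
        if config.markers_from_selection and selected_genes:
            markers = tuple(selected_genes)
        else:
            markers = tuple(config.marker_genes)
        score = molecular_score(fc, cohort.annotation, markers)
        roc_table = grade_dichotomization_auc(score, meta, sample_ids=[
            s for s in score.scores.index if s in set(discovery)
        ])
        thresholds = derive_thresholds(
            score, meta,
            method=config.threshold_method,
            endpoint=config.threshold_endpoint,
            sample_ids=[s for s in score.scores.index if s in set(discovery)],
            lower_cut=config.lower_cut,
            upper_cut=config.upper_cut,
        )
        predictions = validate_cohort(
            fc, cohort.annotation, thresholds, meta,
            marker_probes=score.marker_probes,
            sample_ids=[s for s in score.scores.index if s in set(validation)],
        )
        return markers, score, roc_table, thresholds, predictions

    markers, score, roc_table, thresholds, predictions = _score()

    scores_out = score.scores.to_frame()
    scores_out["role"] = meta.reindex(scores_out.index)["role"]
    scores_out.index.name = "sample_id"
    scores_out.to_csv(outdir / "scores.tsv", sep="\t")
    roc_table.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    (outdir / "thresholds.json").write_text(json.dumps({
        "threshold_I": thresholds.threshold_I,
        "threshold_II": thresholds.threshold_II,
        "method": thresholds.method,
        "endpoint": thresholds.endpoint,
        "clipped": thresholds.clipped,
        "n_discovery": len(thresholds.sample_ids),
    }, indent=2, sort_keys=True))
    predictions.to_csv(outdir / "predictions.tsv", sep="\t")

    composite = {
        row["dichotomization"]: (None if pd.isna(row["auc"]) else round(float(row["auc"]), 6))
        for _, row in roc_table[roc_table["endpoint"] == "composite"].iterrows()
    }
    concord = {
        col: int(predictions[col].sum())
        for col in predictions.columns
        if col.startswith("concordant_")
    } if len(predictions) else {}
    logger.info("stage=score markers=%s threshold_I=%.4g threshold_II=%.4g",
                ",".join(markers), thresholds.threshold_I, thresholds.threshold_II)
    report["stages"]["scoring"] = {
        "marker_genes": list(markers),
        "marker_probes": list(score.marker_probes),
        "composite_auc": composite,
        "threshold_I": thresholds.threshold_I,
        "threshold_II": thresholds.threshold_II,
        "threshold_clipped": thresholds.clipped,
        "n_validation_predicted": int(len(predictions)),
        "validation_concordance": concord,
    }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
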