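"""End-to-end orchestration: simulate/load -> quantify -> QC -> zonation -> ML.

``run_pipeline`` executes the stages in order, writes every declared
output as plain text under the output directory, and finishes with a
machine-readable run manifest recording the effective configuration and
its content hash.  Any stage failure aborts with the stage name and
cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, imaging, io, qc, quant, simulate, zonation
from .config import PipelineConfig

__all__ = ["run_pipeline", "PipelineError", "square_contour", "features_from_truth"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def square_contour(cx: float, cy: float, area_um2: float, pixel_size_um: float = 1.0) -> imaging.Contour:
    """Axis-aligned square contour of a given area centred at (cx, cy)."""
    half = float(np.sqrt(area_um2) / (2.0 * pixel_size_um))
    v = np.array([
        [cx - half, cy - half], [cx + half, cy - half],
        [cx + half, cy + half], [cx - half, cy + half],
    ])
    return imaging.Contour(v, pixel_size_um)


def features_from_truth(
    truth: simulate.LobuleTruth,
    patches: dict[str, np.ndarray],
) -> pd.DataFrame:
    """17-feature table for simulated cells (square stand-in contours)."""
    rows = {}
    for cell_id, cell in truth.cells.iterrows():
        contour = square_contour(cell["x"], cell["y"], cell["area_um2"])
        rows[cell_id] = imaging.extract_features(patches[cell_id], contour)
    feats = pd.DataFrame(rows).T
    return feats[list(imaging.FEATURE_NAMES)]


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, err) from err
        return wrapper
    return decorator


@dataclass
class PipelineResult:
    matrix: pd.DataFrame              # normalised protein x cell log2 matrix (retained cells)
    qc_report: pd.DataFrame
    zonation_table: pd.DataFrame
    class_model: classify.ProteomeClassModel
    classifier_report: classify.ClassifierReport
    predicted: pd.DataFrame
    outputs: dict[str, str]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Simulator-driven end-to-end run writing all declared outputs.

    Stages: synthetic section -> report quantification -> sample QC and
    median normalisation -> spatial binning and zonation statistics ->
    image features -> proteome classes, classifier and weighted
    proteome prediction.  Deterministic for a fixed config (seed
    included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    sim = config.simulator

    @_stage("simulate")
    def _simulate():
        truth = simulate.simulate_lobule(sim.n_cells, sim, seed=config.seed)
        true_matrix = simulate.simulate_proteome(truth, sim)
        report = simulate.simulate_report(true_matrix, truth, sim)
        patches = simulate.simulate_images(truth, sim)
        io.write_report(report, outdir / "report.tsv")
        io.write_cells(truth.cells, outdir / "cells.csv")
        truth.cells.to_csv(outdir / "truth_cells.csv")  # ground truth, separate file
        if truth.ratios is not None:
            truth.ratios.to_csv(outdir / "truth_ratios.csv", index=False)
        outputs["report"] = str(outdir / "report.tsv")
        outputs["cells"] = str(outdir / "cells.csv")
        return truth, report, patches

    truth, report, patches = _simulate()

    @_stage("quantify")
    def _quantify():
        matrix = quant.quantify_report(report, config.report_filter)
        # sample ids are run.channel; translate to cell ids
        key = truth.cells["run"].astype(str) + "." + truth.cells["channel"].astype(str)
        mapping = dict(zip(key, truth.cells.index))
        matrix = matrix.rename(columns=mapping)
        io.write_matrix(matrix, outdir / "protein_matrix.csv")
        outputs["protein_matrix"] = str(outdir / "protein_matrix.csv")
        return matrix

    matrix = _quantify()

    @_stage("qc_normalize")
    def _qc():
        areas = truth.cells["area_um2"].reindex(matrix.columns)
        table = qc.qc_table(matrix, areas, config.qc)
        retained = table.index[table["excluded_reason"] == "none"]
        normalized, norm_set = qc.median_normalize(
            matrix[retained], config.qc.normalize_completeness_fallback
        )
        table.to_csv(outdir / "qc_report.csv")
        io.write_matrix(normalized, outdir / "protein_matrix_normalized.csv")
        outputs["qc_report"] = str(outdir / "qc_report.csv")
        outputs["protein_matrix_normalized"] = str(outdir / "protein_matrix_normalized.csv")
        return normalized, table, norm_set

    normalized, qc_report, norm_set = _qc()

    @_stage("zonation")
    def _zonation():
        cells = truth.cells.loc[normalized.columns]
        r = zonation.relative_distance(cells["d_pv"].to_numpy(), cells["d_cv"].to_numpy())
        bins = zonation.assign_bins(r, config.zonation.n_bins)
        anova = zonation.zonation_anova(
            normalized, bins, config.zonation.completeness_min, config.zonation.moderate
        )
        flat = zonation.flatness_test(normalized, config.zonation.alpha)
        profile = zonation.bin_profile(normalized, bins, config.zonation.n_bins)
        table = anova.join(flat[["p_adj", "flat"]].rename(columns={"p_adj": "shapiro_p_adj"}))
        table.to_csv(outdir / "zonation_results.tsv", sep="\t")
        profile.to_csv(outdir / "bin_profiles.csv")
        pd.DataFrame({"sample_id": normalized.columns, "r": r, "bin": bins}).to_csv(
            outdir / "bin_assignment.csv", index=False
        )
        outputs["zonation_results"] = str(outdir / "zonation_results.tsv")
        outputs["bin_profiles"] = str(outdir / "bin_profiles.csv")
        outputs["bin_assignment"] = str(outdir / "bin_assignment.csv")
        return table, pd.Series(r, index=normalized.columns)

    zonation_table, r_series = _zonation()

    @_stage("image_features")
    def _features():
        feats = features_from_truth(truth, patches)
        feats.to_csv(outdir / "image_features.csv")
        outputs["image_features"] = str(outdir / "image_features.csv")
        return feats

    features = _features()

    @_stage("class_predict")
    def _classify():
        model = classify.kmeans_classes(
            normalized, r_series,
            n_classes=config.classify.n_classes,
            seed=config.classify.seed,
            completeness_min=config.zonation.pca_completeness_min,
            n_restarts=config.classify.kmeans_restarts,
        )
        feats = features.loc[normalized.columns]
        clf, report_ = classify.train_classifier(feats, model.labels, config.classify)
        proba = classify.predict_probabilities(clf, features)
        mu = classify.class_mean_proteomes(normalized, model.labels)
        predicted = classify.weighted_proteome_prediction(proba, mu)
        proba.to_csv(outdir / "class_probabilities.csv")
        predicted.to_csv(outdir / "predicted_proteome.csv")
        model.labels.to_csv(outdir / "proteome_classes.csv")
        with open(outdir / "classifier_report.json", "w") as fh:
            json.dump({
                "test_accuracy": report_.test_accuracy,
                "average_precision": report_.average_precision,
                "confusion": report_.confusion.tolist(),
                "neighbor_error_fraction": report_.neighbor_error_fraction,
            }, fh, indent=2)
        outputs["class_probabilities"] = str(outdir / "class_probabilities.csv")
        outputs["predicted_proteome"] = str(outdir / "predicted_proteome.csv")
        outputs["proteome_classes"] = str(outdir / "proteome_classes.csv")
        outputs["classifier_report"] = str(outdir / "classifier_report.json")
        return model, clf, report_, predicted

    model, clf, clf_report, predicted = _classify()

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "n_cells": int(sim.n_cells),
        "n_retained_samples": int((qc_report["excluded_reason"] == "none").sum()),
        "normalization_set_size": len(norm_set),
        "outputs": outputs,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    outputs["run_manifest"] = str(outdir / "run_manifest.json")

    return PipelineResult(
        matrix=normalized,
        qc_report=qc_report,
        zonation_table=zonation_table,
        class_model=model,
        classifier_report=clf_report,
        predicted=predicted,
        outputs=outputs,
    )
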