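"""Pipeline configuration: every threshold, seed and simulator parameter.

The configuration is a nested set of dataclasses with defaults equal to the
study's printed values (q-value cutoffs, 20 spatial bins, 5 proteome
classes, 0.2 test split, classifier seed 23, 135-1350 um2 contour gates).
It serialises to/from YAML and exposes a stable content hash that is
recorded in every run manifest so outputs are traceable to the exact
settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ReportFilterConfig",
    "QCConfig",
    "ZonationConfig",
    "ClassifyConfig",
    "ImagingConfig",
    "SimulatorConfig",
    "PipelineConfig",
]


@dataclass
class ReportFilterConfig:
    """Strict q-value cutoffs applied to precursor report rows."""

    lib_pg_q_max: float = 0.01
    q_value_max: float = 0.01
    channel_q_max: float = 0.15


@dataclass
class QCConfig:
    """Sample-level quality gates."""

    id_low_k: float = 1.5    # lower bound: median - id_low_k * sd
    id_high_k: float = 3.0   # upper bound: median + id_high_k * sd
    id_window: tuple[float, float] | None = None  # optional absolute ID-count window
    area_min_um2: float = 135.0
    area_max_um2: float = 1350.0
    pca_outlier_sd: float = 5.0  # robust-z threshold on PC1/PC2 scores
    # engaged only when no protein is 100% complete across retained samples
    normalize_completeness_fallback: float | None = 0.95


@dataclass
class ZonationConfig:
    """Portal-to-central axis binning and testing parameters."""

    n_bins: int = 20
    completeness_min: float = 0.5      # protein tested if observed in >=50% of samples
    pca_completeness_min: float = 0.7  # PCA uses proteins observed in >=70% of samples
    alpha: float = 0.05
    moderate: bool = True              # empirical-Bayes variance moderation


@dataclass
class ClassifyConfig:
    """Proteome-class clustering and image-feature classifier."""

    n_classes: int = 5
    test_fraction: float = 0.2
    seed: int = 23        # train/test split and forest seed
    n_trees: int = 200
    kmeans_restarts: int = 10


@dataclass
class ImagingConfig:
    """Image geometry settings.

    ``pixel_size_um`` is the pixel-to-micrometre calibration of the
    microscope setup and must be set for real data; the simulator works
    in a 1 um/px frame.
    """

    pixel_size_um: float = 1.0
    bbox_offset_px: int = 1000
    contour_remove_fraction: float = 0.99


@dataclass
class SimulatorConfig:
    """Synthetic zonated-lobule generator parameters.

    Defaults describe the study conditions: lognormal shape areas with
    median 600 um2 truncated at the 135-1350 um2 segmentation gates,
    ~400 analysed cells spanning the full portal-to-central axis, 40%
    zonated proteins at >=2 log2-unit amplitude, abundance- and
    area-dependent missingness, and zonated marker channels (E-cadherin
    portal at 568 nm, Glul central at 647 nm).
    """

    n_cells: int = 400
    n_proteins: int = 200
    zonated_fraction: float = 0.4

    # geometry (um); one portal and one central landmark bound the axis
    field_size: tuple[float, float] = (1000.0, 1000.0)
    pv_landmarks: tuple[tuple[float, float], ...] = ((0.0, 500.0),)
    cv_landmarks: tuple[tuple[float, float], ...] = ((1000.0, 500.0),)
    placement: str = "axis"           # "axis": uniform along the PV->CV segment
    transverse_jitter_um: float = 20.0

    # shape areas
    area_log_median_um2: float = 600.0
    area_log_sd: float = 0.4
    area_min_um2: float = 135.0
    area_max_um2: float = 1350.0

    # nuclear content; a slice through a hepatocyte may miss the nucleus
    anucleate_fraction: float = 0.25

    # ground-truth zonation profiles (log2 intensity units)
    baseline_mean: float = 12.0
    baseline_sd: float = 2.5
    amplitude_low: float = 2.0
    amplitude_high: float = 4.0
    breakpoint_low: float = 0.3
    breakpoint_high: float = 0.7
    gamma_low: float = 1.0
    gamma_high: float = 2.0

    # measurement model
    noise_sd: float = 0.5             # log2 residual sd per observation
    area_coef: float = 1.0            # log2 intensity per log2(area/median area)
    histone_coef: float = 2.0         # log2 intensity per unit nuclear fraction
    n_histones: int = 4
    histone_baseline: float = 17.0    # histones rank near the top of the abundance range
    detect_midpoint: float = 10.0     # logistic detection midpoint (log2 intensity)
    detect_scale: float = 1.5
    detect_saturation: float = 3.0    # certain detection above midpoint + saturation
    missingness: bool = True
    n_classes: int = 5                # ground-truth spatial classes (r quantiles)

    # fragment-level report
    precursors_per_protein: int = 2
    frag_per_precursor: int = 3
    ratio_noise_sd: float = 0.05      # multiplicative (log) noise on target/ref ratios
    ref_offset_log2: float = 2.0      # reference channel load above single-shape level
    ref_run_noise_sd: float = 0.1     # run-to-run reference level noise (log)
    ms1_share: float = 0.2            # fraction of reference signal carried by MS1
    q_fail_lib: float = 0.002         # fraction of rows failing Lib.PG.Q.Value
    q_fail_q: float = 0.002
    q_fail_channel: float = 0.01

    # image patches
    patch_size: int = 16
    pixel_noise_sd: float = 20.0
    ch568_base: float = 50.0
    ch568_amp: float = 150.0          # portal marker: decreasing in r
    ch647_base: float = 50.0
    ch647_amp: float = 150.0          # central marker: increasing in r
    ch425_level: float = 100.0        # phalloidin: uninformative
    ch488_base: float = 60.0
    ch488_nuclear_amp: float = 80.0   # WGA couples weakly to nuclear content


@dataclass
class PipelineConfig:
    """Top-level configuration bundle for an end-to-end run."""

    seed: int = 0
    report_filter: ReportFilterConfig = field(default_factory=ReportFilterConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    zonation: ZonationConfig = field(default_factory=ZonationConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "report_filter", "qc", "zonation", "classify", "imaging", "simulator",
            ):
                sub_cls = {
                    "report_filter": ReportFilterConfig,
                    "qc": QCConfig,
                    "zonation": ZonationConfig,
                    "classify": ClassifyConfig,
                    "imaging": ImagingConfig,
                    "simulator": SimulatorConfig,
                }[f.name]
                value = _coerce(sub_cls, value)
            kwargs[f.name] = value
        return cls(**kwargs)


def _coerce(sub_cls, value: dict):
    fields = {f.name: f for f in dataclasses.fields(sub_cls)}
    clean = {}
    for k, v in value.items():
        if k not in fields:
            raise ValueError(f"unknown config key {k!r} for {sub_cls.__name__}")
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        clean[k] = v
    return sub_cls(**clean)
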