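"""Sample-level quality control and complete-protein median normalisation.

Single-shape proteomes are excluded when their protein-identification
count is an outlier relative to the cohort (below median - 1.5 sd or
above median + 3 sd), when the contour area falls outside the
segmentation gates (135-1350 um2), or when the sample is a gross outlier
on the first two principal components.  The retained matrix is then
median-normalised against the set of proteins quantified in 100% of
retained samples, which corrects the dependence of summed signal on
shape size without letting partially observed proteins bias the offsets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import QCConfig

__all__ = [
    "id_count_filter",
    "size_filter",
    "median_normalize",
    "pca_outlier_flag",
    "qc_table",
]

log = logging.getLogger(__name__)


def id_count_filter(
    counts: pd.Series,
    low_k: float = 1.5,
    high_k: float = 3.0,
    window: tuple[float, float] | None = None,
) -> tuple[pd.Series, tuple[float, float]]:
    """Keep samples whose protein-ID count is within median -low_k*sd .. +high_k*sd.

    ``sd`` is the ordinary standard deviation (ddof=1) of the counts;
    the bounds are centred on the median.  With zero spread every sample
    is kept.  An optional absolute window (lo, hi) is additionally
    enforced, inclusive.  Returns the boolean keep mask and the realised
    (lower, upper) numeric bounds.
    """
    counts = counts.astype(float)
    if len(counts) < 3:
        raise ValueError("id_count_filter needs at least 3 samples")
    med = float(counts.median())
    sd = float(counts.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        lower, upper = -np.inf, np.inf
    else:
        lower, upper = med - low_k * sd, med + high_k * sd
    keep = (counts >= lower) & (counts <= upper)
    if window is not None:
        lo, hi = window
        keep &= (counts >= lo) & (counts <= hi)
    return keep, (lower, upper)


def size_filter(
    areas: pd.Series, min_um2: float = 135.0, max_um2: float = 1350.0
) -> pd.Series:
    """Keep shapes whose contour area is within the segmentation gates, inclusive.

    Non-positive areas are invalid records and are excluded.
    """
    areas = areas.astype(float)
    valid = areas > 0
    if (~valid).any():
        log.warning("%d samples have non-positive area; excluded as invalid", int((~valid).sum()))
    return valid & (areas >= min_um2) & (areas <= max_um2)


def median_normalize(
    matrix: pd.DataFrame, completeness_fallback: float | None = None
) -> tuple[pd.DataFrame, list]:
    """Median-normalise against proteins quantified in 100% of samples.

    The normalisation set holds every protein with zero missingness
    across the (already QC-filtered) samples.  Each sample is shifted in
    log space so its median over that set equals the global median of the
    per-sample medians.  Returns the normalised matrix and the
    normalisation set.

    If no protein is complete, a ``completeness_fallback`` threshold
    (e.g. 0.95) may relax the rule; without one this raises.
    """
    complete = matrix.dropna(axis=0)
    if complete.empty:
        if completeness_fallback is None:
            raise ValueError(
                "no protein is quantified in 100% of samples; "
                "set a completeness fallback threshold in the QC config"
            )
        frac = matrix.notna().mean(axis=1)
        complete = matrix.loc[frac >= completeness_fallback]
        if complete.empty:
            raise ValueError("normalisation set empty even at the fallback threshold")
        log.warning(
            "normalisation set relaxed to completeness >= %.2f (%d proteins)",
            completeness_fallback, complete.shape[0],
        )
    sample_medians = complete.median(axis=0)
    if sample_medians.isna().any():
        # fallback sets need not cover every sample; such samples stay unshifted
        n_bad = int(sample_medians.isna().sum())
        log.warning("%d samples observe no normalisation protein; left unshifted", n_bad)
    target = float(np.nanmedian(sample_medians))
    offsets = (sample_medians - target).fillna(0.0)
    return matrix.sub(offsets, axis=1), list(complete.index)


def pca_outlier_flag(matrix: pd.DataFrame, n_sd: float = 5.0) -> pd.Series:
    """Flag samples far out on PC1/PC2 (robust z beyond ``n_sd``).

    Robust spread is the median absolute deviation scaled to the normal
    (x1.4826); a component with zero spread flags nothing.
    """
    from .zonation import pca  # local import to avoid a module cycle

    if matrix.shape[1] < 2:
        raise ValueError("PCA outlier flagging needs at least 2 samples")
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    if np.nansum(centered.to_numpy() ** 2) == 0.0:
        return pd.Series(False, index=matrix.columns)
    result = pca(matrix, completeness_min=0.0, n_components=2)
    scores = result.scores  # samples x components
    flags = np.zeros(scores.shape[0], dtype=bool)
    for j in range(scores.shape[1]):
        col = scores.iloc[:, j].to_numpy()
        med = np.median(col)
        mad = np.median(np.abs(col - med)) * 1.4826
        if mad > 0:
            flags |= np.abs(col - med) > n_sd * mad
    return pd.Series(flags, index=scores.index)


def qc_table(
    matrix: pd.DataFrame,
    areas: pd.Series,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Apply all sample filters; one row per sample with the first-triggered reason.

    Reasons, in evaluation order: ``id_low``/``id_high`` (identification
    count), ``size`` (contour gates), ``pca_outlier``; retained samples
    carry ``none``.
    """
    config = config or QCConfig()
    counts = matrix.notna().sum(axis=0)
    keep_id, (lo, hi) = id_count_filter(
        counts, config.id_low_k, config.id_high_k, config.id_window
    )
    areas = areas.reindex(matrix.columns)
    keep_size = size_filter(areas, config.area_min_um2, config.area_max_um2)

    reasons = pd.Series("none", index=matrix.columns, dtype=object)
    reasons[~keep_id & (counts < lo)] = "id_low"
    reasons[~keep_id & (counts > hi)] = "id_high"
    if config.id_window is not None:
        reasons[~keep_id & (reasons == "none")] = "id_low"  # window violations below lo
        outside_hi = ~keep_id & (counts > config.id_window[1]) & (reasons == "id_low")
        reasons[outside_hi] = "id_high"
    reasons[(reasons == "none") & ~keep_size] = "size"

    survivors = reasons == "none"
    if survivors.sum() >= 3:
        flags = pca_outlier_flag(matrix.loc[:, survivors], config.pca_outlier_sd)
        flagged = flags.index[flags]
        reasons[flagged] = "pca_outlier"

    return pd.DataFrame({
        "sample_id": matrix.columns,
        "n_proteins": counts.values,
        "area_um2": areas.values,
        "excluded_reason": reasons.values,
    }).set_index("sample_id")
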