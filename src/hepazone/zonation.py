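"""Spatial zonation statistics along the portal-to-central axis.

Each hepatocyte shape is mapped onto the lobular axis by its measured
distances to the nearest portal vein (PV) and central vein (CV):
r = d_pv / (d_pv + d_cv), so r = 0 at the PV and r = 1 at the CV.
Samples are grouped into B equidistant bins of r (default 20, roughly
the number of cells along the axis) and per-protein zonation is tested
by one-way ANOVA across bins, optionally with limma-style
empirical-Bayes variance moderation, followed by Benjamini-Hochberg
FDR control.  Companion summaries: per-bin expression profiles on the
simplex, log2 fold changes relative to the two mid-lobular bins,
per-bin intensity proportions over annotation sets (e.g. subcellular
compartments), a pseudo-neighbor analysis that averages k axis-adjacent
cells to quantify the information retained at true single-cell
resolution, and a PCA with an explicit missing-value policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "relative_distance",
    "assign_bins",
    "zonation_anova",
    "flatness_test",
    "bin_profile",
    "center_log2fc",
    "annotation_proportions",
    "pseudo_neighbors",
    "pca",
    "PCAResult",
    "PseudoNeighborCurve",
]

log = logging.getLogger(__name__)


def relative_distance(d_pv, d_cv):
    """Relative axis position r = d_pv / (d_pv + d_cv); 0 at PV, 1 at CV."""
    d_pv = np.asarray(d_pv, dtype=float)
    d_cv = np.asarray(d_cv, dtype=float)
    if np.any(d_pv < 0) or np.any(d_cv < 0):
        raise ValueError("distances must be non-negative")
    total = d_pv + d_cv
    if np.any(total == 0):
        raise ValueError("d_pv + d_cv must be positive (shape cannot sit on both veins)")
    return d_pv / total


def assign_bins(r, n_bins: int = 20):
    """Equidistant bins of [0, 1]: bin i covers [(i-1)/B, i/B); bin B is closed at 1."""
    r = np.asarray(r, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("relative distances must lie in [0, 1]")
    bins = np.floor(r * n_bins).astype(int) + 1
    return np.minimum(bins, n_bins)


def _bin_stats(X: np.ndarray, bins: np.ndarray, n_bins: int):
    """Per-bin observation counts and means; X is proteins x samples with NaN."""
    n_prot = X.shape[0]
    counts = np.zeros((n_prot, n_bins), dtype=int)
    sums = np.zeros((n_prot, n_bins))
    obs = ~np.isnan(X)
    for b in range(1, n_bins + 1):
        cols = bins == b
        if not cols.any():
            continue
        counts[:, b - 1] = obs[:, cols].sum(axis=1)
        sums[:, b - 1] = np.nansum(np.where(obs[:, cols], X[:, cols], 0.0), axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return counts, means


def zonation_anova(
    matrix: pd.DataFrame,
    bins,
    completeness_min: float = 0.5,
    moderate: bool = True,
) -> pd.DataFrame:
    """One-way ANOVA of each protein across spatial bins.

    Proteins observed in fewer than ``completeness_min`` of the samples,
    or in fewer than two bins with at least two observations each, are
    reported but not tested.  With ``moderate`` the residual variances
    are shrunk toward a pooled prior by empirical Bayes (posterior
    variance a prior-df-weighted combination of the protein's residual
    variance and the fitted prior) before the F statistic is formed, and
    the denominator degrees of freedom gain the prior df.  P values come
    from the F distribution and are BH-adjusted across tested proteins.

    ``anova_log2fc`` is the mean of the portal-half bin means minus the
    mean of the central-half bin means (log2 scale).

    Returns a frame indexed by protein with columns
    F, p, fdr, anova_log2fc, df1, df2, tested.
    """
    bins = np.asarray(bins, dtype=int)
    X = matrix.to_numpy(dtype=float)
    n_prot, n_samp = X.shape
    if bins.shape[0] != n_samp:
        raise ValueError("bin vector length must match the number of samples")
    n_bins = int(bins.max())

    counts, means = _bin_stats(X, bins, n_bins)
    n_obs = counts.sum(axis=1)
    completeness = n_obs / n_samp
    bins_used = (counts > 0).sum(axis=1)
    bins_ge2 = (counts >= 2).sum(axis=1)

    grand = np.where(n_obs > 0, np.nansum(np.where(np.isnan(X), 0, X), axis=1) / np.maximum(n_obs, 1), np.nan)
    ssb = np.nansum(counts * (means - grand[:, None]) ** 2, axis=1)
    sstot = np.nansum((X - grand[:, None]) ** 2, axis=1)
    ssw = sstot - ssb
    df1 = bins_used - 1
    df2 = n_obs - bins_used

    tested = (completeness >= completeness_min) & (bins_ge2 >= 2) & (df1 >= 1) & (df2 >= 1)

    F = np.full(n_prot, np.nan)
    p = np.full(n_prot, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb / np.maximum(df1, 1)
        s2 = ssw / np.maximum(df2, 1)

    if moderate and tested.sum() >= 3:
        s2_post, d0 = _squeeze_var(s2[tested], df2[tested].astype(float))
        F[tested] = msb[tested] / s2_post
        dfd = df2[tested] + (d0 if np.isfinite(d0) else 1e12)
        p[tested] = stats.f.sf(F[tested], df1[tested], dfd)
    else:
        idx = tested & (s2 > 0)
        F[idx] = msb[idx] / s2[idx]
        p[idx] = stats.f.sf(F[idx], df1[idx], df2[idx])
        # no within-bin variance at all: infinitely significant unless also no between
        degen = tested & (s2 == 0)
        F[degen & (ssb > 0)] = np.inf
        p[degen & (ssb > 0)] = 0.0
        F[degen & (ssb == 0)] = 0.0
        p[degen & (ssb == 0)] = 1.0

    fdr = np.full(n_prot, np.nan)
    has_p = ~np.isnan(p)
    if has_p.any():
        fdr[has_p] = multipletests(p[has_p], method="fdr_bh")[1]

    half = n_bins // 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        portal = np.nanmean(means[:, :half], axis=1)
        central = np.nanmean(means[:, half:], axis=1)
    log2fc = portal - central

    return pd.DataFrame(
        {
            "F": F,
            "p": p,
            "fdr": fdr,
            "anova_log2fc": log2fc,
            "df1": df1,
            "df2": df2.astype(float),
            "tested": tested,
        },
        index=matrix.index,
    )


def _squeeze_var(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of residual variances (scaled inv-chi2 prior).

    Moment estimation on log variances: the prior df solves a trigamma
    equation fitted to the excess spread of log s2 over its sampling
    variance; with no excess spread the prior df is infinite and all
    variances collapse to the pooled value.  Returns posterior variances
    and the prior df.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
        post = np.full_like(s2, s0_sq)
    return post, float(d0)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def flatness_test(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk normality per protein across all samples, BH-adjusted.

    A protein is called "flat" (expressed equally in all zones) when its
    adjusted P exceeds ``alpha``: strong zonation produces skewed or
    multimodal pooled distributions that fail normality.  Proteins with
    fewer than 3 observations are not tested.  (Normality is of course
    only a proxy for flatness; a truly flat protein with Gaussian noise
    passes, a hockey-stick one does not.)
    """
    W = np.full(matrix.shape[0], np.nan)
    p = np.full(matrix.shape[0], np.nan)
    for i, (_, row) in enumerate(matrix.iterrows()):
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size < 3 or np.ptp(vals) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W[i], p[i] = stats.shapiro(vals)
    p_adj = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    flat = np.where(tested, p_adj > alpha, np.nan)
    return pd.DataFrame(
        {"W": W, "p": p, "p_adj": p_adj, "flat": flat, "tested": tested},
        index=matrix.index,
    )


def bin_profile(matrix: pd.DataFrame, bins, n_bins: int | None = None) -> pd.DataFrame:
    """Per-protein spatial profile: per-bin mean linear intensity / total.

    Rows sum to 1 over the bins where the protein is observed; bins
    without data are NaN.
    """
    bins = np.asarray(bins, dtype=int)
    n_bins = n_bins or int(bins.max())
    linear = np.exp2(matrix.to_numpy(dtype=float))
    _, means = _bin_stats(linear, bins, n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        totals = np.nansum(means, axis=1)
    profile = means / totals[:, None]
    return pd.DataFrame(profile, index=matrix.index, columns=[f"bin{b}" for b in range(1, n_bins + 1)])


def center_log2fc(matrix: pd.DataFrame, bins, n_bins: int | None = None) -> pd.DataFrame:
    """Per-bin log2 fold change relative to the two mid-lobular bins.

    The reference is the median of the two centre bins' mean linear
    intensities (bins B/2 and B/2+1).  Proteins lacking either centre
    bin, or with a zero reference, are flagged NaN.
    """
    bins = np.asarray(bins, dtype=int)
    n_bins = n_bins or int(bins.max())
    linear = np.exp2(matrix.to_numpy(dtype=float))
    _, means = _bin_stats(linear, bins, n_bins)
    c1, c2 = n_bins // 2 - 1, n_bins // 2  # 0-based centre pair
    ref = np.median(means[:, [c1, c2]], axis=1)  # NaN if either centre missing
    bad = ~np.isfinite(ref) | (ref <= 0)
    if bad.any():
        log.warning("%d proteins lack a usable centre-bin reference", int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(means / ref[:, None])
    out[bad] = np.nan
    return pd.DataFrame(out, index=matrix.index, columns=[f"bin{b}" for b in range(1, n_bins + 1)])


def annotation_proportions(
    matrix: pd.DataFrame, annotation_sets: dict[str, list], bins, n_bins: int | None = None
) -> pd.DataFrame:
    """Per-bin fraction of summed linear intensity per annotation set.

    Proteins absent from every set are pooled into ``other``.  Fractions
    sum to 1 in every bin with data; empty bins are omitted (logged).
    """
    bins = np.asarray(bins, dtype=int)
    n_bins = n_bins or int(bins.max())
    linear = np.exp2(matrix)
    assigned = set()
    groups: dict[str, list] = {}
    for name, members in annotation_sets.items():
        present = [p for p in members if p in matrix.index]
        groups[name] = present
        assigned.update(present)
    other = [p for p in matrix.index if p not in assigned]
    if other:
        groups["other"] = other

    rows = {}
    for name, members in groups.items():
        sub = linear.loc[members]
        sums = np.zeros(n_bins)
        for b in range(1, n_bins + 1):
            cols = bins == b
            sums[b - 1] = np.nansum(sub.to_numpy()[:, cols]) if cols.any() else np.nan
        rows[name] = sums
    table = pd.DataFrame(rows, index=[f"bin{b}" for b in range(1, n_bins + 1)]).T
    totals = table.sum(axis=0)
    empty = totals[~(totals > 0)].index.tolist()
    if empty:
        log.info("omitting empty bins: %s", empty)
        table = table.drop(columns=empty)
        totals = totals.drop(empty)
    return table / totals


@dataclass
class PseudoNeighborCurve:
    """PCA summary of a k-combined matrix."""

    k: int
    variance_fractions: np.ndarray
    pc1_iqr: float


def pseudo_neighbors(
    matrix: pd.DataFrame,
    r,
    k: int,
    mode: str = "consecutive",
    pca_completeness_min: float = 0.7,
) -> tuple[pd.DataFrame, PseudoNeighborCurve]:
    """Average k axis-adjacent samples ("pseudo-neighbors") and re-run PCA.

    Samples are sorted by relative distance r and combined in
    non-overlapping consecutive windows of k (``mode="sliding"`` uses
    overlapping windows instead); each protein's combined value is the
    mean of its observed values, missing only where all k are missing.
    A trailing partial window is dropped.  Returns the combined matrix
    and the PCA summary (variance fractions and PC1 score IQR).
    """
    r = np.asarray(r, dtype=float)
    n = matrix.shape[1]
    if k < 1 or k > n:
        raise ValueError("k must be between 1 and the number of samples")
    order = np.argsort(r, kind="stable")
    X = matrix.to_numpy(dtype=float)[:, order]
    if k == 1:
        combined = matrix.iloc[:, order].copy()
    else:
        if mode == "consecutive":
            starts = range(0, (n // k) * k, k)
        elif mode == "sliding":
            starts = range(0, n - k + 1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        cols = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            for g, s in enumerate(starts):
                cols[f"pn{g + 1}"] = np.nanmean(X[:, s:s + k], axis=1)
        combined = pd.DataFrame(cols, index=matrix.index)
    result = pca(combined, completeness_min=pca_completeness_min)
    pc1 = result.scores.iloc[:, 0].to_numpy()
    iqr = float(np.percentile(pc1, 75) - np.percentile(pc1, 25))
    return combined, PseudoNeighborCurve(k=k, variance_fractions=result.variance_fractions, pc1_iqr=iqr)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # proteins x components
    variance_fractions: np.ndarray  # per-component fraction of total variance


def pca(
    matrix: pd.DataFrame,
    completeness_min: float = 0.7,
    scale: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of a protein x sample log-intensity matrix with missing values.

    Proteins observed in fewer than ``completeness_min`` of samples are
    dropped; remaining missing entries are imputed with the per-protein
    median (logged).  Proteins are centred (and unit-variance scaled if
    ``scale``); the SVD sign convention makes the largest-magnitude
    loading of each component positive, so output is deterministic.
    """
    frac = matrix.notna().mean(axis=1)
    kept = matrix.loc[frac >= completeness_min]
    if kept.shape[0] < 2 or kept.shape[1] < 2:
        raise ValueError("PCA needs at least 2 proteins and 2 samples after the completeness filter")
    n_missing = int(kept.isna().to_numpy().sum())
    if n_missing:
        log.info("imputing %d missing values with per-protein medians", n_missing)
        kept = kept.apply(lambda row: row.fillna(row.median()), axis=1)
    X = kept.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        raise ValueError("matrix is constant; PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((S**2).sum())
    fractions = S**2 / total_var
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    k = min(k, S.size)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):  # sign convention
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=kept.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=kept.index, columns=comp_names),
        variance_fractions=fractions[:k],
    )
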