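"""Proteome classes from k-means and their prediction from image features.

Normalised single-shape proteomes are clustered into K classes (default
5) by k-means on the z-scored, completeness-filtered matrix; classes are
relabelled 1..K by increasing mean relative distance of their members so
that labels are spatially ordered along the lobular axis.  A
random-forest classifier (200 trees, fixed seed, 0.2 test split) then
learns the class from the 17 image features.  Class probabilities act as
weights over class mean proteomes to reconstruct a predicted proteome
for any imaged cell, which is evaluated against measured proteomes by
Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, average_precision_score, confusion_matrix
from sklearn.model_selection import train_test_split

from .config import ClassifyConfig

__all__ = [
    "ProteomeClassModel",
    "ClassifierReport",
    "kmeans_classes",
    "class_mean_proteomes",
    "train_classifier",
    "predict_probabilities",
    "weighted_proteome_prediction",
    "evaluate_prediction",
]

log = logging.getLogger(__name__)


@dataclass
class ProteomeClassModel:
    """K-means proteome classes, spatially ordered."""

    n_classes: int
    labels: pd.Series            # class 1..K per training sample
    centroids: np.ndarray        # K x proteins, z-scored space
    feature_proteins: list       # proteins used for clustering
    mean_r: pd.Series            # mean relative distance per class (index 1..K)


@dataclass
class ClassifierReport:
    test_accuracy: float
    average_precision: float
    confusion: np.ndarray              # K x K counts, rows = true class
    neighbor_error_fraction: float     # NaN when there are no errors
    classes: np.ndarray
    test_index: pd.Index


def kmeans_classes(
    matrix: pd.DataFrame,
    r: pd.Series,
    n_classes: int = 5,
    seed: int = 0,
    completeness_min: float = 0.7,
    n_restarts: int = 10,
) -> ProteomeClassModel:
    """Cluster samples into K proteome classes by k-means.

    The matrix goes through the PCA missing-value policy (completeness
    filter, per-protein median imputation), is z-scored per protein, and
    clustered with k-means++ at a fixed seed with ``n_restarts``
    restarts (best inertia kept).  Classes are relabelled 1..K by
    increasing mean r of their members.
    """
    if n_classes > matrix.shape[1]:
        raise ValueError("more classes than samples")
    frac = matrix.notna().mean(axis=1)
    kept = matrix.loc[frac >= completeness_min]
    if kept.isna().any().any():
        kept = kept.apply(lambda row: row.fillna(row.median()), axis=1)
    z = kept.sub(kept.mean(axis=1), axis=0)
    sd = kept.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    X = z.to_numpy().T  # samples x proteins

    km = KMeans(n_clusters=n_classes, init="k-means++", n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)

    r = r.reindex(matrix.columns)
    mean_r_raw = pd.Series(
        [r.to_numpy()[raw == c].mean() for c in range(n_classes)], index=range(n_classes)
    )
    order = mean_r_raw.sort_values().index.to_numpy()  # raw label -> rank
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=matrix.columns, name="class")
    centroids = km.cluster_centers_[order]
    mean_r = pd.Series(
        [mean_r_raw[old] for old in order], index=range(1, n_classes + 1), name="mean_r"
    )
    return ProteomeClassModel(
        n_classes=n_classes,
        labels=labels,
        centroids=centroids,
        feature_proteins=list(kept.index),
        mean_r=mean_r,
    )


def class_mean_proteomes(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-class mean of normalised log intensities over observed values.

    Returns proteins x classes; a protein unobserved in a class is NaN
    there.
    """
    cols = {}
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        cols[c] = matrix[members].mean(axis=1)
    return pd.DataFrame(cols)


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ClassifyConfig | None = None,
) -> tuple[RandomForestClassifier, ClassifierReport]:
    """Random-forest image-feature classifier with a fixed random split.

    ``features`` is cells x 17; ``labels`` the spatially ordered class
    per cell.  The split is plain random (no stratification) at
    ``test_fraction`` with the configured seed; the report is computed
    on the held-out test samples.  Average precision is macro-averaged
    one-vs-rest on the predicted probabilities.
    ``neighbor_error_fraction`` is the share of misclassified test
    samples whose predicted class is spatially adjacent to the true one
    (|class difference| == 1); NaN when the test set has no errors.
    """
    config = config or ClassifyConfig()
    labels = labels.reindex(features.index)
    classes = np.sort(labels.unique())
    if classes.size < 2:
        raise ValueError("training needs at least 2 classes")

    X_train, X_test, y_train, y_test = train_test_split(
        features, labels, test_size=config.test_fraction, random_state=config.seed
    )
    model = RandomForestClassifier(n_estimators=config.n_trees, random_state=config.seed)
    model.fit(X_train.to_numpy(), y_train.to_numpy())

    y_pred = model.predict(X_test.to_numpy())
    proba = model.predict_proba(X_test.to_numpy())
    acc = float(accuracy_score(y_test, y_pred))
    onehot = np.stack([(y_test.to_numpy() == c).astype(int) for c in model.classes_], axis=1)
    ap = float(average_precision_score(onehot, proba, average="macro"))
    conf = confusion_matrix(y_test, y_pred, labels=classes)

    errors = y_pred != y_test.to_numpy()
    if errors.any():
        adjacent = np.abs(y_pred[errors] - y_test.to_numpy()[errors]) == 1
        neighbor_fraction = float(adjacent.mean())
    else:
        neighbor_fraction = float("nan")

    report = ClassifierReport(
        test_accuracy=acc,
        average_precision=ap,
        confusion=conf,
        neighbor_error_fraction=neighbor_fraction,
        classes=classes,
        test_index=X_test.index,
    )
    return model, report


def predict_probabilities(model: RandomForestClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities per cell (rows sum to 1)."""
    if features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match training ({model.n_features_in_})"
        )
    proba = model.predict_proba(features.to_numpy())
    return pd.DataFrame(proba, index=features.index, columns=model.classes_)


def weighted_proteome_prediction(
    probabilities: pd.DataFrame, class_means: pd.DataFrame
) -> pd.DataFrame:
    """Predicted proteome per cell: probability-weighted blend of class means.

    x_hat = sum_c p_c * mu_c per protein.  Proteins missing a mean in
    some class are predicted over the renormalised available classes
    (logged); proteins with no class mean at all are omitted.
    """
    classes = list(probabilities.columns)
    mu = class_means[classes]
    available = mu.notna()
    n_partial = int((available.sum(axis=1).between(1, len(classes) - 1)).sum())
    if n_partial:
        log.info("%d proteins predicted over a renormalised class subset", n_partial)
    usable = available.any(axis=1)
    mu = mu.loc[usable]
    avail = available.loc[usable].to_numpy()

    P = probabilities.to_numpy()          # cells x K
    M = np.nan_to_num(mu.to_numpy())      # proteins x K
    num = M @ P.T                         # proteins x cells
    denom = avail.astype(float) @ P.T     # renormalisation over available classes
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(denom > 0, num / denom, np.nan)
    return pd.DataFrame(pred, index=mu.index, columns=probabilities.index)


def evaluate_prediction(
    predicted: pd.DataFrame, measured: pd.DataFrame
) -> tuple[float, pd.Series]:
    """Pearson R between predicted and measured normalised log intensities.

    Pooled over all overlapping protein x cell entries, plus the
    per-protein R distribution (proteins with >=3 overlapping cells).
    """
    proteins = predicted.index.intersection(measured.index)
    cells = predicted.columns.intersection(measured.columns)
    if len(proteins) == 0 or len(cells) == 0:
        raise ValueError("no overlap between predicted and measured matrices")
    P = predicted.loc[proteins, cells].to_numpy().ravel()
    M = measured.loc[proteins, cells].to_numpy().ravel()
    ok = np.isfinite(P) & np.isfinite(M)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 overlapping entries")
    pooled = float(stats.pearsonr(P[ok], M[ok])[0])

    per_protein = {}
    pred_sub = predicted.loc[proteins, cells]
    meas_sub = measured.loc[proteins, cells]
    for prot in proteins:
        x = pred_sub.loc[prot].to_numpy()
        y = meas_sub.loc[prot].to_numpy()
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() >= 3 and np.ptp(x[mask]) > 0 and np.ptp(y[mask]) > 0:
            per_protein[prot] = float(stats.pearsonr(x[mask], y[mask])[0])
    return pooled, pd.Series(per_protein, name="pearson_r")
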