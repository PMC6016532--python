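"""PCA, between-group PCA, and cross-validated group classification.

Between-group PCA (bgPCA) takes the principal components of the ``g`` group
mean shapes (equal group weights) and projects every specimen onto those
axes after centering on the grand mean of the group means; it yields at
most ``g - 1`` components.  Used as a classifier, a specimen is assigned to
the group whose mean is nearest in bgPC score space; leave-one-out
cross-validation refits the means (and, by default, the axes) without the
held-out specimen.  Classification quality is summarized by a confusion
matrix, per-class rates, overall accuracy, and Cohen's kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: np.ndarray              # (n, k)
    variance_explained: np.ndarray  # percentages, length k
    loadings: np.ndarray            # (q, k), orthonormal columns
    mean: np.ndarray                # (q,) centering vector


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame      # g x g counts, rows = true
    per_class_pct: pd.DataFrame  # row-normalized percentages
    accuracy_pct: float
    kappa: float


def pca(tangent_coords: np.ndarray) -> PcaResult:
    """Ordinary PCA of shape variables (covariance eigendecomposition)."""
    y = np.asarray(tangent_coords, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("PCA requires at least 2 specimens")
    mean = y.mean(axis=0)
    centered = y - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > 1e-12 * max(1.0, s[0])
    s, vt, u = s[keep], vt[keep], u[:, keep]
    var = s**2
    return PcaResult(
        scores=u * s,
        variance_explained=100.0 * var / var.sum(),
        loadings=vt.T,
        mean=mean,
    )


def bgpca(tangent_coords: np.ndarray, groups) -> PcaResult:
    """Between-group PCA: principal axes of the (equal-weight) group means.

    All specimens are projected onto the axes after centering on the grand
    mean of the group means; at most ``g - 1`` components result.
    """
    y = np.asarray(tangent_coords, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("bgPCA requires at least 2 groups")
    means = []
    for g in labels:
        members = y[groups == g]
        if members.shape[0] == 0:
            raise ValueError(f"group {g!r} has no members")
        means.append(members.mean(axis=0))
    means = np.asarray(means)
    grand = means.mean(axis=0)
    _, s, vt = np.linalg.svd(means - grand, full_matrices=False)
    keep = s > 1e-12 * max(1.0, s[0])
    keep[min(len(labels) - 1, len(keep)):] = False
    axes = vt[keep].T
    var = s[keep] ** 2
    return PcaResult(
        scores=(y - grand) @ axes,
        variance_explained=100.0 * var / var.sum(),
        loadings=axes,
        mean=grand,
    )


def loocv_classify(
    tangent_coords: np.ndarray,
    groups,
    refit_axes: bool = True,
) -> ClassificationReport:
    """Leave-one-out cross-validated nearest-group-mean bgPCA classification.

    For each specimen the group means (and with ``refit_axes`` the bgPCA
    axes) are recomputed without it; the specimen is projected and assigned
    to the group whose projected mean is nearest (Euclidean, ties to the
    lowest-indexed group with a logged warning).
    """
    y = np.asarray(tangent_coords, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(
                f"group {g!r} has fewer than 2 members; leave-one-out would "
                "empty it"
            )
    n = y.shape[0]
    full = bgpca(y, groups)
    predictions = []
    for i in range(n):
        mask = np.arange(n) != i
        if refit_axes:
            fold = bgpca(y[mask], groups[mask])
            axes, grand = fold.loadings, fold.mean
        else:
            axes, grand = full.loadings, full.mean
        means = np.asarray([
            y[mask][groups[mask] == g].mean(axis=0) for g in labels
        ])
        mean_scores = (means - grand) @ axes
        score = (y[i] - grand) @ axes
        d = np.linalg.norm(mean_scores - score, axis=1)
        winners = np.nonzero(d == d.min())[0]
        if len(winners) > 1:
            log.warning(
                "distance tie for specimen %d; assigning lowest-indexed "
                "group %r", i, labels[winners[0]]
            )
        predictions.append(labels[winners[0]])
    confusion = pd.DataFrame(
        0, index=labels, columns=labels, dtype=int
    )
    for true, pred in zip(groups, predictions):
        confusion.loc[true, pred] += 1
    return classification_report(confusion)


def classification_report(confusion: pd.DataFrame | np.ndarray
                          ) -> ClassificationReport:
    """Accuracy, per-class rates, and Cohen's kappa from a confusion matrix
    (rows = true classes, columns = predicted)."""
    if not isinstance(confusion, pd.DataFrame):
        confusion = np.asarray(confusion)
        labels = [str(i) for i in range(confusion.shape[0])]
        confusion = pd.DataFrame(confusion, index=labels, columns=labels)
    counts = confusion.to_numpy(dtype=float)
    if counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("confusion matrix must hold non-negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, np.nan)
    return ClassificationReport(
        confusion=confusion.astype(int),
        per_class_pct=pd.DataFrame(pct, index=confusion.index,
                                   columns=confusion.columns),
        accuracy_pct=float(100.0 * p_o),
        kappa=float(kappa),
    )


def average_replicates(tangent_coords: np.ndarray, factors: pd.DataFrame,
                       by: list[str] = ("individual", "device"),
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Average shape variables over replicate triads, keeping ``by`` cells
    separate; returns the averaged coordinates and the collapsed factors."""
    y = np.asarray(tangent_coords, dtype=float)
    factors = factors.reset_index(drop=True)
    by = list(by)
    means, rows = [], []
    for key, idx in factors.groupby(by, sort=False).groups.items():
        idx = np.asarray(idx)
        means.append(y[idx].mean(axis=0))
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        for col in factors.columns:
            if col not in by:
                vals = factors.loc[idx, col].unique()
                rec[col] = vals[0] if len(vals) == 1 else None
        rows.append(rec)
    return np.asarray(means), pd.DataFrame(rows)
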