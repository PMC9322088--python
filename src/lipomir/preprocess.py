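"""From absolute copies to the analysis-ready log2 expression matrix.

The pipeline follows the profiling study design this package emulates:
miRNAs detected in fewer than 90% of all samples (classes pooled) are
excluded; detected copies are log2-transformed and global-mean normalized
(each sample centered on its mean over the filtered panel's detected
entries); remaining non-detects and per-miRNA 3-SD outliers are imputed to
the nearest in-window observed value.  ``explore`` provides the standard
exploratory projections (PCA variance fractions, sample dendrogram).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from lipomir.containers import CopyMatrix, ExplorationSummary, ExpressionMatrix


def detection_filter(copies: CopyMatrix, min_rate: float = 0.90) -> CopyMatrix:
    """Drop assays detected in less than ``min_rate`` of all samples.

    The boundary is inclusive: an assay detected in exactly ``min_rate`` of
    samples is retained.  Column order is preserved.  Raises ValueError if
    no assay survives.
    """
    if copies.values.empty:
        raise ValueError("empty copy matrix")
    rates = copies.detection_rate()
    keep = rates.index[rates >= min_rate]
    if len(keep) == 0:
        raise ValueError("no assay passes the detection filter")
    return CopyMatrix(
        values=copies.values[keep].copy(),
        detected=copies.detected[keep].copy(),
        factors=copies.factors,
    )


def global_mean_normalize(
    copies: CopyMatrix, labels: pd.Series, min_rate: float | None = 0.90
) -> ExpressionMatrix:
    """log2-transform and center each sample on its global mean.

    The global mean is each sample's mean log2 copies over the *detected*
    entries of the filtered panel, so the normalization is invariant to any
    per-sample multiplicative scaling of copies.  Non-detects stay missing
    (NaN) for the imputation step.
    """
    vals = copies.values.to_numpy(dtype=float)
    det = copies.detected.to_numpy(dtype=bool)
    if np.any(det & ~(vals > 0)):
        raise ValueError("detected copies must be positive")
    log2 = np.where(det, np.log2(vals, where=det, out=np.full_like(vals, np.nan)), np.nan)
    n_det = det.sum(axis=1)
    if (n_det == 0).any():
        bad = copies.samples[n_det == 0].tolist()
        raise ValueError(f"samples with no detected entries: {bad}")
    sample_mean = np.nansum(np.where(det, log2, 0.0), axis=1) / n_det
    centered = log2 - sample_mean[:, None]
    values = pd.DataFrame(centered, index=copies.samples, columns=copies.assays)
    return ExpressionMatrix(
        values=values,
        detected=copies.detected.copy(),
        labels=labels.reindex(copies.samples),
        provenance={
            "filter_min_rate": min_rate,
            "normalization": "global_mean",
            "scale": "log2",
        },
    )


def impute(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace non-detects and 3-SD outliers per miRNA.

    For each miRNA, the mean m and sample SD s (ddof=1) are computed once
    over the detected pre-imputation values.  Missing values and values
    below m - 3s are replaced by the minimum observed value inside
    [m - 3s, m + 3s]; values above m + 3s by the maximum inside the window.
    A miRNA with no observed value inside its window signals corrupt input.
    """
    vals = expr.values.to_numpy(dtype=float).copy()
    det = expr.detected.to_numpy(dtype=bool)
    for j, mirna in enumerate(expr.mirnas):
        col = vals[:, j]
        obs = col[det[:, j]]
        if len(obs) < 2:
            raise ValueError(f"miRNA {mirna!r}: need >= 2 detected values to impute")
        m, s = obs.mean(), obs.std(ddof=1)
        lo, hi = m - 3 * s, m + 3 * s
        in_window = obs[(obs >= lo) & (obs <= hi)]
        if len(in_window) == 0:
            raise ValueError(f"miRNA {mirna!r}: no detected value within 3 SD of the mean")
        low_mask = ~det[:, j] | (col < lo)
        high_mask = det[:, j] & (col > hi)
        col[low_mask] = in_window.min()
        col[high_mask] = in_window.max()
        vals[:, j] = col
    values = pd.DataFrame(vals, index=expr.samples, columns=expr.mirnas)
    provenance = dict(expr.provenance, imputation="min/max within 3 SD, single pass")
    return ExpressionMatrix(
        values=values,
        detected=expr.detected.copy(),
        labels=expr.labels.copy(),
        provenance=provenance,
    )


def explore(
    expr: ExpressionMatrix,
    n_components: int | None = None,
    distance_metric: str = "correlation",
    linkage_method: str = "average",
) -> ExplorationSummary:
    """Principal components and hierarchical clustering of samples.

    PCA is computed on the column-centered matrix via SVD; variance
    fractions are eigenvalue shares of total variance.  Samples are
    clustered agglomeratively (correlation distance, average linkage by
    default) and the scipy linkage matrix is returned.
    """
    X = expr.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for exploration")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    k = min(n_components or min(n, p), len(svals))
    scores = pd.DataFrame(
        u[:, :k] * svals[:k],
        index=expr.samples,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    dists = pdist(X, metric=distance_metric)
    dists = np.clip(dists, 0.0, None)  # guard tiny negative rounding
    Z = hierarchy.linkage(dists, method=linkage_method)
    return ExplorationSummary(
        scores=scores,
        variance_fractions=fractions[:k],
        linkage=Z,
        distance_metric=distance_metric,
        linkage_method=linkage_method,
    )


def preprocess(
    copies: CopyMatrix, labels: pd.Series, min_rate: float = 0.90
) -> ExpressionMatrix:
    """Filter, normalize and impute in one call."""
    filtered = detection_filter(copies, min_rate=min_rate)
    expr = global_mean_normalize(filtered, labels, min_rate=min_rate)
    return impute(expr)
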