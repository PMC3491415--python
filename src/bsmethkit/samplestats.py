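"""Descriptive statistics, correlation, clustering and PCA on methylomes.

A healthy bisulfite library shows a bimodal percent-methylation histogram
(most cytosines near 0% or near 100%) and a unimodal coverage histogram; a
secondary high-coverage mode signals PCR-duplication (clonal) bias.  Sample
relationships are assessed on the percent-methylation matrix of commonly
covered units only: pairwise correlation (Pearson, Kendall or Spearman),
hierarchical clustering under the usual distance metrics, and PCA with
samples as observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .datamodel_io import SampleMethylome, ValidationError
from .regionalize import UnitedMethylome

CORRELATION_METHODS = ("pearson", "kendall", "spearman")

#: Supported clustering distances, mapped to scipy pdist metrics.
#: "correlation" is 1 - Pearson correlation of percent profiles; "maximum",
#: "manhattan" and "binary" follow the naming of R's dist().
DISTANCE_METRICS = {
    "correlation": "correlation",
    "euclidean": "euclidean",
    "maximum": "chebyshev",
    "manhattan": "cityblock",
    "canberra": "canberra",
    "binary": "jaccard",
    "minkowski": "minkowski",
}

LINKAGE_METHODS = ("ward", "single", "complete", "average")


def percent_methylation(n_meth: int, n_unmeth: int) -> float:
    """Percent methylation 100*C/(C+T), reported to two decimals."""
    cov = n_meth + n_unmeth
    if cov < 1:
        raise ValidationError("percent methylation undefined at zero coverage")
    return round(100.0 * n_meth / cov, 2)


@dataclass
class Histogram:
    """Binned counts plus location summaries of a per-record statistic."""

    counts: np.ndarray
    bin_edges: np.ndarray
    mean: float
    median: float
    q1: float
    q3: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _histogram(values: np.ndarray, bins, range_) -> Histogram:
    counts, edges = np.histogram(values, bins=bins, range=range_)
    q1, med, q3 = np.percentile(values, [25, 50, 75]) if len(values) else (np.nan,) * 3
    return Histogram(counts, edges, float(np.mean(values)) if len(values) else np.nan,
                     float(med), float(q1), float(q3))


def methylation_stats(m: SampleMethylome, bins: int = 20) -> Histogram:
    """Histogram + summary of percent methylation per record over [0, 100]."""
    return _histogram(m.percent.to_numpy(), bins, (0.0, 100.0))


def coverage_stats(m: SampleMethylome, bins: int = 20, log10: bool = False) -> Histogram:
    """Histogram + summary of read coverage per record.

    With ``log10=True`` the histogram is taken on log10(coverage), which makes
    a clonal second mode easier to see against the main coverage mode.
    """
    cov = m.coverage.to_numpy().astype(float)
    if log10:
        cov = np.log10(cov)
    return _histogram(cov, bins, None)


def correlation_matrix(u: UnitedMethylome, method: str = "pearson") -> pd.DataFrame:
    """Pairwise sample correlation of percent-methylation profiles.

    Returns a symmetric samples x samples matrix with unit diagonal.  A
    sample with zero variance yields NaN entries (flagged, never silently 0).
    """
    if method not in CORRELATION_METHODS:
        raise ValidationError(f"method must be one of {CORRELATION_METHODS}")
    if u.n_samples < 2:
        raise ValidationError("correlation needs >= 2 samples")
    if len(u) < 3:
        raise ValidationError("correlation needs >= 3 commonly covered units")
    pm = u.percent_matrix()
    corr = pm.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_samples(u: UnitedMethylome, dist: str = "correlation",
                    linkage: str = "ward") -> dict:
    """Hierarchical clustering of samples on their percent profiles.

    Returns a dict with the condensed distance vector, the scipy linkage
    matrix and the leaf labels (sample ids).  Ward linkage uses the
    squared-distance ("ward.D2"-style) update on the chosen metric.
    """
    if dist not in DISTANCE_METRICS:
        raise ValidationError(f"unknown distance {dist!r}; valid: {sorted(DISTANCE_METRICS)}")
    if linkage not in LINKAGE_METHODS:
        raise ValidationError(f"unknown linkage {linkage!r}; valid: {sorted(LINKAGE_METHODS)}")
    if u.n_samples < 2:
        raise ValidationError("clustering needs >= 2 samples")
    profiles = u.percent_matrix().to_numpy().T  # samples x units
    metric = DISTANCE_METRICS[dist]
    if metric == "jaccard":
        profiles = profiles > 0
    d = pdist(profiles, metric=metric)
    z = hierarchy.linkage(d, method=linkage)
    return {"distances": d, "distance_matrix": squareform(d), "linkage": z,
            "labels": list(u.samples)}


@dataclass
class PCAResult:
    """Sample scores, unit loadings and explained-variance fractions."""

    scores: pd.DataFrame          # samples x components
    loadings: np.ndarray          # units x components
    variance_fraction: np.ndarray


def pca_samples(u: UnitedMethylome, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of samples on the percent-methylation matrix (units as variables).

    Components are ordered by decreasing explained variance; the sign of each
    component is fixed so that its largest-magnitude loading is positive,
    making scores reproducible across runs and platforms.
    """
    if u.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    if len(u) < 2:
        raise ValidationError("PCA needs >= 2 commonly covered units")
    x = u.percent_matrix().to_numpy().T.astype(float)  # samples x units
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    n_comp = min(x.shape)
    svd_u, svd_s, svd_vt = np.linalg.svd(x, full_matrices=False)
    scores = svd_u[:, :n_comp] * svd_s[:n_comp]
    loadings = svd_vt[:n_comp].T
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_comp):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    var = svd_s[:n_comp] ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    score_df = pd.DataFrame(scores, index=list(u.samples),
                            columns=[f"PC{i + 1}" for i in range(n_comp)])
    return PCAResult(score_df, loadings, frac)
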