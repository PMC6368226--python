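"""Cohort scoring on the signature's first principal component.

A cohort is scored by subsetting its expression matrix to the signature
probesets, autoscaling, and taking first-principal-component sample
scores.  Because the sign of a principal component is arbitrary, PC1 is
oriented so that the correlation between its loadings and the signature
direction signs is positive — "high score" then deterministically means
"more mesenchymal", and orientation never consults outcome data.

Two stratifications are provided: a median split (ties and the median
sample itself go to the low group) and a two-cluster k-means on the
autoscaled signature-gene expression, with the cluster of higher mean
PC1 score labelled high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix, autoscale, pca
from .signature import Signature


@dataclass
class ScoredCohort:
    """Per-sample signature scores with optional high/low grouping."""

    scores: pd.Series
    loadings: pd.Series
    orientation_sign: int
    pct_variance: float
    groups: pd.Series | None = None
    method: str | None = None


def score_cohort(m: ExpressionMatrix, sig: Signature) -> ScoredCohort:
    """Oriented PC1 scores of the signature genes in a cohort.

    Requires ≥ 3 signature probesets in the matrix (the error lists the
    missing entries otherwise).  Zero-variance probesets are dropped by
    autoscaling before the PCA.
    """
    present = [p for p in sig.probeset_ids if p in m.values.index]
    if len(present) < 3:
        missing = [p for p in sig.probeset_ids if p not in m.values.index]
        raise ValueError(
            f"only {len(present)} signature probesets present (need >= 3); "
            f"missing: {missing[:20]}")
    sub = autoscale(m.subset_probesets(present))
    res = pca(sub, 1)
    load = res.loadings["PC1"]
    scores = res.scores["PC1"]
    dirs = sig.directions.loc[load.index].astype(float)
    corr = float(np.dot(load, dirs))
    sign = -1 if corr < 0 else 1
    return ScoredCohort(scores=scores * sign, loadings=load * sign,
                        orientation_sign=sign,
                        pct_variance=float(res.pct_variance[0]))


def median_split(scores: pd.Series) -> pd.Series:
    """High/low split at the median PC1 score (median and ties go low)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(np.median(scores))
    if np.all(scores.to_numpy() == scores.iloc[0]):
        raise ValueError("all scores identical; no stratification possible")
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index, name="group")


def kmeans_split(m: ExpressionMatrix, sig: Signature, restarts: int = 10,
                 seed: int = 0) -> pd.Series:
    """Two-cluster k-means split on autoscaled signature-gene expression.

    Uses k-means++ seeding with ``restarts`` initializations (best by
    within-cluster sum of squares, deterministic given ``seed``).  The
    cluster with the higher mean PC1 signature score is labelled high,
    so the labelling does not depend on cluster indexing.
    """
    if m.shape[1] < 4:
        raise ValueError("need at least 4 samples for k-means stratification")
    scored = score_cohort(m, sig)
    sub = autoscale(m.subset_probesets(
        [p for p in sig.probeset_ids if p in m.values.index]))
    X = sub.values.to_numpy().T
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all samples identical")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed).fit(X)
    labels = pd.Series(km.labels_, index=sub.values.columns)
    means = scored.scores.groupby(labels).mean()
    high_cluster = means.idxmax()
    return pd.Series(np.where(labels == high_cluster, "high", "low"),
                     index=labels.index, name="group")
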