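"""Subpopulation assignment from ancestry-ratio vectors.

Accessions are clustered by k-means on their Q rows; the number of clusters
is chosen by an elbow on the between-cluster / total sum-of-squares (BCTSS)
ratio, and each cluster gets a bootstrap stability support: the mean Jaccard
similarity between the reference cluster and its best-matching cluster
across re-clusterings of accession resamples.  An admixed subpopulation —
whose Q rows spread between two ancestors — shows up as the cluster with the
lowest support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["ClusterAssignment", "kmeans_cluster", "bctss_ratio",
           "select_k_elbow", "bootstrap_support"]


@dataclass
class ClusterAssignment:
    """Per-accession subpopulation labels with quality measures.

    ``labels`` are 1-based cluster indices; ``support`` is filled by
    :func:`bootstrap_support`.
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    bctss: float
    support: np.ndarray = None
    n_boot: int = 0
    seed: int = 0
    skipped_replicates: np.ndarray = field(default=None, repr=False)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels - 1, minlength=self.k)

    def support_table(self) -> pd.DataFrame:
        """Table 2 layout: population, number of accessions, support."""
        rows = {"population": [f"POP{c + 1}" for c in range(self.k)],
                "n_accessions": self.sizes()}
        if self.support is not None:
            rows["support"] = np.round(self.support, 4)
        return pd.DataFrame(rows)


def bctss_ratio(Q, labels) -> float:
    """Between-cluster / total sum of squares: (TSS - WSS) / TSS.

    TSS is the scatter around the grand mean (the single-cluster
    assignment); WSS the scatter around the cluster centroids.  0 for one
    cluster, 1 when every point sits on its centroid; defined as 0 when
    TSS = 0 (all rows identical).
    """
    Q = np.asarray(Q, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != Q.shape[0]:
        raise ValueError("one label per row required")
    tss = float(((Q - Q.mean(axis=0)) ** 2).sum())
    if tss == 0.0:
        return 0.0
    wss = 0.0
    for c in np.unique(labels):
        block = Q[labels == c]
        wss += float(((block - block.mean(axis=0)) ** 2).sum())
    return (tss - wss) / tss


def kmeans_cluster(Q, k: int, n_init: int = 20, seed: int = 0) -> ClusterAssignment:
    """Lloyd's k-means (k-means++ seeding, ``n_init`` restarts) on Q rows,
    keeping the assignment with minimal within-cluster sum of squares."""
    Q = np.asarray(Q, dtype=float)
    if k < 1 or k > Q.shape[0]:
        raise ValueError(f"k={k} must lie in [1, n={Q.shape[0]}]")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=300,
                random_state=seed % (2**32)).fit(Q)
    labels = km.labels_ + 1
    return ClusterAssignment(labels=labels, k=k, centroids=km.cluster_centers_,
                             bctss=bctss_ratio(Q, labels), seed=seed)


def select_k_elbow(Q, k_range, n_init: int = 20, seed: int = 0,
                   return_curve: bool = False):
    """Choose k by the elbow of the BCTSS-ratio curve.

    With gain(k) = bctss(k) - bctss(k-1) (bctss(1) = 0), the elbow is the k
    maximizing the ratio gain(k) / gain(k+1): the last k whose improvement
    dwarfs the next one's, i.e. the point after which adding a cluster
    stops paying.  ``k_range`` must be contiguous with min >= 2; bctss is
    additionally evaluated at max(k_range) + 1 so the range maximum is a
    candidate.  Ties break toward smaller k.
    """
    Q = np.asarray(Q, dtype=float)
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2:
        raise ValueError("k_range minimum must be >= 2")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k_range must be contiguous")
    evals = list(range(ks[0] - 1, ks[-1] + 2))
    curve = {}
    for k in evals:
        if k <= 1:
            curve[k] = 0.0
        else:
            curve[k] = kmeans_cluster(Q, k, n_init=n_init, seed=seed + k).bctss
    gain = {k: curve[k] - curve[k - 1] for k in evals if k - 1 in curve}
    floor = 1e-9
    ratios = {k: max(gain[k], floor) / max(gain[k + 1], floor) for k in ks}
    chosen = min(ks, key=lambda k: (-ratios[k], k))
    if return_curve:
        return chosen, curve
    return chosen


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.sum(a & b)
    union = np.sum(a | b)
    return inter / union if union else 0.0


def bootstrap_support(Q, reference: ClusterAssignment, n_boot: int = 10000,
                      seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Clusterwise bootstrap stability of a reference clustering.

    For each replicate, n accessions are resampled with replacement and
    re-clustered with the reference k; each reference cluster is matched to
    the replicate cluster of maximal Jaccard similarity over the resampled
    positions, and that Jaccard value is recorded.  A cluster's support is
    the mean recorded value over the replicates in which it had at least one
    resampled member (replicates without one are skipped and counted).

    The support array (and skip counts) are also written back onto
    ``reference``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    k = reference.k
    ref_labels = np.asarray(reference.labels)
    rng = np.random.default_rng(seed)
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    skipped = np.zeros(k, dtype=int)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        km = KMeans(n_clusters=k, n_init=n_init, max_iter=300,
                    random_state=int(rng.integers(2**32))).fit(Q[idx])
        rep_labels = km.labels_
        ref_on_sample = ref_labels[idx]
        for c in range(1, k + 1):
            mask_ref = ref_on_sample == c
            if not mask_ref.any():
                skipped[c - 1] += 1
                continue
            best = max(_jaccard(mask_ref, rep_labels == d) for d in range(k))
            sums[c - 1] += best
            counts[c - 1] += 1
    support = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    reference.support = support
    reference.n_boot = n_boot
    reference.skipped_replicates = skipped
    return support
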