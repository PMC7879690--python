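"""Expression-profile tools: hierarchical clustering, shape classes,
peak normalization, and natural-abscission direction calls.

Differentially expressed genes are grouped by hierarchical clustering of
their time-course profiles, using 1 - Pearson correlation as the distance
and average linkage; correlation distance makes the partition invariant
to per-gene affine rescaling, so no log transform or centering choice can
change it.  The four canonical shape classes over an ethylene time course
(0, 3, 6, 9, 12 h) are

    A  sustained induction (non-decreasing, ends above start)
    B  transient, peak at 3 h
    C  transient, peak at 6 h
    D  repression (non-increasing, ends below start)

Profiles from the natural time course (30, 120, 160 days after
pollination) are called up / down / flat from the ripe 160 DAP value
against the maximum of the earlier stages, with a fold threshold and a
small pseudo-abundance floor to tame zero RPKMs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ProfileClusterer",
    "hca_cluster",
    "classify_shape",
    "normalize_to_peak",
    "natural_direction",
]

REJECT_LABEL = 0  # cluster id reserved for zero-variance profiles

ETHYLENE_TIMES_H = (0, 3, 6, 9, 12)

PSEUDO_FLOOR = 0.1  # pseudo-RPKM added before natural-profile ratios


@dataclass
class ClusterAssignment:
    """Result of clustering a set of expression profiles.

    ``labels`` maps contig -> integer cluster id (1..k; 0 = rejected
    zero-variance profile).  ``shapes`` is the per-contig rule-based shape
    class, ``cluster_shapes`` the majority shape per cluster (ties broken
    alphabetically), and ``linkage_matrix`` the scipy merge list.
    """

    labels: pd.Series
    shapes: pd.Series
    cluster_shapes: dict[int, str]
    linkage_matrix: np.ndarray | None

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels[self.labels != REJECT_LABEL])).size)


class ProfileClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of expression profiles.

    Distance is 1 - Pearson correlation, linkage is average, and the tree
    is cut into ``n_clusters`` flat clusters.  Constant (zero-variance)
    profiles, for which correlation is undefined, are set aside in a
    reject class (label 0) before clustering and logged.

    Attributes
    ----------
    labels_ : ndarray of shape (n_profiles,)
        Cluster id per profile, 1..n_clusters; 0 marks rejected profiles.
    linkage_ : ndarray
        scipy linkage matrix over the non-degenerate profiles.
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D with >= 2 time points per profile")
        n = X.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(
                f"n_clusters={self.n_clusters} out of range for {n} profiles"
            )
        variances = X.var(axis=1)
        ok = variances > 0
        n_rejected = int((~ok).sum())
        if n_rejected:
            logger.warning(
                "%d zero-variance profile(s) assigned to the reject class",
                n_rejected,
            )
        labels = np.zeros(n, dtype=int)
        valid = X[ok]
        if valid.shape[0] == 1:
            labels[ok] = 1
            self.linkage_ = None
        elif valid.shape[0] > 1:
            k = min(self.n_clusters, valid.shape[0])
            dist = pdist(valid, metric="correlation")
            self.linkage_ = linkage(dist, method="average")
            labels[ok] = fcluster(self.linkage_, t=k, criterion="maxclust")
        else:
            self.linkage_ = None
        self.labels_ = labels
        return self


def hca_cluster(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Cluster contig profiles (rows) into ``k`` groups.

    Thin wrapper over :class:`ProfileClusterer` that also attaches the
    rule-based shape class per contig and per cluster.
    """
    est = ProfileClusterer(n_clusters=k).fit(profiles.to_numpy(dtype=float))
    labels = pd.Series(est.labels_, index=profiles.index, name="cluster")
    shapes = pd.Series(
        [
            classify_shape(row) if len(row) == 5 else "other"
            for row in profiles.to_numpy(dtype=float)
        ],
        index=profiles.index,
        name="shape",
    )
    cluster_shapes: dict[int, str] = {}
    for cid in sorted(set(labels) - {REJECT_LABEL}):
        members = shapes[labels == cid]
        counts = members.value_counts().sort_index()  # alphabetical tie-break
        cluster_shapes[cid] = counts.index[counts.to_numpy().argmax()]
    return ClusterAssignment(labels, shapes, cluster_shapes, est.linkage_)


def classify_shape(profile) -> str:
    """Classify a 5-point ethylene time-course profile into A/B/C/D/other.

    A: non-decreasing with final > initial (sustained induction).
    D: non-increasing with final < initial (repression).
    B: strict maximum at 3 h; C: strict maximum at 6 h.
    Anything else — including constant profiles and ties between the 3 h
    and 6 h peaks — is ``other``.  Ties are logged, not silently broken.
    """
    v = np.asarray(profile, dtype=float)
    if v.shape != (5,):
        raise ValueError("shape classification expects a 5-point profile")
    diffs = np.diff(v)
    if np.all(v == v[0]):
        return "other"
    if np.all(diffs >= 0) and v[-1] > v[0]:
        return "A"
    if np.all(diffs <= 0) and v[-1] < v[0]:
        return "D"
    peak = v.argmax()
    if np.sum(v == v.max()) > 1:
        if set(np.flatnonzero(v == v.max())) == {1, 2}:
            logger.info("tied 3 h / 6 h peak; classified as other")
        return "other"
    if peak == 1:
        return "B"
    if peak == 2:
        return "C"
    return "other"


def normalize_to_peak(profile):
    """Divide a profile by its maximum so the peak equals 1."""
    v = np.asarray(profile, dtype=float)
    peak = v.max(initial=-np.inf)
    if peak <= 0:
        raise ValueError("peak normalization needs a positive maximum")
    return v / peak


def natural_direction(
    rpkm30: float,
    rpkm120: float,
    rpkm160: float,
    fold: float = 2.0,
    floor: float = PSEUDO_FLOOR,
) -> str:
    """Direction of a natural-abscission profile: up / down / flat.

    The ripe, abscising 160 DAP abundance is compared against the maximum
    of the two pre-abscission stages.  ``up`` requires the 160 DAP value
    to exceed that maximum ``fold``-fold, ``down`` to fall below it
    ``fold``-fold; everything else is flat.  ``floor`` is added to both
    sides first so all-zero profiles resolve to flat instead of 0/0.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    if min(rpkm30, rpkm120, rpkm160) < 0:
        raise ValueError("RPKM values must be nonnegative")
    ripe = rpkm160 + floor
    before = max(rpkm30, rpkm120) + floor
    if ripe >= fold * before:
        return "up"
    if ripe <= before / fold:
        return "down"
    return "flat"
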