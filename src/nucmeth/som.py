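"""Self-organizing-map clustering of dyad-centered methylation matrices.

Loci with phased nucleosome arrays show structured, alternating methylation
around their dyads; an SOM over per-locus binned methylation rows groups
such loci together.  The map is a 1 x k grid trained with the standard
Kohonen update (best-matching unit by Euclidean distance, Gaussian
neighborhood, learning rate and neighborhood width decaying linearly over
epochs).  Cluster labels are arbitrary; the "phased" cluster is identified
post hoc as the one whose centroid has the largest peak-to-trough amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .profiles import MethylationProfile, _safe_fraction, profile_around_anchors

logger = logging.getLogger(__name__)


@dataclass
class LocusMatrix:
    """Per-anchor binned methylation (rows = anchors, columns = offset bins)."""

    values: np.ndarray  # fractions, NaN where a cell has no coverage
    n_meth: np.ndarray
    n_total: np.ndarray
    anchors: pd.DataFrame  # chrom, pos (row order matches values)
    bin_offsets: np.ndarray
    bin_size: int
    context: str

    def pooled_profile(self, rows: np.ndarray | None = None,
                       label: str = "") -> MethylationProfile:
        """Count-wise pooling of (a subset of) rows into one profile."""
        sel = slice(None) if rows is None else rows
        n_meth = self.n_meth[sel].sum(axis=0)
        n_total = self.n_total[sel].sum(axis=0)
        n_anchors = self.values[sel].shape[0]
        return MethylationProfile(self.bin_offsets.copy(), self.bin_size,
                                  n_meth, n_total,
                                  _safe_fraction(n_meth, n_total),
                                  self.context, label=label,
                                  n_anchors=n_anchors)


def build_locus_matrix(anchors: pd.DataFrame, records: pd.DataFrame,
                       flank: int, bin_size: int = 10,
                       context: str = "CG") -> LocusMatrix:
    """One binned methylation row per anchor (no cross-anchor pooling).

    Rows with no covered cytosine are retained as all-NaN (and logged), so
    row order always matches the anchor table.
    """
    if len(anchors) == 0:
        raise InvalidConfigError("at least one anchor required")
    if bin_size <= 0 or flank % bin_size:
        raise InvalidConfigError("flank must be a positive multiple of bin")
    offsets = np.arange(-flank, flank, bin_size)
    n_bins = len(offsets)
    n_meth = np.zeros((len(anchors), n_bins))
    n_total = np.zeros((len(anchors), n_bins))
    recs = records[records["context"] == context]
    by_chrom = {}
    for chrom, grp in recs.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (grp["pos"].to_numpy()[order],
                           grp["count_meth"].to_numpy()[order],
                           grp["count_total"].to_numpy()[order])
    for r, row in enumerate(anchors.itertuples(index=False)):
        if row.chrom not in by_chrom:
            continue
        pos, meth, total = by_chrom[row.chrom]
        center = int(row.pos)
        lo = np.searchsorted(pos, center - flank, side="left")
        hi = np.searchsorted(pos, center + flank, side="left")
        if hi <= lo:
            continue
        idx = (pos[lo:hi] - center + flank) // bin_size
        np.add.at(n_meth[r], idx, meth[lo:hi])
        np.add.at(n_total[r], idx, total[lo:hi])
    empty = int((n_total.sum(axis=1) == 0).sum())
    if empty:
        logger.info("%d anchors with no covered cytosines (all-NaN rows)",
                    empty)
    values = _safe_fraction(n_meth, n_total)
    return LocusMatrix(values, n_meth, n_total,
                       anchors.reset_index(drop=True), offsets, bin_size,
                       context)


class SelfOrganizingMap:
    """1 x k Kohonen map with an sklearn-like fit/predict surface.

    Parameters
    ----------
    n_clusters : number of map units (clusters).
    n_epochs : full passes over the rows.
    learning_rate : initial learning rate; decays linearly to ~0.
    sigma : initial Gaussian neighborhood width in units; defaults to
        n_clusters / 2, decaying linearly to 0.1.
    random_state : seed for row shuffling and codebook initialization.

    Fitted attributes: ``cluster_centers_`` (k x p codebook), ``labels_``
    (best-matching unit per training row, 0-based), ``column_means_`` (the
    imputation values used for missing cells).
    """

    def __init__(self, n_clusters: int = 5, n_epochs: int = 100,
                 learning_rate: float = 0.5, sigma: float | None = None,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.sigma = sigma
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "n_epochs": self.n_epochs,
                "learning_rate": self.learning_rate, "sigma": self.sigma,
                "random_state": self.random_state}

    def set_params(self, **params) -> "SelfOrganizingMap":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _impute(self, X: np.ndarray, means: np.ndarray) -> np.ndarray:
        X = np.array(X, float)
        missing = ~np.isfinite(X)
        if missing.any():
            X[missing] = np.broadcast_to(means, X.shape)[missing]
        return X

    def fit(self, X) -> "SelfOrganizingMap":
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise InvalidConfigError("X must be a 2D matrix")
        n, p = X.shape
        if self.n_clusters > n:
            raise InvalidConfigError(
                f"n_clusters={self.n_clusters} exceeds number of rows {n}"
            )
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=0)
        means = np.where(np.isfinite(means), means, np.nanmean(X))
        if not np.isfinite(means).all():
            raise InvalidConfigError("matrix has no finite values")
        data = self._impute(X, means)

        rng = np.random.default_rng(self.random_state)
        codebook = data[rng.choice(n, self.n_clusters, replace=False)].copy()
        units = np.arange(self.n_clusters)
        sigma0 = self.sigma if self.sigma is not None else self.n_clusters / 2
        for epoch in range(self.n_epochs):
            t = epoch / max(self.n_epochs - 1, 1)
            lr = self.learning_rate * (1.0 - t) + 1e-3
            sig = max(sigma0 * (1.0 - t), 0.1)
            for i in rng.permutation(n):
                x = data[i]
                bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
                h = np.exp(-((units - bmu) ** 2) / (2 * sig ** 2))
                codebook += lr * h[:, None] * (x - codebook)
        self.cluster_centers_ = codebook
        self.column_means_ = means
        self.n_features_in_ = p
        self.labels_ = self._assign(data)
        return self

    def _assign(self, data: np.ndarray) -> np.ndarray:
        d2 = ((data[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise InvalidConfigError("map is not fitted")
        return self._assign(self._impute(np.asarray(X, float),
                                         self.column_means_))

    def fit_predict(self, X) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusterAssignment:
    """SOM result with 1-based cluster labels and training metadata."""

    labels: np.ndarray  # 1..k per row
    centroids: np.ndarray
    n_clusters: int
    metadata: dict = field(default_factory=dict)

    def rows_in(self, cluster: int) -> np.ndarray:
        if not 1 <= cluster <= self.n_clusters:
            raise InvalidConfigError(
                f"cluster {cluster} outside 1..{self.n_clusters}"
            )
        return np.nonzero(self.labels == cluster)[0]


def som_cluster(matrix: LocusMatrix | np.ndarray, k: int = 5,
                epochs: int = 100, learning_rate: float = 0.5,
                seed: int | None = None) -> ClusterAssignment:
    """Cluster locus rows on a 1 x k SOM grid (deterministic given seed)."""
    X = matrix.values if isinstance(matrix, LocusMatrix) else matrix
    som = SelfOrganizingMap(n_clusters=k, n_epochs=epochs,
                            learning_rate=learning_rate, random_state=seed)
    labels = som.fit_predict(X) + 1
    sizes = np.bincount(labels, minlength=k + 1)[1:]
    logger.info("SOM clustering: k=%d, cluster sizes %s", k, sizes.tolist())
    return ClusterAssignment(labels, som.cluster_centers_, k,
                             metadata={"epochs": epochs,
                                       "learning_rate": learning_rate,
                                       "seed": seed})


def identify_phased_cluster(assignment: ClusterAssignment) -> int:
    """Cluster (1-based) whose centroid has the largest peak-to-trough range."""
    amplitudes = assignment.centroids.max(axis=1) - \
        assignment.centroids.min(axis=1)
    return int(np.argmax(amplitudes)) + 1


def cluster_profiles(matrix: LocusMatrix, assignment: ClusterAssignment,
                     cluster: int,
                     records_by_genotype: dict[str, pd.DataFrame],
                     flank: int | None = None, bin_size: int | None = None,
                     context: str | None = None
                     ) -> dict[str, MethylationProfile]:
    """Per-genotype metaprofiles restricted to one cluster's anchors."""
    rows = assignment.rows_in(cluster)
    if len(rows) == 0:
        raise InvalidConfigError(f"cluster {cluster} is empty")
    anchors = matrix.anchors.iloc[rows]
    flank = flank if flank is not None else int(-matrix.bin_offsets[0])
    bin_size = bin_size if bin_size is not None else matrix.bin_size
    context = context or matrix.context
    return {
        genotype: profile_around_anchors(records, anchors, flank=flank,
                                         bin_size=bin_size, context=context,
                                         label=f"cluster{cluster}_{genotype}")
        for genotype, records in records_by_genotype.items()
    }
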