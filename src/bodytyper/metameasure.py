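"""Aggregation of correlated measures into meta-measures.

Roughly 130 scanner measures are redundant: girths of neighbouring body
parts, left/right variants, and length chains are strongly correlated.
This module partitions the measures into k clusters of mutually
correlated measures (default k=13, labels A..M) and scores each
participant on each cluster by the mean of the member Z values, yielding
a compact "meta-measure" representation of body shape.

Two clustering routes are provided.  The default trains a small
two-dimensional self-organizing map on the measure profiles and cuts its
codebook into k groups by agglomerative clustering under correlation
distance; a direct hierarchical route (average linkage, distance =
1 - Pearson correlation between measure columns) serves as the
deterministic fallback and must give the same partition on
well-separated block data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .cohort import Z_SCORED, MeasureMatrix
from .measures import BLOCK_LABELS, block_members

log = logging.getLogger(__name__)


@dataclass
class MetaMeasureDefinition:
    """A labeled partition of the clustered measure set."""

    clusters: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.clusters.items():
            if not members:
                raise ValueError(f"meta-measure {label!r} has no members")
            dup = seen & set(members)
            if dup:
                raise ValueError(f"measures in more than one cluster: {sorted(dup)}")
            seen |= set(members)

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def labels(self) -> list[str]:
        return list(self.clusters)

    def measure_label(self) -> pd.Series:
        """Series measure name -> cluster label."""
        return pd.Series({m: lab for lab, ms in self.clusters.items() for m in ms})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({lab: list(ms) for lab, ms in self.clusters.items()},
                           fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MetaMeasureDefinition":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


# ----------------------------------------------------------------------
# batch self-organizing map
# ----------------------------------------------------------------------
class SelfOrganizingMap:
    """Small 2-D batch SOM.

    Items are mapped onto a ``grid`` of units; each epoch assigns every
    item to its best-matching unit and moves codebooks toward the
    neighbourhood-weighted item mean.  The neighbourhood radius decays
    linearly over the epochs.  Deterministic under a fixed seed.
    """

    def __init__(self, grid: tuple[int, int] = (8, 8), epochs: int = 100,
                 sigma0: float | None = None, seed: int = 0):
        self.grid = grid
        self.epochs = epochs
        self.sigma0 = max(grid) / 2.0 if sigma0 is None else sigma0
        self.seed = seed
        gy, gx = np.meshgrid(range(grid[0]), range(grid[1]), indexing="ij")
        self._coords = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
        self.codebook: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        rng = np.random.default_rng(self.seed)
        self.codebook = self._pca_init(X)
        self.codebook = self.codebook + 1e-6 * rng.standard_normal(self.codebook.shape)
        grid_d2 = ((self._coords[:, None, :] - self._coords[None, :, :]) ** 2).sum(-1)
        for epoch in range(self.epochs):
            frac = epoch / max(self.epochs - 1, 1)
            sigma = self.sigma0 * (1.0 - frac) + 0.5 * frac
            bmu = self.predict(X)
            h = np.exp(-grid_d2[:, bmu] / (2.0 * sigma ** 2))  # units x items
            wsum = h.sum(axis=1, keepdims=True)
            self.codebook = np.where(wsum > 0, (h @ X) / np.maximum(wsum, 1e-12),
                                     self.codebook)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)

    def _pca_init(self, X: np.ndarray) -> np.ndarray:
        """Span the unit grid over the plane of the two leading principal
        components (deterministic, standard SOM initialization)."""
        mu = X.mean(axis=0)
        Xc = X - mu
        # items may be few; PCA via SVD of the centered item matrix
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        axes = vt[:2]
        sds = s[:2] / max(np.sqrt(len(X)), 1.0)
        gy = np.linspace(-2, 2, self.grid[0])
        gx = np.linspace(-2, 2, self.grid[1])
        yy, xx = np.meshgrid(gy, gx, indexing="ij")
        comp = np.column_stack([yy.ravel(), xx.ravel()])
        if len(axes) < 2:  # degenerate: single direction
            return mu + np.outer(comp[:, 0] * sds[0], axes[0])
        return mu + comp @ (sds[:, None] * axes)


# ----------------------------------------------------------------------
def _corr_distance(z: pd.DataFrame) -> np.ndarray:
    """1 - Pearson correlation between measure columns, clipped to >= 0."""
    d = 1.0 - z.corr().to_numpy()
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _hierarchical_partition(z: pd.DataFrame, k: int) -> np.ndarray:
    dist = _corr_distance(z)
    link = linkage(squareform(dist, checks=False), method="average")
    return fcluster(link, t=k, criterion="maxclust")


def _corr_distance_matrix(a: np.ndarray) -> np.ndarray:
    c = np.corrcoef(a)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _som_partition(z: pd.DataFrame, k: int, seed: int,
                   grid: tuple[int, int], epochs: int) -> np.ndarray:
    X = z.to_numpy().T  # measures as items, participants as features
    som = SelfOrganizingMap(grid=grid, epochs=epochs, seed=seed).fit(X)
    bmu = som.predict(X)
    occupied = np.unique(bmu)
    if len(occupied) < k:
        log.warning("WARN SOM occupies %d < k=%d units; falling back to "
                    "hierarchical clustering", len(occupied), k)
        return _hierarchical_partition(z, k)
    # cut the occupied codebook into k groups under correlation distance
    cb = som.codebook[occupied]
    dist = _corr_distance_matrix(cb)
    link = linkage(squareform(dist, checks=False), method="average")
    unit_group = fcluster(link, t=k, criterion="maxclust")
    group_of_unit = dict(zip(occupied, unit_group))
    return np.array([group_of_unit[u] for u in bmu])


def _assign_labels(partition: np.ndarray, names: list[str]) -> dict[str, list[str]]:
    """Label recovered clusters by maximal overlap with the default A..M
    blocks (optimal one-to-one matching); leftovers get N1, N2, ..."""
    reference = block_members(include_indices=True)
    clusters = {cid: [names[i] for i in np.flatnonzero(partition == cid)]
                for cid in np.unique(partition)}
    cids = list(clusters)
    overlap = np.zeros((len(cids), len(BLOCK_LABELS)))
    for i, cid in enumerate(cids):
        for j, block in enumerate(BLOCK_LABELS):
            overlap[i, j] = len(set(clusters[cid]) & set(reference[block]))
    ri, ci = linear_sum_assignment(-overlap)
    label_of: dict[int, str] = {}
    for i, j in zip(ri, ci):
        if overlap[i, j] > 0:
            label_of[cids[i]] = BLOCK_LABELS[j]
    counter = 0
    for cid in cids:
        if cid not in label_of:
            counter += 1
            label_of[cid] = f"N{counter}"
    ordered = sorted(cids, key=lambda c: label_of[c])
    return {label_of[c]: clusters[c] for c in ordered}


def derive_metameasures(matrix: MeasureMatrix, k: int = 13,
                        method: str = "som", seed: int = 0,
                        som_grid: tuple[int, int] = (8, 8),
                        som_epochs: int = 100) -> MetaMeasureDefinition:
    """Partition the measures of a Z-scored matrix into k meta-measures.

    ``method="som"`` (default) clusters via the self-organizing map
    codebook; ``method="hierarchical"`` clusters the measures directly.
    Cluster labels are matched to the default blocks A..M by overlap.
    """
    matrix.require_state(Z_SCORED, "derive_metameasures")
    names = matrix.measure_names
    if not 1 <= k <= len(names):
        raise ValueError(f"k={k} outside [1, {len(names)}]")
    if k == 1:
        return MetaMeasureDefinition({"A": list(names)})
    if method == "som":
        partition = _som_partition(matrix.data, k, seed, som_grid, som_epochs)
    elif method == "hierarchical":
        partition = _hierarchical_partition(matrix.data, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MetaMeasureDefinition(_assign_labels(partition, names))


def score_metameasures(matrix: MeasureMatrix,
                       definition: MetaMeasureDefinition) -> pd.DataFrame:
    """Per-participant meta-measure scores: mean Z of the member measures."""
    matrix.require_state(Z_SCORED, "score_metameasures")
    missing = [m for ms in definition.clusters.values() for m in ms
               if m not in matrix.data.columns]
    if missing:
        raise KeyError(f"definition references absent measures: {missing}")
    return pd.DataFrame(
        {lab: matrix.data[ms].mean(axis=1)
         for lab, ms in definition.clusters.items()})


def partition_silhouette(matrix: MeasureMatrix, partition: np.ndarray) -> float:
    """Mean silhouette of a measure partition under correlation distance."""
    dist = _corr_distance(matrix.data)
    return float(silhouette_score(dist, partition, metric="precomputed"))


def auto_select_k(matrix: MeasureMatrix, k_range=range(2, 21)) -> int:
    """Select the measure-cluster count by maximal mean silhouette.

    Candidate partitions come from the deterministic hierarchical route
    (the SOM route must agree with it on separable data); ties resolve
    to the smallest k.
    """
    matrix.require_state(Z_SCORED, "auto_select_k")
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    n = len(matrix.measure_names)
    if any(k < 2 or k > n for k in ks):
        raise ValueError(f"k range must lie within [2, {n}]")
    dist = _corr_distance(matrix.data)
    link = linkage(squareform(dist, checks=False), method="average")
    best_k, best_s = None, -np.inf
    for k in ks:
        part = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(part)) < 2 or len(np.unique(part)) >= n:
            continue
        s = silhouette_score(dist, part, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid partition in the given k range")
    return best_k
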