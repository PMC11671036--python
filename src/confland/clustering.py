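"""Density-based clustering of encoded alignments and epsilon selection.

Sequences are clustered with DBSCAN on Euclidean distances between one-hot
encodings of their match columns, so the squared distance between two rows is
twice their Hamming distance and epsilon values live on the scale used
across the MSA-clustering ecosystem. Two selection strategies for epsilon
are provided: the
cluster-count maximum (``epsmax``) and the downstream criterion that counts
confidently classified conformational states per epsilon.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ArgumentError
from .msa import Msa, encode_onehot

#: Default epsilon grid for scans: 3.0 to 25.0 in steps of 0.5. Chosen to
#: bracket the useful range on the one-hot Euclidean scale at desk scale.
DEFAULT_EPS_GRID: tuple[float, ...] = tuple(np.arange(3.0, 25.0 + 1e-9, 0.5))

#: Default DBSCAN core-point threshold (neighbors within epsilon, inclusive
#: of the point itself). Configurable on every entry point.
DEFAULT_MIN_SAMPLES = 3

#: Mean-plDDT gate for counting a state call as confident during epsilon
#: selection (AlphaFold's conventional "good backbone" threshold).
CONFIDENT_PLDDT = 70.0


@dataclass(frozen=True)
class SequenceCluster:
    """One DBSCAN cluster with the query prepended to its members."""

    label: int
    members: Msa

    def __post_init__(self) -> None:
        if self.label < 0:
            raise ArgumentError("noise (label -1) is never emitted as a cluster")

    @property
    def size(self) -> int:
        """Number of non-query member rows."""
        return self.members.n_rows - 1


@dataclass
class EpsilonScanRow:
    epsilon: float
    n_clusters: int
    n_noise: int
    n_confident_classified: int | None = field(default=None)


def dbscan(
    distance_matrix: np.ndarray, epsilon: float, min_samples: int
) -> np.ndarray:
    """DBSCAN on a precomputed distance matrix; returns integer labels.

    Core points have at least ``min_samples`` points (themselves included)
    within distance ``epsilon``; clusters are connected components of core
    points under epsilon-reachability plus attached border points; noise is
    labeled ``-1``. Expansion proceeds in ascending point-index order, so a
    border point reachable from several clusters joins the one seeded by the
    lowest core index — the same deterministic rule scikit-learn applies.
    """
    d = np.asarray(distance_matrix, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ArgumentError(f"distance matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ArgumentError("distance matrix must be symmetric")
    if epsilon <= 0:
        raise ArgumentError(f"epsilon must be positive, got {epsilon}")
    if min_samples < 1:
        raise ArgumentError(f"min_samples must be >= 1, got {min_samples}")

    n = d.shape[0]
    within = d <= epsilon
    neighbor_counts = within.sum(axis=1)
    core = neighbor_counts >= min_samples
    labels = np.full(n, -1, dtype=np.int64)

    current = 0
    for start in range(n):
        if labels[start] != -1 or not core[start]:
            continue
        labels[start] = current
        queue: deque[int] = deque([start])
        while queue:
            point = queue.popleft()
            if not core[point]:
                continue  # border points do not expand the cluster
            for nb in np.flatnonzero(within[point]):
                if labels[nb] == -1:
                    labels[nb] = current
                    queue.append(nb)
        current += 1
    return labels


def msa_distance_matrix(msa: Msa) -> np.ndarray:
    """Pairwise Euclidean distances between one-hot encoded non-query rows."""
    if msa.n_rows < 2:
        raise ArgumentError("need at least one non-query row")
    x = encode_onehot(msa)[1:]
    return squareform(pdist(x, metric="euclidean"))


def _clusters_from_labels(
    msa: Msa, labels: np.ndarray
) -> list[SequenceCluster]:
    clusters = []
    for label in sorted(set(labels[labels >= 0])):
        idx = np.flatnonzero(labels == label)
        member_rows = (msa.rows[0],) + tuple(msa.rows[1 + i] for i in idx)
        clusters.append(SequenceCluster(int(label), Msa(member_rows)))
    clusters.sort(key=lambda c: (-c.size, c.label))
    return clusters


def cluster_msa(
    msa: Msa,
    epsilon: float,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    distance_matrix: np.ndarray | None = None,
) -> list[SequenceCluster]:
    """Cluster the non-query rows of an (already gap-filtered) alignment.

    The query never participates in the distance computation; it is
    prepended to every emitted cluster so each cluster is itself a valid
    prediction-ready alignment. Clusters are ordered by descending size,
    then ascending label. Noise rows are dropped.
    """
    if distance_matrix is None:
        distance_matrix = msa_distance_matrix(msa)
    labels = dbscan(distance_matrix, epsilon, min_samples)
    return _clusters_from_labels(msa, labels)


def scan_epsilon(
    msa: Msa,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[list[EpsilonScanRow], float]:
    """Run DBSCAN across an epsilon grid; also return ``epsmax``.

    ``epsmax`` is the grid value maximizing the number of clusters, ties
    broken toward the smaller epsilon. The distance matrix is computed once.
    """
    grid = [float(e) for e in eps_grid]
    if not grid:
        raise ArgumentError("epsilon grid must be nonempty")
    if any(e <= 0 for e in grid):
        raise ArgumentError("epsilon grid values must be positive")
    d = msa_distance_matrix(msa)
    rows = []
    for eps in grid:
        labels = dbscan(d, eps, min_samples)
        n_clusters = int(len(set(labels[labels >= 0])))
        n_noise = int(np.sum(labels == -1))
        rows.append(EpsilonScanRow(eps, n_clusters, n_noise))
    best = max(rows, key=lambda r: (r.n_clusters, -r.epsilon))
    return rows, best.epsilon


def select_epsilon_by_state_coverage(
    scan: Iterable[EpsilonScanRow],
    calls_per_eps: Mapping[float, Sequence],
    plddt_threshold: float = CONFIDENT_PLDDT,
) -> float:
    """Pick the epsilon maximizing confidently classified state calls.

    A call counts when its state is ``active`` or ``inactive`` and its mean
    plDDT exceeds ``plddt_threshold``. This is the selection used to raise
    epsilon above ``epsmax`` when the cluster-count optimum yields clusters
    too shallow to predict confidently. Ties go to the smaller epsilon.
    ``n_confident_classified`` is filled in on the scan rows as a side effect.
    """
    rows = list(scan)
    if not rows:
        raise ArgumentError("scan must be nonempty")
    for row in rows:
        if row.epsilon not in calls_per_eps:
            raise ArgumentError(f"no calls supplied for epsilon {row.epsilon}")
        calls = calls_per_eps[row.epsilon]
        row.n_confident_classified = sum(
            1
            for c in calls
            if c.state in ("active", "inactive") and c.mean_plddt > plddt_threshold
        )
    best = max(rows, key=lambda r: (r.n_confident_classified, -r.epsilon))
    return best.epsilon
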