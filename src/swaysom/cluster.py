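"""Second abstraction level: K-means over the SOM's active prototypes,
Davies-Bouldin K-scan, K selection, and propagation of cluster identity
back to the underlying data points.

Clustering the handful of active SOM prototypes instead of the raw data is
the classic two-level shortcut: the map quantises the data, K-means then
groups the prototype centroids, and every data point inherits the cluster
of its prototype.  The number of clusters is scanned over K = 2..30 with
the Davies-Bouldin (DB) index

    DB = (1/k) sum_i max_{j != i} (sigma_i + sigma_j) / ||mu_i - mu_j||

(sigma: RMS distance of members to their cluster mean; lower is better);
candidate K values are the local minima of the mean DB curve and the final
choice among them is the K with the highest external F-measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateClusteringError,
    EmptyResultError,
    InvalidArgumentError,
)
from .som import SOMModel, bmu_indices

logger = logging.getLogger(__name__)


@dataclass
class PrototypeSet:
    """Active SOM neurons (>= 1 hit) with their member data points."""

    vectors: np.ndarray               # (P, d) prototype vectors
    member_ids: list[np.ndarray]      # data-point indices per prototype
    neuron_indices: np.ndarray        # (P,) source neuron per prototype

    @property
    def n_prototypes(self) -> int:
        return len(self.member_ids)


class KMeansResult(NamedTuple):
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    history: list[float]              # WCSS after each Lloyd assignment step


@dataclass
class ClusterSolution:
    """A chosen-K clustering of the prototypes, propagated to data points."""

    K: int
    prototype_labels: np.ndarray
    point_labels: np.ndarray
    centroids: np.ndarray
    db_value: float
    db_curve: pd.DataFrame | None = None


def active_prototypes(
    model: SOMModel, data: np.ndarray, use_weights: bool = False
) -> PrototypeSet:
    """Prototype per neuron with at least one hit.

    By default the prototype vector is the centroid (mean) of the data
    points won by the neuron; ``use_weights`` substitutes the raw neuron
    weight instead.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise EmptyResultError("no data: no active prototypes")
    labels = bmu_indices(data, model.weights)
    active = np.unique(labels)
    members = [np.flatnonzero(labels == n) for n in active]
    if use_weights:
        vectors = model.weights[active]
    else:
        vectors = np.vstack([data[m].mean(axis=0) for m in members])
    return PrototypeSet(vectors=vectors, member_ids=members,
                        neuron_indices=active)


def _kmeans_pp(points: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding."""
    n = len(points)
    centroids = np.empty((K, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centroids[k] = points[rng.integers(n)]
        else:
            centroids[k] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centroids[k]) ** 2, axis=1))
    return centroids


def _lloyd(
    points: np.ndarray, centroids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    K = len(centroids)
    history: list[float] = []
    labels = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        d2 = np.sum((points[:, None, :] - centroids[None]) ** 2, axis=2)
        labels = np.argmin(d2, axis=1)
        wcss = float(d2[np.arange(len(points)), labels].sum())
        history.append(wcss)
        new = centroids.copy()
        for k in range(K):
            members = points[labels == k]
            if len(members):
                new[k] = members.mean(axis=0)
            else:
                # empty cluster: re-seed at the point farthest from its centroid
                far = np.argmax(d2[np.arange(len(points)), labels])
                new[k] = points[far]
        if np.allclose(new, centroids):
            centroids = new
            break
        centroids = new
    d2 = np.sum((points[:, None, :] - centroids[None]) ** 2, axis=2)
    labels = np.argmin(d2, axis=1)
    wcss = float(d2[np.arange(len(points)), labels].sum())
    if not history or wcss < history[-1]:
        history.append(wcss)
    return labels, centroids, wcss, history


def kmeans(
    points: np.ndarray,
    K: int,
    seed=None,
    max_iter: int = 300,
    n_init: int = 1,
) -> KMeansResult:
    """Lloyd's algorithm from k-means++ seeding (Euclidean metric).

    ``n_init`` independent restarts keep the solution with the lowest
    within-cluster sum of squares (WCSS).  Deterministic given the seed.
    ``history`` records WCSS after every Lloyd assignment step of the
    winning restart; it is non-increasing.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    if K > len(points):
        raise InvalidArgumentError(
            f"K = {K} exceeds the number of points ({len(points)})"
        )
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(max(n_init, 1)):
        centroids = _kmeans_pp(points, K, rng)
        labels, centroids, wcss, history = _lloyd(points, centroids, max_iter)
        if best is None or wcss < best.wcss:
            best = KMeansResult(labels, centroids, wcss, history)
    assert best is not None
    return best


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index with sigma = RMS member-to-centroid distance.

    DB_ij = (sigma_i + sigma_j) / ||mu_i - mu_j||, DB_i = max_{j != i} DB_ij,
    DB = mean_i DB_i.  Scale-invariant; lower indicates better separation.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise InvalidArgumentError("Davies-Bouldin needs >= 2 non-empty clusters")
    mus = np.vstack([points[labels == c].mean(axis=0) for c in clusters])
    sigmas = np.array(
        [
            np.sqrt(np.mean(np.sum((points[labels == c] - mu) ** 2, axis=1)))
            for c, mu in zip(clusters, mus)
        ]
    )
    k = clusters.size
    gaps = np.linalg.norm(mus[:, None, :] - mus[None], axis=2)
    off = ~np.eye(k, dtype=bool)
    if np.any(gaps[off] == 0.0):
        raise DegenerateClusteringError("coincident cluster centroids")
    ratio = (sigmas[:, None] + sigmas[None, :]) / np.where(off, gaps, np.inf)
    return float(np.mean(np.max(ratio, axis=1)))


def local_minima(k_values: Sequence[int], db_values: Sequence[float]) -> list[int]:
    """K values whose mean DB is below both neighbours (one-sided at the ends)."""
    db = np.asarray(db_values, dtype=float)
    ks = list(k_values)
    out = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or db[i] < db[i - 1]
        right_ok = i == len(ks) - 1 or db[i] < db[i + 1]
        if left_ok and right_ok:
            out.append(k)
    return out


def scan_k(
    points: np.ndarray,
    k_range: Sequence[int] = range(2, 31),
    reps: int = 10,
    seed=None,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, list[int]]:
    """Mean Davies-Bouldin over randomized K-means repetitions per K.

    Returns the DB curve (columns K, mean_db) and the list of its local
    minima.  K values above len(points) - 1 are clipped with a warning
    (K = n yields all-singleton clusters, degenerate for the DB ratio).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rng = np.random.default_rng(seed)
    kmax = len(points) - 1
    ks = [k for k in k_range if 2 <= k <= kmax]
    if len(ks) < len(list(k_range)):
        logger.warning(
            "scan_k: clipped K range to 2..%d for %d points", kmax, len(points)
        )
    if not ks:
        raise InvalidArgumentError("no feasible K in range for this point count")
    rows = []
    for k in ks:
        vals = []
        for _ in range(reps):
            res = kmeans(points, k, seed=rng, n_init=n_init, max_iter=max_iter)
            vals.append(davies_bouldin(points, res.labels))
        rows.append({"K": k, "mean_db": float(np.mean(vals))})
    curve = pd.DataFrame(rows)
    minima = local_minima(curve["K"].tolist(), curve["mean_db"].tolist())
    return curve, minima


def select_k(
    db_curve: pd.DataFrame,
    candidate_minima: Sequence[int],
    f_by_k: dict[int, float],
) -> int:
    """Choose K among the DB local minima by the highest mean F-measure.

    The global DB minimum is always a candidate; ties on F resolve to the
    smaller K.  The caller reuses the K chosen on the reference condition
    pair for the other pairs.
    """
    candidates = set(candidate_minima)
    if len(db_curve):
        global_min = int(db_curve.loc[db_curve["mean_db"].idxmin(), "K"])
        candidates.add(global_min)
    candidates = sorted(c for c in candidates if c in f_by_k)
    if not candidates:
        raise InvalidArgumentError("no candidate K with an F-measure value")
    return max(candidates, key=lambda k: (f_by_k[k], -k))


def propagate(
    prototype_labels: np.ndarray, prototype_set: PrototypeSet, n_points: int | None = None
) -> np.ndarray:
    """Assign every data point the cluster of its prototype."""
    prototype_labels = np.asarray(prototype_labels)
    if len(prototype_labels) != prototype_set.n_prototypes:
        raise InvalidArgumentError("one label per prototype required")
    if n_points is None:
        n_points = int(max(m.max() for m in prototype_set.member_ids) + 1)
    out = np.full(n_points, -1, dtype=int)
    for label, members in zip(prototype_labels, prototype_set.member_ids):
        out[members] = label
    if np.any(out < 0):
        raise InvalidArgumentError("prototype members do not cover all points")
    return out
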