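"""Kohonen self-organizing map: competition, adaptation, sequential and
batch training, plus the standard map diagnostics (hit counts, U-matrix,
weight planes).

A SOM projects input vectors onto a low-dimensional neuron grid by
competitive learning.  Each neuron n carries a weight vector w_n of the
input dimensionality; the best-matching unit (BMU) for an input x minimises
the Euclidean distance

    d_n = sqrt(sum_m (x_m - w_mn)^2)

Sequential training updates the winner and its grid neighbours after every
sample with the Kohonen rule W <- W + mu * h * (X - W), where h is a
Gaussian neighbourhood factor that shrinks with grid distance; the learning
rate and neighbourhood radius decay linearly from coarse to fine.  Batch
training replaces the recursion with one update per epoch: every neuron's
weight becomes the mean of all samples whose BMU lies within the current
neighbourhood radius (a step-function kernel), so there is no learning rate
and no dependence on the order in which the data are presented.

The grid is hexagonal by default with a link (hop-count) neighbourhood
distance, mirroring the conventions of the classic SOM toolboxes; a
rectangular topology is available for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError


class SOMGrid:
    """Neuron grid geometry: layout positions and inter-neuron distances."""

    def __init__(self, rows: int = 10, cols: int = 10, topology: str = "hexagonal"):
        if rows < 1 or cols < 1:
            raise InvalidArgumentError("grid must have at least one neuron")
        if topology not in ("hexagonal", "rectangular"):
            raise InvalidArgumentError("topology must be hexagonal or rectangular")
        self.rows = rows
        self.cols = cols
        self.topology = topology
        self._positions: np.ndarray | None = None
        self._link: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def positions(self) -> np.ndarray:
        """(n_neurons, 2) layout-space coordinates, row-major neuron order."""
        if self._positions is None:
            i, j = np.divmod(np.arange(self.n_neurons), self.cols)
            if self.topology == "hexagonal":
                x = j + 0.5 * (i % 2)
                y = i * (np.sqrt(3.0) / 2.0)
            else:
                x = j.astype(float)
                y = i.astype(float)
            self._positions = np.column_stack([x, y])
        return self._positions

    @property
    def link_distances(self) -> np.ndarray:
        """Hop-count grid distance: neighbours are units one layout step apart."""
        if self._link is None:
            adj = cdist(self.positions, self.positions) <= 1.0 + 1e-9
            np.fill_diagonal(adj, False)
            self._link = shortest_path(adj.astype(float), unweighted=True)
        return self._link

    def to_dict(self) -> dict:
        return {"rows": self.rows, "cols": self.cols, "topology": self.topology}


@dataclass
class SOMModel:
    """A trained (or initialised) map: grid + per-neuron weight vectors."""

    grid: SOMGrid
    weights: np.ndarray                 # (n_neurons, n_features)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.grid.n_neurons:
            raise InvalidArgumentError("weights rows must equal neuron count")
        if not np.all(np.isfinite(self.weights)):
            raise InvalidArgumentError("weights must be finite")

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "grid": self.grid.to_dict(),
            "weights": self.weights.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        grid = SOMGrid(**payload["grid"])
        return cls(grid=grid, weights=np.array(payload["weights"]),
                   metadata=payload.get("metadata", {}))


def _check_data(data: np.ndarray) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise InvalidArgumentError("data must be non-empty")
    return data


def bmu_indices(data: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Best-matching unit per row; ties resolve to the lowest neuron index."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != weights.shape[1]:
        raise InvalidArgumentError(
            f"input dimensionality {data.shape[1]} != weight dimensionality "
            f"{weights.shape[1]}"
        )
    # squared Euclidean suffices for the argmin; argmin returns the first
    # (lowest-index) minimiser, which is the documented tie rule
    d2 = (
        np.sum(data**2, axis=1)[:, None]
        - 2.0 * data @ weights.T
        + np.sum(weights**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def bmu(x: np.ndarray, model: SOMModel) -> int:
    """Winning neuron index for a single input vector."""
    return int(bmu_indices(np.atleast_2d(x), model.weights)[0])


def quantization_error(data: np.ndarray, weights: np.ndarray) -> float:
    """Mean Euclidean distance of samples to their BMU weights."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = bmu_indices(data, weights)
    return float(np.mean(np.linalg.norm(data - weights[labels], axis=1)))


def initial_weights(
    grid: SOMGrid, n_features: int, data: np.ndarray | None = None,
    method: str = "random", seed=None,
) -> np.ndarray:
    """Initial weights: small uniform random values in [0, 0.01] (default),
    or a linear span of the data's top two principal axes ("linear")."""
    rng = np.random.default_rng(seed)
    if method == "random":
        return rng.uniform(0.0, 0.01, size=(grid.n_neurons, n_features))
    if method == "linear":
        if data is None:
            raise InvalidArgumentError("linear initialization requires data")
        data = _check_data(data)
        mean = data.mean(axis=0)
        centered = data - mean
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        coords = np.zeros((grid.n_neurons, 2))
        i, j = np.divmod(np.arange(grid.n_neurons), grid.cols)
        coords[:, 0] = (j / max(grid.cols - 1, 1)) * 2 - 1
        coords[:, 1] = (i / max(grid.rows - 1, 1)) * 2 - 1
        n_axes = min(2, vt.shape[0])
        scale = s[:n_axes] / np.sqrt(max(len(data) - 1, 1))
        w = mean + coords[:, :n_axes] * scale @ vt[:n_axes]
        return w
    raise InvalidArgumentError("init method must be 'random' or 'linear'")


def batch_update(
    weights: np.ndarray, data: np.ndarray, grid: SOMGrid, radius: float
) -> np.ndarray:
    """One batch epoch with a step-function neighbourhood of the given radius.

    Every neuron's new weight is the mean of all samples whose BMU lies
    within ``radius`` link-distance of it; neurons with no contributing
    samples keep their previous weights.  Order-independent by construction.
    """
    labels = bmu_indices(data, weights)
    counts = np.bincount(labels, minlength=grid.n_neurons).astype(float)
    sums = np.zeros_like(weights)
    np.add.at(sums, labels, data)
    mask = (grid.link_distances <= radius + 1e-12).astype(float)
    num = mask @ sums
    den = mask @ counts
    new = weights.copy()
    hit = den > 0
    new[hit] = num[hit] / den[hit, None]
    return new


def _radius_schedule(iterations: int, radius0: float, radius_floor: float) -> np.ndarray:
    """Linear shrink from radius0 to the floor over the ordering phase
    (first half of training), then constant at the floor."""
    ordering = max(iterations // 2, 1)
    t = np.arange(iterations, dtype=float)
    frac = np.minimum(t / max(ordering - 1, 1), 1.0)
    return radius0 + (radius_floor - radius0) * frac


def train_batch(
    data: np.ndarray,
    grid: SOMGrid | None = None,
    iterations: int = 1000,
    neighborhood0: float = 3.0,
    seed=None,
    init: str = "random",
    radius_floor: float = 1.0,
    track_qe: bool = False,
) -> SOMModel:
    """Batch-train a SOM (the pipeline's training mode).

    Deterministic given the seed (which only drives initialisation) and
    independent of the order of the data rows.
    """
    data = _check_data(data)
    if grid is None:
        grid = SOMGrid()
    if iterations < 1:
        raise InvalidArgumentError("iterations must be >= 1")
    weights = initial_weights(grid, data.shape[1], data=data, method=init, seed=seed)
    radii = _radius_schedule(iterations, neighborhood0, radius_floor)
    qe_history = []
    for radius in radii:
        weights = batch_update(weights, data, grid, radius)
        if track_qe:
            qe_history.append(quantization_error(data, weights))
    metadata = {
        "mode": "batch",
        "iterations": iterations,
        "neighborhood0": neighborhood0,
        "radius_floor": radius_floor,
        "init": init,
        "seed": None if seed is None else repr(seed),
    }
    if track_qe:
        metadata["qe_history"] = qe_history
    return SOMModel(grid=grid, weights=weights, metadata=metadata)


def train_sequential(
    data: np.ndarray,
    grid: SOMGrid | None = None,
    epochs: int = 10,
    mu0: float = 0.5,
    neighborhood0: float = 3.0,
    seed=None,
    mu_floor: float = 0.01,
    radius_floor: float = 1.0,
    init: str = "random",
) -> SOMModel:
    """Sequential (per-sample) Kohonen training with a Gaussian neighbourhood.

    W <- W + mu_t * h * (X - W), with h = exp(-link^2 / (2 sigma_t^2));
    mu decays linearly from mu0 to mu_floor and sigma from neighborhood0 to
    radius_floor over all presentations.  Sample order is reshuffled each
    epoch from the seeded generator, so results depend on the seed.
    """
    data = _check_data(data)
    if not 0 < mu0 <= 1:
        raise InvalidArgumentError("mu0 must lie in (0, 1]")
    if grid is None:
        grid = SOMGrid()
    rng = np.random.default_rng(seed)
    weights = initial_weights(grid, data.shape[1], data=data, method=init, seed=rng)
    link = grid.link_distances
    n = len(data)
    total = max(epochs * n - 1, 1)
    step = 0
    for _ in range(epochs):
        for idx in rng.permutation(n):
            frac = step / total
            mu = mu0 + (mu_floor - mu0) * frac
            sigma = max(neighborhood0 + (radius_floor - neighborhood0) * frac, 1e-12)
            x = data[idx]
            winner = int(bmu_indices(x[None, :], weights)[0])
            h = np.exp(-(link[winner] ** 2) / (2.0 * sigma**2))
            weights = weights + mu * h[:, None] * (x - weights)
            step += 1
    return SOMModel(
        grid=grid,
        weights=weights,
        metadata={
            "mode": "sequential", "epochs": epochs, "mu0": mu0,
            "neighborhood0": neighborhood0, "mu_floor": mu_floor,
            "radius_floor": radius_floor, "init": init,
            "seed": None if seed is None else repr(seed),
        },
    )


def hits(data: np.ndarray, model: SOMModel) -> np.ndarray:
    """Per-neuron count of samples whose BMU is that neuron."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        return np.zeros(model.grid.n_neurons, dtype=int)
    labels = bmu_indices(data, model.weights)
    return np.bincount(labels, minlength=model.grid.n_neurons)


def u_matrix(model: SOMModel) -> np.ndarray:
    """Per-neuron mean weight-space distance to its immediate grid neighbours."""
    link = model.grid.link_distances
    d = cdist(model.weights, model.weights)
    out = np.zeros(model.grid.n_neurons)
    for n in range(model.grid.n_neurons):
        nbrs = np.flatnonzero(np.isclose(link[n], 1.0))
        if nbrs.size:
            out[n] = d[n, nbrs].mean()
    return out


def weight_planes(model: SOMModel) -> np.ndarray:
    """(n_features, rows, cols) view of the weights, one plane per feature."""
    g = model.grid
    return model.weights.T.reshape(model.n_features, g.rows, g.cols)
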