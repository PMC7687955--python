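"""Self-organizing map on a hexagonal grid with cosine-similarity
best-matching-unit search.

The map is a rows x cols array of neurons laid out hexagonally (odd rows
offset by half a column, rows sqrt(3)/2 apart).  Training presents
individual spectra in a seeded shuffled order; the winning neuron and its
grid neighbours move toward the input under a Gaussian neighbourhood
kernel whose width and the learning rate decay over the schedule.
Defaults follow the study's stated hyperparameters: 20x20 neurons,
5 epochs, initial learning rate 0.2, initial neighbourhood 2/3 of the
grid edge length, cosine similarity for the BMU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import LabeledDataset

#: Neighbourhood weights below this are skipped during the update.
_H_CUTOFF = 1e-6


@dataclass
class SOMConfig:
    rows: int = 20
    cols: int = 20
    epochs: int = 5
    steps: int | None = None          # overrides epochs * n_samples when set
    initial_learning_rate: float = 0.2
    final_learning_rate: float = 0.01
    initial_neighborhood: float | None = None   # default 2/3 * max(rows, cols)
    final_neighborhood: float = 1.0
    lr_decay: str = "linear"          # linear | exponential
    nbh_decay: str = "linear"         # linear | exponential | constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not (0.0 < self.initial_learning_rate <= 1.0):
            raise ValueError("initial_learning_rate must lie in (0, 1]")
        if self.initial_neighborhood is None:
            self.initial_neighborhood = (2.0 / 3.0) * max(self.rows, self.cols)
        if self.initial_neighborhood <= 0:
            raise ValueError("initial_neighborhood must be positive")
        if self.lr_decay not in ("linear", "exponential"):
            raise ValueError(f"unknown lr_decay {self.lr_decay!r}")
        if self.nbh_decay not in ("linear", "exponential", "constant"):
            raise ValueError(f"unknown nbh_decay {self.nbh_decay!r}")

    def total_steps(self, n_samples: int) -> int:
        """Training presentations: explicit ``steps`` or epochs * n."""
        return self.steps if self.steps is not None else self.epochs * n_samples


def hex_coordinates(rows: int, cols: int) -> np.ndarray:
    """2-D layout coordinates of a hexagonal grid, row-major neuron order:
    odd rows shifted by 0.5 columns, rows sqrt(3)/2 apart."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y]).astype(float)


@dataclass
class SOMGrid:
    """Trained (or initial) map: neuron weights + layout, and after
    supervised hit accumulation the per-neuron class hit counts."""

    weights: np.ndarray               # (n_neurons, n_points)
    coords: np.ndarray                # (n_neurons, 2) hex layout
    rows: int
    cols: int
    wavenumbers: np.ndarray | None = None
    class_hits: np.ndarray | None = None   # (n_neurons, n_classes)
    classes: tuple[str, ...] | None = None
    _sq_dists: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def squared_distances(self) -> np.ndarray:
        """Pairwise squared hex-layout distances, cached."""
        if self._sq_dists is None:
            d = self.coords[:, None, :] - self.coords[None, :, :]
            self._sq_dists = np.einsum("ijk,ijk->ij", d, d)
        return self._sq_dists

    def copy(self) -> "SOMGrid":
        return SOMGrid(
            self.weights.copy(), self.coords, self.rows, self.cols,
            self.wavenumbers,
            None if self.class_hits is None else self.class_hits.copy(),
            self.classes,
        )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a||b|); rejects zero vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _similarities(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(x)
    if nx == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    nw = np.linalg.norm(weights, axis=1)
    if np.any(nw == 0.0):
        raise ValueError("grid contains an all-zero weight vector")
    return (weights @ x) / (nw * nx)


def find_bmu(grid: SOMGrid, spectrum: np.ndarray) -> int:
    """Index of the most cosine-similar neuron; ties -> lowest index."""
    x = np.asarray(spectrum, float)
    if x.shape != (grid.weights.shape[1],):
        raise ValueError(
            f"spectrum length {x.shape} does not match weight dimension "
            f"{grid.weights.shape[1]}"
        )
    return int(np.argmax(_similarities(grid.weights, x)))


def bmu_indices(grid: SOMGrid, data: np.ndarray) -> np.ndarray:
    """Vectorized BMU search for a (n, p) matrix of spectra."""
    X = np.atleast_2d(np.asarray(data, float))
    nx = np.linalg.norm(X, axis=1)
    if np.any(nx == 0.0):
        raise ValueError("cosine similarity undefined for a zero vector")
    nw = np.linalg.norm(grid.weights, axis=1)
    sims = (X / nx[:, None]) @ (grid.weights / nw[:, None]).T
    return np.argmax(sims, axis=1)


def init_grid(config: SOMConfig, data: LabeledDataset,
              jitter: float = 1e-3) -> SOMGrid:
    """Seed neuron weights from random training spectra plus small jitter
    (sd = ``jitter`` x RMS of the data), then unit-normalize."""
    if data.n_spectra == 0:
        raise ValueError("cannot initialize a SOM from empty data")
    rng = np.random.default_rng(config.seed)
    n_neurons = config.rows * config.cols
    idx = rng.integers(0, data.n_spectra, size=n_neurons)
    W = data.intensities[idx].astype(float).copy()
    if jitter > 0:
        scale = float(np.sqrt(np.mean(data.intensities**2))) or 1.0
        W += rng.normal(0.0, jitter * scale, size=W.shape)
    nrm = np.linalg.norm(W, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    W /= nrm
    return SOMGrid(W, hex_coordinates(config.rows, config.cols),
                   config.rows, config.cols, wavenumbers=data.wavenumbers)


def _schedule(kind: str, start: float, end: float, t: int, total: int) -> float:
    frac = t / max(total - 1, 1)
    if kind == "constant":
        return start
    if kind == "linear":
        return start + (end - start) * frac
    return start * (end / start) ** frac      # exponential


def train(grid: SOMGrid, data: LabeledDataset, config: SOMConfig
          ) -> tuple[SOMGrid, np.ndarray]:
    """Sequential SOM training.

    Spectra are presented in a fresh seeded shuffle each epoch.  Every
    step updates all neurons i by ``w_i += alpha(t) * h(i, bmu, t) *
    (x - w_i)`` with a Gaussian kernel ``h = exp(-d^2 / (2 sigma^2))`` on
    hex-layout Euclidean distance.  Returns (trained grid, quantization
    error after each completed epoch).
    """
    out = grid.copy()
    X = data.intensities
    n = X.shape[0]
    total = config.total_steps(n)
    if total < 1:
        raise ValueError("training needs at least one step")
    rng = np.random.default_rng(config.seed)
    D2 = out.squared_distances()
    W = out.weights
    qe_trace: list[float] = []
    order = rng.permutation(n)
    pos = 0
    for t in range(total):
        if pos == n:
            qe_trace.append(quantization_error(out, data))
            order = rng.permutation(n)
            pos = 0
        x = X[order[pos]]
        pos += 1
        alpha = _schedule(config.lr_decay, config.initial_learning_rate,
                          config.final_learning_rate, t, total)
        sigma = _schedule(config.nbh_decay, config.initial_neighborhood,
                          config.final_neighborhood, t, total)
        b = int(np.argmax(_similarities(W, x)))
        h = np.exp(-D2[b] / (2.0 * sigma * sigma))
        active = h >= _H_CUTOFF
        W[active] += (alpha * h[active])[:, None] * (x - W[active])
    qe_trace.append(quantization_error(out, data))
    return out, np.asarray(qe_trace)


def quantization_error(grid: SOMGrid, data: LabeledDataset | np.ndarray) -> float:
    """Mean (1 - cosine similarity to the BMU) over all spectra."""
    X = data.intensities if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    if X.shape[0] == 0:
        raise ValueError("quantization error undefined for empty data")
    nx = np.linalg.norm(X, axis=1)
    nw = np.linalg.norm(grid.weights, axis=1)
    sims = (X / nx[:, None]) @ (grid.weights / nw[:, None]).T
    return float(np.mean(1.0 - sims.max(axis=1)))
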