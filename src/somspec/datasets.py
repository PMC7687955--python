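"""Core containers for Raman spectra, spatial maps, labelled collections
and component libraries.

Everything downstream (preprocessing, the self-organizing map, spectral
unmixing, ratio imaging) operates on these four containers.  Intensities
are stored as float64 arrays on a shared, strictly increasing wavenumber
axis in cm^-1; spatial positions are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Axes whose pointwise differences stay below this (cm^-1) are "common".
AXIS_TOL = 1e-6


def _as_axis(values: Iterable[float]) -> np.ndarray:
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(axis)):
        raise ValueError("wavenumber axis contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


def axes_match(a: np.ndarray, b: np.ndarray, tol: float = AXIS_TOL) -> bool:
    """True when two wavenumber axes agree pointwise within ``tol`` cm^-1."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return a.shape == b.shape and bool(np.max(np.abs(a - b)) < tol)


@dataclass
class Spectrum:
    """A single Raman measurement: intensities over a wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _as_axis(self.wavenumbers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavenumbers.shape:
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"axis shape {self.wavenumbers.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy())

    def index_of(self, wavenumber: float) -> int:
        """Index of the axis point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))


@dataclass
class SpectralMap:
    """A grid of spectra acquired at regular spatial positions.

    ``intensities`` is (n_spectra, n_points) row-per-position; ``positions``
    is (n_spectra, 2) in micrometres with ``step`` the grid pitch.
    ``provenance`` carries free-form metadata (group/mouse/eye labels,
    injected cosmic-ray spikes, repair logs).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    positions: np.ndarray
    step: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _as_axis(self.wavenumbers)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, float))
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError("spectra and axis lengths differ")
        if self.positions.shape != (self.intensities.shape[0], 2):
            raise ValueError("positions must be (n_spectra, 2)")
        if self.step <= 0:
            raise ValueError("step must be positive")
        uniq = {tuple(p) for p in np.round(self.positions, 9)}
        if len(uniq) != self.positions.shape[0]:
            raise ValueError("map positions must be unique")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i])

    def grid_indices(self) -> np.ndarray:
        """Integer (row, col) grid indices recovered from positions/step."""
        return np.rint(self.positions / self.step).astype(int)

    def grid_shape(self) -> tuple[int, int]:
        ij = self.grid_indices()
        return int(ij[:, 0].max()) + 1, int(ij[:, 1].max()) + 1


@dataclass
class LabeledDataset:
    """Flat collection of spectra with group / mouse / eye metadata.

    ``classes`` fixes the declared class order, used for deterministic
    tie-breaking in classification and for confusion-matrix layout.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    mouse_ids: np.ndarray
    eye_sides: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.wavenumbers = _as_axis(self.wavenumbers)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.mouse_ids = np.asarray(self.mouse_ids, dtype=object)
        self.eye_sides = np.asarray(self.eye_sides, dtype=object)
        self.classes = tuple(self.classes)
        n = self.intensities.shape[0]
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError("spectra and axis lengths differ")
        for name, arr in (
            ("labels", self.labels),
            ("mouse_ids", self.mouse_ids),
            ("eye_sides", self.eye_sides),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per spectrum")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared class set: {sorted(unknown)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i])

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.wavenumbers,
            self.intensities[idx],
            self.labels[idx],
            self.mouse_ids[idx],
            self.eye_sides[idx],
            self.classes,
        )

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.classes}

    def replace_intensities(self, intensities: np.ndarray) -> "LabeledDataset":
        return replace(self, intensities=np.asarray(intensities, float))


@dataclass
class ComponentLibrary:
    """Named component spectra on one shared wavenumber axis."""

    names: tuple[str, ...]
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        self.wavenumbers = _as_axis(self.wavenumbers)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, float))
        if self.intensities.shape != (len(self.names), self.wavenumbers.size):
            raise ValueError("library intensities must be (n_components, n_points)")

    @property
    def n_components(self) -> int:
        return len(self.names)

    def component(self, name: str) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[self.names.index(name)])
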