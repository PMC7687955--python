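"""Spectral preprocessing: cosmic-ray removal, baseline subtraction,
map averaging, normalization and stratified train/test splitting.

The cleaning chain mirrors standard Raman map post-processing: spikes are
repaired from spatially adjacent grid neighbours, the fluorescence
background is estimated by an iterative lower-envelope cubic spline with
a fixed number of nodes (default 11), maps are averaged to one spectrum
per tissue sample, and spectra are unit-norm scaled before training the
(cosine-metric) self-organizing map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .datasets import LabeledDataset, SpectralMap, Spectrum

#: Consistency factor making the MAD an unbiased robust sd for Gaussians.
MAD_SCALE = 1.4826


@dataclass
class PreprocessConfig:
    cosmic_k: float = 8.0          # spike threshold, in MADs of the residual
    baseline_nodes: int = 11
    baseline_max_iter: int = 100
    normalize: bool = True
    split_fraction: float = 0.2
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_nodes < 3:
            raise ValueError("baseline_nodes must be >= 3")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.cosmic_k <= 0:
            raise ValueError("cosmic_k must be positive")


def _grid_neighbors(map_: SpectralMap) -> list[np.ndarray]:
    """Indices of 4-connected grid neighbours for every spectrum."""
    ij = map_.grid_indices()
    lookup = {tuple(p): i for i, p in enumerate(ij)}
    out = []
    for r, c in ij:
        nbr = [lookup[p] for p in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
               if p in lookup]
        out.append(np.asarray(nbr, dtype=int))
    return out


def remove_cosmic_rays(map_: SpectralMap,
                       config: PreprocessConfig | None = None
                       ) -> tuple[SpectralMap, list[tuple[int, int]]]:
    """Repair single-channel spikes using spatial grid neighbours.

    For each spectrum, the channelwise median of its 4-connected
    neighbours defines a clean reference; channels whose positive
    residual exceeds ``cosmic_k`` robust deviations (1.4826 x the median
    absolute deviation of that spectrum's residuals, the Gaussian-
    consistent robust sd) are replaced by the reference value.

    Returns the repaired map and the list of (spectrum_index, channel)
    repairs (also stored in ``provenance['repairs']``).
    """
    config = config or PreprocessConfig()
    if map_.n_spectra < 2:
        raise ValueError("cosmic-ray removal needs a map with >= 2 spectra")
    nbrs = _grid_neighbors(map_)
    intens = map_.intensities.copy()
    repairs: list[tuple[int, int]] = []
    for i in range(map_.n_spectra):
        ref = np.median(map_.intensities[nbrs[i]], axis=0)
        resid = map_.intensities[i] - ref
        scale = MAD_SCALE * float(np.median(np.abs(resid - np.median(resid))))
        flagged = np.flatnonzero(resid > config.cosmic_k * scale)
        for ch in flagged:
            intens[i, ch] = ref[ch]
            repairs.append((i, int(ch)))
    prov = dict(map_.provenance)
    prov["repairs"] = list(repairs)
    fixed = SpectralMap(map_.wavenumbers, intens, map_.positions.copy(),
                        map_.step, provenance=prov)
    return fixed, repairs


def estimate_baseline(spectrum: Spectrum,
                      config: PreprocessConfig | None = None) -> np.ndarray:
    """Iterative lower-envelope cubic-spline background estimate.

    ``baseline_nodes`` windows are placed evenly across the axis; node
    positions/values start at the window minima of the signal.  Points of
    the working signal falling below the current spline are raised onto
    it (de-biasing noise minima), node minima are recomputed and the
    spline refitted until node values move by less than 1e-6 of the data
    range (making the estimate exactly scale-equivariant) or
    ``baseline_max_iter`` is reached.
    """
    config = config or PreprocessConfig()
    x, y = spectrum.wavenumbers, spectrum.intensities
    n_nodes = config.baseline_nodes
    if y.size <= 2 * n_nodes:
        raise ValueError("spectrum too short for the requested node count")
    edges = np.linspace(0, y.size, n_nodes + 1).astype(int)
    windows = [slice(edges[k], edges[k + 1]) for k in range(n_nodes)]
    scale = float(np.ptp(y)) or 1.0
    work = y.astype(float).copy()
    prev = None
    base = np.zeros_like(work)
    for _ in range(config.baseline_max_iter):
        node_x = np.empty(n_nodes)
        node_y = np.empty(n_nodes)
        for k, w in enumerate(windows):
            j = int(np.argmin(work[w])) + w.start
            node_x[k] = x[j]
            node_y[k] = work[j]
        base = CubicSpline(node_x, node_y)(x)
        if prev is not None and np.max(np.abs(node_y - prev)) < 1e-6 * scale:
            break
        prev = node_y
        np.maximum(work, base, out=work)
    return base


def subtract_baseline(spectrum: Spectrum,
                      config: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the lower-envelope spline background (output not clipped)."""
    base = estimate_baseline(spectrum, config)
    return Spectrum(spectrum.wavenumbers, spectrum.intensities - base)


def average_map(map_: SpectralMap) -> Spectrum:
    """Pointwise arithmetic mean over all spectra of a map."""
    if map_.n_spectra == 0:
        raise ValueError("cannot average an empty map")
    return Spectrum(map_.wavenumbers, map_.intensities.mean(axis=0))


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm (rejects the all-zero spectrum)."""
    nrm = float(np.linalg.norm(spectrum.intensities))
    if nrm == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return Spectrum(spectrum.wavenumbers, spectrum.intensities / nrm)


def preprocess_dataset(dataset: LabeledDataset,
                       config: PreprocessConfig | None = None,
                       baseline: bool = True) -> LabeledDataset:
    """Row-wise baseline subtraction and unit-norm scaling of a dataset."""
    config = config or PreprocessConfig()
    out = dataset.intensities.astype(float).copy()
    if baseline:
        for i in range(out.shape[0]):
            out[i] -= estimate_baseline(Spectrum(dataset.wavenumbers, out[i]), config)
    if config.normalize:
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        if np.any(nrm == 0):
            raise ValueError("dataset contains an all-zero spectrum")
        out /= nrm
    return dataset.replace_intensities(out)


def preprocess_maps(maps, config: PreprocessConfig | None = None,
                    baseline: bool = True):
    """Map-wise cosmic-ray removal followed by per-spectrum cleaning.

    Returns (cleaned maps, list of per-map repair lists); feed the maps to
    :func:`somspec.synthetic.flatten_maps` or :func:`average_map`.
    """
    config = config or PreprocessConfig()
    cleaned, all_repairs = [], []
    for m in maps:
        fixed, repairs = remove_cosmic_rays(m, config)
        if baseline:
            intens = fixed.intensities
            for i in range(intens.shape[0]):
                intens[i] -= estimate_baseline(Spectrum(fixed.wavenumbers, intens[i]), config)
        cleaned.append(fixed)
        all_repairs.append(repairs)
    return cleaned, all_repairs


def split_dataset(dataset: LabeledDataset,
                  config: PreprocessConfig | None = None
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split: exactly round(fraction * n_g) spectra
    per group go to the test set, deterministically under ``split_seed``."""
    config = config or PreprocessConfig()
    rng = np.random.default_rng(config.split_seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in dataset.classes:
        idx = np.flatnonzero(dataset.labels == cls)
        n_test = int(np.floor(config.split_fraction * idx.size + 0.5))
        if idx.size == 0 or n_test == 0 or n_test == idx.size:
            raise ValueError(f"group {cls!r} too small for fraction {config.split_fraction}")
        perm = rng.permutation(idx.size)
        test_idx += list(idx[perm[:n_test]])
        train_idx += list(idx[perm[n_test:]])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))
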