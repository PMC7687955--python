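"""Band-ratio imaging of spectral maps and SOM hit-map rendering.

Ratio images visualise local chemistry (default: 1447 / 1266 cm^-1, the
CH2-bending to CH-bending ratio that rises when the 1266 cm^-1 band is
suppressed after injury).  Hit maps tile the hexagonal SOM with
per-neuron colors mixed according to the class hit proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpectralMap, Spectrum
from .som import SOMGrid

#: Default class palette (RGB in [0, 1]).
DEFAULT_PALETTE = {
    "sham": (0.0, 0.0, 0.0),          # black
    "mTBI": (0.5, 0.0, 0.5),          # purple
    "sTBI": (1.0, 0.55, 0.0),         # orange
}

#: Color of neurons that received no hits.
GREY = (0.7, 0.7, 0.7)

_DENOM_EPS = 1e-9


def band_intensity(spectrum: Spectrum, center: float, half_width: float = 8.0,
                   statistic: str = "max") -> float:
    """Band statistic within [center - half_width, center + half_width].

    ``statistic`` is "max" (default; robust to small calibration shifts)
    or "area" (trapezoidal integral over the window).
    """
    x = spectrum.wavenumbers
    if center - half_width < x[0] or center + half_width > x[-1]:
        raise ValueError(f"band window around {center} cm^-1 outside the axis")
    mask = (x >= center - half_width) & (x <= center + half_width)
    y = spectrum.intensities[mask]
    if statistic == "max":
        return float(y.max())
    if statistic == "area":
        return float(np.trapezoid(y, x[mask]))
    raise ValueError(f"unknown band statistic {statistic!r}")


@dataclass
class RatioImage:
    """Grid of band-intensity ratios aligned to the source map layout.

    Pixels whose denominator intensity is ~0 are flagged invalid (NaN in
    ``values``, False in ``valid``) rather than dropped, preserving the
    grid shape.
    """

    values: np.ndarray                # 2-D, NaN where invalid
    valid: np.ndarray                 # 2-D bool
    numerator: float
    denominator: float
    half_width: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def flat_values(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


def ratio_map(map_: SpectralMap, numerator: float = 1447.0,
              denominator: float = 1266.0, half_width: float = 8.0,
              statistic: str = "max") -> RatioImage:
    """Per-position band-intensity ratio over a (preprocessed) map."""
    ij = map_.grid_indices()
    shape = map_.grid_shape()
    values = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for k in range(map_.n_spectra):
        s = map_.spectrum(k)
        num = band_intensity(s, numerator, half_width, statistic)
        den = band_intensity(s, denominator, half_width, statistic)
        r, c = ij[k]
        if den > _DENOM_EPS:
            values[r, c] = num / den
            valid[r, c] = True
    return RatioImage(values, valid, numerator, denominator, half_width)


def neuron_colors(grid: SOMGrid, palette: dict | None = None) -> np.ndarray:
    """Per-neuron RGB: hit-proportion-weighted mix of class colors;
    zero-hit neurons neutral grey."""
    if grid.class_hits is None or grid.classes is None:
        raise ValueError("class hits not populated")
    palette = palette or DEFAULT_PALETTE
    missing = [c for c in grid.classes if c not in palette]
    if missing:
        raise ValueError(f"palette missing classes: {missing}")
    rgb = np.asarray([palette[c] for c in grid.classes], dtype=float)
    hits = grid.class_hits
    totals = hits.sum(axis=1, keepdims=True)
    out = np.tile(np.asarray(GREY), (grid.n_neurons, 1))
    occ = totals[:, 0] > 0
    out[occ] = (hits[occ] / totals[occ]) @ rgb
    return out


def render_hitmap(grid: SOMGrid, palette: dict | None = None, ax=None,
                  hex_radius: float = 0.5774):
    """Draw the hexagon-tiled hit map; returns the matplotlib Axes.

    ``hex_radius`` defaults to 1/sqrt(3), giving touching hexagons on the
    unit-pitch layout.  Deterministic given grid and palette.
    """
    from matplotlib import pyplot as plt
    from matplotlib.patches import RegularPolygon

    colors = neuron_colors(grid, palette)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for (x, y), col in zip(grid.coords, colors):
        ax.add_patch(RegularPolygon((x, y), numVertices=6, radius=hex_radius,
                                    orientation=0.0, facecolor=col,
                                    edgecolor="white", linewidth=0.3))
    ax.set_xlim(grid.coords[:, 0].min() - 1, grid.coords[:, 0].max() + 1)
    ax.set_ylim(grid.coords[:, 1].min() - 1, grid.coords[:, 1].max() + 1)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
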