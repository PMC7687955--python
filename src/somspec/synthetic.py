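"""Synthetic Raman dataset generator.

Emulates the statistical structure of a controlled-cortical-impact study:
three injury groups (sham, moderate and severe TBI), six mice per group,
two retinae per mouse, each measured as a 20x20 spectral map on a
605-1715 cm^-1 axis.  Group membership perturbs a fixed set of tissue
bands multiplicatively (severe injury raises 850/1098/1337 cm^-1 and
lowers 1003/1266/1660 cm^-1; moderate injury applies the same pattern
more weakly but with larger mouse-to-mouse heterogeneity).  Each spectrum
additionally carries a smooth random fluorescence-like baseline, additive
Gaussian noise, and maps receive occasional single-channel cosmic-ray
spikes whose coordinates are recorded in the map provenance so that
removal can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import ComponentLibrary, LabeledDataset, SpectralMap, Spectrum

#: Band centers raised / lowered in injured tissue relative to sham (cm^-1).
UP_BANDS = (850.0, 1098.0, 1337.0)
DOWN_BANDS = (1003.0, 1266.0, 1660.0)

#: Cosmic-ray spike amplitude, as a multiple of the map's 95th percentile.
SPIKE_FACTOR = 20.0

EYE_SIDES = ("ipsilateral", "contralateral")


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: a Gaussian or Lorentzian line profile."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Line profile evaluated on ``axis`` with peak value ``amplitude``."""
        d = np.asarray(axis, float) - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * d**2 / self.fwhm**2)
        hw2 = (self.fwhm / 2.0) ** 2
        return self.amplitude * hw2 / (d**2 + hw2)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative band changes and mouse-level heterogeneity of a group.

    ``band_multipliers`` maps band centers to intensity factors; bands not
    listed keep factor 1 (so an empty map is the sham null effect).
    ``heterogeneity`` is the coefficient of variation of per-mouse random
    band multipliers.
    """

    group: str
    band_multipliers: dict = field(default_factory=dict)
    heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")
        if any(m <= 0 for m in self.band_multipliers.values()):
            raise ValueError("band multipliers must be positive")

    def multiplier(self, center: float) -> float:
        return float(self.band_multipliers.get(center, 1.0))


def default_bands() -> list[BandSpec]:
    """Tissue band set: centers from the study's assignment table plus the
    1098 cm^-1 band; the sharp phenylalanine line at 1003 cm^-1 is
    Lorentzian, the broader mixed protein/lipid bands Gaussian."""
    return [
        BandSpec(850.0, 18.0, 0.50),
        BandSpec(1003.0, 8.0, 0.90, shape="lorentzian"),
        BandSpec(1098.0, 20.0, 0.40),
        BandSpec(1266.0, 24.0, 0.70),
        BandSpec(1337.0, 22.0, 0.60),
        BandSpec(1447.0, 20.0, 1.00),
        BandSpec(1660.0, 26.0, 0.90),
    ]


def default_effects() -> list[GroupEffect]:
    """Severe TBI: +-15% band changes, low heterogeneity; moderate TBI:
    +-7% changes but CV 0.10 mouse heterogeneity; sham: null effect."""
    up, down = UP_BANDS, DOWN_BANDS

    def mult(u: float, d: float) -> dict:
        return {**{c: u for c in up}, **{c: d for c in down}}

    return [
        GroupEffect("sham", {}, heterogeneity=0.05),
        GroupEffect("mTBI", mult(1.07, 0.93), heterogeneity=0.10),
        GroupEffect("sTBI", mult(1.15, 0.85), heterogeneity=0.05),
    ]


@dataclass
class SimulationConfig:
    """Full description of a synthetic study.

    Defaults reproduce the retina design: 3 groups x 6 mice x 2 eyes,
    20x20 maps (400 spectra each, 4800 per group, 14,400 total) on a
    605-1715 cm^-1 axis at 1 cm^-1 spacing with 1.5 um grid pitch.
    """

    mice_per_group: int = 6
    eyes_per_mouse: int = 2
    grid_side: int = 20
    axis_start: float = 605.0
    axis_stop: float = 1715.0
    axis_step: float = 1.0
    step_um: float = 1.5
    bands: list = field(default_factory=default_bands)
    effects: list = field(default_factory=default_effects)
    baseline_scale: float = 0.5
    noise_sigma: float = 0.05
    cosmic_ray_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mice_per_group, self.eyes_per_mouse, self.grid_side) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.axis_step <= 0 or self.axis_stop <= self.axis_start:
            raise ValueError("invalid axis specification")
        if self.baseline_scale < 0 or self.noise_sigma < 0 or self.cosmic_ray_rate < 0:
            raise ValueError("scales and rates must be non-negative")
        if not self.effects:
            raise ValueError("at least one group effect is required")
        axis = self.axis()
        for b in self.bands:
            if not (axis[0] <= b.center <= axis[-1]):
                raise ValueError(f"band center {b.center} outside axis range")

    def axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + self.axis_step / 2, self.axis_step)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(e.group for e in self.effects)

    @property
    def n_groups(self) -> int:
        return len(self.effects)

    def effect(self, group: str) -> GroupEffect:
        for e in self.effects:
            if e.group == group:
                return e
        raise ValueError(f"unknown group {group!r}")

    def total_spectra(self) -> int:
        return self.n_groups * self.mice_per_group * self.eyes_per_mouse * self.grid_side**2


def brain_config(**overrides) -> SimulationConfig:
    """Brain-tissue preset: one map per mouse (whole-brain contusion core,
    2400 spectra per group, 7200 total) and a stronger fluorescence
    baseline emulating hemoglobin absorption at the injury site."""
    kw = dict(eyes_per_mouse=1, baseline_scale=2.0)
    kw.update(overrides)
    return SimulationConfig(**kw)


def make_component_spectrum(bands: Sequence[BandSpec], axis: np.ndarray) -> Spectrum:
    """Sum of band profiles on ``axis``; rejects bands centered off-axis."""
    axis = np.asarray(axis, float)
    if axis.ndim != 1 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be 1-D and strictly increasing")
    y = np.zeros_like(axis)
    for b in bands:
        if not (axis[0] <= b.center <= axis[-1]):
            raise ValueError(f"band center {b.center} outside axis range")
        y += b.profile(axis)
    return Spectrum(axis, y)


def draw_mouse_factors(effect: GroupEffect, bands: Sequence[BandSpec],
                       rng: np.random.Generator) -> dict:
    """Per-mouse multiplicative band factors ~ N(1, heterogeneity), floored
    at 0.05 to keep intensities positive."""
    return {
        b.center: float(max(rng.normal(1.0, effect.heterogeneity), 0.05))
        for b in bands
    }


def clean_signal(group: str, mouse_factors: dict, config: SimulationConfig) -> np.ndarray:
    """Noise- and baseline-free spectrum for one mouse of one group."""
    effect = config.effect(group)
    axis = config.axis()
    y = np.zeros_like(axis)
    for b in config.bands:
        y += b.profile(axis) * effect.multiplier(b.center) * mouse_factors.get(b.center, 1.0)
    return y


def _random_baselines(axis: np.ndarray, scale: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Smooth positive random cubic backgrounds, one row per spectrum."""
    if scale == 0:
        return np.zeros((n, axis.size))
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    coef = rng.uniform(-1.0, 1.0, size=(n, 4))
    shapes = coef @ np.vstack([np.ones_like(t), t, t**2, t**3])
    shapes -= shapes.min(axis=1, keepdims=True)
    peak = shapes.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    amp = scale * rng.uniform(0.5, 1.5, size=(n, 1))
    return amp * shapes / peak


def _map_baselines(axis: np.ndarray, scale: float, side: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Baselines for one map (side*side rows, row-major grid order).

    Fluorescence varies slowly over the few-um map extent, so all spectra
    share one random cubic spectral shape; its amplitude varies across
    the grid as a smooth random quadratic field (sd ~5%), emulating focus
    and topography drift rather than point-to-point scatter."""
    n = side * side
    if scale == 0:
        return np.zeros((n, axis.size))
    shape = _random_baselines(axis, 1.0, 1, rng)[0]
    amp = scale * rng.uniform(0.5, 1.5)
    ii, jj = np.divmod(np.arange(n), side)
    u = 2.0 * ii / max(side - 1, 1) - 1.0
    v = 2.0 * jj / max(side - 1, 1) - 1.0
    coef = rng.normal(size=5)
    f = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u**2 + coef[4] * v**2
    sd = float(f.std()) or 1.0
    per = np.clip(amp * (1.0 + 0.05 * f / sd), 0.0, None)
    return per[:, None] * shape


def generate_spectrum(group: str, mouse_factors: dict, config: SimulationConfig,
                      rng: np.random.Generator) -> Spectrum:
    """One noisy spectrum: clean band sum + random baseline + Gaussian noise,
    clipped at zero."""
    axis = config.axis()
    y = clean_signal(group, mouse_factors, config)
    y = y + _random_baselines(axis, config.baseline_scale, 1, rng)[0]
    if config.noise_sigma > 0:
        y = y + rng.normal(0.0, config.noise_sigma, size=axis.size)
    return Spectrum(axis, np.clip(y, 0.0, None))


def generate_map(group: str, mouse: str, eye: str, config: SimulationConfig,
                 rng: np.random.Generator, mouse_factors: dict | None = None) -> SpectralMap:
    """One grid_side x grid_side map for a single tissue sample.

    Cosmic-ray spikes (Poisson count with mean ``cosmic_ray_rate``) are
    injected at random (spectrum, channel) coordinates with amplitude
    ``SPIKE_FACTOR`` times the map's 95th intensity percentile; their
    coordinates and amplitudes are recorded in ``provenance['spikes']``.
    """
    if mouse_factors is None:
        mouse_factors = draw_mouse_factors(config.effect(group), config.bands, rng)
    axis = config.axis()
    side = config.grid_side
    n = side * side
    clean = clean_signal(group, mouse_factors, config)
    intens = np.tile(clean, (n, 1))
    intens += _map_baselines(axis, config.baseline_scale, side, rng)
    if config.noise_sigma > 0:
        intens += rng.normal(0.0, config.noise_sigma, size=intens.shape)
    np.clip(intens, 0.0, None, out=intens)

    spikes: list[tuple[int, int, float]] = []
    n_spikes = int(rng.poisson(config.cosmic_ray_rate)) if config.cosmic_ray_rate > 0 else 0
    if n_spikes:
        ref = float(np.percentile(intens, 95))
        amp = SPIKE_FACTOR * max(ref, 1e-6)
        for _ in range(n_spikes):
            i = int(rng.integers(n))
            ch = int(rng.integers(axis.size))
            intens[i, ch] += amp
            spikes.append((i, ch, amp))

    ii, jj = np.divmod(np.arange(n), side)
    positions = np.column_stack([ii, jj]).astype(float) * config.step_um
    return SpectralMap(
        axis, intens, positions, config.step_um,
        provenance={"group": group, "mouse": mouse, "eye": eye, "spikes": spikes},
    )


def generate_maps(config: SimulationConfig) -> list[SpectralMap]:
    """All maps of the study design, one per (group, mouse, eye).

    Per-mouse band factors are drawn once per mouse and shared by both
    eyes, so mouse-level heterogeneity is a between-animal effect.
    """
    rng = np.random.default_rng(config.seed)
    maps = []
    for effect in config.effects:
        for m in range(config.mice_per_group):
            mouse = f"{effect.group}-m{m + 1}"
            factors = draw_mouse_factors(effect, config.bands, rng)
            for e in range(config.eyes_per_mouse):
                eye = EYE_SIDES[e] if e < len(EYE_SIDES) else f"eye{e + 1}"
                maps.append(generate_map(effect.group, mouse, eye, config, rng, factors))
    return maps


def flatten_maps(maps: Sequence[SpectralMap], classes: tuple[str, ...]) -> LabeledDataset:
    """Stack maps into a flat labelled dataset, one row per spectrum."""
    if not maps:
        raise ValueError("no maps to flatten")
    axis = maps[0].wavenumbers
    intens = np.vstack([m.intensities for m in maps])
    labels, mice, eyes = [], [], []
    for m in maps:
        labels += [m.provenance["group"]] * m.n_spectra
        mice += [m.provenance["mouse"]] * m.n_spectra
        eyes += [m.provenance["eye"]] * m.n_spectra
    return LabeledDataset(axis, intens, labels, mice, eyes, classes)


def generate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Full labelled dataset of the design (cosmic-ray spikes included;
    remove them map-wise via :mod:`somspec.preprocess` before analysis)."""
    return flatten_maps(generate_maps(config), config.groups)


def synthetic_component_library(axis: np.ndarray | None = None) -> ComponentLibrary:
    """Synthetic stand-in component library for spectral unmixing.

    The shipped profiles are *synthetic* idealisations, not measured
    spectra: a cardiolipin-like component dominated by 1266 and
    1660 cm^-1, cholesterol-, sphingomyelin- and cytochrome-c-like
    profiles with distinct band patterns.  Real libraries load through
    :func:`somspec.io.read_component_library`.
    """
    if axis is None:
        axis = np.arange(1100.0, 1801.0, 1.0)
    defs = {
        "cardiolipin": [
            BandSpec(1266.0, 26.0, 1.00),
            BandSpec(1440.0, 22.0, 0.45),
            BandSpec(1660.0, 24.0, 0.95),
        ],
        "cholesterol": [
            BandSpec(1300.0, 20.0, 0.55),
            BandSpec(1440.0, 24.0, 1.00),
            BandSpec(1672.0, 18.0, 0.40),
        ],
        "sphingomyelin": [
            BandSpec(1296.0, 22.0, 0.60),
            BandSpec(1438.0, 20.0, 0.90),
            BandSpec(1635.0, 28.0, 0.30),
        ],
        "cytochrome_c": [
            BandSpec(1315.0, 16.0, 0.80),
            BandSpec(1585.0, 18.0, 1.00),
            BandSpec(1640.0, 20.0, 0.35),
        ],
    }
    intens = np.vstack([make_component_spectrum(b, axis).intensities for b in defs.values()])
    return ComponentLibrary(tuple(defs), axis, intens)
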