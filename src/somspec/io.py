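"""Plain-text input/output and axis resampling.

Formats
-------
* Spectrum: two numeric columns (wavenumber, intensity), whitespace- or
  comma-delimited, ``#`` comment lines allowed.  Instrument exports with a
  descending axis are reordered ascending on read.
* Dataset: a directory of spectrum files plus ``manifest.csv`` with
  columns ``file, group, mouse, eye, x_um, y_um`` (one row per spectrum)
  and, when present, ``spikes.csv`` logging injected cosmic-ray spikes.
* Component library: one delimited table, first column wavenumber, one
  named column per component.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import (
    AXIS_TOL,
    ComponentLibrary,
    LabeledDataset,
    SpectralMap,
    Spectrum,
    axes_match,
)


def read_spectrum(path: str) -> Spectrum:
    """Read a two-column spectrum file; axis returned ascending."""
    wn, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: non-numeric or malformed row at line {lineno}")
            wn.append(x)
            inten.append(y)
    if len(wn) < 2:
        raise ValueError(f"{path}: a spectrum needs at least 2 points")
    wn_arr = np.asarray(wn)
    int_arr = np.asarray(inten)
    order = np.argsort(wn_arr, kind="stable")
    return Spectrum(wn_arr[order], int_arr[order])


def write_spectrum(spectrum: Spectrum, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1 intensity\n")
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{x:.10g} {y:.10g}\n")


def resample(spectrum: Spectrum, target_axis: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``target_axis`` (no extrapolation)."""
    target = np.asarray(target_axis, float)
    src = spectrum.wavenumbers
    if target.min() < src[0] - AXIS_TOL or target.max() > src[-1] + AXIS_TOL:
        raise ValueError(
            f"target axis [{target.min()}, {target.max()}] extends beyond "
            f"source range [{src[0]}, {src[-1]}]"
        )
    return Spectrum(target, np.interp(target, src, spectrum.intensities))


def _read_manifest(manifest_path: str) -> tuple[pd.DataFrame, str]:
    base = os.path.dirname(os.path.abspath(manifest_path))
    df = pd.read_csv(manifest_path)
    required = {"file", "group", "mouse", "eye", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df, base


def _load_rows(df: pd.DataFrame, base: str) -> tuple[np.ndarray, np.ndarray]:
    spectra = []
    axis = None
    ref_file = None
    for _, row in df.iterrows():
        path = os.path.join(base, row["file"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest references missing file: {row['file']}")
        s = read_spectrum(path)
        if axis is None:
            axis, ref_file = s.wavenumbers, row["file"]
        elif not axes_match(axis, s.wavenumbers):
            raise ValueError(
                f"axis of {row['file']} does not match axis of {ref_file}"
            )
        spectra.append(s.intensities)
    if axis is None:
        raise ValueError("manifest contains no spectra")
    return axis, np.vstack(spectra)


def read_map(manifest_path: str) -> SpectralMap:
    """Load a single spectral map from a manifest of spectrum files."""
    df, base = _read_manifest(manifest_path)
    axis, intens = _load_rows(df, base)
    positions = df[["x_um", "y_um"]].to_numpy(float)
    diffs = np.unique(np.abs(np.diff(np.unique(positions))))
    step = float(diffs[diffs > 0][0]) if np.any(diffs > 0) else 1.0
    prov = {
        "group": df["group"].iloc[0],
        "mouse": df["mouse"].iloc[0],
        "eye": df["eye"].iloc[0],
    }
    return SpectralMap(axis, intens, positions, step, provenance=prov)


def read_maps(manifest_path: str) -> list[SpectralMap]:
    """Load every map in a manifest, grouped by (group, mouse, eye)."""
    df, base = _read_manifest(manifest_path)
    maps = []
    for (group, mouse, eye), sub in df.groupby(["group", "mouse", "eye"], sort=False):
        axis, intens = _load_rows(sub, base)
        positions = sub[["x_um", "y_um"]].to_numpy(float)
        diffs = np.unique(np.abs(np.diff(np.unique(positions))))
        step = float(diffs[diffs > 0][0]) if np.any(diffs > 0) else 1.0
        maps.append(SpectralMap(axis, intens, positions, step,
                                provenance={"group": group, "mouse": mouse, "eye": eye}))
    return maps


def read_dataset(manifest_path: str,
                 classes: Sequence[str] | None = None) -> LabeledDataset:
    """Load a labelled dataset (all manifest rows, any number of maps)."""
    df, base = _read_manifest(manifest_path)
    axis, intens = _load_rows(df, base)
    if classes is None:
        classes = tuple(dict.fromkeys(df["group"]))
    return LabeledDataset(
        axis, intens, df["group"].to_numpy(object),
        df["mouse"].to_numpy(object), df["eye"].to_numpy(object), tuple(classes),
    )


def write_dataset(maps: Sequence[SpectralMap], out_dir: str) -> str:
    """Write maps as per-spectrum files + manifest.csv (+ spikes.csv).

    Returns the manifest path.  Map identity (group/mouse/eye) is read
    from each map's provenance.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows, spike_rows = [], []
    counter = 0
    for m in maps:
        prov = m.provenance
        tag = f"{prov.get('group', 'g')}_{prov.get('mouse', 'm')}_{prov.get('eye', 'e')}"
        for i in range(m.n_spectra):
            fname = f"{tag}_{i:04d}.txt"
            write_spectrum(m.spectrum(i), os.path.join(out_dir, fname))
            rows.append(
                dict(file=fname, group=prov.get("group", ""), mouse=prov.get("mouse", ""),
                     eye=prov.get("eye", ""), x_um=m.positions[i, 0], y_um=m.positions[i, 1])
            )
            counter += 1
        for i, ch, amp in prov.get("spikes", []):
            spike_rows.append(dict(map=tag, spectrum_index=i, channel=ch, amplitude=amp))
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame(spike_rows, columns=["map", "spectrum_index", "channel", "amplitude"]).to_csv(
        os.path.join(out_dir, "spikes.csv"), index=False
    )
    return manifest


def read_component_library(path: str) -> ComponentLibrary:
    """Read a delimited library table (wavenumber column + one per component)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: library table needs a wavenumber column and >=1 component")
    axis = df.iloc[:, 0].to_numpy(float)
    order = np.argsort(axis, kind="stable")
    names = tuple(df.columns[1:])
    intens = df.iloc[:, 1:].to_numpy(float).T[:, order]
    return ComponentLibrary(names, axis[order], intens)


def write_component_library(library: ComponentLibrary, path: str) -> None:
    df = pd.DataFrame({"wavenumber": library.wavenumbers})
    for i, name in enumerate(library.names):
        df[name] = library.intensities[i]
    df.to_csv(path, index=False)
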