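"""Non-negative least-squares spectral unmixing and group comparison.

Average tissue spectra are decomposed as non-negative combinations of a
component library (lipids, cytochrome c, ...) over the fingerprint
window 1200-1714 cm^-1 resampled to 1 cm^-1 (515 points).  Fitted
coefficients are proportional to component contributions and are
compared across injury groups with a one-way ANOVA plus Welch t-tests of
each injury group against the sham reference (raw and Holm-adjusted).

Model/Results entry point: :class:`SpectralUnmixing` -> ``fit()`` ->
:class:`UnmixingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls as _lawson_hanson_nnls
from statsmodels.stats.multitest import multipletests

from .datasets import ComponentLibrary, Spectrum
from .io import resample

#: Default fingerprint fitting window (cm^-1) and increment.
DEFAULT_WINDOW = (1200.0, 1714.0)
DEFAULT_STEP = 1.0


def default_axis(window: tuple[float, float] = DEFAULT_WINDOW,
                 step: float = DEFAULT_STEP) -> np.ndarray:
    lo, hi = window
    return np.arange(lo, hi + step / 2, step)


def build_design(library: ComponentLibrary,
                 target_axis: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Resample every library component onto ``target_axis``.

    Returns (target_axis, design) with design of shape (n_points,
    n_components), one column per component in library order.  Rejects
    components that do not span the target range, naming them.
    """
    axis = default_axis() if target_axis is None else np.asarray(target_axis, float)
    cols = []
    for k, name in enumerate(library.names):
        src = library.wavenumbers
        if axis[0] < src[0] - 1e-9 or axis[-1] > src[-1] + 1e-9:
            raise ValueError(f"component {name!r} does not cover the target range")
        cols.append(resample(library.component(name), axis).intensities)
    return axis, np.column_stack(cols)


@dataclass
class UnmixingResult:
    """NNLS fit of one sample: non-negative coefficients + residual norm."""

    sample_id: str
    group: str
    components: tuple[str, ...]
    coefficients: np.ndarray
    residual: float

    def coefficient(self, component: str) -> float:
        return float(self.coefficients[self.components.index(component)])


def nnls_fit(spectrum: Spectrum | np.ndarray, design: np.ndarray,
             components: Sequence[str] | None = None,
             sample_id: str = "", group: str = "") -> UnmixingResult:
    """Solve min ||y - D c||_2 s.t. c >= 0 (Lawson-Hanson active set)."""
    y = spectrum.intensities if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    D = np.asarray(design, float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(D))):
        raise ValueError("non-finite values in spectrum or design")
    if y.shape != (D.shape[0],):
        raise ValueError("spectrum length does not match design rows")
    coef, resid = _lawson_hanson_nnls(D, y)
    names = tuple(components) if components is not None else tuple(
        f"c{k}" for k in range(D.shape[1]))
    return UnmixingResult(sample_id, group, names, coef, float(resid))


def fit_dataset(samples: Sequence[tuple[str, str, Spectrum]],
                library: ComponentLibrary,
                target_axis: np.ndarray | None = None) -> list[UnmixingResult]:
    """NNLS fit per (sample_id, group, average spectrum) triple.

    Each sample spectrum is resampled onto the fitting axis before the
    fit; results are returned in input order.
    """
    axis, D = build_design(library, target_axis)
    out = []
    for sample_id, group, spec in samples:
        y = resample(spec, axis)
        out.append(nnls_fit(y, D, library.names, sample_id=sample_id, group=group))
    return out


def results_to_frame(results: Sequence[UnmixingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample": r.sample_id, "group": r.group, "residual": r.residual}
        row.update(dict(zip(r.components, r.coefficients)))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """One-way ANOVA across groups for one component, plus pairwise Welch
    t-tests of each non-reference group against the reference."""

    component: str
    groups: tuple[str, ...]
    means: dict
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)   # group, p_raw, p_holm
    message: str | None = None

    def summary(self) -> str:
        lines = [f"One-way ANOVA for {self.component!r}"]
        if self.message:
            lines.append(f"  {self.message}")
        else:
            lines.append(f"  F = {self.f_statistic:.4g}, p = {self.p_value:.4g}")
        for g, mu in self.means.items():
            lines.append(f"  mean[{g}] = {mu:.6g}")
        if len(self.pairwise):
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def compare_groups(results: Sequence[UnmixingResult] | pd.DataFrame,
                   component: str, reference: str = "sham") -> GroupComparison:
    """Compare one component's coefficients across groups.

    ``results`` may be UnmixingResult objects or a data frame with
    ``group`` and component columns.  Degenerate input (all observations
    identical) reports F as undefined with a message instead of a value.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if component not in df.columns:
        raise ValueError(f"unknown component {component!r}")
    groups = tuple(dict.fromkeys(df["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    values = {g: df.loc[df["group"] == g, component].to_numpy(float) for g in groups}
    if any(v.size < 2 for v in values.values()):
        raise ValueError("need at least two samples per group")
    means = {g: float(v.mean()) for g, v in values.items()}
    allv = np.concatenate(list(values.values()))

    pair_rows = []
    if np.ptp(allv) == 0.0:
        comparison = GroupComparison(
            component, groups, means, float("nan"), float("nan"),
            pd.DataFrame(columns=["group", "p_raw", "p_holm"]),
            message="F undefined: all coefficient values identical (zero variance)",
        )
        return comparison
    # two-pass between/within mean squares (scipy's f_oneway cancels
    # catastrophically when within-group variance is ~0)
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in values.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values.values())
    df_between = len(groups) - 1
    df_within = allv.size - len(groups)
    if ss_within == 0.0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p_val = float(stats.f.sf(f_stat, df_between, df_within))
    others = [g for g in groups if g != reference]
    if reference in values and others:
        raw = [stats.ttest_ind(values[g], values[reference], equal_var=False).pvalue
               for g in others]
        holm = multipletests(raw, method="holm")[1]
        pair_rows = [dict(group=g, p_raw=float(r), p_holm=float(h))
                     for g, r, h in zip(others, raw, holm)]
    return GroupComparison(component, groups, means, float(f_stat), float(p_val),
                           pd.DataFrame(pair_rows, columns=["group", "p_raw", "p_holm"]))


class SpectralUnmixing:
    """Spectral unmixing model over a sample collection.

    Parameters
    ----------
    samples : sequence of (sample_id, group, Spectrum)
        One average spectrum per tissue sample.
    library : ComponentLibrary
    window, step : fitting range in cm^-1 (default 1200-1714, step 1).
    """

    def __init__(self, samples: Sequence[tuple[str, str, Spectrum]],
                 library: ComponentLibrary,
                 window: tuple[float, float] = DEFAULT_WINDOW,
                 step: float = DEFAULT_STEP):
        if not samples:
            raise ValueError("no samples to fit")
        self.samples = list(samples)
        self.library = library
        self.axis = default_axis(window, step)

    def fit(self) -> "UnmixingResults":
        results = fit_dataset(self.samples, self.library, self.axis)
        return UnmixingResults(self, results)


class UnmixingResults:
    """Fitted coefficients for all samples, with group comparisons."""

    def __init__(self, model: SpectralUnmixing, results: list[UnmixingResult]):
        self.model = model
        self.results = results
        self.coefficients = results_to_frame(results)

    def compare(self, component: str, reference: str = "sham") -> GroupComparison:
        return compare_groups(self.results, component, reference=reference)

    def summary(self) -> str:
        comps = self.model.library.names
        lines = [
            f"NNLS unmixing of {len(self.results)} samples against "
            f"{len(comps)} components on {self.model.axis[0]:.0f}-"
            f"{self.model.axis[-1]:.0f} cm^-1 ({self.model.axis.size} points)",
            self.coefficients.round(6).to_string(index=False),
        ]
        return "\n".join(lines)
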