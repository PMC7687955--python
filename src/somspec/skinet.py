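"""Supervised layer over the self-organizing map.

After unsupervised training, each training spectrum is assigned to its
best-matching neuron and per-neuron class hit counts are accumulated.
The hit counts drive three things:

* classification -- a new spectrum takes the majority class of its BMU
  (falling back to the nearest neuron with hits when the BMU was never
  activated in training);
* the discriminant index (SOMDI) -- a per-class spectrum-like vector,
  the hit-share-contrast-weighted sum of neuron weights, whose positive
  entries mark wavenumbers elevated in that class relative to the rest;
* evaluation -- stratified k-fold cross-validation and repeated
  re-initialization test evaluation summarised as a percentage
  confusion matrix.

The statsmodels-style entry point is :class:`SupervisedSOM` (model) /
:class:`SupervisedSOMResults` (fit results); the module-level functions
are the underlying operations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset, Spectrum
from .som import SOMConfig, SOMGrid, bmu_indices, init_grid, quantization_error, train


# ---------------------------------------------------------------------------
# hit accumulation, SOMDI, classification


def accumulate_hits(grid: SOMGrid, data: LabeledDataset) -> SOMGrid:
    """Return a grid whose ``class_hits[i, k]`` counts class-k training
    spectra with BMU i (total hits == number of spectra)."""
    classes = data.classes
    unknown = set(data.labels) - set(classes)
    if unknown:
        raise ValueError(f"labels outside class set: {sorted(unknown)}")
    hits = np.zeros((grid.n_neurons, len(classes)), dtype=float)
    bmus = bmu_indices(grid, data.intensities)
    kidx = {c: k for k, c in enumerate(classes)}
    for b, lab in zip(bmus, data.labels):
        hits[b, kidx[lab]] += 1
    out = grid.copy()
    out.class_hits = hits
    out.classes = tuple(classes)
    return out


@dataclass
class SOMDIResult:
    """Per-class discriminant spectra on the input wavenumber axis."""

    classes: tuple[str, ...]
    wavenumbers: np.ndarray | None
    vectors: np.ndarray               # (n_classes, n_points)

    def vector(self, cls: str) -> np.ndarray:
        return self.vectors[self.classes.index(cls)]

    def value_at(self, cls: str, wavenumber: float) -> float:
        """Discriminant value at the axis point nearest ``wavenumber``."""
        if self.wavenumbers is None:
            raise ValueError("grid carries no wavenumber axis")
        j = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        return float(self.vector(cls)[j])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors.T, columns=list(self.classes))
        if self.wavenumbers is not None:
            df.insert(0, "wavenumber", self.wavenumbers)
        return df


def somdi(grid: SOMGrid) -> SOMDIResult:
    """Discriminant index from hit shares.

    For class k, neuron i's activation share is m[i, k] = hits[i, k] /
    sum_j hits[j, k]; the class-k discriminant is the contrast-weighted
    sum over neurons sum_i (m[i, k] - mean_{k' != k} m[i, k']) * w_i.
    Rejects classes that received no hits.
    """
    if grid.class_hits is None or grid.classes is None:
        raise ValueError("class hits not populated; run accumulate_hits first")
    hits = grid.class_hits
    totals = hits.sum(axis=0)
    for k, cls in enumerate(grid.classes):
        if totals[k] == 0:
            raise ValueError(f"class {cls!r} has zero hits")
    m = hits / totals
    n_cls = len(grid.classes)
    vectors = np.empty((n_cls, grid.weights.shape[1]))
    for k in range(n_cls):
        others = [j for j in range(n_cls) if j != k]
        contrast = m[:, k] - m[:, others].mean(axis=1)
        vectors[k] = contrast @ grid.weights
    return SOMDIResult(grid.classes, grid.wavenumbers, vectors)


def neuron_labels(grid: SOMGrid) -> np.ndarray:
    """Class index predicted at each neuron.

    Neurons with hits take the argmax class (ties -> first class in the
    declared order).  Zero-hit neurons inherit the label of the nearest
    neuron with hits (hex-layout distance, ties -> lowest neuron index).
    Rejects grids in which no neuron has hits.
    """
    if grid.class_hits is None:
        raise ValueError("class hits not populated; run accumulate_hits first")
    hits = grid.class_hits
    occupied = np.flatnonzero(hits.sum(axis=1) > 0)
    if occupied.size == 0:
        raise ValueError("no neuron has any hits")
    labels = np.empty(grid.n_neurons, dtype=int)
    D2 = grid.squared_distances()
    for i in range(grid.n_neurons):
        if hits[i].sum() > 0:
            labels[i] = int(np.argmax(hits[i]))
        else:
            j = occupied[int(np.argmin(D2[i, occupied]))]   # stable: lowest index on ties
            labels[i] = int(np.argmax(hits[j]))
    return labels


def classify(grid: SOMGrid, spectrum: Spectrum | np.ndarray) -> str:
    """Predicted class label for one spectrum."""
    x = spectrum.intensities if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    return predict(grid, x[None, :])[0]


def predict(grid: SOMGrid, data: LabeledDataset | np.ndarray) -> np.ndarray:
    """Predicted class labels for a matrix/dataset of spectra."""
    if grid.classes is None:
        raise ValueError("class hits not populated; run accumulate_hits first")
    X = data.intensities if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    labels = neuron_labels(grid)
    cls = np.asarray(grid.classes, dtype=object)
    return cls[labels[bmu_indices(grid, X)]]


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ConfusionMatrix:
    """Row-normalised percentage confusion (rows: actual, cols: predicted),
    averaged over repeats, with the per-repeat sd of each diagonal entry."""

    classes: tuple[str, ...]
    matrix: np.ndarray                # (n_classes, n_classes), percent
    diagonal_sd: np.ndarray           # (n_classes,)
    n_repeats: int

    def __post_init__(self) -> None:
        rows = self.matrix.sum(axis=1)
        if np.any(np.abs(rows - 100.0) > 0.1):
            raise ValueError("confusion rows must sum to 100%")

    def accuracy(self, cls: str) -> float:
        k = self.classes.index(cls)
        return float(self.matrix[k, k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.classes),
                            columns=list(self.classes))

    def summary(self) -> str:
        lines = [f"Confusion matrix (% of actual class, mean of "
                 f"{self.n_repeats} initializations)", str(self.to_frame().round(1))]
        sd = ", ".join(f"{c}: {s:.1f}" for c, s in zip(self.classes, self.diagonal_sd))
        lines.append(f"diagonal sd across repeats -- {sd}")
        return "\n".join(lines)


def _fit_once(data: LabeledDataset, config: SOMConfig) -> tuple[SOMGrid, np.ndarray]:
    grid = init_grid(config, data)
    trained, qe = train(grid, data, config)
    return accumulate_hits(trained, data), qe


def _confusion_counts(actual: np.ndarray, predicted: np.ndarray,
                      classes: tuple[str, ...]) -> np.ndarray:
    kidx = {c: k for k, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)))
    for a, p in zip(actual, predicted):
        M[kidx[a], kidx[p]] += 1
    return M


def evaluate(train_data: LabeledDataset, test_data: LabeledDataset,
             config: SOMConfig, repeats: int = 10) -> ConfusionMatrix:
    """Repeated-initialization test evaluation.

    The SOM is re-initialized and retrained ``repeats`` times (seeds
    config.seed + r), each time classifying the held-out test set; the
    row-normalised percentage confusions are averaged and the per-repeat
    sd of the diagonal recorded.
    """
    classes = train_data.classes
    missing = [c for c in classes if c not in set(test_data.labels)]
    if missing:
        raise ValueError(f"classes absent from test data: {missing}")
    mats = []
    for r in range(repeats):
        grid, _ = _fit_once(train_data, dc_replace(config, seed=config.seed + r))
        preds = predict(grid, test_data)
        counts = _confusion_counts(test_data.labels, preds, classes)
        mats.append(100.0 * counts / counts.sum(axis=1, keepdims=True))
    mats = np.asarray(mats)
    return ConfusionMatrix(classes, mats.mean(axis=0),
                           mats.diagonal(axis1=1, axis2=2).std(axis=0), repeats)


@dataclass
class CVResult:
    accuracies: np.ndarray
    predictions: np.ndarray           # aligned with the input dataset
    fold_ids: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std())


def cross_validate(dataset: LabeledDataset, config: SOMConfig,
                   k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation (one SOM per fold, seeded
    config.seed + fold); every spectrum is predicted exactly once."""
    counts = dataset.class_counts()
    too_small = [c for c, n in counts.items() if n < k]
    if too_small:
        raise ValueError(f"groups with fewer than {k} spectra: {too_small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = np.asarray(dataset.labels, dtype=str)
    preds = np.empty(dataset.n_spectra, dtype=object)
    fold_ids = np.full(dataset.n_spectra, -1, dtype=int)
    accs = []
    for f, (tr, te) in enumerate(skf.split(dataset.intensities, y)):
        grid, _ = _fit_once(dataset.subset(tr), dc_replace(config, seed=config.seed + f))
        p = predict(grid, dataset.subset(te))
        preds[te] = p
        fold_ids[te] = f
        accs.append(float(np.mean(p == dataset.labels[te])))
    return CVResult(np.asarray(accs), preds, fold_ids)


# ---------------------------------------------------------------------------
# model / results objects


class SupervisedSOM:
    """Supervised self-organizing map classifier.

    Parameters
    ----------
    data : LabeledDataset
        Training spectra (preprocessed: baseline-subtracted and, for the
        cosine metric, conventionally unit-normalised).
    config : SOMConfig, optional
        Grid size, schedule and seed; defaults to the study settings.
    """

    def __init__(self, data: LabeledDataset, config: SOMConfig | None = None):
        if data.n_spectra == 0:
            raise ValueError("empty training data")
        self.data = data
        self.config = config or SOMConfig()

    def fit(self, seed: int | None = None) -> "SupervisedSOMResults":
        cfg = self.config if seed is None else dc_replace(self.config, seed=seed)
        grid, qe = _fit_once(self.data, cfg)
        return SupervisedSOMResults(self, grid, qe, cfg)

    def evaluate(self, test_data: LabeledDataset, repeats: int = 10) -> ConfusionMatrix:
        return evaluate(self.data, test_data, self.config, repeats=repeats)

    def cross_validate(self, k: int = 10, seed: int = 0) -> CVResult:
        return cross_validate(self.data, self.config, k=k, seed=seed)


class SupervisedSOMResults:
    """Fitted supervised SOM: trained grid with class hits plus diagnostics."""

    def __init__(self, model: SupervisedSOM, grid: SOMGrid,
                 qe_trace: np.ndarray, config: SOMConfig):
        self.model = model
        self.grid = grid
        self.qe_trace = qe_trace
        self.config = config

    def predict(self, data: LabeledDataset | np.ndarray) -> np.ndarray:
        return predict(self.grid, data)

    def classify(self, spectrum: Spectrum | np.ndarray) -> str:
        return classify(self.grid, spectrum)

    def somdi(self) -> SOMDIResult:
        return somdi(self.grid)

    def score(self, data: LabeledDataset) -> float:
        return float(np.mean(self.predict(data) == data.labels))

    def quantization_error(self, data: LabeledDataset | None = None) -> float:
        return quantization_error(self.grid, data if data is not None else self.model.data)

    def summary(self) -> str:
        cfg = self.config
        n = self.model.data.n_spectra
        lines = [
            "Supervised SOM results",
            f"  grid: {cfg.rows} x {cfg.cols} neurons (hexagonal), cosine BMU metric",
            f"  training: {cfg.total_steps(n)} presentations over {n} spectra "
            f"(lr {cfg.initial_learning_rate} -> {cfg.final_learning_rate}, "
            f"sigma {cfg.initial_neighborhood:.2f} -> {cfg.final_neighborhood}, seed {cfg.seed})",
            f"  final quantization error: {self.qe_trace[-1]:.6f}",
        ]
        if self.grid.class_hits is not None:
            totals = self.grid.class_hits.sum(axis=0).astype(int)
            hits = ", ".join(f"{c}: {t}" for c, t in zip(self.grid.classes, totals))
            lines.append(f"  training hits -- {hits}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model persistence


def save_model(grid: SOMGrid, path: str) -> None:
    """Serialize a grid (weights, layout, axis, class hits) to ``.npz``."""
    payload = dict(weights=grid.weights, coords=grid.coords,
                   rows=grid.rows, cols=grid.cols)
    if grid.wavenumbers is not None:
        payload["wavenumbers"] = grid.wavenumbers
    if grid.class_hits is not None:
        payload["class_hits"] = grid.class_hits
        payload["classes"] = np.asarray(grid.classes, dtype=object)
    np.savez(path, **payload)


def load_model(path: str) -> SOMGrid:
    with np.load(path, allow_pickle=True) as z:
        return SOMGrid(
            z["weights"], z["coords"], int(z["rows"]), int(z["cols"]),
            z["wavenumbers"] if "wavenumbers" in z else None,
            z["class_hits"] if "class_hits" in z else None,
            tuple(z["classes"]) if "classes" in z else None,
        )
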