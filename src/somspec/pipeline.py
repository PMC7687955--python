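"""End-to-end study pipelines: simulate -> clean -> train -> evaluate.

These helpers chain the package's stages exactly as the analysis
prescribes (map-wise cosmic-ray removal, lower-envelope baseline
subtraction, unit-norm scaling, stratified 80/20 split, supervised SOM)
and back the worked examples and the acceptance script.  The reduced
study design (3 mice per group, 10x10 maps, a 10x10 neuron grid) keeps a
full run to seconds while preserving the design's group structure.
"""

from __future__ import annotations

import numpy as np

from .preprocess import PreprocessConfig, average_map, preprocess_maps, split_dataset
from .skinet import ConfusionMatrix, SOMDIResult, SupervisedSOM, evaluate
from .som import SOMConfig
from .synthetic import (
    SimulationConfig,
    brain_config,
    default_effects,
    flatten_maps,
    generate_maps,
    synthetic_component_library,
)
from .unmixing import SpectralUnmixing, UnmixingResults


def reduced_retina_config(seed: int = 0, mice_per_group: int = 3,
                          grid_side: int = 10, groups=None) -> SimulationConfig:
    """Scaled-down retina design: 3 groups x 3 mice x 2 eyes, 10x10 maps."""
    effects = default_effects()
    if groups is not None:
        effects = [e for e in effects if e.group in groups]
    return SimulationConfig(mice_per_group=mice_per_group, eyes_per_mouse=2,
                            grid_side=grid_side, effects=effects, seed=seed)


def reduced_som_config(seed: int = 0) -> SOMConfig:
    """10x10 neuron grid with the study's schedule (5 epochs, lr 0.2)."""
    return SOMConfig(rows=10, cols=10, epochs=5, seed=seed)


def prepare_dataset(config: SimulationConfig,
                    pre: PreprocessConfig | None = None):
    """Simulate maps, repair spikes, subtract baselines, flatten and
    unit-normalize.  Returns (dataset, repairs per map)."""
    pre = pre or PreprocessConfig()
    maps = generate_maps(config)
    cleaned, repairs = preprocess_maps(maps, pre, baseline=True)
    ds = flatten_maps(cleaned, config.groups)
    nrm = np.linalg.norm(ds.intensities, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return ds.replace_intensities(ds.intensities / nrm), repairs


def run_classification(config: SimulationConfig, som_config: SOMConfig,
                       repeats: int = 1,
                       pre: PreprocessConfig | None = None) -> ConfusionMatrix:
    """Full classification experiment on one simulated study."""
    ds, _ = prepare_dataset(config, pre)
    train_ds, test_ds = split_dataset(ds, pre or PreprocessConfig(
        split_seed=config.seed))
    return evaluate(train_ds, test_ds, som_config, repeats=repeats)


def mean_confusion(seeds, mice_per_group: int = 3,
                   grid_side: int = 10) -> ConfusionMatrix:
    """Average the confusion matrix over independent simulated studies
    (fresh data and SOM initialization per seed)."""
    mats, sds = [], []
    classes = None
    for s in seeds:
        cm = run_classification(
            reduced_retina_config(seed=int(s), mice_per_group=mice_per_group,
                                  grid_side=grid_side),
            reduced_som_config(seed=int(s)),
            pre=PreprocessConfig(split_seed=int(s)))
        mats.append(cm.matrix)
        classes = cm.classes
    mats = np.asarray(mats)
    return ConfusionMatrix(classes, mats.mean(axis=0),
                           mats.diagonal(axis1=1, axis2=2).std(axis=0),
                           len(mats))


def run_somdi(seed: int = 0, mice_per_group: int = 6,
              grid_side: int = 10) -> SOMDIResult:
    """Two-class (sham vs severe injury) discriminant extraction.

    Keeps the study's 6 mice per group: per-mouse factors and per-map
    baseline residuals average out across animals, which the band-level
    discriminant signs rely on."""
    config = reduced_retina_config(seed=seed, mice_per_group=mice_per_group,
                                   grid_side=grid_side,
                                   groups=("sham", "sTBI"))
    ds, _ = prepare_dataset(config)
    res = SupervisedSOM(ds, reduced_som_config(seed=seed)).fit()
    return res.somdi()


def run_brain_unmixing(seed: int = 0, mice_per_group: int = 6,
                       grid_side: int = 10) -> UnmixingResults:
    """Brain-tissue pipeline: one map per mouse, clean, average to one
    spectrum per sample, NNLS-fit the synthetic component library over
    the 1200-1714 cm^-1 fingerprint window."""
    config = brain_config(mice_per_group=mice_per_group, grid_side=grid_side,
                          seed=seed)
    maps = generate_maps(config)
    cleaned, _ = preprocess_maps(maps, baseline=True)
    samples = [(m.provenance["mouse"], m.provenance["group"], average_map(m))
               for m in cleaned]
    return SpectralUnmixing(samples, synthetic_component_library()).fit()
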