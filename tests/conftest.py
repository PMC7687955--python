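import numpy as np
import pytest

from somspec import SimulationConfig, SOMConfig
from somspec.synthetic import GroupEffect, default_effects, flatten_maps, generate_maps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Reduced study design used throughout the unit tests: 3 groups x
    2 mice x 1 eye, 5x5 maps on a coarsened axis."""
    return SimulationConfig(mice_per_group=2, eyes_per_mouse=1, grid_side=5,
                            axis_step=2.0, seed=7)


@pytest.fixture
def small_dataset(small_sim):
    from somspec import generate_dataset

    return generate_dataset(small_sim)


def separable_config(seed=3, factor=10.0, **kw):
    """Trivially separable design: group effects amplified ``factor``-fold
    beyond their deviation from 1, no noise, no baseline, no spikes."""
    effects = []
    for e in default_effects():
        mult = {c: 1.0 + factor * (m - 1.0) for c, m in e.band_multipliers.items()}
        mult = {c: max(m, 0.05) for c, m in mult.items()}
        effects.append(GroupEffect(e.group, mult, heterogeneity=0.0))
    base = dict(mice_per_group=2, eyes_per_mouse=1, grid_side=4, axis_step=2.0,
                baseline_scale=0.0, noise_sigma=0.0, cosmic_ray_rate=0.0,
                effects=effects, seed=seed)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture
def separable_dataset():
    cfg = separable_config()
    ds = flatten_maps(generate_maps(cfg), cfg.groups)
    nrm = np.linalg.norm(ds.intensities, axis=1, keepdims=True)
    return ds.replace_intensities(ds.intensities / nrm)


@pytest.fixture
def small_som_config():
    return SOMConfig(rows=4, cols=4, epochs=3, seed=2)
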