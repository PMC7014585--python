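import numpy as np
import pandas as pd
import pytest

from vegspec.spectra import SpectralDataset, Spectrum, WavelengthGrid
from vegspec.synthetic import (
    Archetype,
    ArchetypeParams,
    SyntheticConfig,
    default_archetypes,
    generate_scene,
)


@pytest.fixture
def uniform_grid():
    return WavelengthGrid(np.arange(400.0, 2501.0, 10.0))


@pytest.fixture
def fine_grid():
    return WavelengthGrid(np.arange(400.0, 801.0, 2.0))


@pytest.fixture
def grass_spectrum(uniform_grid):
    from vegspec.synthetic import spectrum_from_params
    import dataclasses
    p = ArchetypeParams()
    r = spectrum_from_params(uniform_grid.wavelengths,
                             **{f.name: getattr(p, f.name)
                                for f in dataclasses.fields(p)})
    return Spectrum(uniform_grid, r)


def make_dataset(grid, reflectance, labels, patch_ids=None, x=None, y=None):
    """Assemble a SpectralDataset from arrays with minimal metadata."""
    n = reflectance.shape[0]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "patch_id": patch_ids if patch_ids is not None else ["p0"] * n,
        "type_id": list(labels),
        "x": x if x is not None else np.arange(n, dtype=float),
        "y": y if y is not None else np.zeros(n),
        "label_default": list(labels),
    })
    return SpectralDataset(grid, reflectance, meta)


@pytest.fixture
def small_scene_config():
    """A compact scene: 4 communities / 6 finest categories, 101 bands."""
    return SyntheticConfig(
        archetypes=default_archetypes(4, 6),
        n_bands=101,
        wide_patches_per_category=2,
        narrow_patches_per_category=2,
    )


@pytest.fixture
def small_scene(small_scene_config):
    return generate_scene(small_scene_config, seed=7)
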