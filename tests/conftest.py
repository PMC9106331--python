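"""Shared fixtures: small synthetic colonies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pgcolony.linking import LinkParams
from pgcolony.synthetic import ColonySpec, generate_colony


@pytest.fixture(scope="session")
def small_spec() -> ColonySpec:
    """A quick 150 um colony (~120 cells, 8 slices) for pipeline tests."""
    return ColonySpec(diameter=150.0, n_cells=120, n_slices=8, pixel_size=1.0, seed=11)


@pytest.fixture(scope="session")
def small_colony(small_spec):
    return generate_colony(small_spec)


@pytest.fixture(scope="session")
def clean_colony():
    """A noise-free colony: measured intensities equal planted ones."""
    spec = ColonySpec(
        diameter=150.0, n_cells=100, n_slices=8, pixel_size=1.0, noise_sd=0.0,
        background_level=0.0, seed=7,
    )
    return generate_colony(spec)


@pytest.fixture(scope="session")
def link_params(small_spec) -> LinkParams:
    return LinkParams.from_geometry(
        nucleus_diameter_um=2 * small_spec.nucleus_radius,
        z_spacing_um=small_spec.z_spacing,
        pixel_size_um=small_spec.pixel_size,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
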