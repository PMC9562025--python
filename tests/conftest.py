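import numpy as np
import pytest

import tntdetect as td


@pytest.fixture(scope="session")
def small_phantom():
    """A 256x256 phantom with a handful of cells and TNTs, fixed seed."""
    spec = td.PhantomSpec(
        image_height_px=256, image_width_px=256, n_cells=6,
        tnt_probability_per_cell_pair=0.5, noise_sd=0.02, seed=3)
    image, truth = td.generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def tiled_phantom():
    """A phantom with 2x2 tile shadows; tiles are large relative to cells,
    matching the stitched-acquisition geometry."""
    spec = td.PhantomSpec(
        image_height_px=384, image_width_px=384, n_cells=12,
        cell_radius_um_range=(5.0, 8.0),
        tnt_probability_per_cell_pair=0.3, noise_sd=0.02,
        tile_grid=(2, 2), tile_shadow_amplitude=0.3, seed=9)
    image, truth = td.generate_phantom(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
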