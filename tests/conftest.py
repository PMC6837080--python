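import numpy as np
import pytest

from rowgraphics.annotation import rasterize_lines
from rowgraphics.network import NetConfig
from rowgraphics.synthetic_scene import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene_spec():
    """A 96x96 four-row scene family used across the suite."""
    return SceneSpec(
        image_height=96,
        image_width=96,
        n_rows=4,
        vanishing_point=(-60.0, 48.0),
        row_spacing_at_bottom=22.0,
        plant_spacing=12.0,
        plant_radius_near=4.0,
        plant_radius_far=1.5,
        weed_density=0.5,
        weed_radius_range=(1.5, 3.0),
        jitter_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_net_config():
    return NetConfig(
        encoder_stages=((2, 16), (2, 32)),
        tail_blocks=2,
        tail_kernel=7,
        tail_separable=True,
        skip_mode="multiscale",
        multiscale_kernels=(3, 5, 7),
        skip_branch_channels=12,
        decoder_channels=32,
        n_classes=2,
    )


@pytest.fixture(scope="session")
def tiny_line_dataset(small_scene_spec):
    """Eight 96x96 (image, line mask) pairs with thin strokes."""
    ds = []
    for i in range(8):
        img, gt = generate_scene(small_scene_spec.replace(seed=100 + i))
        mask = rasterize_lines(gt.to_graphic((96, 96)), thickness=3)
        ds.append((img, mask))
    return ds
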