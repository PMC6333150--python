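import numpy as np
import pytest

from protonprep import DoseGrid


def make_grid(values, spacing=3.0, origin=(0.0, 0.0, 0.0), scaling=1.0):
    values = np.asarray(values, float)
    return DoseGrid(
        values=values,
        grid_scaling=scaling,
        image_position=np.asarray(origin, float),
        pixel_spacing=np.array([spacing, spacing]),
        frame_offsets=np.arange(values.shape[0]) * spacing,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


@pytest.fixture
def small_grid_pair(rng):
    """A smooth-ish random reference and a mildly perturbed evaluation."""
    ref = rng.uniform(0.3, 2.0, (6, 8, 8))
    ev = ref * (1.0 + rng.normal(0, 0.04, ref.shape))
    return make_grid(ref), make_grid(ev)
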