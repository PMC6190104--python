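import numpy as np
import pytest

from embryoserv import DefocusModel, SceneParams, generate_defocus_stack


@pytest.fixture(scope="session")
def standard_stack():
    """The standard synthetic through-focus stack: 31 frames, 200 um spacing."""
    params = SceneParams(
        image_height=192,
        image_width=192,
        embryo_center=(96.0, 96.0),
        embryo_axes=(66.0, 56.0),
        pipette_tip=(180.0, 30.0),
        seed=42,
    )
    model = DefocusModel(focal_z=3000.0)
    z = [i * 200.0 for i in range(31)]
    stack, truth = generate_defocus_stack(params, model, z)
    return stack, truth


@pytest.fixture(scope="session")
def texture_image():
    """Seeded 8-bit texture image with content at all spatial frequencies."""
    rng = np.random.default_rng(7)
    img = rng.integers(0, 256, size=(48, 48), dtype=np.uint8)
    return img
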