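import numpy as np
import pytest

from peonyqc.synthetic import EllipseSpec, SceneSpec, render_scene


@pytest.fixture(scope="session")
def simple_scene():
    """One 20x15 mm ellipse at 25 deg plus the card, ppm 10, mild noise."""
    spec = SceneSpec(
        ppm=10.0,
        slices=(EllipseSpec((25.0, 25.0), 20.0, 15.0, 25.0),),
        card_center_mm=(62.0, 26.0),
        image_size_px=(520, 840),
        noise_sigma=3.0,
        seed=7,
    )
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
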