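import numpy as np
import pytest

from quantafm import PipelineConfig
from quantafm.afm_io import AFMImage


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, nm_per_px=1.0):
    return AFMImage(np.asarray(pixels, dtype=float), nm_per_px=nm_per_px)


@pytest.fixture(scope="session")
def nucleosome_scene():
    """One rendered nucleosome (theta=60) plus one free filament, mild noise."""
    from quantafm.synthetic import (
        GroundTruthObject,
        NoiseParams,
        generate_filament,
        generate_nucleosome,
        render_scene,
    )

    rng = np.random.default_rng(77)
    objects = [
        generate_nucleosome((50.0, 58.0), 60.0, rng=rng),
        GroundTruthObject("free_dna", [generate_filament(157.8, rng=rng)], 157.8),
    ]
    return render_scene(objects, shape=(384, 384),
                        noise=NoiseParams(background_sigma=5), rng=rng, rng_seed=77)
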