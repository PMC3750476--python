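import numpy as np
import pytest

from mamle import ColonyParams, PipelineConfig, fit_shape_model, generate_colony
from mamle.shape import features_of_coords
from mamle.synthetic import _cell_mask


@pytest.fixture(scope="session")
def small_colony():
    """A 256x256 dense-ish colony (50 rods) with ground truth."""
    params = ColonyParams(image_size=(256, 256), n_cells=50, clumping=0.7, seed=7)
    return generate_colony(params)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(max_cell_area=450, min_object_area=25)


def rod_features(rng, n=60, length=(20, 40), width=(7, 11)):
    """Feature vectors of randomly oriented rasterized rods."""
    feats = []
    for _ in range(n):
        ln = rng.uniform(*length)
        w = rng.uniform(*width)
        theta = rng.uniform(0, np.pi)
        mask = _cell_mask(ln, w, theta, "rod")
        rr, cc = np.nonzero(mask)
        feats.append(features_of_coords(rr.astype(float), cc.astype(float)))
    return feats


@pytest.fixture(scope="session")
def rod_model():
    """Shape model trained on single rasterized rods (the truth population)."""
    rng = np.random.default_rng(42)
    return fit_shape_model(rod_features(rng, n=200), trim_fraction=0.0)
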