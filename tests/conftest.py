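import numpy as np
import pandas as pd
import pytest

from polyptile import features, imaging, phantoms


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210722)


@pytest.fixture(scope="session")
def phantom_record():
    """One deterministic phantom image with a polyp and mask."""
    return phantoms.generate_phantom(phantoms.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def labelled_tiles(phantom_record):
    img = imaging.to_hsv(phantom_record.image)
    return imaging.label_tiles(imaging.tile_image(img, 50))


@pytest.fixture(scope="session")
def small_feature_frame():
    """Feature table from a handful of phantoms: both classes present."""
    recs = phantoms.generate_dataset(6, phantoms.PhantomSpec(n_polyps=2),
                                     seed=5)
    frames = []
    for rec in recs:
        img = imaging.to_hsv(rec.image)
        tiles = imaging.label_tiles(imaging.tile_image(img, 50))
        frames.append(features.features_to_frame(
            [features.extract_antecedents(t) for t in tiles]))
    frame = pd.concat(frames, ignore_index=True)
    assert set(frame["label"]) == {"polyp", "no_polyp"}
    return frame
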