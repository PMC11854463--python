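import numpy as np
import pytest

import daqugrade as dq


@pytest.fixture(scope="session")
def default_params():
    return dq.GenParams()


@pytest.fixture(scope="session")
def p_image(default_params):
    return dq.generate_daqu_image("P", default_params, seed=0)


@pytest.fixture(scope="session")
def s_image(default_params):
    return dq.generate_daqu_image("S", default_params, seed=0)


@pytest.fixture(scope="session")
def p_segmented(p_image):
    return dq.segment(p_image.pixels, "morph_fusion")


@pytest.fixture(scope="session")
def small_corpus(default_params):
    """10 images per grade under default (high-separability) conditions."""
    images, manifest = dq.generate_dataset(10, default_params, seed=11)
    return images, manifest


@pytest.fixture(scope="session")
def l2_table(small_corpus):
    images, _ = small_corpus
    pf = [img for img in images if img.grade.value != "S"]
    return dq.build_feature_table(pf, "L2")


@pytest.fixture(scope="session")
def l1_table(small_corpus):
    images, _ = small_corpus
    return dq.build_feature_table(images, "L1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
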