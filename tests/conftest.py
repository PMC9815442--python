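"""Shared fixtures: the desk-scale benchmark and reference matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tracheidnet.training import make_desk_dataset, split_dataset

TEXTURE_NAMES = ["ASM", "CON", "CORR", "ENT", "VAR", "SA", "SV", "IDM", "SE"]

# Correlation matrix among the nine texture features reported for the
# reference larch dataset (1600 micrographs); used as the worked example
# for redundancy pruning.
PUBLISHED_TEXTURE_CORRELATIONS = pd.DataFrame(
    np.array([
        [1.000, 0.170, 0.209, 0.330, 0.147, 0.986, 0.955, 0.421, 0.935],
        [0.170, 1.000, 0.304, 0.334, 0.411, 0.220, 0.053, 0.607, 0.282],
        [0.209, 0.304, 1.000, 0.171, 0.267, 0.236, 0.139, 0.263, 0.265],
        [0.330, 0.334, 0.171, 1.000, 0.569, 0.429, 0.505, 0.357, 0.690],
        [0.147, 0.411, 0.267, 0.569, 1.000, 0.139, 0.176, 0.541, 0.111],
        [0.986, 0.220, 0.236, 0.429, 0.139, 1.000, 0.896, 0.408, 0.980],
        [0.955, 0.053, 0.139, 0.505, 0.176, 0.896, 1.000, 0.445, 0.789],
        [0.421, 0.607, 0.263, 0.357, 0.541, 0.408, 0.445, 1.000, 0.361],
        [0.935, 0.282, 0.265, 0.690, 0.111, 0.980, 0.789, 0.361, 1.000],
    ]),
    index=TEXTURE_NAMES,
    columns=TEXTURE_NAMES,
)


@pytest.fixture(scope="session")
def desk_dataset():
    """The default synthetic benchmark: 500 images, balanced grades, seed 1."""
    return make_desk_dataset(n_images=500, seed=1)


@pytest.fixture(scope="session")
def desk_split(desk_dataset):
    return split_dataset(desk_dataset.labels, 0.8, seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fast 60-image campaign for training smoke tests."""
    return make_desk_dataset(n_images=60, seed=3, net_image_px=16)


@pytest.fixture()
def published_correlations():
    return PUBLISHED_TEXTURE_CORRELATIONS.copy()
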