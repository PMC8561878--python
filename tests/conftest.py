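"""Shared fixtures: worked-example toy images and the seeded benchmark set.

The two toy images are synthetic reconstructions of the method's small
worked examples (the published figures are unavailable as data): they
are built to satisfy exactly the documented co-occurrence and
run-length counts.
"""

from __future__ import annotations

import numpy as np
import pytest

from stubbletex import Patch, SynthConfig, generate_dataset
from stubbletex.texture import glcm_feature_vector


@pytest.fixture(scope="session")
def glcm_toy() -> Patch:
    """Synthetic 8-gray-level toy image for the GLCM worked example.

    Reading each row left to right (the 0-degree direction, d=1), the
    gray pair (1, 1) occurs exactly once and (1, 2) exactly twice.
    """
    pixels = np.array(
        [[1, 1, 2, 3],
         [1, 2, 4, 5],
         [6, 7, 2, 1],
         [8, 5, 3, 2]]
    )
    return Patch(pixels, levels=9)


@pytest.fixture(scope="session")
def glrlm_toy() -> Patch:
    """Synthetic toy image for the GLRLM worked example.

    At 0 degrees, gray value 3 forms four maximal runs of length 1 and
    one run of length 2, and no longer run.
    """
    pixels = np.array(
        [[3, 1, 3, 2],
         [2, 3, 4, 1],
         [3, 3, 1, 2],
         [4, 3, 2, 1]]
    )
    return Patch(pixels, levels=5)


def random_patch(rng: np.random.Generator, shape=(6, 6), levels=4) -> Patch:
    return Patch(rng.integers(0, levels, shape), levels=levels)


@pytest.fixture(scope="session")
def easy_benchmark():
    """Seeded easy-separability benchmark: 150 patches per class."""
    return generate_dataset(SynthConfig(separability="easy", n_per_class=150, seed=42))


@pytest.fixture(scope="session")
def easy_glcm_features(easy_benchmark):
    X = np.array([glcm_feature_vector(p).values for p in easy_benchmark.patches])
    return X, list(easy_benchmark.labels)
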