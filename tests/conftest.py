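"""Shared fixtures: rendered fields and a trained shape model.

Expensive artefacts (rendered fields, the trained classifier) are session
scoped so every test file reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphoscreen.config import Config
from morphoscreen.pipeline import training_table
from morphoscreen.shape_classify import train
from morphoscreen.synth import FieldSpec, reference_shapes, render_field


@pytest.fixture(scope="session")
def shapes():
    return reference_shapes()


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def balanced_field(shapes):
    """Noisy field, 30 cells, all five classes, no contact."""
    mix = [(s, 0.2) for s in shapes.values()]
    fspec = FieldSpec(image_shape=(640, 640), n_cells=30, rng_seed=11)
    return render_field(fspec, mix)


@pytest.fixture(scope="session")
def training_data(config):
    """Labelled per-cell training fixture, 300 cells per class (~1,500)."""
    return training_table(300, seed=20_001, config=config)


@pytest.fixture(scope="session")
def shape_model(training_data, config):
    table, labels = training_data
    return train(table, labels, config.classify)


def disc_mask(radius: int, pad: int = 6) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[0:size, 0:size]
    c = radius + pad
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def disc50():
    return disc_mask(50)
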