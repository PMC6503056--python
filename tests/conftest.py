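"""Shared fixtures: simulated fields and a session-trained classifier."""

from __future__ import annotations

import numpy as np
import pytest

from nethcs import phenotyping
from nethcs import synthetic_imaging as si


@pytest.fixture(scope="session")
def mixed_field():
    """One 200-cell field with a stimulated-well phenotype mixture."""
    img, truth = si.simulate_field(200, (0.3, 0.6, 0.1), np.random.default_rng(2024))
    return img, truth


@pytest.fixture(scope="session")
def training_cells():
    """Segmentation-matched labeled features, 300 cells per phenotype."""
    return phenotyping.build_training_set(n_per_class=300, seed=11)


@pytest.fixture(scope="session")
def trained_model(training_cells):
    return phenotyping.train(training_cells, seed=1)
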