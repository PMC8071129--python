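"""Shared fixtures: synthetic study conditions and trained models.

Session scope keeps the expensive pieces (model training, corrupted-fixture
standardization) computed once for the whole suite.
"""

import numpy as np
import pytest

from tcrlatent.datasets import assemble_split
from tcrlatent.model import ModelConfig, train
from tcrlatent.simulate import (
    MotifSpec,
    corrupt_properness,
    default_motif_specs,
    generate_ambient_pool,
    generate_repertoire,
)
from tcrlatent.standardize import standardize_dataset

SEED = 7


@pytest.fixture(scope="session")
def motif_specs():
    return default_motif_specs()


@pytest.fixture(scope="session")
def repertoire(motif_specs):
    """Default 3-class, 300-per-class motif-implanted positive set."""
    return generate_repertoire(motif_specs, rng_seed=SEED)


@pytest.fixture(scope="session")
def ambient_pool(repertoire):
    return generate_ambient_pool(4000, rng_seed=SEED + 1,
                                 exclude=repertoire["cdr3b"])


@pytest.fixture(scope="session")
def default_split(repertoire, ambient_pool):
    return assemble_split(repertoire, ambient_pool,
                          sorted(repertoire["epitope"].unique()),
                          test_negative_count=2000, rng_seed=SEED + 2)


@pytest.fixture(scope="session")
def model50(default_split):
    """Standard-config model (50 epochs) for evaluation-level tests."""
    return train(default_split, ModelConfig(epochs=50, rng_seed=0))


@pytest.fixture(scope="session")
def model150(default_split):
    """Interpretation-grade model (150 epochs) for MCMC salience tests."""
    return train(default_split, ModelConfig(epochs=150, rng_seed=0))


@pytest.fixture(scope="session")
def corrupted_two_class():
    """Two classes x 500 with epitope-correlated curation artifacts.

    Returns (original pairs, corrupted pairs, unfixed, fixed, report).
    """
    specs = [
        MotifSpec("GILGFVFTL", "TSS", (5, 6, 7), class_size=500),
        MotifSpec("NLVPMVATV", "QPN", (5, 6, 7), class_size=500),
    ]
    pairs = generate_repertoire(specs, rng_seed=SEED)
    # near-deterministic properness/epitope association: a clean positive
    # control for artifact learning at desk-scale test sizes
    corrupted = corrupt_properness(
        pairs,
        {"GILGFVFTL": 0.02, "NLVPMVATV": 0.95},
        {"GILGFVFTL": 0.05, "NLVPMVATV": 0.05},
        rng_seed=SEED + 3,
    )
    unfixed, fixed, report = standardize_dataset(
        corrupted[["cdr3b", "epitope", "source"]]
    )
    return pairs, corrupted, unfixed, fixed, report


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
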