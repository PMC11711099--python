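"""Shared fixtures: tiny deterministic objects reused across test modules."""

import numpy as np
import pytest

from enzopt.core_sequences import ProteinSequence
from enzopt.mutation_strategies import build_basic_matrix
from enzopt.synthetic_data import (
    SyntheticReactionSpec,
    make_reaction_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_protein():
    return ProteinSequence(id="toy", residues="MKTAYIAKQR")


@pytest.fixture(scope="session")
def basic_matrix():
    return build_basic_matrix()


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated labelled reaction corpus (reused: generation is cheap,
    model fits are not)."""
    return make_reaction_dataset(
        SyntheticReactionSpec(n_reported=100, n_random=100, separation=3.0, seed=5)
    )
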