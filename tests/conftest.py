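import numpy as np
import pytest

from biosimgen import Alphabet, FamilySpec, make_sequence_family


@pytest.fixture(scope="session")
def dna_family():
    """50 mixed-length DNA records with moderate composition spread."""
    return make_sequence_family(
        FamilySpec(Alphabet.DNA, 50, "lognormal", (5.0, 0.3), seed=11))


@pytest.fixture(scope="session")
def protein_family():
    return make_sequence_family(
        FamilySpec(Alphabet.PROTEIN, 40, "lognormal", (4.5, 0.25), seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
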