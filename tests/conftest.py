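import numpy as np
import pytest

from hdxdiff.corrections import LabellingCondition
from hdxdiff.io import PeptideRecord
from hdxdiff.simulate import (
    ExperimentDesign,
    generate_peptide_map,
    random_exchange_model,
    random_protein_sequence,
    uniform_state,
)


@pytest.fixture(scope="session")
def sequence():
    return random_protein_sequence(120, seed=42)


@pytest.fixture(scope="session")
def model(sequence):
    return random_exchange_model(sequence, seed=42)


@pytest.fixture(scope="session")
def peptides(sequence):
    return generate_peptide_map(sequence, mean_length=12, overlap=5, seed=42)


@pytest.fixture(scope="session")
def condition():
    return LabellingCondition(pH_read=5.38, d_frac=0.78)


@pytest.fixture
def flat_state(sequence):
    return uniform_state("flat", len(sequence), 2.0)


@pytest.fixture
def small_design(condition):
    return ExperimentDesign(
        states=("a", "b"),
        conditions={"a": condition, "b": condition},
        timepoints=(15.0, 60.0, 600.0, 6000.0),
        replicate_schedule={60.0: 3, 600.0: 3},
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture
def myoglobin_peptide():
    return PeptideRecord("demo", "GLSDGEWQLVLNVWGKVEAD", 1, 20)
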