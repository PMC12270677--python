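import numpy as np
import pytest

from lariat import (
    GRN_P4A,
    GeneratorConfig,
    build_structure,
    make_restraints,
    parse_sequence,
)

GRANULIN = ((1, 14), (8, 23), (15, 24))


@pytest.fixture(scope="session")
def seq_p4a():
    return parse_sequence(GRN_P4A)


@pytest.fixture(scope="session")
def reference_structure():
    """A deterministic synthetic reference with the granulin matching."""
    return build_structure(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def reference_restraints(reference_structure):
    return make_restraints(reference_structure, GeneratorConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
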