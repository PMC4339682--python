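import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rkalign import GeneratorConfig, ScoringParams, Structure, generate_structure


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def h_type_toy() -> Structure:
    """Two stems of two stacked pairs each, crossing ABAB."""
    return Structure(
        "htoy", "GGAACCAAGGCC", {(1, 8), (2, 7), (5, 12), (6, 11)}
    )


@pytest.fixture(scope="session")
def nested_toy() -> Structure:
    return Structure("ntoy", "GGGAAACCCAA", {(1, 9), (2, 8), (3, 7)})


@pytest.fixture(scope="session")
def h_type_structure() -> Structure:
    return generate_structure(GeneratorConfig(seed=11), sid="hgen")
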