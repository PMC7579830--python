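import numpy as np
import pytest

from m2gmda import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    SyntheticConfig,
    generate,
)


@pytest.fixture
def toy_assoc() -> AssociationMatrix:
    values = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ]
    )
    return AssociationMatrix(values, ["r1", "r2", "r3", "r4"], ["d1", "d2", "d3"])


@pytest.fixture
def sibling_dags() -> tuple[DiseaseDAG, DiseaseDAG]:
    """Two sibling diseases sharing a single parent term."""
    d1 = DiseaseDAG("d1", {"d1", "p"}, {("p", "d1")})
    d2 = DiseaseDAG("d2", {"d2", "p"}, {("p", "d2")})
    return d1, d2


@pytest.fixture(scope="session")
def synthetic_default():
    """The default planted-block data set, seed 1."""
    return generate(SyntheticConfig(seed=1))


def random_similarity(rng: np.random.Generator, labels: list[str]) -> SimilarityMatrix:
    k = len(labels)
    raw = rng.random((k, k))
    values = 0.5 * (raw + raw.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, labels)
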