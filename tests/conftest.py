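import numpy as np
import pytest

from plantdemog.records import ProjectionMatrixRecord


@pytest.fixture
def worked_record() -> ProjectionMatrixRecord:
    """2-stage semelparous life cycle used as the hand-computed oracle:
    survival 0.5 into the reproductive stage, 4 offspring, so
    lam = sqrt(2), Ro = 2, Lmean = 1.5, Lalpha = 1, S = 0."""
    return ProjectionMatrixRecord(
        species_id="worked",
        listed=False,
        T=np.array([[0.0, 0.0], [0.5, 0.0]]),
        F=np.array([[0.0, 4.0], [0.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def archetype_bundle():
    from plantdemog.synth import make_archetype_bundle

    records, truth = make_archetype_bundle(count_per_archetype=12, seed=0)
    return records, truth


@pytest.fixture(scope="session")
def random_records():
    """A reusable batch of random valid records across dimensions 2-6."""
    from plantdemog.synth import random_valid_matrix

    rng = np.random.default_rng(2024)
    return [
        random_valid_matrix(
            int(rng.integers(2, 7)), density=0.6, seed=int(rng.integers(2**31 - 1))
        )
        for _ in range(30)
    ]
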