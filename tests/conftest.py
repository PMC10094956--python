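import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def substances():
    from haptenml import fixtures

    return fixtures.load_substances()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ear_training_matrix():
    """Small deterministic descriptor matrix keyed by the eAR haptens.

    Synthetic numeric columns (not chemistry) so dataset/evaluate tests
    run without RDKit; informative column correlates with the label.
    """
    from haptenml import fixtures
    from haptenml.dataset import propagate_labels
    from haptenml.featurize import DescriptorMatrix

    records = propagate_labels(fixtures.load_substances(), "eAR")
    gen = np.random.default_rng(7)
    n = len(records)
    labels = np.array([r.label for r in records], dtype=float)
    values = np.column_stack(
        [
            labels * 2.0 + gen.normal(0, 0.5, n),  # informative
            gen.normal(0, 1, n),  # noise
            gen.normal(5, 2, n),  # noise
        ]
    )
    matrix = DescriptorMatrix(
        row_ids=[r.hapten_name for r in records],
        descriptor_names=["sig", "noise_a", "noise_b"],
        values=values,
        provider_id="test-synthetic",
    )
    return records, matrix
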