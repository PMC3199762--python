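import pytest

from syntenyviz import figure1_fixture, figure1_state
from syntenyviz.simulate import SimSpec, generate_dataset


@pytest.fixture(scope="session")
def demo_dataset():
    return figure1_fixture()


@pytest.fixture()
def demo_state(demo_dataset):
    return figure1_state(demo_dataset)


@pytest.fixture()
def small_dataset():
    """A small two-sequence dataset with mixed orientations."""
    spec = SimSpec(
        n_sequences=2,
        seq_length=100_000,
        n_blocks=8,
        block_length_range=(1_000, 8_000),
        inversion_rate=0.4,
        n_features_per_track=5,
        seed=7,
    )
    return generate_dataset(spec)
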