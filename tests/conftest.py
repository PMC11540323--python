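import numpy as np
import pytest

from readscape.io_core import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_record(rng, length, rid="r", gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return SeqRecord(id=rid, seq="".join(rng.choice(list("ACGT"), size=length, p=p)))


@pytest.fixture
def random_records(rng):
    return [random_record(rng, int(rng.integers(1000, 10_000)), rid=f"r{i}") for i in range(20)]


@pytest.fixture(scope="session")
def hexamer_table():
    """Scoring table trained on synthetic coding sequence (shared, expensive)."""
    from readscape.coding_density import train_hexamer_table
    from readscape.synthetic_data import simulate_coding_training_set

    return train_hexamer_table(simulate_coding_training_set(150, 500, seed=42), source="synthetic")
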