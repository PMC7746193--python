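import pytest

from waldscan import AlignmentSet, SyntheticConfig, simulate_dataset


def make_alignment(seqs, reference_id="ref", ids=None):
    if ids is None:
        ids = ["ref"] + [f"s{i}" for i in range(1, len(seqs))]
    return AlignmentSet(tuple(ids), tuple(seqs), reference_id)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic bundle with the built-in asymmetric configuration."""
    return simulate_dataset(SyntheticConfig(seed=42))


@pytest.fixture
def aln_factory():
    return make_alignment
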