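import pytest

from nusfold.model import RnaSequence, normalize_sequence
from nusfold.oracle import random_sequences


@pytest.fixture
def seq_hairpin() -> RnaSequence:
    # three nested GC pairs around an AAA loop
    return normalize_sequence("GGGAAACCC", id="hairpin")


@pytest.fixture
def small_random_batch():
    """A fixed batch of short random sequences shared across tests."""
    return random_sequences(40, list(range(3, 33)), seed=424242)


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "records.fa"
    path.write_text(
        ">hairpin\nGGGAAACCC\n"
        ">split\nGAAA\nC\n"  # multi-line record
        ">dna\nACGT\n"
    )
    return path
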