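import numpy as np
import pytest

from profam.seqio import CANONICAL_AA, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture
def random_records(rng):
    """30 random sequences of length 50-200."""
    return [
        ProteinRecord(id=f"r{i}", sequence=random_sequence(rng, int(rng.integers(50, 201))))
        for i in range(30)
    ]


@pytest.fixture
def fasta_file(tmp_path):
    """Write a FASTA file from (id, sequence) pairs; returns the writer."""

    def write(pairs, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in pairs:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return write
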