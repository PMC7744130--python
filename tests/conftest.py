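import pytest

from brisk import GenSpec, random_sequence


@pytest.fixture
def make_fasta(tmp_path):
    """Write sequences to a FASTA file and return its path."""

    def _make(records, name="input.fa", width=0):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n")
                if width:
                    for i in range(0, len(seq), width):
                        fh.write(seq[i : i + width] + "\n")
                else:
                    fh.write(seq + "\n")
        return path

    return _make


@pytest.fixture
def random_seq():
    """Deterministic random ACGT sequence factory."""

    def _make(length, seed, gc=0.5):
        return random_sequence(GenSpec(length, seed, gc))

    return _make
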