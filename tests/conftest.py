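import pytest

from ampedit import example_locus


@pytest.fixture(scope="session")
def locus():
    """The deterministic synthetic toy locus used across tests."""
    return example_locus()


def make_read(seq: str, read_id: str = "r"):
    """Wrap a bare sequence as a successfully merged read."""
    from ampedit.readprep import MergedRead

    return MergedRead(read_id, seq, "I" * len(seq), len(seq), "merged")


def mutate(seq: str, coord: int, base: str) -> str:
    assert seq[coord] != base
    return seq[:coord] + base + seq[coord + 1 :]


def delete(seq: str, start: int, length: int) -> str:
    return seq[:start] + seq[start + length :]


def insert(seq: str, anchor: int, ins: str) -> str:
    return seq[:anchor] + ins + seq[anchor:]
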