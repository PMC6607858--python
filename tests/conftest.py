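import numpy as np
import pytest

from cmuscan import SeqRecord, bundled_cmub_scheme


@pytest.fixture
def cmub_scheme():
    return bundled_cmub_scheme()


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "in.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def random_dna(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
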