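import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    """Seeded stdlib RNG for reproducible random oligos."""
    return random.Random(20260922)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA text to a temp file and returning the path."""

    def _write(text: str, name: str = "input.fa") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
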