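import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from spscreen import gen_table_fixture, synthetic_vector


@pytest.fixture(scope="session")
def table_fixture():
    """The eight published benchmark candidates, keyed by short name."""
    return {f.name: f for f in gen_table_fixture()}


@pytest.fixture(scope="session")
def top5(table_fixture):
    return [table_fixture[n] for n in ["SP1", "SP2", "SP3", "SP4", "SP5"]]


@pytest.fixture(scope="session")
def small_vector():
    """Synthetic vector context scaled down for fast assembly/folding."""
    return synthetic_vector(propeptide_codons=30, utr3_length=20, polya_tail_length=10)


@pytest.fixture(scope="session")
def full_vector():
    """Synthetic vector context at realistic (~1.7 kb transcript) scale."""
    return synthetic_vector()
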