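import random

import pytest

from prfsource import NucRecord, PepRecord


@pytest.fixture
def rng():
    return random.Random(20240901)


def make_pep(seq: str, title: str = "query") -> PepRecord:
    return PepRecord(title=title, seq=seq)


def make_nuc(seq: str, title: str = "subject") -> NucRecord:
    return NucRecord(title=title, seq=seq)
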