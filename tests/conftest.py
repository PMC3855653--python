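import random

import pytest

from lstclust.seqio import Transcript


@pytest.fixture
def rng():
    return random.Random(20130961)


@pytest.fixture
def make_transcript():
    def _make(tid: str, seq: str, locus: str = "Locus_1") -> Transcript:
        return Transcript(tid, locus, seq)

    return _make


@pytest.fixture
def write_file(tmp_path):
    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
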