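import random

import pytest

from ngsqc.encodings import SANGER
from ngsqc.seqio import SequenceRead


@pytest.fixture
def rng():
    return random.Random(20240901)


def random_read(rng, rid="r", length=None, qmin=0, qmax=40, desc=""):
    n = length if length is not None else rng.randint(1, 150)
    seq = "".join(rng.choice("ACGTN") for _ in range(n))
    quals = [rng.randint(qmin, qmax) for _ in range(n)]
    return SequenceRead(rid, seq, quals, desc)


def fastq_text(reads, encoding=SANGER):
    lines = []
    for r in reads:
        lines.append(f"@{r.header}")
        lines.append(r.seq)
        lines.append("+")
        lines.append(encoding.encode(r.quals))
    return "\n".join(lines) + "\n"
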