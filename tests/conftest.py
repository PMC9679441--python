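import numpy as np
import pytest

from coipipe import synthetic
from coipipe.seqio import ReadPair, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20220915)


@pytest.fixture
def community():
    """A small mock community with defaults (6 haplotypes, 800 pairs)."""
    spec = synthetic.CommunitySpec(seed=11)
    return spec, synthetic.generate_community(spec)


def make_pair(fwd_seq, rev_seq, fwd_q=None, rev_q=None, name="r1"):
    fq = tuple(fwd_q) if fwd_q is not None else (35,) * len(fwd_seq)
    rq = tuple(rev_q) if rev_q is not None else (35,) * len(rev_seq)
    return ReadPair(
        SequenceRecord(f"{name}/1", fwd_seq, fq),
        SequenceRecord(f"{name}/2", rev_seq, rq),
    )


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
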