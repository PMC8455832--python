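import numpy as np
import pytest

from sdrkit.io_formats import AlignmentRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_alignment_record(rng, seq_lengths=None, query_id="q", subject_id="s"):
    """A random but internally consistent alignment hit."""
    if seq_lengths:
        query_id = rng.choice(list(seq_lengths))
        subject_id = rng.choice(list(seq_lengths))
        qlen = seq_lengths[query_id]
        slen = seq_lengths[subject_id]
    else:
        qlen = slen = 10_000
    q_start = int(rng.integers(1, qlen))
    q_end = int(rng.integers(q_start, qlen + 1))
    s_start = int(rng.integers(1, slen))
    s_end = int(rng.integers(s_start, slen + 1))
    return AlignmentRecord(
        query_id=str(query_id),
        subject_id=str(subject_id),
        pident=float(np.round(rng.uniform(50, 100), 2)),
        aln_len=int(rng.integers(50, 2000)),
        mismatches=int(rng.integers(0, 200)),
        gap_opens=int(rng.integers(0, 20)),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=float(rng.uniform(0, 1e-3)),
        bitscore=float(np.round(rng.uniform(100, 5000), 1)),
        strand="+" if rng.random() < 0.5 else "-",
        gaps=int(rng.integers(0, 50)),
    )
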