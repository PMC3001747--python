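import numpy as np
import pytest

from protadapt.align_io import AlignedSequence, AnnotatedAlignment, GroupScheme


@pytest.fixture
def two_group_scheme():
    return GroupScheme(
        ("meso", "psychro"),
        {"m1": ("meso", None), "m2": ("meso", None),
         "p1": ("psychro", None), "p2": ("psychro", None)},
    )


@pytest.fixture
def toy_alignment():
    """4 sequences, 2 groups, 8 columns, no annotation."""
    seqs = [
        AlignedSequence("m1", "ACDEFGHK", group=1),
        AlignedSequence("m2", "ACDEFGHK", group=1),
        AlignedSequence("p1", "ACDEFGHR", group=2),
        AlignedSequence("p2", "ACDEFGRR", group=2),
    ]
    return AnnotatedAlignment("toy", seqs)


def brute_force_mismatch_count(seq_a, seq_b):
    """Independent per-column recount of differing, not-both-gap pairs."""
    n = 0
    for ra, rb in zip(seq_a.residues, seq_b.residues):
        if ra == rb:
            continue
        if ra == "-" and rb == "-":
            continue
        n += 1
    return n
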