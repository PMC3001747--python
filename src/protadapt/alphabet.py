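"""Amino-acid alphabet and gap conventions shared across the package.

The 20 standard residues are kept in alphabetical one-letter order.  The
gap/indel state is normalized to ``-`` internally; substitution outputs
render it as ``~`` (the display convention for deletion/insertion).
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Internal (normalized) gap symbol.
GAP: str = "-"

#: Gap symbols accepted on input.
GAP_INPUT: frozenset = frozenset("-.~")

#: Gap symbol used in substitution-matrix output.
GAP_DISPLAY: str = "~"

#: The 21 states of a substitution-pair matrix: 20 residues + gap.
STATES21: tuple = tuple(AMINO_ACIDS) + (GAP,)

#: Display labels for the 21 states (gap rendered as '~').
STATE_LABELS21: tuple = tuple(AMINO_ACIDS) + (GAP_DISPLAY,)

AA_INDEX: dict = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
STATE_INDEX: dict = {s: i for i, s in enumerate(STATES21)}

_VALID = frozenset(AMINO_ACIDS) | {GAP}


def normalize_gaps(residues: str) -> str:
    """Map every accepted gap symbol ('-', '.', '~') to the internal '-'."""
    return residues.replace(".", GAP).replace("~", GAP)


def validate_residues(residues: str, seq_id: str = "?") -> None:
    """Raise ``ValueError`` (naming the offending 1-based position) on any
    character outside the 20 amino acids + gap."""
    for pos, ch in enumerate(residues, start=1):
        if ch not in _VALID:
            raise ValueError(
                f"illegal residue character {ch!r} at position {pos} "
                f"in sequence {seq_id!r}"
            )


def encode(residues: str) -> np.ndarray:
    """Encode a normalized residue string as int8 state codes (gap = 20)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 20, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        out[arr == ord(aa)] = i
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    lut = np.frombuffer((AMINO_ACIDS + GAP).encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")
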