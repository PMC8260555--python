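"""Canonical 21-letter alphabet for alignment-based Potts models.

The 20 standard amino acids in alphabetical one-letter order, followed by the
gap character ``-`` as the 21st symbol.  The gap plays a gauge role in the
coupling tensor (all interactions involving it are zero), so ambiguous or
non-standard letters must not invent residue statistics: they are mapped to
the gap symbol on input.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Gap character; treated as the 21st residue type.
GAP_CHAR = "-"

#: Full alphabet (residues + gap).
ALPHABET = AMINO_ACIDS + GAP_CHAR

#: Number of Potts states.
N_STATES = 21

#: Integer code of the gap state.
GAP_STATE = 20

#: Characters that are mapped to gap on input: ambiguity codes, rare
#: non-standard residues, and the Stockholm "no residue" dot.
GAP_EQUIVALENT = set("XBZUO.*" + GAP_CHAR)

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


def encode_symbol(ch: str) -> int:
    """Map a single alignment character to its integer state.

    Uppercase standard residues map to 0..19 and ``-`` to 20.  Ambiguity
    codes (X, B, Z), non-standard residues (U, O), ``.`` and lowercase
    letters (insert states in Pfam/Stockholm alignments) all map to gap.
    Anything else raises ``ValueError``.
    """
    if ch in _CODE:
        return _CODE[ch]
    if ch in GAP_EQUIVALENT or ch.islower():
        return GAP_STATE
    raise ValueError(f"symbol {ch!r} is not in the 21-letter alphabet")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence string into an int8 state vector."""
    return np.fromiter((encode_symbol(c) for c in seq), dtype=np.int8, count=len(seq))


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` (gap-mapped symbols stay gaps)."""
    return "".join(ALPHABET[int(c)] for c in codes)


#: Documented hydrophobic subset used for composition checks.
HYDROPHOBIC = frozenset("AVLIMFWC")

HYDROPHOBIC_STATES = frozenset(_CODE[a] for a in HYDROPHOBIC)
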