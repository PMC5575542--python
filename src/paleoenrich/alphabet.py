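"""Amino-acid alphabet shared across the package.

States are indexed in alphabetical one-letter order so that ``np.argmax``
tie-breaking (lowest index wins) coincides with the documented alphabetical
tie-break for maximum-likelihood ancestral states.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_STATES: int = 20
GAP: str = "-"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: symbols treated as missing data in likelihood computations
MISSING_SYMBOLS = frozenset({GAP, "X", "?", "."})

THREE_LETTER: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER: dict[str, str] = {v: k for k, v in THREE_LETTER.items()}


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as state indices; missing symbols become -1."""
    out = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence.upper()):
        if ch in MISSING_SYMBOLS:
            out[i] = -1
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"illegal amino-acid symbol {ch!r}") from None
    return out


def decode(states: np.ndarray, present: np.ndarray | None = None) -> str:
    """Decode state indices to a string, emitting gaps where absent."""
    chars = []
    for j, s in enumerate(states):
        if (present is not None and not present[j]) or s < 0:
            chars.append(GAP)
        else:
            chars.append(AMINO_ACIDS[s])
    return "".join(chars)
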