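"""In-memory containers for gapped protein alignments."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, GAP, MISSING_SYMBOLS, encode

__all__ = ["ProteinAlignment"]

_LEGAL = set(AMINO_ACIDS) | MISSING_SYMBOLS


class ProteinAlignment:
    """A gapped amino-acid alignment with named rows.

    Rows are stored as a ``(n_taxa, L)`` array of single characters; gaps are
    ``'-'``.  Taxon names must be unique and every row must have the same
    length.
    """

    def __init__(self, sequences: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
        if not items:
            raise ValueError("alignment must contain at least one sequence")
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("taxon names must be unique")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError("all aligned rows must have equal length")
        for name, seq in items:
            bad = set(seq.upper()) - _LEGAL
            if bad:
                raise ValueError(f"illegal symbols {sorted(bad)} in row {name!r}")
        self.taxa: list[str] = names
        self.matrix = np.array([list(s.upper()) for _, s in items], dtype="U1")
        self._row = {n: i for i, n in enumerate(names)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.n_taxa

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._row

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self._row[taxon]])

    def encoded(self, taxon: str) -> np.ndarray:
        """Row as state indices with -1 for gap/missing."""
        return encode(self.sequence(taxon))

    def presence_matrix(self) -> np.ndarray:
        """Boolean (n_taxa, L): True where the row has a residue, not a gap."""
        return self.matrix != GAP

    def ungapped(self, taxon: str) -> str:
        return self.sequence(taxon).replace(GAP, "")

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls([(r.id, str(r.seq)) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(t)), id=t, description="") for t in self.taxa
        ]
        SeqIO.write(records, str(path), "fasta")
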