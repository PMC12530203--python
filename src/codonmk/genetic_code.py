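"""Genetic code tables used for synonymous/non-synonymous classification.

The standard code (NCBI translation table 1) is embedded directly so the
core counting machinery has no runtime dependency for its default path;
any other NCBI table id is materialised from Biopython's tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

BASES = "TCAG"
STOP = "*"

#: All 64 codons in NCBI order (first base slowest: TTT, TTC, TTA, ...).
CODONS: tuple[str, ...] = tuple(a + b + c for a, b, c in product(BASES, BASES, BASES))

# Amino-acid line of NCBI translation table 1, aligned with CODONS.
_STANDARD_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with an explicit stop set.

    Parameters
    ----------
    table_id:
        NCBI translation-table id this code was built from (1 = standard).
    codon_map:
        Mapping of all 64 codons (DNA alphabet, upper case) to one-letter
        amino acids, with ``*`` marking stop codons.
    """

    table_id: int
    codon_map: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValueError(f"genetic code needs 64 codons, got {len(self.codon_map)}")

    def translate(self, codon: str) -> str:
        """One-letter amino acid for *codon* (``*`` for stop)."""
        return self.codon_map[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_map[codon] == STOP

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_map.items() if aa == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The non-stop codons, in NCBI codon order."""
        return tuple(c for c in CODONS if self.codon_map[c] != STOP)

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        """True if the two codons encode the same amino acid."""
        return self.codon_map[codon_a] == self.codon_map[codon_b]

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear code (table 1; stops TAA, TAG, TGA)."""
        return cls(table_id=1, codon_map=dict(zip(CODONS, _STANDARD_AAS)))

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        """Build a code from an NCBI translation-table id via Biopython."""
        if table_id == 1:
            return cls.standard()
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_map = {c: STOP for c in table.stop_codons}
        codon_map.update(table.forward_table)
        return cls(table_id=table_id, codon_map={c: codon_map[c] for c in CODONS})
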