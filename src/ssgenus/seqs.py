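"""Codon tables and small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)  # TAA TAG TGA

#: The 61 sense codons in fixed lexicographic order (the axis of every
#: codon-frequency vector).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid -> codons encoding it (sorted, stable)
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, ())
CODONS_BY_AA = {
    aa: tuple(c for c in SENSE_CODONS if standard_dna_table.forward_table[c] == aa)
    for aa in sorted({standard_dna_table.forward_table[c] for c in SENSE_CODONS})
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(CODONS_BY_AA))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a DNA string frame 0; trailing partial codon dropped, stops as '*'."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def is_stop(codon: str) -> bool:
    """A codon terminates translation if it is a stop or contains an N.

    Treating N-containing codons as terminators makes assembly gaps act
    like contig ends for open-reading-frame extraction.
    """
    return codon in STOP_CODONS or "N" in codon
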