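"""Domain objects for protein-coding gene structure and aligned sequence pairs.

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from the
1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = "ACGT"


def is_transition(ref: str, alt: str) -> bool:
    """True if ref->alt is a transition (purine<->purine or pyrimidine<->pyrimidine)."""
    return (ref in PURINES and alt in PURINES) or (ref in PYRIMIDINES and alt in PYRIMIDINES)


import itertools as _itertools

#: standard genetic code, precomputed once (hot path in the simulator)
CODON_TABLE: dict[str, str] = {
    codon: str(Seq(codon).translate())
    for codon in ("".join(p) for p in _itertools.product(BASES, repeat=3))
}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop."""
    return CODON_TABLE[codon]


class Completeness(str, Enum):
    COMPLETE = "COMPLETE"
    INCOMPLETE = "INCOMPLETE"


@dataclass
class GeneModel:
    """Exon/intron structure of one protein-coding gene.

    Parameters
    ----------
    gene_id : str
        Identifier shared with the sequence records.
    exon_lengths : list of int
        CDS-contributing exon lengths in bp, in transcription order.
    strand : str
        '+' or '-'.
    cds_start_offset : int
        Offset of the CDS start on its scaffold (0-based).
    splice_dinucleotides : list of (str, str)
        Per intron, the (donor, acceptor) 2-mers; canonically ('GT', 'AG').
    """

    gene_id: str
    exon_lengths: list[int]
    strand: str = "+"
    cds_start_offset: int = 0
    splice_dinucleotides: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.splice_dinucleotides and len(self.splice_dinucleotides) != self.intron_count:
            raise ValueError(
                f"{self.gene_id}: {len(self.splice_dinucleotides)} splice dinucleotide "
                f"pairs for {self.intron_count} introns"
            )

    @property
    def intron_count(self) -> int:
        return len(self.exon_lengths) - 1

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)


@dataclass
class GeneSequencePair:
    """A reference (functional) CDS aligned to the query species' CDS.

    Both strings have equal length; '-' marks alignment gaps, 'N' is treated
    as ambiguity, not as a gap.
    """

    gene_id: str
    reference_cds: str
    query_cds: str
    completeness: Completeness = Completeness.COMPLETE
    missing_exons: list[int] = field(default_factory=list)
    query_splice_dinucleotides: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if len(self.reference_cds) != len(self.query_cds):
            raise ValueError(
                f"{self.gene_id}: aligned reference ({len(self.reference_cds)} bp) and "
                f"query ({len(self.query_cds)} bp) differ in length"
            )
        if self.missing_exons and self.completeness is not Completeness.INCOMPLETE:
            self.completeness = Completeness.INCOMPLETE

    @property
    def reference_ungapped(self) -> str:
        return self.reference_cds.replace("-", "")

    @property
    def query_ungapped(self) -> str:
        return self.query_cds.replace("-", "")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
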