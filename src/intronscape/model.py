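"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; GFF3 files are
read and written 1-based inclusive at the boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One genomic sequence (chromosome / scaffold)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A protein-coding gene reduced to one representative mRNA.

    ``exon_intervals`` and ``cds_intervals`` are sorted by genomic start and
    non-overlapping; ``protein`` is the conceptual translation of the joined
    CDS with any trailing stop removed.
    """

    id: str
    seq_id: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    protein: str = ""
    mrna_id: str = ""

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exon_intervals[0][0], self.exon_intervals[-1][1])


@dataclass
class Intron:
    """One spliceosomal intron between two CDS-bearing exons.

    ``seq`` is the sense-strand (transcript orientation) intron sequence, so
    ``donor2``/``acceptor2`` are its first/last two bases regardless of the
    genomic strand. ``coding_offset`` counts coding nucleotides 5' of the
    intron in the CDS; ``phase = coding_offset mod 3``.
    """

    id: str
    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    ordinal: int
    seq: str
    coding_offset: int
    gc_percent: float
    class_label: str = "unclassified"
    family_id: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def phase(self) -> int:
        return self.coding_offset % 3

    @property
    def donor2(self) -> str:
        return self.seq[:2]

    @property
    def acceptor2(self) -> str:
        return self.seq[-2:]


@dataclass
class AnnotationSet:
    """Genome sequences + gene models + the derived intron inventory."""

    sequences: dict[str, SequenceRecord] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    introns: list[Intron] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def intron_by_id(self) -> dict[str, Intron]:
        return {i.id: i for i in self.introns}

    def introns_of_gene(self, gene_id: str) -> list[Intron]:
        return sorted(
            (i for i in self.introns if i.gene_id == gene_id),
            key=lambda i: i.ordinal,
        )

    def validate(self) -> None:
        """Check cross-references and intron invariants; raise on violation."""
        for g in self.genes.values():
            if g.seq_id not in self.sequences:
                raise ValueError(f"gene {g.id} references unknown sequence {g.seq_id}")
        for i in self.introns:
            if i.gene_id not in self.genes:
                raise ValueError(f"intron {i.id} references unknown gene {i.gene_id}")
            if i.length != len(i.seq) or i.length < 4:
                raise ValueError(f"intron {i.id} has inconsistent length")
            genomic = self.sequences[i.seq_id].seq[i.start : i.end]
            expected = genomic if i.strand == "+" else revcomp(genomic)
            if i.seq != expected:
                raise ValueError(f"intron {i.id} sequence does not match the genome")
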