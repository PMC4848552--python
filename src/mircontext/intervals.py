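"""Coordinate-level domain objects shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)`` on a named chromosome,
the BED convention; GFF3 input is converted on read. A single convention is
used internally so interval arithmetic never mixes offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when a genomic record violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name; non-empty.
    start, end : int
        0-based inclusive start, exclusive end; ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (isinstance(self.start, (int,)) and isinstance(self.end, (int,))):
            raise ValidationError("start/end must be integers")
        if not self.start < self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between closest edges; 0 if abutting or overlapping.

        Returns None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.start <= other.start:
            earlier, later = self, other
        else:
            earlier, later = other, self
        return max(0, later.start - earlier.end)


def gap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap between two same-chromosome intervals; raises on chrom mismatch."""
    g = a.gap_to(b)
    if g is None:
        raise ValidationError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return g


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA (5p or 3p arm) of a precursor."""

    mature_id: str
    interval: GenomicInterval
    sequence: Optional[str] = None


@dataclass(frozen=True)
class MirnaPrecursor:
    """A pre-miRNA hairpin with one or two mature products.

    Invariants: 1-2 matures, each contained in the precursor interval and on
    the precursor strand.
    """

    mirna_id: str
    interval: GenomicInterval
    matures: tuple = ()

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise ValidationError("mirna_id must be non-empty")
        if self.matures:
            if not 1 <= len(self.matures) <= 2:
                raise ValidationError(
                    f"{self.mirna_id}: precursors carry 1-2 matures, got {len(self.matures)}"
                )
            for m in self.matures:
                if not self.interval.contains(m.interval):
                    raise ValidationError(
                        f"{self.mirna_id}: mature {m.mature_id} not contained in precursor"
                    )
                if m.interval.strand != self.interval.strand:
                    raise ValidationError(
                        f"{self.mirna_id}: mature {m.mature_id} strand differs from precursor"
                    )


@dataclass(frozen=True)
class Transcript:
    """A transcript: sorted non-overlapping exons, optional CDS/UTR parts."""

    transcript_id: str
    exons: tuple
    cds: tuple = ()
    utr5: tuple = ()
    utr3: tuple = ()

    def __post_init__(self) -> None:
        prev_end = None
        for ex in self.exons:
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: span, strand, transcripts and a branch age.

    ``gene_age`` is the branch index on the species tree (1 = most ancient),
    or None when unknown.
    """

    gene_id: str
    span: GenomicInterval
    transcripts: tuple = ()
    gene_age: Optional[int] = None

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            for ex in tx.exons:
                if not self.span.contains(ex):
                    raise ValidationError(
                        f"{self.gene_id}: exon of {tx.transcript_id} outside gene span"
                    )

    @property
    def strand(self) -> str:
        return self.span.strand

    def longest_transcript(self) -> Optional[Transcript]:
        """Transcript with greatest summed exon length; ties by transcript_id."""
        if not self.transcripts:
            return None
        return min(self.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))

    def introns(self, transcript: Optional[Transcript] = None) -> list:
        """Intron intervals of a transcript (default: the longest one)."""
        tx = transcript or self.longest_transcript()
        if tx is None or len(tx.exons) < 2:
            return []
        out = []
        for a, b in zip(tx.exons, tx.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.span.chrom, a.end, b.start, self.span.strand)
                )
        return out


INTERGENIC = "intergenic"
INTRAGENIC = "intragenic"
SENSE = "sense"
ANTISENSE = "antisense"
NOT_APPLICABLE = "not-applicable"
INTRON = "intron"
CDS_EXON = "CDS-exon"
FIVE_PRIME_UTR = "five-prime-UTR"
THREE_PRIME_UTR = "three-prime-UTR"


@dataclass(frozen=True)
class ContextAnnotation:
    """Genomic-context call for one precursor.

    Intragenic records carry host/orientation/subregion; intergenic records
    carry the closest-neighbour gene and its distance.
    """

    mirna_id: str
    category: str
    orientation: str = NOT_APPLICABLE
    subregion: str = NOT_APPLICABLE
    host_gene_id: Optional[str] = None
    neighbor_gene_id: Optional[str] = None
    neighbor_distance_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in (INTERGENIC, INTRAGENIC):
            raise ValidationError(f"bad category {self.category!r}")
        if self.category == INTRAGENIC:
            if self.host_gene_id is None:
                raise ValidationError(f"{self.mirna_id}: intragenic without host")
            if self.neighbor_gene_id is not None:
                raise ValidationError(f"{self.mirna_id}: intragenic with neighbor fields")
        else:
            if self.host_gene_id is not None:
                raise ValidationError(f"{self.mirna_id}: intergenic with host")
            if self.orientation != NOT_APPLICABLE or self.subregion != NOT_APPLICABLE:
                raise ValidationError(
                    f"{self.mirna_id}: intergenic with orientation/subregion set"
                )


@dataclass(frozen=True)
class MirnaCluster:
    """A merged group of nearby precursors with one random representative."""

    cluster_id: str
    member_ids: tuple
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValidationError(
                f"{self.cluster_id}: representative not among members"
            )
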