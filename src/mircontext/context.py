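"""Genomic-context classification of miRNA precursors.

A precursor overlapping (>= 1 bp) any protein-coding gene span is intragenic;
otherwise intergenic. Intragenic precursors are oriented sense/antisense
relative to the host and placed in a subregion (intron, CDS exon, 5'/3' UTR)
against the host's longest transcript. Nearby precursors are merged into
clusters (single-linkage, gap <= max_gap inclusive) and intergenic precursors
get closest-neighbour gene distances.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .intervals import (
    ANTISENSE,
    CDS_EXON,
    FIVE_PRIME_UTR,
    INTERGENIC,
    INTRAGENIC,
    INTRON,
    NOT_APPLICABLE,
    SENSE,
    THREE_PRIME_UTR,
    ContextAnnotation,
    GeneModel,
    GenomicInterval,
    MirnaCluster,
    MirnaPrecursor,
    ValidationError,
    gap_bp,
)

NEIGHBOR_MODE_ANY = "any"
NEIGHBOR_MODE_SAME_STRAND_DOWNSTREAM = "same-strand-downstream"


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: List[GeneModel] = list(genes)
        self._trees: Dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.span.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g
            )

    def overlapping(self, iv: GenomicInterval) -> List[GeneModel]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def on_chrom(self, chrom: str) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree]


def _pick_host(precursor: MirnaPrecursor, candidates: Sequence[GeneModel]) -> GeneModel:
    """Deterministic host tie-break: same strand, larger overlap, longest
    transcript, lexicographic gene id."""

    def key(g: GeneModel):
        lt = g.longest_transcript()
        return (
            0 if g.strand == precursor.interval.strand else 1,
            -precursor.interval.overlap_bp(g.span),
            -(lt.exonic_length if lt is not None else 0),
            g.gene_id,
        )

    return min(candidates, key=key)


def _subregion(precursor: MirnaPrecursor, host: GeneModel) -> str:
    """Subregion against the host's longest transcript.

    Any exon overlap (>= 1 bp) makes the call exonic; exonic calls are split
    into UTR5/UTR3/CDS by largest overlap (CDS wins ties; exon overlap with
    no annotated CDS/UTR parts is treated as CDS of a coding host).
    """
    tx = host.longest_transcript()
    if tx is None:
        return INTRON
    iv = precursor.interval
    exon_bp = sum(iv.overlap_bp(e) for e in tx.exons)
    if exon_bp == 0:
        return INTRON
    cds_bp = sum(iv.overlap_bp(p) for p in tx.cds)
    utr5_bp = sum(iv.overlap_bp(p) for p in tx.utr5)
    utr3_bp = sum(iv.overlap_bp(p) for p in tx.utr3)
    best = max(cds_bp, utr5_bp, utr3_bp)
    if best == 0 or cds_bp == best:
        return CDS_EXON
    if utr5_bp == best:
        return FIVE_PRIME_UTR
    return THREE_PRIME_UTR


def classify_context(
    precursor: MirnaPrecursor,
    genes: "GeneIndex | Iterable[GeneModel]",
    neighbor_mode: str = NEIGHBOR_MODE_ANY,
) -> ContextAnnotation:
    """Classify one precursor as inter-/intragenic with orientation and subregion.

    An empty gene set yields an intergenic call with no neighbour (not an
    error). Intergenic calls carry the closest gene under ``neighbor_mode``.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    overlapping = index.overlapping(precursor.interval)
    if overlapping:
        host = _pick_host(precursor, overlapping)
        orientation = SENSE if host.strand == precursor.interval.strand else ANTISENSE
        return ContextAnnotation(
            mirna_id=precursor.mirna_id,
            category=INTRAGENIC,
            orientation=orientation,
            subregion=_subregion(precursor, host),
            host_gene_id=host.gene_id,
        )
    neighbor = nearest_neighbor(precursor, index, mode=neighbor_mode)
    gene_id, dist = neighbor if neighbor is not None else (None, None)
    return ContextAnnotation(
        mirna_id=precursor.mirna_id,
        category=INTERGENIC,
        neighbor_gene_id=gene_id,
        neighbor_distance_bp=dist,
    )


def classify_contexts(
    precursors: Iterable[MirnaPrecursor],
    genes: "GeneIndex | Iterable[GeneModel]",
    neighbor_mode: str = NEIGHBOR_MODE_ANY,
) -> List[ContextAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_context(p, index, neighbor_mode) for p in precursors]


def nearest_neighbor(
    precursor: MirnaPrecursor,
    genes: "GeneIndex | Iterable[GeneModel]",
    mode: str = NEIGHBOR_MODE_ANY,
) -> Optional[Tuple[str, int]]:
    """Closest gene to an intergenic precursor, or None when no gene qualifies.

    Distance is the gap between closest edges (0 if abutting). Mode ``any``
    scans both flanks; ``same-strand-downstream`` keeps genes on the
    precursor's strand lying 3' of it (higher coordinates for ``+``, lower
    for ``-``).
    """
    if mode not in (NEIGHBOR_MODE_ANY, NEIGHBOR_MODE_SAME_STRAND_DOWNSTREAM):
        raise ValidationError(f"unknown neighbor mode {mode!r}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    iv = precursor.interval
    best: Optional[Tuple[str, int]] = None
    for g in index.on_chrom(iv.chrom):
        if mode == NEIGHBOR_MODE_SAME_STRAND_DOWNSTREAM:
            if g.strand != iv.strand:
                continue
            if iv.strand == "+" and g.span.start < iv.end:
                continue
            if iv.strand == "-" and g.span.end > iv.start:
                continue
        d = gap_bp(iv, g.span)
        if best is None or (d, g.gene_id) < (best[1], best[0]):
            best = (g.gene_id, d)
    return best


def cluster_mirnas(
    precursors: Sequence[MirnaPrecursor],
    max_gap_bp: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> List[MirnaCluster]:
    """Merge precursors <= ``max_gap_bp`` apart (inclusive) into clusters.

    Clusters are the connected components of the same-chromosome proximity
    graph, computed by a sorted sweep (equivalent to transitive closure for
    intervals). Each cluster's representative is drawn uniformly with ``rng``.
    """
    if max_gap_bp < 0:
        raise ValidationError("max_gap_bp must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    by_chrom: Dict[str, List[MirnaPrecursor]] = {}
    for p in precursors:
        by_chrom.setdefault(p.interval.chrom, []).append(p)

    clusters: List[MirnaCluster] = []
    n = 0
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.mirna_id))
        current: List[MirnaPrecursor] = []
        reach = None  # rightmost end seen in the open cluster
        for p in group:
            if current and p.interval.start - reach > max_gap_bp:
                clusters.append(_close_cluster(current, n, rng))
                n += 1
                current = []
                reach = None
            current.append(p)
            reach = p.interval.end if reach is None else max(reach, p.interval.end)
        if current:
            clusters.append(_close_cluster(current, n, rng))
            n += 1
    return clusters


def _close_cluster(
    members: Sequence[MirnaPrecursor], idx: int, rng: np.random.Generator
) -> MirnaCluster:
    ids = tuple(p.mirna_id for p in members)
    rep = ids[int(rng.integers(0, len(ids)))]
    return MirnaCluster(cluster_id=f"cluster_{idx:05d}", member_ids=ids, representative_id=rep)
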