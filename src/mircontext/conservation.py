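"""Per-base conservation-score averaging over precursors, seeds and matched
random backgrounds.

Scores come from a bedGraph-style track (runs of constant score); uncovered
bases are excluded from means rather than imputed, and the covered-base count
is reported so callers can filter low-coverage entities. Backgrounds are
equal-length regions drawn from the host's introns (intragenic entities) or
from a +/- 10-kb window purged of gene overlap (intergenic entities).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .context import GeneIndex
from .intervals import ContextAnnotation, GeneModel, GenomicInterval, ValidationError

BACKGROUND_INTRONIC = "intronic"
BACKGROUND_INTERGENIC = "intergenic"
DEFAULT_N_BACKGROUND = 100
DEFAULT_WINDOW_BP = 10_000


class ScoreTrack:
    """Sparse per-base score track with bedGraph semantics.

    Built from non-overlapping (chrom, start, end, score) runs; positions not
    covered by any run have no score.
    """

    def __init__(self, runs: Iterable[Tuple[str, int, int, float]]):
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, score in runs:
            if end <= start:
                raise ValidationError(f"empty run {chrom}:{start}-{end}")
            if not np.isfinite(score):
                raise ValidationError(f"non-finite score at {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(score)))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._scores: Dict[str, np.ndarray] = {}
        for chrom, rr in per_chrom.items():
            rr.sort()
            for (s1, e1, _), (s2, _, _) in zip(rr, rr[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping runs on {chrom} at {s2}")
            arr = np.asarray(rr, dtype=float)
            self._starts[chrom] = arr[:, 0].astype(int)
            self._ends[chrom] = arr[:, 1].astype(int)
            self._scores[chrom] = arr[:, 2]

    def interval_sum(self, chrom: str, start: int, end: int) -> Tuple[float, int]:
        """(sum of per-base scores, number of covered bases) over [start, end)."""
        if chrom not in self._starts:
            return 0.0, 0
        starts, ends, scores = self._starts[chrom], self._ends[chrom], self._scores[chrom]
        i = np.searchsorted(ends, start, side="right")
        j = np.searchsorted(starts, end, side="left")
        if i >= j:
            return 0.0, 0
        s = np.maximum(starts[i:j], start)
        e = np.minimum(ends[i:j], end)
        widths = np.maximum(0, e - s)
        return float(np.dot(widths, scores[i:j])), int(widths.sum())


@dataclass(frozen=True)
class TrackMean:
    mean: Optional[float]
    n_covered: int

    @property
    def defined(self) -> bool:
        return self.n_covered > 0


def mean_track_score(track: ScoreTrack, interval: GenomicInterval) -> TrackMean:
    """Mean score over the covered bases of ``interval``.

    Bases absent from the track are excluded from the mean; zero coverage
    yields an undefined (mean None) result rather than an error.
    """
    total, n = track.interval_sum(interval.chrom, interval.start, interval.end)
    return TrackMean(mean=(total / n if n else None), n_covered=n)


def seed_score(track: ScoreTrack, mature: GenomicInterval) -> float:
    """Mean score over the seed (mature positions 2-8 from the 5' end).

    The 5' end is the low genomic coordinate on '+' and the high one on '-';
    the 7 seed bases are [start+1, start+8) on '+' and [end-8, end-1) on '-'.
    """
    if len(mature) < 8:
        raise ValidationError("mature shorter than 8 nt: no seed")
    if mature.strand == "+":
        seed = GenomicInterval(mature.chrom, mature.start + 1, mature.start + 8, "+")
    else:
        seed = GenomicInterval(mature.chrom, mature.end - 8, mature.end - 1, "-")
    res = mean_track_score(track, seed)
    if not res.defined:
        raise ValidationError("seed region has no covered bases")
    return float(res.mean)


def _intronic_placements(
    entity: GenomicInterval, host: GeneModel
) -> List[Tuple[int, int]]:
    """Valid (start_lo, start_hi_exclusive) ranges for equal-length windows
    inside the host's introns, excluding any overlap with the entity."""
    length = len(entity)
    ranges: List[Tuple[int, int]] = []
    for intron in host.introns():
        pieces = [(intron.start, intron.end)]
        if entity.overlaps(intron):
            pieces = []
            if entity.start > intron.start:
                pieces.append((intron.start, entity.start))
            if entity.end < intron.end:
                pieces.append((entity.end, intron.end))
        for s, e in pieces:
            if e - s >= length:
                ranges.append((s, e - length + 1))
    return ranges


def _intergenic_placements(
    entity: GenomicInterval,
    genes: GeneIndex,
    window_bp: int,
) -> List[Tuple[int, int]]:
    length = len(entity)
    lo = max(0, entity.start - window_bp)
    hi = entity.end + window_bp
    # forbidden: the entity itself plus any overlapping gene span
    forbidden = [(entity.start, entity.end)]
    window = GenomicInterval(entity.chrom, lo, hi, entity.strand)
    for g in genes.overlapping(window):
        forbidden.append((g.span.start, g.span.end))
    forbidden.sort()
    merged: List[Tuple[int, int]] = []
    for s, e in forbidden:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    free: List[Tuple[int, int]] = []
    cursor = lo
    for s, e in merged:
        if s > cursor:
            free.append((cursor, min(s, hi)))
        cursor = max(cursor, e)
        if cursor >= hi:
            break
    if cursor < hi:
        free.append((cursor, hi))
    return [(s, e - length + 1) for s, e in free if e - s >= length]


def background_scores(
    track: ScoreTrack,
    entity: GenomicInterval,
    context: ContextAnnotation,
    genes: "GeneIndex | Iterable[GeneModel]",
    n_samples: int = DEFAULT_N_BACKGROUND,
    window_bp: int = DEFAULT_WINDOW_BP,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Optional[float]], str]:
    """Mean scores of ``n_samples`` random equal-length background regions.

    Intragenic entities sample uniformly from the host's introns (the entity
    itself excluded); intergenic entities sample from the +/- ``window_bp``
    window around the entity, excluding the entity and any gene overlap.
    Sampling is with replacement over all valid placements. Regions with no
    track coverage yield None entries.

    Returns (means, background_kind).
    """
    rng = rng if rng is not None else np.random.default_rng()
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if context.category == "intragenic":
        host = next((g for g in index.genes if g.gene_id == context.host_gene_id), None)
        if host is None:
            raise ValidationError(f"host {context.host_gene_id} not in gene set")
        ranges = _intronic_placements(entity, host)
        kind = BACKGROUND_INTRONIC
        if not ranges:
            raise ValidationError(
                f"{context.mirna_id}: no host intron can hold a {len(entity)}-bp window"
            )
    else:
        ranges = _intergenic_placements(entity, index, window_bp)
        kind = BACKGROUND_INTERGENIC
        if not ranges:
            raise ValidationError(
                f"{context.mirna_id}: no gene-free placement within +/-{window_bp} bp"
            )
    widths = np.array([hi - lo for lo, hi in ranges], dtype=float)
    probs = widths / widths.sum()
    means: List[Optional[float]] = []
    length = len(entity)
    for _ in range(n_samples):
        r = int(rng.choice(len(ranges), p=probs))
        lo, hi = ranges[r]
        start = int(rng.integers(lo, hi))
        res = mean_track_score(
            track, GenomicInterval(entity.chrom, start, start + length, entity.strand)
        )
        means.append(res.mean)
    return means, kind


@dataclass(frozen=True)
class ConservationSummary:
    entity_id: str
    mean_score: Optional[float]
    n_bases_covered: int
    background_means: Tuple[Optional[float], ...]
    background_kind: str
    seed_mean: Optional[float] = None


def summarize_conservation(
    track: ScoreTrack,
    entity_id: str,
    precursor_interval: GenomicInterval,
    context: ContextAnnotation,
    genes: "GeneIndex | Iterable[GeneModel]",
    mature_interval: Optional[GenomicInterval] = None,
    n_samples: int = DEFAULT_N_BACKGROUND,
    window_bp: int = DEFAULT_WINDOW_BP,
    rng: Optional[np.random.Generator] = None,
) -> ConservationSummary:
    """Precursor mean, matched background means and optional seed mean."""
    res = mean_track_score(track, precursor_interval)
    bg, kind = background_scores(
        track, precursor_interval, context, genes, n_samples, window_bp, rng
    )
    seed = None
    if mature_interval is not None and len(mature_interval) >= 8:
        seed = seed_score(track, mature_interval)
    return ConservationSummary(
        entity_id=entity_id,
        mean_score=res.mean,
        n_bases_covered=res.n_covered,
        background_means=tuple(bg),
        background_kind=kind,
        seed_mean=seed,
    )
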