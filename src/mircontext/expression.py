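"""Mature-level read counting, normalization and precursor profile selection.

Counting follows the small-RNA rules used throughout the analysis: a read is
counted for a mature iff it is entirely contained in the mature interval
extended by 3 nt at the mature 3' end (the 5' end is never extended, to
preserve the seed); a read mapping to L loci contributes 1/L at each locus.
Weighted counts are scaled to counts-per-million per sample, samples are
collapsed to tissues by the median, and each precursor is represented by its
most highly expressed mature (median across samples), with identical mature
sequences deduplicated to the oldest precursor and a >= 1 c.p.m. in >= 1
tissue expression filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import MatureMirna, MirnaPrecursor, ValidationError

MATURE_3P_EXTENSION = 3
DEFAULT_CPM_THRESHOLD = 1.0


def extended_interval(m: MatureMirna, extension: int = MATURE_3P_EXTENSION) -> Tuple[int, int]:
    """(start, end) of the mature extended by ``extension`` nt at its 3' end.

    The 3' end is the high coordinate on '+' and the low coordinate on '-'.
    """
    iv = m.interval
    if iv.strand == "+":
        return iv.start, iv.end + extension
    return iv.start - extension, iv.end


def count_mature_reads(
    reads: pd.DataFrame,
    matures: Sequence[Tuple[str, MatureMirna]],
    extension: int = MATURE_3P_EXTENSION,
) -> pd.DataFrame:
    """Weighted read counts per (mature, sample).

    Parameters
    ----------
    reads : DataFrame
        Columns ``chrom, start, end, strand, sample_id, n_loci``; one row per
        mapped locus of a read.
    matures : sequence of (mature_id, MatureMirna)
        The mature annotation; mature ids must be unique.

    Returns
    -------
    DataFrame (rows = mature ids, columns = sample ids) of weighted counts;
    a read locus contributes ``1 / n_loci`` to every mature that fully
    contains it (same chrom and strand, within the 3'-extended interval).
    """
    required = {"chrom", "start", "end", "strand", "sample_id", "n_loci"}
    missing = required - set(reads.columns)
    if missing:
        raise ValidationError(f"read table missing columns {sorted(missing)}")
    if (reads["n_loci"] < 1).any():
        raise ValidationError("n_loci must be >= 1 for every read")

    mature_ids = [mid for mid, _ in matures]
    if len(set(mature_ids)) != len(mature_ids):
        raise ValidationError("duplicate mature ids")
    samples = sorted(reads["sample_id"].unique())
    counts = pd.DataFrame(0.0, index=mature_ids, columns=samples)
    if not len(reads):
        return counts

    sample_pos = {s: j for j, s in enumerate(samples)}
    values = counts.to_numpy()

    by_key: Dict[Tuple[str, str], pd.DataFrame] = {
        k: g for k, g in reads.groupby(["chrom", "strand"], sort=False)
    }
    for i, (mid, m) in enumerate(matures):
        s, e = extended_interval(m, extension)
        g = by_key.get((m.interval.chrom, m.interval.strand))
        if g is None:
            continue
        inside = g[(g["start"].to_numpy() >= s) & (g["end"].to_numpy() <= e)]
        if not len(inside):
            continue
        w = 1.0 / inside["n_loci"].to_numpy(dtype=float)
        cols = inside["sample_id"].map(sample_pos).to_numpy()
        np.add.at(values[i], cols, w)
    return pd.DataFrame(values, index=mature_ids, columns=samples)


def to_cpm(
    raw: pd.DataFrame,
    scale_factors: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Counts-per-million per sample on the weighted library size.

    ``scale_factors`` optionally multiplies each sample's library size
    (hook for externally computed between-sample normalization factors).
    Raises on an all-zero sample, naming it.
    """
    lib = raw.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {', '.join(map(str, zero.index))}")
    if scale_factors is not None:
        lib = lib * pd.Series(scale_factors).reindex(lib.index).fillna(1.0)
    return raw.div(lib, axis=1) * 1e6


def aggregate_tissues(cpm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse sample columns to tissues by the per-tissue median c.p.m.

    ``meta`` has columns ``sample_id, tissue`` (extra columns ignored); every
    c.p.m. column must be present in the metadata.
    """
    mapping = meta.set_index("sample_id")["tissue"]
    unknown = [c for c in cpm.columns if c not in mapping.index]
    if unknown:
        raise ValidationError(f"samples missing from metadata: {unknown}")
    return cpm.T.groupby(mapping.reindex(cpm.columns)).median().T


@dataclass(frozen=True)
class PrecursorProfile:
    """Tissue expression profile of a precursor via its representative mature."""

    mirna_id: str
    mature_id: str
    sequence: Optional[str]
    values: pd.Series  # index = tissues, c.p.m. scale


def select_profiles(
    cpm: pd.DataFrame,
    tissue_profiles: pd.DataFrame,
    precursors: Sequence[MirnaPrecursor],
    ages: Optional[Mapping[str, int]] = None,
    threshold_cpm: float = DEFAULT_CPM_THRESHOLD,
) -> pd.DataFrame:
    """Precursor-level tissue profiles after representative-mature selection,
    family deduplication and the expression threshold.

    Rules, in order:

    1. each precursor is represented by its mature with the highest median
       c.p.m. across samples (ties: higher maximum, then the 5p arm, then
       lexicographic mature id);
    2. precursors whose representative matures share an identical sequence
       collapse to a single record attributed to the oldest precursor
       (smallest branch age in ``ages``; ties lexicographic);
    3. records without >= ``threshold_cpm`` in >= 1 tissue are dropped.

    Returns a DataFrame indexed by precursor id with tissue columns.
    """
    chosen: List[Tuple[str, str, Optional[str]]] = []
    for p in precursors:
        cands = [m for m in p.matures if m.mature_id in cpm.index]
        if not cands:
            continue

        def key(m: MatureMirna):
            row = cpm.loc[m.mature_id]
            is_5p = 0 if m.mature_id.endswith("5p") else 1
            return (-row.median(), -row.max(), is_5p, m.mature_id)

        best = min(cands, key=key)
        chosen.append((p.mirna_id, best.mature_id, best.sequence))

    # family dedup on identical mature sequence -> oldest precursor
    def age_of(mirna_id: str) -> float:
        if ages is None:
            return float("inf")
        a = ages.get(mirna_id)
        return float("inf") if a is None else float(a)

    by_seq: Dict[str, Tuple[str, str, Optional[str]]] = {}
    no_seq: List[Tuple[str, str, Optional[str]]] = []
    for rec in chosen:
        mirna_id, mature_id, seq = rec
        if seq is None:
            no_seq.append(rec)
            continue
        cur = by_seq.get(seq)
        if cur is None or (age_of(mirna_id), mirna_id) < (age_of(cur[0]), cur[0]):
            by_seq[seq] = rec
    final = sorted(by_seq.values()) + sorted(no_seq)

    rows = {}
    for mirna_id, mature_id, _ in final:
        prof = tissue_profiles.loc[mature_id]
        if prof.max() >= threshold_cpm:
            rows[mirna_id] = prof
    out = pd.DataFrame(rows).T
    out.index.name = "mirna_id"
    return out


def quantify(
    reads: pd.DataFrame,
    meta: pd.DataFrame,
    precursors: Sequence[MirnaPrecursor],
    ages: Optional[Mapping[str, int]] = None,
    threshold_cpm: float = DEFAULT_CPM_THRESHOLD,
    scale_factors: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """End-to-end: reads -> weighted counts -> c.p.m. -> tissue medians ->
    precursor profiles (see the individual steps for the rules)."""
    matures = [(m.mature_id, m) for p in precursors for m in p.matures]
    raw = count_mature_reads(reads, matures)
    cpm = to_cpm(raw, scale_factors)
    tissues = aggregate_tissues(cpm, meta)
    return select_profiles(cpm, tissues, precursors, ages, threshold_cpm)
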