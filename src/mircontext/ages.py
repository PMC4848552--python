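"""Phylostratigraphic branch-age assignment for miRNAs and genes.

Per-species, per-method ortholog hit tables are filtered on hit/query length
ratio, reduced to consensus presence calls (two methods with overlapping loci
on the same strand, or adoption of an annotated ortholog covering >= half of
the hit region), and dated on a species tree whose branches are numbered from
the most ancient split (1) to the focal-species-specific branch (B). The age
of an entity is the most ancient branch with a presence call (Dollo parsimony:
lineage losses are allowed silently); an entity present nowhere is assigned
the focal branch B. Origination rates per branch are counts divided by the
time elapsed since the previous split, with a two-sided exact binomial test of
the inter/intragenic split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import math

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, ValidationError

#: age-class binning used throughout: vertebrates, amniotes, placental
#: mammals, primates.
AGE_CLASS_BINS: Tuple[Tuple[int, int, str], ...] = (
    (1, 1, "1"),
    (2, 4, "2-4"),
    (5, 6, "5-6"),
    (7, 12, "7-12"),
)


def age_class(branch_age: int) -> str:
    for lo, hi, label in AGE_CLASS_BINS:
        if lo <= branch_age <= hi:
            return label
    raise ValidationError(f"branch age {branch_age} outside 1-12")


@dataclass(frozen=True)
class SpeciesTree:
    """Branch-ordered species tree with divergence times.

    ``species_branch`` maps query species to the branch (1..n_branches) at
    which their lineage split from the focal species; several species may
    share a branch. ``divergence_myr[k]`` is the split time (Myr) between the
    focal species and branch ``k``; times strictly decrease with branch index
    and the focal branch has time 0.
    """

    n_branches: int
    species_branch: Mapping[str, int]
    divergence_myr: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValidationError("need at least one branch")
        for sp, b in self.species_branch.items():
            if not 1 <= b <= self.n_branches:
                raise ValidationError(f"species {sp} mapped to bad branch {b}")
        times = [self.divergence_myr[k] for k in range(1, self.n_branches + 1)]
        if any(b >= a for a, b in zip(times, times[1:])):
            raise ValidationError("divergence times must strictly decrease with branch")
        if times[-1] != 0:
            raise ValidationError("focal branch divergence time must be 0")

    def branch_of(self, species: str) -> int:
        try:
            return self.species_branch[species]
        except KeyError:
            raise ValidationError(f"unknown species {species!r}") from None

    def elapsed_myr(self, branch: int) -> float:
        """Time elapsed within ``branch``: D(branch-1) - D(branch); NaN for branch 1."""
        if branch == 1:
            return float("nan")
        return self.divergence_myr[branch - 1] - self.divergence_myr[branch]


#: the 13-species, 12-branch vertebrate tree used by the study design
#: (divergence times in Myr, TimeTree-style).
HUMAN_12_BRANCH_TREE = SpeciesTree(
    n_branches=12,
    species_branch={
        "zebrafish": 1,
        "chicken": 2,
        "platypus": 3,
        "opossum": 4,
        "cow": 5,
        "dog": 5,
        "mouse": 6,
        "rat": 6,
        "marmoset": 7,
        "rhesus": 8,
        "orangutan": 9,
        "gorilla": 10,
        "chimpanzee": 11,
    },
    divergence_myr={
        1: 435.0,
        2: 312.0,
        3: 177.0,
        4: 159.0,
        5: 96.0,
        6: 90.0,
        7: 43.0,
        8: 29.0,
        9: 15.7,
        10: 9.0,
        11: 6.6,
        12: 0.0,
    },
)


@dataclass(frozen=True)
class OrthologHit:
    """One method's reciprocal-best hit for a miRNA in one species."""

    mirna_id: str
    species: str
    method: str
    locus: GenomicInterval
    length_ratio: float

    def __post_init__(self) -> None:
        if self.length_ratio <= 0:
            raise ValidationError(f"length_ratio must be > 0, got {self.length_ratio}")


@dataclass(frozen=True)
class OrthologCall:
    """Consensus presence call for (miRNA, species)."""

    mirna_id: str
    species: str
    present: bool
    supporting_methods: tuple = ()
    adopted_annotation: bool = False

    def __post_init__(self) -> None:
        if self.present and len(self.supporting_methods) < 2 and not self.adopted_annotation:
            raise ValidationError(
                f"{self.mirna_id}/{self.species}: presence needs >=2 methods or annotation"
            )


@dataclass(frozen=True)
class AgeAssignment:
    entity_id: str
    branch_age: int
    age_class: str = ""

    def __post_init__(self) -> None:
        expected = age_class(self.branch_age)
        if self.age_class and self.age_class != expected:
            raise ValidationError(
                f"{self.entity_id}: age_class {self.age_class} inconsistent with "
                f"branch {self.branch_age}"
            )
        if not self.age_class:
            object.__setattr__(self, "age_class", expected)


@dataclass(frozen=True)
class OriginationRate:
    branch: int
    n_inter: int
    n_intra: int
    elapsed_myr: float
    rate_inter: float
    rate_intra: float
    binomial_p: float


RATIO_MIN = 0.70
RATIO_MAX = 1.30
ANNOTATION_MIN_OVERLAP = 0.50


def call_orthologs(
    hits: pd.DataFrame,
    annotated_orthologs: Optional[pd.DataFrame] = None,
    tree: Optional[SpeciesTree] = None,
    ratio_min: float = RATIO_MIN,
    ratio_max: float = RATIO_MAX,
    annotation_min_overlap: float = ANNOTATION_MIN_OVERLAP,
) -> pd.DataFrame:
    """Reduce per-method hits to consensus presence calls.

    Parameters
    ----------
    hits : DataFrame
        Columns ``mirna_id, species, method, chrom, start, end, strand,
        length_ratio``; one row per retained reciprocal-best hit.
    annotated_orthologs : DataFrame, optional
        Per-species miRNA annotations (``species, chrom, start, end, strand``).
        A retained hit overlapping an annotation on the same strand over at
        least ``annotation_min_overlap`` of the hit's length marks the call
        present with ``adopted_annotation``.
    tree : SpeciesTree, optional
        When given, species names are validated against the tree.

    Returns
    -------
    DataFrame with one row per (mirna_id, species) observed in ``hits``:
    ``mirna_id, species, present, n_methods, methods, adopted_annotation``.

    Notes
    -----
    Hits with length ratio outside ``[ratio_min, ratio_max]`` (inclusive) are
    discarded first; presence requires two distinct methods whose loci overlap
    >= 1 bp on the same strand, unless an annotation is adopted. A species is
    present if any locus passes the consensus.
    """
    required = {"mirna_id", "species", "method", "chrom", "start", "end", "strand", "length_ratio"}
    missing = required - set(hits.columns)
    if missing:
        raise ValidationError(f"hit table missing columns {sorted(missing)}")
    if tree is not None:
        unknown = set(hits["species"].unique()) - set(tree.species_branch)
        if unknown:
            raise ValidationError(f"unknown species in hit table: {sorted(unknown)}")

    kept = hits[(hits["length_ratio"] >= ratio_min) & (hits["length_ratio"] <= ratio_max)]

    # annotation lookup: per (species, chrom, strand), start-sorted arrays
    # probed through a bisect window bounded by the longest annotation
    ann_index: Dict[Tuple[str, str, str], Tuple[np.ndarray, np.ndarray, int]] = {}
    if annotated_orthologs is not None and len(annotated_orthologs):
        tmp: Dict[Tuple[str, str, str], List[Tuple[int, int]]] = {}
        for row in annotated_orthologs.itertuples(index=False):
            key = (row.species, row.chrom, row.strand)
            tmp.setdefault(key, []).append((int(row.start), int(row.end)))
        for key, ivs in tmp.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            ann_index[key] = (starts, ends, int((ends - starts).max()))

    records = []
    group_keys = hits[["mirna_id", "species"]].drop_duplicates()
    kept_groups = {k: g for k, g in kept.groupby(["mirna_id", "species"], sort=False)}
    for mirna_id, species in group_keys.itertuples(index=False):
        g = kept_groups.get((mirna_id, species))
        present = False
        methods: tuple = ()
        adopted = False
        if g is not None and len(g):
            rows = list(g.itertuples(index=False))
            # two-method consensus: loci from distinct methods overlapping on
            # the same strand
            support = set()
            for i, a in enumerate(rows):
                for b in rows[i + 1:]:
                    if a.method == b.method or a.strand != b.strand or a.chrom != b.chrom:
                        continue
                    if min(a.end, b.end) - max(a.start, b.start) > 0:
                        support.update((a.method, b.method))
            if len(support) >= 2:
                present = True
                methods = tuple(sorted(support))
            # annotated-ortholog adoption on any retained hit
            for r in rows:
                entry = ann_index.get((species, r.chrom, r.strand))
                if entry is None:
                    continue
                starts, ends, max_len = entry
                i0 = int(np.searchsorted(starts, r.start - max_len, side="left"))
                i1 = int(np.searchsorted(starts, r.end, side="left"))
                for j in range(i0, i1):
                    ov = min(ends[j], r.end) - max(starts[j], r.start)
                    if ov >= annotation_min_overlap * (r.end - r.start):
                        adopted = True
                        present = True
                        break
                if adopted:
                    break
        records.append(
            {
                "mirna_id": mirna_id,
                "species": species,
                "present": present,
                "n_methods": len(methods),
                "methods": ",".join(methods),
                "adopted_annotation": adopted,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["mirna_id", "species", "present", "n_methods", "methods", "adopted_annotation"]
    )


def assign_ages(
    calls: pd.DataFrame,
    tree: SpeciesTree,
    all_mirna_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Date each miRNA at the most ancient branch with a presence call.

    ``calls`` has columns ``mirna_id, species, present``. miRNAs in
    ``all_mirna_ids`` with no presence anywhere (or no calls at all) are
    assigned the focal branch ``tree.n_branches``.

    Returns a DataFrame ``entity_id, branch_age, age_class``.
    """
    ages: Dict[str, int] = {}
    if len(calls):
        present = calls[calls["present"].astype(bool)]
        for row in present.itertuples(index=False):
            b = tree.branch_of(row.species)
            cur = ages.get(row.mirna_id)
            ages[row.mirna_id] = b if cur is None else min(cur, b)
    ids = list(all_mirna_ids) if all_mirna_ids is not None else sorted(
        set(calls["mirna_id"]) if len(calls) else []
    )
    for mid in ids:
        ages.setdefault(mid, tree.n_branches)
    out = pd.DataFrame(
        {
            "entity_id": list(ages.keys()),
            "branch_age": [ages[k] for k in ages],
        }
    )
    out["age_class"] = out["branch_age"].map(age_class)
    return out.sort_values("entity_id", ignore_index=True)


def reconcile_pairs(
    mirna_ages: pd.DataFrame,
    gene_ages: pd.DataFrame,
    contexts: pd.DataFrame,
) -> Tuple[pd.DataFrame, int]:
    """Build the (miRNA, host) age pair table, dropping inconsistent pairs.

    A host must predate (or co-date) its miRNA: pairs where the host branch
    age is numerically greater (nominally younger) than the miRNA's are
    removed. Equal ages are retained.

    Parameters
    ----------
    mirna_ages, gene_ages : DataFrames with ``entity_id``/``gene_id`` and
        ``branch_age``.
    contexts : context table with ``mirna_id, category, orientation,
        host_gene_id`` (only sense intragenic rows are paired).

    Returns
    -------
    (pairs, n_removed) where pairs has columns ``mirna_id, host_gene_id,
    mirna_age, host_age``.
    """
    intra = contexts[
        (contexts["category"] == "intragenic") & (contexts["orientation"] == "sense")
    ][["mirna_id", "host_gene_id"]]
    m = intra.merge(
        mirna_ages.rename(columns={"entity_id": "mirna_id", "branch_age": "mirna_age"}),
        on="mirna_id",
        how="inner",
    ).merge(
        gene_ages.rename(columns={"gene_id": "host_gene_id", "branch_age": "host_age"})[
            ["host_gene_id", "host_age"]
        ],
        on="host_gene_id",
        how="inner",
    )
    bad = m["host_age"] > m["mirna_age"]
    return m[~bad].reset_index(drop=True), int(bad.sum())


def binomial_two_sided_p(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial P (small-mass method, as in binomtest)."""
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def origination_stats(
    age_table: pd.DataFrame,
    tree: SpeciesTree,
    p0: float = 0.5,
) -> pd.DataFrame:
    """Per-branch inter/intragenic origination counts, per-Myr rates and a
    two-sided binomial test of the split against ``p0``.

    ``age_table`` has columns ``branch_age`` and ``category`` ("intergenic" /
    "intragenic"). The rate in branch k is count / (D(k-1) - D(k)); branch 1
    has no preceding split, so its elapsed time and rates are NaN.
    """
    if not 0 < p0 < 1:
        raise ValidationError("p0 must be in (0,1)")
    rows = []
    for branch in range(1, tree.n_branches + 1):
        sub = age_table[age_table["branch_age"] == branch]
        n_inter = int((sub["category"] == "intergenic").sum())
        n_intra = int((sub["category"] == "intragenic").sum())
        elapsed = tree.elapsed_myr(branch)
        if elapsed is not None and not math.isnan(elapsed) and elapsed <= 0:
            raise ValidationError(f"non-positive elapsed time in branch {branch}")
        if math.isnan(elapsed):
            r_inter = r_intra = float("nan")
        else:
            r_inter = n_inter / elapsed
            r_intra = n_intra / elapsed
        n_tot = n_inter + n_intra
        p = binomial_two_sided_p(n_inter, n_tot, p0) if n_tot > 0 else float("nan")
        rows.append(
            OriginationRate(
                branch=branch,
                n_inter=n_inter,
                n_intra=n_intra,
                elapsed_myr=elapsed,
                rate_inter=r_inter,
                rate_intra=r_intra,
                binomial_p=p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
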