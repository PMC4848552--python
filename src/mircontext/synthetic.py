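"""Synthetic input generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a linear genome of
multi-exon protein-coding genes with branch ages (old genes longer), miRNA
precursors placed intergenically or inside host introns with a planted
old-host bias, per-species per-method ortholog hit tables implying the
planted branch ages, tissue expression with age/host-dependent breadth and
optional miRNA-host co-expression, and a conservation score track with
age-class-dependent precursor means over a flat background.

Everything is deterministic under a fixed seed: one master seed fans out to
per-stage streams, so regenerating any one output never shifts another's
randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ages import HUMAN_12_BRANCH_TREE, SpeciesTree, age_class
from .intervals import (
    GeneModel,
    GenomicInterval,
    MatureMirna,
    MirnaPrecursor,
    Transcript,
    ValidationError,
)

CROSS_SPECIES_TISSUES = ("brain", "cerebellum", "heart", "kidney", "testis")
DEFAULT_TISSUES = CROSS_SPECIES_TISSUES + (
    "liver",
    "lung",
    "muscle",
    "spleen",
    "ovary",
    "placenta",
    "skin",
)

_STAGE_ANNOTATION = 0
_STAGE_HITS = 1
_STAGE_EXPRESSION = 2
_STAGE_TRACK = 3


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic inputs.

    Defaults encode the analysed data set's structure: ~61% intragenic
    miRNAs, ~84% of those in sense orientation, ~83% of hosts on the oldest
    branch, a miRNA age distribution concentrated in primates (~70% in
    branches 7-12, modes at 7-8) with ~85% after the placental split, and a
    12-tissue human panel containing the 5-tissue cross-species panel.
    """

    seed: int = 0
    n_chromosomes: int = 4
    n_genes: int = 400
    n_mirnas: int = 300
    fraction_intragenic: float = 0.61
    sense_fraction: float = 0.84
    host_age_bias: float = 0.83
    gene_age_probs: Tuple[float, ...] = (
        0.60, 0.08, 0.05, 0.05, 0.05, 0.05, 0.04, 0.03, 0.02, 0.01, 0.01, 0.01,
    )
    mirna_age_probs: Tuple[float, ...] = (
        0.08, 0.02, 0.02, 0.03, 0.04, 0.06, 0.25, 0.25, 0.08, 0.06, 0.06, 0.05,
    )
    # ortholog-hit emulation
    methods: Tuple[str, ...] = ("m1", "m2", "m3")
    detection_prob: float = 0.9
    ratio_noise_sd: float = 0.05
    false_positive_prob: float = 0.0
    annotated_fraction: float = 0.15
    # gene structure
    exon_length: int = 150
    utr_length: int = 50
    n_exons_range: Tuple[int, int] = (4, 7)
    intron_length_range: Tuple[int, int] = (1_200, 3_000)
    old_gene_length_factor: float = 1.6
    intergenic_gap_range: Tuple[int, int] = (6_000, 14_000)
    precursor_length: int = 80
    mature_length: int = 22
    family_fraction: float = 0.05
    # expression
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    n_samples_per_tissue: int = 2
    alpha_broad: float = 2.0
    alpha_narrow: float = 0.15
    coexpression_weight: float = 0.7
    mean_reads_per_mirna_sample: float = 60.0
    level_sigma: float = 0.6
    multimapper_fraction: float = 0.1
    gene_fpkm_mean: float = 20.0
    # conservation
    cons_mean_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"1": 2.0, "2-4": 1.5, "5-6": 1.0, "7-12": 0.5}
    )
    cons_background_mean: float = 0.0
    cons_sd: float = 0.3
    cons_run_length: int = 100

    def __post_init__(self) -> None:
        for name in ("fraction_intragenic", "sense_fraction", "host_age_bias",
                     "detection_prob", "false_positive_prob", "annotated_fraction",
                     "family_fraction", "multimapper_fraction", "coexpression_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        for name in ("gene_age_probs", "mirna_age_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size != 12 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValidationError(f"{name} must be a 12-way distribution summing to 1")
        if len(self.tissues) < 5 or any(t not in self.tissues for t in CROSS_SPECIES_TISSUES):
            raise ValidationError(
                f"tissue panel must contain the cross-species panel {CROSS_SPECIES_TISSUES}"
            )

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class SyntheticTruth:
    """Planted ground truth consistent with the emitted files."""

    genes: pd.DataFrame       # gene_id, chrom, start, end, strand, branch_age
    mirnas: pd.DataFrame      # mirna_id, chrom, start, end, strand, category,
                              # orientation, host_gene_id, branch_age, broad, cons_mean
    gene_profiles: Optional[pd.DataFrame] = None   # genes x tissues, expected FPKM
    mirna_profiles: Optional[pd.DataFrame] = None  # mirnas x tissues, expected share

    def to_json(self, path: str) -> None:
        doc = {
            "genes": self.genes.to_dict(orient="list"),
            "mirnas": self.mirnas.to_dict(orient="list"),
            "gene_profiles": None
            if self.gene_profiles is None
            else {
                "index": list(self.gene_profiles.index),
                "columns": list(self.gene_profiles.columns),
                "values": self.gene_profiles.to_numpy().tolist(),
            },
            "mirna_profiles": None
            if self.mirna_profiles is None
            else {
                "index": list(self.mirna_profiles.index),
                "columns": list(self.mirna_profiles.columns),
                "values": self.mirna_profiles.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)

        def frame(key):
            d = doc.get(key)
            if d is None:
                return None
            return pd.DataFrame(d["values"], index=d["index"], columns=d["columns"])

        return cls(
            genes=pd.DataFrame(doc["genes"]),
            mirnas=pd.DataFrame(doc["mirnas"]),
            gene_profiles=frame("gene_profiles"),
            mirna_profiles=frame("mirna_profiles"),
        )


# ---------------------------------------------------------------------------
# annotation


def _build_gene(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    branch_age: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> GeneModel:
    n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
    factor = cfg.old_gene_length_factor if branch_age == 1 else 1.0
    lo, hi = cfg.intron_length_range
    intron_lens = (rng.integers(lo, hi + 1, size=n_exons - 1) * factor).astype(int)
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + cfg.exon_length, strand))
        if i < n_exons - 1:
            pos += cfg.exon_length + int(intron_lens[i])
        else:
            pos += cfg.exon_length
    span = GenomicInterval(chrom, start, pos, strand)
    # CDS/UTR split of the terminal exons (strand-aware)
    first, last = exons[0], exons[-1]
    u = cfg.utr_length
    if strand == "+":
        utr5 = (GenomicInterval(chrom, first.start, first.start + u, strand),)
        utr3 = (GenomicInterval(chrom, last.end - u, last.end, strand),)
    else:
        utr5 = (GenomicInterval(chrom, last.end - u, last.end, strand),)
        utr3 = (GenomicInterval(chrom, first.start, first.start + u, strand),)
    cds = []
    for i, e in enumerate(exons):
        s, en = e.start, e.end
        for piece in utr5 + utr3:
            if piece.start <= s < piece.end:
                s = piece.end
            if piece.start < en <= piece.end:
                en = piece.start
        if s < en:
            cds.append(GenomicInterval(chrom, s, en, strand))
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        exons=tuple(exons),
        cds=tuple(cds),
        utr5=utr5,
        utr3=utr3,
    )
    return GeneModel(gene_id=gene_id, span=span, transcripts=(tx,), gene_age=branch_age)


def generate_annotation(
    cfg: GeneratorConfig,
) -> Tuple[List[GeneModel], List[MirnaPrecursor], pd.DataFrame, SyntheticTruth]:
    """Genome annotation with planted gene/miRNA ages and contexts.

    Returns (genes, precursors, gene-age table, truth). Intragenic miRNAs
    land in a random intron of a host whose branch age is 1 with probability
    ``host_age_bias`` and otherwise uniform on {2..a} for a miRNA of planted
    age a (hosts are always as old or older than their miRNAs); age-1 miRNAs
    always get age-1 hosts.
    """
    rng = cfg.stage_rng(_STAGE_ANNOTATION)
    branches = np.arange(1, 13)
    gene_ages = rng.choice(branches, size=cfg.n_genes, p=cfg.gene_age_probs)

    genes: List[GeneModel] = []
    cursor = {f"chr{i + 1}": 10_000 for i in range(cfg.n_chromosomes)}
    for i in range(cfg.n_genes):
        chrom = f"chr{(i % cfg.n_chromosomes) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        g = _build_gene(
            f"gene{i:05d}", chrom, cursor[chrom], strand, int(gene_ages[i]), cfg, rng
        )
        genes.append(g)
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        cursor[chrom] = g.span.end + gap

    by_age: Dict[int, List[GeneModel]] = {}
    for g in genes:
        by_age.setdefault(g.gene_age, []).append(g)
    if cfg.n_mirnas > 0 and cfg.fraction_intragenic > 0 and 1 not in by_age:
        raise ValidationError("no age-1 genes generated; enlarge n_genes or gene_age_probs[0]")

    mirna_ages = rng.choice(branches, size=cfg.n_mirnas, p=cfg.mirna_age_probs)
    precursors: List[MirnaPrecursor] = []
    rows = []
    plen = cfg.precursor_length
    # intergenic placements draw from mid-gap positions after the genes laid
    # on each chromosome
    for i in range(cfg.n_mirnas):
        mid = f"mir{i:05d}"
        a = int(mirna_ages[i])
        intragenic = rng.random() < cfg.fraction_intragenic
        if intragenic:
            if a == 1 or rng.random() < cfg.host_age_bias:
                host_pool = by_age[1]
            else:
                young_ages = [b for b in range(2, a + 1) if b in by_age]
                host_pool = by_age[int(rng.choice(young_ages))] if young_ages else by_age[1]
            host = host_pool[int(rng.integers(0, len(host_pool)))]
            introns = host.introns()
            introns = [iv for iv in introns if len(iv) >= plen + 40]
            if not introns:
                raise ValidationError(f"host {host.gene_id} has no intron able to hold a precursor")
            intron = introns[int(rng.integers(0, len(introns)))]
            start = int(rng.integers(intron.start + 20, intron.end - plen - 20 + 1))
            sense = rng.random() < cfg.sense_fraction
            strand = host.strand if sense else ("-" if host.strand == "+" else "+")
            chrom = host.span.chrom
            host_id = host.gene_id
            category, orientation = "intragenic", ("sense" if sense else "antisense")
        else:
            chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
            # place beyond the last gene on the chromosome, inside its own slot
            start = cursor[chrom] + 2_000
            cursor[chrom] = start + plen + int(rng.integers(*cfg.intergenic_gap_range))
            strand = "+" if rng.random() < 0.5 else "-"
            host_id = None
            category, orientation = "intergenic", "not-applicable"
        iv = GenomicInterval(chrom, start, start + plen, strand)
        seq5 = "".join(rng.choice(list("ACGU"), size=cfg.mature_length))
        seq3 = "".join(rng.choice(list("ACGU"), size=cfg.mature_length))
        matures = (
            MatureMirna(f"{mid}-5p", GenomicInterval(chrom, start + 10, start + 10 + cfg.mature_length, strand), seq5),
            MatureMirna(f"{mid}-3p", GenomicInterval(chrom, start + plen - 10 - cfg.mature_length, start + plen - 10, strand), seq3),
        )
        precursors.append(MirnaPrecursor(mirna_id=mid, interval=iv, matures=matures))
        host_age = next(g.gene_age for g in genes if g.gene_id == host_id) if host_id else None
        broad = (a <= 6) or (category == "intragenic" and orientation == "sense" and host_age == 1)
        rows.append(
            {
                "mirna_id": mid,
                "chrom": chrom,
                "start": start,
                "end": start + plen,
                "strand": strand,
                "category": category,
                "orientation": orientation,
                "host_gene_id": host_id,
                "host_age": host_age,
                "branch_age": a,
                "age_class": age_class(a),
                "broad": bool(broad),
                "cons_mean": float(cfg.cons_mean_by_class[age_class(a)]),
            }
        )

    # plant identical-mature families: a late miRNA copies an earlier one's 5p
    mirna_df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "chrom", "start", "end", "strand", "category", "orientation",
            "host_gene_id", "host_age", "branch_age", "age_class", "broad", "cons_mean",
        ],
    )
    if cfg.n_mirnas >= 2 and cfg.family_fraction > 0:
        n_fam = int(round(cfg.family_fraction * cfg.n_mirnas))
        for j in rng.choice(cfg.n_mirnas, size=n_fam, replace=False):
            k = int(rng.integers(0, cfg.n_mirnas))
            if k == j:
                continue
            donor = precursors[k].matures[0]
            p = precursors[j]
            precursors[j] = MirnaPrecursor(
                mirna_id=p.mirna_id,
                interval=p.interval,
                matures=(
                    MatureMirna(p.matures[0].mature_id, p.matures[0].interval, donor.sequence),
                    p.matures[1],
                ),
            )

    gene_rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.span.chrom,
            "start": g.span.start,
            "end": g.span.end,
            "strand": g.span.strand,
            "branch_age": g.gene_age,
        }
        for g in genes
    ]
    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "branch_age"]
    )
    gene_age_table = genes_df[["gene_id", "branch_age"]].copy()
    truth = SyntheticTruth(genes=genes_df, mirnas=mirna_df)
    return genes, precursors, gene_age_table, truth


# ---------------------------------------------------------------------------
# ortholog hits


def generate_ortholog_hits(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    tree: SpeciesTree = HUMAN_12_BRANCH_TREE,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species per-method hit tables implying the planted ages.

    Species whose branch is >= the miRNA's planted age receive a hit from
    each method independently with ``detection_prob``; all methods hit the
    same locus, so surviving pairs overlap. Length ratios are
    Normal(1, ratio_noise_sd) truncated positive (ratios straying outside
    [0.70, 1.30] are the noise the filter is meant to remove). With
    ``false_positive_prob`` 0 (default) no species below the planted age is
    ever hit, so recovered ages can only be equal to or younger than planted.

    Returns (hits, annotated_orthologs).
    """
    rng = cfg.stage_rng(_STAGE_HITS)
    hit_rows = []
    ann_rows = []
    species_items = sorted(tree.species_branch.items())
    plen = cfg.precursor_length
    for idx, row in enumerate(truth.mirnas.itertuples(index=False)):
        for species, branch in species_items:
            eligible = branch >= row.branch_age
            if not eligible and not (
                cfg.false_positive_prob > 0 and rng.random() < cfg.false_positive_prob
            ):
                continue
            locus_start = 1_000_000 + idx * 1_000
            chrom = f"{species}_chr1"
            detected = []
            for method in cfg.methods:
                if rng.random() < cfg.detection_prob:
                    ratio = float(max(0.05, rng.normal(1.0, cfg.ratio_noise_sd)))
                    jitter = int(rng.integers(0, 6))
                    length = max(10, int(round(plen * ratio)))
                    hit_rows.append(
                        {
                            "mirna_id": row.mirna_id,
                            "species": species,
                            "method": method,
                            "chrom": chrom,
                            "start": locus_start + jitter,
                            "end": locus_start + jitter + length,
                            "strand": "+",
                            "length_ratio": ratio,
                        }
                    )
                    detected.append(method)
            if detected and rng.random() < cfg.annotated_fraction:
                ann_rows.append(
                    {
                        "species": species,
                        "chrom": chrom,
                        "start": locus_start,
                        "end": locus_start + plen,
                        "strand": "+",
                    }
                )
    hits = pd.DataFrame(
        hit_rows,
        columns=["mirna_id", "species", "method", "chrom", "start", "end", "strand", "length_ratio"],
    )
    annotated = pd.DataFrame(ann_rows, columns=["species", "chrom", "start", "end", "strand"])
    return hits, annotated


# ---------------------------------------------------------------------------
# expression


def generate_expression_data(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    precursors: Optional[Sequence[MirnaPrecursor]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Reads, sample metadata and coding-gene expression with planted
    breadth/co-expression structure.

    Expected tissue profiles are Dirichlet draws whose concentration encodes
    the planted breadth class (``alpha_broad`` for broad entities,
    ``alpha_narrow`` for narrow); sense intragenic miRNA profiles are mixed
    with their host's profile by ``coexpression_weight``. Read counts per
    (mature, sample) are Poisson around the expected profile scaled by a
    log-normal level; the dominant arm takes 80% of a precursor's reads.
    A ``multimapper_fraction`` of reads is emitted at 2 loci with n_loci=2.

    Returns (reads, sample_meta, gene_expression, truth) with the expected
    profiles attached to the truth object.
    """
    rng = cfg.stage_rng(_STAGE_EXPRESSION)
    tissues = list(cfg.tissues)
    T = len(tissues)

    # coding genes: expected FPKM profiles (old genes broad)
    gene_ids = list(truth.genes["gene_id"])
    g_alpha = np.where(truth.genes["branch_age"].to_numpy() == 1, cfg.alpha_broad, cfg.alpha_narrow)
    gene_profiles = np.vstack(
        [rng.dirichlet(np.full(T, a)) for a in g_alpha]
    ) if gene_ids else np.zeros((0, T))
    gene_levels = rng.lognormal(mean=np.log(cfg.gene_fpkm_mean), sigma=cfg.level_sigma, size=len(gene_ids))
    gene_fpkm = gene_profiles * gene_levels[:, None] * T
    gene_profiles_df = pd.DataFrame(gene_fpkm, index=gene_ids, columns=tissues)
    gene_expr_rows = gene_profiles_df.reset_index(names="gene_id").melt(
        id_vars="gene_id", var_name="tissue", value_name="fpkm"
    )
    gene_expr_rows["expressed"] = gene_expr_rows["fpkm"] > 1.0

    # samples
    meta_rows = []
    for t in tissues:
        for r in range(cfg.n_samples_per_tissue):
            meta_rows.append(
                {"sample_id": f"{t}_s{r + 1}", "tissue": t, "study_id": f"study{(r % 2) + 1}"}
            )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "tissue", "study_id"])

    # miRNA expected profiles
    mirna_ids = list(truth.mirnas["mirna_id"])
    shares = np.zeros((len(mirna_ids), T))
    host_share = gene_profiles_df.div(gene_profiles_df.sum(axis=1), axis=0) if gene_ids else None
    for i, row in enumerate(truth.mirnas.itertuples(index=False)):
        alpha = cfg.alpha_broad if row.broad else cfg.alpha_narrow
        own = rng.dirichlet(np.full(T, alpha))
        if (
            row.category == "intragenic"
            and row.orientation == "sense"
            and cfg.coexpression_weight > 0
            and host_share is not None
        ):
            h = host_share.loc[row.host_gene_id].to_numpy()
            own = cfg.coexpression_weight * h + (1.0 - cfg.coexpression_weight) * own
        shares[i] = own
    mirna_profiles_df = pd.DataFrame(shares, index=mirna_ids, columns=tissues)

    # read records
    pre_by_id = {p.mirna_id: p for p in (precursors or ())}
    levels = rng.lognormal(
        mean=np.log(max(cfg.mean_reads_per_mirna_sample, 1e-9)),
        sigma=cfg.level_sigma,
        size=len(mirna_ids),
    )
    read_rows: List[tuple] = []
    mirna_meta = list(truth.mirnas.itertuples(index=False))
    for i, row in enumerate(mirna_meta):
        p = pre_by_id.get(row.mirna_id)
        if p is None:
            continue
        dominant = 0 if rng.random() < 0.5 else 1
        lam = shares[i] * levels[i]  # expected reads per tissue, summing to the level
        for m_idx, m in enumerate(p.matures):
            arm_frac = 0.8 if m_idx == dominant else 0.2
            iv = m.interval
            for t_idx, t in enumerate(tissues):
                for r in range(cfg.n_samples_per_tissue):
                    c = int(rng.poisson(lam[t_idx] * arm_frac))
                    if c == 0:
                        continue
                    ext = rng.integers(0, 4, size=c)  # 3' extension jitter, <= 3 nt
                    multi = rng.random(c) < cfg.multimapper_fraction
                    sample = f"{t}_s{r + 1}"
                    for ci in range(c):
                        if iv.strand == "+":
                            s, e = iv.start, iv.end + int(ext[ci])
                        else:
                            s, e = iv.start - int(ext[ci]), iv.end
                        n_loci = 2 if multi[ci] else 1
                        read_rows.append((iv.chrom, s, e, iv.strand, sample, n_loci))
                        if n_loci == 2:
                            # second locus inside another random mature
                            other = mirna_meta[int(rng.integers(0, len(mirna_meta)))]
                            op = pre_by_id.get(other.mirna_id)
                            if op is None:
                                read_rows[-1] = (iv.chrom, s, e, iv.strand, sample, 1)
                                continue
                            om = op.matures[int(rng.integers(0, len(op.matures)))].interval
                            read_rows.append(
                                (om.chrom, om.start, om.end, om.strand, sample, 2)
                            )
    reads = pd.DataFrame(
        read_rows, columns=["chrom", "start", "end", "strand", "sample_id", "n_loci"]
    )
    out_truth = SyntheticTruth(
        genes=truth.genes,
        mirnas=truth.mirnas,
        gene_profiles=gene_profiles_df,
        mirna_profiles=mirna_profiles_df,
    )
    return reads, meta, gene_expr_rows, out_truth


# ---------------------------------------------------------------------------
# conservation track


def generate_score_track(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    genome_extent: Optional[Mapping[str, int]] = None,
) -> List[Tuple[str, int, int, float]]:
    """bedGraph runs: background Normal(background mean, sd) everywhere,
    precursor bases Normal(planted mean by age class, sd).

    Runs are ``cons_run_length`` bp in the background and 20 bp inside
    precursors (finer so per-precursor means average several independent
    values).
    """
    rng = cfg.stage_rng(_STAGE_TRACK)
    entities: Dict[str, List[Tuple[int, int, float]]] = {}
    extent: Dict[str, int] = dict(genome_extent or {})
    for row in truth.mirnas.itertuples(index=False):
        entities.setdefault(row.chrom, []).append((int(row.start), int(row.end), float(row.cons_mean)))
        extent[row.chrom] = max(extent.get(row.chrom, 0), int(row.end) + 15_000)
    for row in truth.genes.itertuples(index=False):
        extent[row.chrom] = max(extent.get(row.chrom, 0), int(row.end) + 15_000)

    runs: List[Tuple[str, int, int, float]] = []
    bg_len = cfg.cons_run_length
    for chrom in sorted(extent):
        stops = sorted(entities.get(chrom, []))
        cursor = 0
        chrom_end = extent[chrom]

        def emit(lo: int, hi: int, mean: float, step: int) -> None:
            pos = lo
            while pos < hi:
                nxt = min(pos + step, hi)
                runs.append((chrom, pos, nxt, float(rng.normal(mean, cfg.cons_sd))))
                pos = nxt

        for s, e, mean in stops:
            s = max(s, cursor)  # clip rare overlapping precursors
            if s >= e:
                continue
            if s > cursor:
                emit(cursor, s, cfg.cons_background_mean, bg_len)
            emit(s, e, mean, 20)
            cursor = e
        if cursor < chrom_end:
            emit(cursor, chrom_end, cfg.cons_background_mean, bg_len)
    return runs


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(cfg: GeneratorConfig, outdir: str) -> Dict[str, str]:
    """Generate the complete input bundle plus truth JSON into ``outdir``.

    Emits the exact dialects the pipeline readers consume; returns a name ->
    path map.
    """
    import os

    from . import io as mio

    os.makedirs(outdir, exist_ok=True)
    genes, precursors, gene_age_table, truth = generate_annotation(cfg)
    hits, annotated = generate_ortholog_hits(truth, cfg)
    reads, meta, gene_expr, truth = generate_expression_data(truth, cfg, precursors)
    runs = generate_score_track(truth, cfg)

    paths = {
        "genes_gff3": os.path.join(outdir, "genes.gff3"),
        "precursor_bed": os.path.join(outdir, "precursors.bed"),
        "mature_bed": os.path.join(outdir, "matures.bed"),
        "gene_ages_tsv": os.path.join(outdir, "gene_ages.tsv"),
        "hits_tsv": os.path.join(outdir, "ortholog_hits.tsv"),
        "annotated_orthologs_tsv": os.path.join(outdir, "annotated_orthologs.tsv"),
        "reads_tsv": os.path.join(outdir, "reads.tsv"),
        "samples_tsv": os.path.join(outdir, "samples.tsv"),
        "gene_expression_tsv": os.path.join(outdir, "gene_expression.tsv"),
        "track_bedgraph": os.path.join(outdir, "conservation.bedgraph"),
        "species_tree_yaml": os.path.join(outdir, "species_tree.yaml"),
        "truth_json": os.path.join(outdir, "truth.json"),
    }
    mio.write_gff3_genes(genes, paths["genes_gff3"])
    mio.write_precursors(precursors, paths["precursor_bed"], paths["mature_bed"])
    mio.write_tsv(gene_age_table, paths["gene_ages_tsv"])
    mio.write_tsv(hits, paths["hits_tsv"])
    mio.write_tsv(annotated, paths["annotated_orthologs_tsv"])
    mio.write_tsv(reads, paths["reads_tsv"])
    mio.write_tsv(meta, paths["samples_tsv"])
    mio.write_tsv(gene_expr, paths["gene_expression_tsv"])
    mio.write_bedgraph(runs, paths["track_bedgraph"])
    mio.write_species_tree(HUMAN_12_BRANCH_TREE, paths["species_tree_yaml"])
    truth.to_json(paths["truth_json"])
    return paths
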