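"""Readers and writers for the pipeline's file dialects.

GFF3 (1-based inclusive) is converted to the internal 0-based half-open
convention on read; BED and bedGraph are consumed natively. Tables are plain
TSV throughout.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
import yaml

from .ages import SpeciesTree
from .conservation import ScoreTrack
from .intervals import (
    GeneModel,
    GenomicInterval,
    MatureMirna,
    MirnaPrecursor,
    Transcript,
    ValidationError,
)

# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_genes(path: str) -> List[GeneModel]:
    """Load gene models (gene / mRNA / exon / CDS / five|three_prime_UTR)."""
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        strand = g.strand if g.strand in "+-" else "+"
        span = GenomicInterval(g.seqid, g.start - 1, g.end, strand)
        transcripts = []
        for tx in db.children(g, featuretype="mRNA"):
            def parts(ft: str) -> tuple:
                return tuple(
                    GenomicInterval(f.seqid, f.start - 1, f.end, strand)
                    for f in sorted(
                        db.children(tx, featuretype=ft), key=lambda f: f.start
                    )
                )

            transcripts.append(
                Transcript(
                    transcript_id=tx.id,
                    exons=parts("exon"),
                    cds=parts("CDS"),
                    utr5=parts("five_prime_UTR"),
                    utr3=parts("three_prime_UTR"),
                )
            )
        genes.append(
            GeneModel(gene_id=g.id, span=span, transcripts=tuple(transcripts))
        )
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            fh.write(
                f"{s.chrom}\tmircontext\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                lo = min(e.start for e in tx.exons)
                hi = max(e.end for e in tx.exons)
                fh.write(
                    f"{s.chrom}\tmircontext\tmRNA\t{lo + 1}\t{hi}\t.\t{s.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for ft, parts in (
                    ("exon", tx.exons),
                    ("CDS", tx.cds),
                    ("five_prime_UTR", tx.utr5),
                    ("three_prime_UTR", tx.utr3),
                ):
                    for i, p in enumerate(parts):
                        fh.write(
                            f"{s.chrom}\tmircontext\t{ft}\t{p.start + 1}\t{p.end}\t.\t{s.strand}\t.\t"
                            f"ID={tx.transcript_id}.{ft}.{i};Parent={tx.transcript_id}\n"
                        )


# ---------------------------------------------------------------------------
# BED6 precursors and matures

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    return df


def write_bed6(df: pd.DataFrame, path: str) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_precursors(precursor_bed: str, mature_bed: Optional[str] = None) -> List[MirnaPrecursor]:
    """Assemble precursors from a precursor BED6 and an optional mature BED6.

    Mature names are ``<precursor_id>|<mature_id>`` (or
    ``<precursor_id>|<mature_id>|<sequence>`` when the generator embeds the
    mature sequence for family deduplication).
    """
    pre = read_bed6(precursor_bed)
    matures_by_parent: Dict[str, List[MatureMirna]] = {}
    if mature_bed is not None:
        mat = read_bed6(mature_bed)
        for row in mat.itertuples(index=False):
            fields = str(row.name).split("|")
            if len(fields) < 2:
                raise ValidationError(f"mature name {row.name!r} lacks parent id")
            parent, mature_id = fields[0], fields[1]
            seq = fields[2] if len(fields) > 2 and fields[2] else None
            matures_by_parent.setdefault(parent, []).append(
                MatureMirna(
                    mature_id=mature_id,
                    interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                    sequence=seq,
                )
            )
    out = []
    for row in pre.itertuples(index=False):
        out.append(
            MirnaPrecursor(
                mirna_id=str(row.name),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                matures=tuple(matures_by_parent.get(str(row.name), ())),
            )
        )
    return out


def write_precursors(precursors: Sequence[MirnaPrecursor], precursor_bed: str, mature_bed: str) -> None:
    pre_rows = []
    mat_rows = []
    for p in precursors:
        iv = p.interval
        pre_rows.append([iv.chrom, iv.start, iv.end, p.mirna_id, 0, iv.strand])
        for m in p.matures:
            name = f"{p.mirna_id}|{m.mature_id}" + (f"|{m.sequence}" if m.sequence else "")
            mi = m.interval
            mat_rows.append([mi.chrom, mi.start, mi.end, name, 0, mi.strand])
    write_bed6(pd.DataFrame(pre_rows, columns=BED6_COLUMNS), precursor_bed)
    write_bed6(pd.DataFrame(mat_rows, columns=BED6_COLUMNS), mature_bed)


# ---------------------------------------------------------------------------
# bedGraph score tracks


def read_bedgraph(path: str) -> ScoreTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"], comment="#"
    )
    return ScoreTrack(df.itertuples(index=False, name=None))


def write_bedgraph(runs: Iterable[Tuple[str, int, int, float]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in runs:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.4f}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_ages(path: str) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"gene_id", "branch_age"} - set(df.columns)
    if missing:
        raise ValidationError(f"gene-age table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# species tree config


def read_species_tree(path: str) -> SpeciesTree:
    """Species tree from a YAML document with keys ``n_branches``,
    ``species_branch`` and ``divergence_myr``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SpeciesTree(
        n_branches=int(doc["n_branches"]),
        species_branch={str(k): int(v) for k, v in doc["species_branch"].items()},
        divergence_myr={int(k): float(v) for k, v in doc["divergence_myr"].items()},
    )


def write_species_tree(tree: SpeciesTree, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "n_branches": tree.n_branches,
                "species_branch": dict(tree.species_branch),
                "divergence_myr": {int(k): float(v) for k, v in tree.divergence_myr.items()},
            },
            fh,
            sort_keys=True,
        )
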