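import filecmp
import os

import numpy as np
import pandas as pd
import pytest

from mircontext import (
    GeneratorConfig,
    HUMAN_12_BRANCH_TREE,
    SyntheticTruth,
    ValidationError,
    assign_ages,
    call_orthologs,
    classify_contexts,
    generate_annotation,
    generate_expression_data,
    generate_ortholog_hits,
    generate_score_track,
    rank_match_statistic,
    simulate_bundle,
)
from mircontext import io as mio
from mircontext.context import GeneIndex

SMALL = dict(n_genes=80, n_mirnas=60, seed=5)


@pytest.fixture(scope="module")
def small_annotation():
    return generate_annotation(GeneratorConfig(**SMALL))


class TestAnnotation:
    def test_truth_consistent_with_placement(self, small_annotation):
        genes, precursors, gene_ages, truth = small_annotation
        by_id = {g.gene_id: g for g in genes}
        for row in truth.mirnas.itertuples(index=False):
            if row.category == "intragenic":
                host = by_id[row.host_gene_id]
                assert host.span.chrom == row.chrom
                assert host.span.start <= row.start and row.end <= host.span.end
                # planted inside an intron of the longest transcript
                assert any(
                    iv.start <= row.start and row.end <= iv.end for iv in host.introns()
                )

    def test_classifier_recovers_planted_contexts(self, small_annotation):
        genes, precursors, _, truth = small_annotation
        ann = {a.mirna_id: a for a in classify_contexts(precursors, GeneIndex(genes))}
        for row in truth.mirnas.itertuples(index=False):
            a = ann[row.mirna_id]
            assert a.category == row.category
            if row.category == "intragenic":
                assert a.host_gene_id == row.host_gene_id
                assert a.orientation == row.orientation
                assert a.subregion == "intron"

    def test_full_host_age_bias(self):
        _, _, _, truth = generate_annotation(
            GeneratorConfig(n_genes=80, n_mirnas=60, seed=6, host_age_bias=1.0)
        )
        intra = truth.mirnas[truth.mirnas["category"] == "intragenic"]
        assert (intra["host_age"] == 1).all()

    def test_host_age_bias_concentration(self):
        cfg = GeneratorConfig(n_genes=150, n_mirnas=660, seed=7,
                              fraction_intragenic=1.0, host_age_bias=0.85)
        _, _, _, truth = generate_annotation(cfg)
        old = truth.mirnas[truth.mirnas["branch_age"] >= 2]
        frac = (old["host_age"] == 1).mean()
        n = len(old)
        sd = np.sqrt(0.85 * 0.15 / n)
        assert abs(frac - 0.85) < 3 * sd

    def test_old_genes_longer_on_average(self, small_annotation):
        genes, _, _, truth = small_annotation
        lengths = truth.genes["end"] - truth.genes["start"]
        old = lengths[truth.genes["branch_age"] == 1]
        young = lengths[truth.genes["branch_age"] > 1]
        assert old.mean() > young.mean()

    def test_determinism(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_bundle(GeneratorConfig(**SMALL), str(d1))
        simulate_bundle(GeneratorConfig(**SMALL), str(d2))
        for name in os.listdir(d1):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_seed_changes_content_not_schema(self, tmp_path):
        p1 = simulate_bundle(GeneratorConfig(n_genes=40, n_mirnas=20, seed=1), str(tmp_path / "s1"))
        p2 = simulate_bundle(GeneratorConfig(n_genes=40, n_mirnas=20, seed=2), str(tmp_path / "s2"))
        t1, t2 = mio.read_tsv(p1["hits_tsv"]), mio.read_tsv(p2["hits_tsv"])
        assert list(t1.columns) == list(t2.columns)
        assert not t1.equals(t2)

    def test_zero_mirnas_valid_empty_files(self, tmp_path):
        paths = simulate_bundle(GeneratorConfig(n_genes=40, n_mirnas=0, seed=3), str(tmp_path / "z"))
        assert len(mio.read_precursors(paths["precursor_bed"], paths["mature_bed"])) == 0
        assert len(mio.read_tsv(paths["hits_tsv"])) == 0


class TestOrthologHits:
    def test_noiseless_recovery_is_exact(self, small_annotation):
        _, _, _, truth = small_annotation
        cfg = GeneratorConfig(**SMALL, detection_prob=1.0, ratio_noise_sd=0.0,
                              annotated_fraction=0.0)
        hits, _ = generate_ortholog_hits(truth, cfg)
        calls = call_orthologs(hits, tree=HUMAN_12_BRANCH_TREE)
        ages = assign_ages(calls, HUMAN_12_BRANCH_TREE, all_mirna_ids=truth.mirnas["mirna_id"])
        rec = ages.set_index("entity_id")["branch_age"]
        assert (rec.loc[truth.mirnas["mirna_id"]].to_numpy()
                == truth.mirnas["branch_age"].to_numpy()).all()

    def test_zero_detection_dates_everything_focal(self, small_annotation):
        _, _, _, truth = small_annotation
        cfg = GeneratorConfig(**SMALL, detection_prob=0.0, annotated_fraction=0.0)
        hits, _ = generate_ortholog_hits(truth, cfg)
        ages = assign_ages(
            call_orthologs(hits, tree=HUMAN_12_BRANCH_TREE),
            HUMAN_12_BRANCH_TREE,
            all_mirna_ids=truth.mirnas["mirna_id"],
        )
        assert (ages["branch_age"] == 12).all()

    def test_dropout_never_recovers_more_ancient_age(self, small_annotation):
        _, _, _, truth = small_annotation
        cfg = GeneratorConfig(**SMALL, detection_prob=0.5, ratio_noise_sd=0.0)
        hits, ann = generate_ortholog_hits(truth, cfg)
        ages = assign_ages(
            call_orthologs(hits, ann, HUMAN_12_BRANCH_TREE),
            HUMAN_12_BRANCH_TREE,
            all_mirna_ids=truth.mirnas["mirna_id"],
        )
        rec = ages.set_index("entity_id")["branch_age"].loc[truth.mirnas["mirna_id"]]
        assert (rec.to_numpy() >= truth.mirnas["branch_age"].to_numpy()).all()


class TestExpression:
    def test_full_coexpression_weight_gives_identical_rank_order(self, small_annotation):
        genes, precursors, _, truth0 = small_annotation
        cfg = GeneratorConfig(**SMALL, coexpression_weight=1.0)
        _, _, _, truth = generate_expression_data(truth0, cfg, precursors)
        pairs = truth.mirnas[
            (truth.mirnas["category"] == "intragenic") & (truth.mirnas["orientation"] == "sense")
        ]
        assert len(pairs) > 0
        for row in pairs.itertuples(index=False):
            m = truth.mirna_profiles.loc[row.mirna_id].to_numpy()
            h = truth.gene_profiles.loc[row.host_gene_id].to_numpy()
            assert rank_match_statistic(m, h) == 1.0

    def test_no_multimappers_when_fraction_zero(self, small_annotation):
        genes, precursors, _, truth0 = small_annotation
        cfg = GeneratorConfig(**SMALL, multimapper_fraction=0.0)
        reads, _, _, _ = generate_expression_data(truth0, cfg, precursors)
        assert (reads["n_loci"] == 1).all()

    def test_planted_breadth_effect_detectable(self, small_annotation):
        from mircontext import tau
        from mircontext.stats import mannwhitney

        genes, precursors, _, truth0 = small_annotation
        cfg = GeneratorConfig(**SMALL)
        _, _, _, truth = generate_expression_data(truth0, cfg, precursors)
        taus = {"broad": [], "narrow": []}
        for row in truth.mirnas.itertuples(index=False):
            prof = truth.mirna_profiles.loc[row.mirna_id].to_numpy() * 100
            taus["broad" if row.broad else "narrow"].append(tau(prof).tau)
        assert np.mean(taus["broad"]) < np.mean(taus["narrow"])
        _, p = mannwhitney(taus["broad"], taus["narrow"])
        assert p < 0.05

    def test_invalid_panel_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(tissues=("brain", "heart", "kidney", "testis", "liver"))


class TestScoreTrack:
    def test_zero_sd_plants_exact_means(self, small_annotation):
        from mircontext import ScoreTrack, mean_track_score, GenomicInterval

        _, _, _, truth = small_annotation
        cfg = GeneratorConfig(**SMALL, cons_sd=0.0)
        runs = generate_score_track(truth, cfg)
        track = ScoreTrack(runs)
        for row in truth.mirnas.head(10).itertuples(index=False):
            res = mean_track_score(track, GenomicInterval(row.chrom, row.start, row.end, row.strand))
            assert res.mean == pytest.approx(row.cons_mean, abs=1e-9)

    def test_roundtrip_through_reader(self, small_annotation, tmp_path):
        _, _, _, truth = small_annotation
        cfg = GeneratorConfig(**SMALL)
        runs = generate_score_track(truth, cfg)
        path = str(tmp_path / "t.bedgraph")
        mio.write_bedgraph(runs, path)
        mio.read_bedgraph(path)  # must not raise (no overlaps, finite scores)


class TestRoundTrips:
    def test_gff3_and_bed_roundtrip(self, small_annotation, tmp_path):
        genes, precursors, _, _ = small_annotation
        gff = str(tmp_path / "g.gff3")
        mio.write_gff3_genes(genes, gff)
        back = mio.read_gff3_genes(gff)
        assert len(back) == len(genes)
        by_id = {g.gene_id: g for g in back}
        for g in genes:
            b = by_id[g.gene_id]
            assert b.span == g.span
            assert b.longest_transcript().exons == g.longest_transcript().exons
            assert b.longest_transcript().utr5 == g.longest_transcript().utr5
        pre_bed, mat_bed = str(tmp_path / "p.bed"), str(tmp_path / "m.bed")
        mio.write_precursors(precursors, pre_bed, mat_bed)
        back_p = mio.read_precursors(pre_bed, mat_bed)
        assert back_p == precursors
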