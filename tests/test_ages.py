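import math

import numpy as np
import pandas as pd
import pytest
from fractions import Fraction

from mircontext import (
    HUMAN_12_BRANCH_TREE,
    SpeciesTree,
    ValidationError,
    age_class,
    assign_ages,
    call_orthologs,
    origination_stats,
    reconcile_pairs,
)
from mircontext.ages import binomial_two_sided_p

TREE = HUMAN_12_BRANCH_TREE


def hit(mirna, species, method, start=100, end=180, strand="+", ratio=1.0, chrom="c1"):
    return dict(
        mirna_id=mirna, species=species, method=method, chrom=chrom,
        start=start, end=end, strand=strand, length_ratio=ratio,
    )


class TestCallOrthologs:
    def test_two_overlapping_methods_present(self):
        hits = pd.DataFrame([hit("m", "mouse", "m1", ratio=0.9), hit("m", "mouse", "m2", start=150, end=230)])
        calls = call_orthologs(hits, tree=TREE)
        row = calls.iloc[0]
        assert row.present and row.methods == "m1,m2" and not row.adopted_annotation

    def test_single_method_absent(self):
        calls = call_orthologs(pd.DataFrame([hit("m", "mouse", "m1")]), tree=TREE)
        assert not calls.iloc[0].present

    def test_length_filter_then_consensus(self):
        """A 0.65-ratio hit is filtered, leaving one method: absent."""
        hits = pd.DataFrame([hit("m", "mouse", "m1", ratio=0.65), hit("m", "mouse", "m2", ratio=0.9)])
        assert not call_orthologs(hits, tree=TREE).iloc[0].present

    @pytest.mark.parametrize("ratio,ok", [(0.70, True), (1.30, True), (0.699, False), (1.301, False)])
    def test_ratio_bounds_inclusive(self, ratio, ok):
        hits = pd.DataFrame([
            hit("m", "mouse", "m1", ratio=ratio), hit("m", "mouse", "m2"),
        ])
        assert bool(call_orthologs(hits, tree=TREE).iloc[0].present) is ok

    def test_methods_must_overlap_same_strand(self):
        apart = pd.DataFrame([hit("m", "mouse", "m1"), hit("m", "mouse", "m2", start=500, end=580)])
        assert not call_orthologs(apart, tree=TREE).iloc[0].present
        anti = pd.DataFrame([hit("m", "mouse", "m1"), hit("m", "mouse", "m2", strand="-")])
        assert not call_orthologs(anti, tree=TREE).iloc[0].present

    def test_annotation_adoption_rescues_single_method(self):
        hits = pd.DataFrame([hit("m", "mouse", "m1", start=100, end=180)])
        # annotation covers exactly half of the 80-bp hit: adopted (>= 50%)
        ann = pd.DataFrame([dict(species="mouse", chrom="c1", start=100, end=140, strand="+")])
        row = call_orthologs(hits, ann, TREE).iloc[0]
        assert row.present and row.adopted_annotation
        under = pd.DataFrame([dict(species="mouse", chrom="c1", start=100, end=139, strand="+")])
        assert not call_orthologs(hits, under, TREE).iloc[0].present

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError):
            call_orthologs(pd.DataFrame([hit("m", "martian", "m1")]), tree=TREE)

    def test_filter_order_invariance(self, rng):
        """Filtering ratios before or after grouping yields identical calls."""
        rows = []
        for i in range(40):
            for sp in ("mouse", "chicken", "rhesus"):
                for meth in ("m1", "m2", "m3"):
                    if rng.random() < 0.7:
                        rows.append(hit(f"m{i}", sp, meth, ratio=float(rng.uniform(0.5, 1.5))))
        hits = pd.DataFrame(rows)
        direct = call_orthologs(hits, tree=TREE)
        prefiltered = call_orthologs(
            hits[(hits.length_ratio >= 0.7) & (hits.length_ratio <= 1.3)], tree=TREE
        )
        merged = direct.merge(prefiltered, on=["mirna_id", "species"], how="left")
        # groups absent after prefiltering are absent calls in the direct run
        prefilt_present = merged["present_y"].map(lambda v: bool(v) if v == v else False)
        assert (prefilt_present == merged["present_x"]).all()


def calls_df(present_species):
    return pd.DataFrame(
        [{"mirna_id": "m", "species": sp, "present": True} for sp in present_species]
    )


class TestAssignAges:
    def test_min_branch_wins(self):
        ages = assign_ages(calls_df(["chicken", "mouse", "chimpanzee"]), TREE)
        assert ages.iloc[0].branch_age == 2 and ages.iloc[0].age_class == "2-4"

    def test_no_presence_is_focal_specific(self):
        ages = assign_ages(pd.DataFrame(columns=["mirna_id", "species", "present"]),
                           TREE, all_mirna_ids=["m"])
        assert ages.iloc[0].branch_age == 12 and ages.iloc[0].age_class == "7-12"

    def test_most_ancient_branch(self):
        ages = assign_ages(calls_df(["zebrafish"]), TREE)
        assert ages.iloc[0].branch_age == 1 and ages.iloc[0].age_class == "1"

    def test_dollo_gap_resolved_to_oldest_presence(self):
        ages = assign_ages(calls_df(["chicken", "rhesus"]), TREE)
        assert ages.iloc[0].branch_age == 2

    def test_removing_presence_never_makes_age_older(self, rng):
        species = list(TREE.species_branch)
        for _ in range(30):
            present = [sp for sp in species if rng.random() < 0.5]
            if not present:
                continue
            full = assign_ages(calls_df(present), TREE).iloc[0].branch_age
            drop = [sp for sp in present if rng.random() < 0.5]
            reduced = [sp for sp in present if sp not in drop]
            red_age = (
                assign_ages(calls_df(reduced), TREE, all_mirna_ids=["m"]).iloc[0].branch_age
            )
            assert red_age >= full


class TestReconcile:
    CONTEXTS = pd.DataFrame(
        [
            {"mirna_id": "a", "category": "intragenic", "orientation": "sense", "host_gene_id": "g1"},
            {"mirna_id": "b", "category": "intragenic", "orientation": "sense", "host_gene_id": "g2"},
            {"mirna_id": "c", "category": "intragenic", "orientation": "sense", "host_gene_id": "g3"},
        ]
    )

    def test_younger_host_removed_equal_and_older_retained(self):
        mirna_ages = pd.DataFrame(
            {"entity_id": ["a", "b", "c"], "branch_age": [2, 7, 5]}
        )
        gene_ages = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "branch_age": [5, 1, 5]})
        pairs, removed = reconcile_pairs(mirna_ages, gene_ages, self.CONTEXTS)
        assert removed == 1
        assert set(pairs["mirna_id"]) == {"b", "c"}  # b: host older; c: equal age


class TestOrigination:
    def test_rate_is_count_over_elapsed(self):
        table = pd.DataFrame(
            {"branch_age": [2] * 30, "category": ["intergenic"] * 15 + ["intragenic"] * 15}
        )
        tree = SpeciesTree(
            n_branches=2, species_branch={"x": 1, "y": 2}, divergence_myr={1: 30.0, 2: 0.0}
        )
        row = origination_stats(table, tree).set_index("branch").loc[2]
        assert row.elapsed_myr == 30.0
        assert row.rate_inter + row.rate_intra == pytest.approx(1.0)

    def test_symmetric_split_p_is_one(self):
        assert binomial_two_sided_p(10, 20, 0.5) == pytest.approx(1.0)

    def test_two_sided_binomial_matches_enumeration(self):
        """Exact mass enumeration oracle over all n <= 30, k, at several p0."""
        for p0 in (0.5, 0.3):
            fp0 = Fraction(p0).limit_denominator(10)
            for n in range(1, 31):
                pmf = [
                    Fraction(math.comb(n, k)) * fp0**k * (1 - fp0) ** (n - k)
                    for k in range(n + 1)
                ]
                for k in range(n + 1):
                    expected = float(sum(p for p in pmf if p <= pmf[k]))
                    assert binomial_two_sided_p(k, n, p0) == pytest.approx(expected, abs=1e-12)

    def test_worked_value_one_of_ten(self):
        # both tails of Binomial(10, 0.5) at mass <= P(X=1): k in {0,1,9,10}
        assert binomial_two_sided_p(1, 10, 0.5) == pytest.approx(22 / 1024, abs=1e-12)

    def test_doubling_counts_doubles_rates(self):
        tree = SpeciesTree(
            n_branches=2, species_branch={"x": 1, "y": 2}, divergence_myr={1: 10.0, 2: 0.0}
        )
        t1 = pd.DataFrame({"branch_age": [2] * 8, "category": ["intergenic"] * 4 + ["intragenic"] * 4})
        t2 = pd.concat([t1, t1], ignore_index=True)
        r1 = origination_stats(t1, tree).set_index("branch").loc[2]
        r2 = origination_stats(t2, tree).set_index("branch").loc[2]
        assert r2.rate_inter == pytest.approx(2 * r1.rate_inter)
        assert r1.binomial_p == pytest.approx(1.0) and r2.binomial_p == pytest.approx(1.0)


def test_age_class_bins():
    assert [age_class(b) for b in (1, 2, 4, 5, 6, 7, 12)] == [
        "1", "2-4", "2-4", "5-6", "5-6", "7-12", "7-12",
    ]
    with pytest.raises(ValidationError):
        age_class(13)
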