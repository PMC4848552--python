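# Methods

This note records the models and procedures implemented in `mircontext`, the
conventions and numerical choices behind them, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Coordinates and annotation model

All coordinates are 0-based half-open (`[start, end)`), the BED convention;
GFF3 input (1-based inclusive) is converted on read. A precursor is
**intragenic** if it overlaps any protein-coding gene span by ≥ 1 bp — full
containment is not required, since dating and expression treat partially
overlapping precursors identically to contained ones. When several genes
overlap a precursor, the host is chosen deterministically: same-strand gene
first, then larger overlap, then longer (summed exon length) longest
transcript, then lexicographic gene id. The subregion (intron / CDS-exon /
5′-UTR / 3′-UTR) is computed against the host's longest transcript only;
any exon overlap ≥ 1 bp makes the call exonic (no fraction rule), with
exonic calls split by the largest overlap among annotated CDS/UTR parts
(CDS wins ties, and an exon-overlapping precursor with no CDS/UTR
annotation is called CDS-exon, the default for a coding host). Downstream
analyses use the *strict* set: sense-oriented intragenic plus intergenic
miRNAs; antisense records are flagged, not analysed.

Clustering merges precursors whose inter-interval gap (max(0, later.start −
earlier.end)) is ≤ 10 kb, **inclusive**; clusters are connected components
of that proximity graph, computed with a sorted sweep that is exactly the
transitive closure for intervals, and each cluster is represented by one
member drawn uniformly with the stage RNG.

## Species tree and branch ages

The dating fixture is a 13-species, 12-branch vertebrate tree (zebrafish =
branch 1, chicken = 2, platypus = 3, opossum = 4, cow/dog = 5, mouse/rat =
6, marmoset = 7, rhesus = 8, orangutan = 9, gorilla = 10, chimpanzee = 11,
human-specific = 12) with TimeTree-style divergence times (435, 312, 177,
159, 96, 90, 43, 29, 15.7, 9.0, 6.6, 0 Myr). Branch ages bin into classes
1 (vertebrates), 2–4 (amniotes), 5–6 (placental mammals), 7–12 (primates).

Hit filtering keeps length ratios in [0.70, 1.30] (inclusive bounds). Two
methods *support* the same orthologue when their loci overlap ≥ 1 bp on the
same strand; this is the weakest defensible reading of "supported by two
methods" and errs toward sensitivity. A retained hit overlapping an
annotated miRNA of the species on the same strand over ≥ 50% of the hit's
length marks the call present regardless of method count. A species is
present if any locus passes; multi-locus ambiguity is not penalised. Ages
are Dollo-style: the most ancient presence wins and lineage losses are
silent, so (given no false-positive hits) removing evidence can only move
an age toward the present — the monotonicity property the tests exercise.
Entities with no presence anywhere are assigned the focal branch (12).

Gene ages are consumed from an external table (the syntenic dating of genes
is out of scope) and only re-binned to this tree. Host/miRNA pairs where
the host is nominally *younger* than its miRNA are contradictory under the
model (a host must predate what it hosts) and are removed, with the count
reported; equal ages are retained.

Per-branch origination rates divide counts by the time elapsed since the
previous split; branch 1 has no preceding split, so its rate is undefined
(NaN). The inter/intragenic split per branch gets a two-sided exact
binomial test against p₀ = 0.5 by default — the null of equal origination
odds; p₀ is configurable since no other value is canonical.

## Expression quantification

A read locus is counted for a mature iff it is fully contained in the
mature interval extended by 3 nt at the mature 3′ end (high coordinate on
`+`, low on `-`); the 5′ end is never extended, preserving the seed. Reads
must match the mature strand. A read mapped to L loci contributes 1/L at
each locus, conserving read mass. Weighted counts are scaled to counts per
million of the weighted library size; between-sample scaling factors beyond
plain c.p.m. (e.g. TMM-style factors) can be supplied per sample but are
not computed. Samples collapse to tissues by the median — robust to study
effects and consistent with the median-based representative-arm rule.
Each precursor is represented by the arm with the highest median c.p.m.
across samples (ties: higher maximum, then the 5p arm); precursors whose
representative matures share an identical sequence (miRNA families)
collapse to one record attributed to the oldest precursor; records never
reaching 1 c.p.m. in any tissue are dropped.

## Statistics

**Expression breadth.** τ = Σ(1 − x̂ᵢ)/(N − 1) on x = log₂(c.p.m. + 1),
x̂ = x/max(x). τ is undefined (an error) for all-zero profiles and N < 2.
The breadth-count variant counts tissues at ≥ threshold (inclusive).
Log base 2 is used everywhere a log transform appears.

**Constrained resampling for host ages.** Observed statistic: fraction of
hosts on branch 1. Null: each miRNA of age a draws, independently and
*with replacement*, one gene from the pool restricted to branch ≤ a
("just as old or older"); per-miRNA eligibility is the only reading that
honours the constraint for mixed-age miRNA sets. 10,000 draws by default.
Empirical P uses the add-one rule (k+1)/(N+1), so P is never 0 and the
floor at 10,000 draws is 1/10001 < 0.0001. A 1-df χ² compares the observed
old-host count against the expectation from the null mean. The
implementation samples gene indices uniformly within each eligible pool
(vectorised over draws), which is distribution-identical to resampling the
gene list itself.

**Co-expression rank-order test.** Tissues are sorted by expression
(descending) in the miRNA and, independently, in the host; the statistic is
the fraction of rank positions occupied by the same tissue. Ties are broken
by the fixed tissue order (stable sort); constant profiles are rejected as
having no defined ordering rather than ordered arbitrarily. The null
shuffles the miRNA's tissue labels (3,000 times by default). The verbal
definition admits a threshold-based alternative — counting only positions
where the miRNA is expressed above a cutoff — which is available as
`method="expressed-rank-match"`; the plain rank-match reading is the
default. A group-level variant averages the per-pair statistic and
shuffles every miRNA independently per draw.

Because these statistics are discrete (the rank-match statistic is the
fixed-point count of a permutation), the add-one empirical P has large
atoms and is *valid but conservative*, never uniform. Results therefore
also carry the standard randomized p-value
u = (#{null > obs} + V·(#{null = obs} + 1))/(N+1), V ~ Uniform(0,1),
which is exactly Uniform(0,1) under the permutation null and is the
quantity used to verify calibration; reported inference uses the add-one P.

**Divergence, correlations, exact tests.** Cross-species expression
divergence is the Euclidean distance between log₂(v+1) profiles over the
5-tissue panel (brain, cerebellum, heart, kidney, testis), with pairs
excluded unless both sides reach 1 c.p.m. in ≥ 1 tissue. Correlations are
Spearman with midrank ties; two independent correlations are compared by
Fisher z, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), one-tailed
normal upper tail. Fisher's exact two-sided P is computed in-package as the
conditional hypergeometric small-mass sum (log-pmf via `gammaln`,
vectorised over the support, masses compared with relative tolerance
1 + 10⁻⁷ to absorb float ties); it matches integer enumeration exactly on
every 2×2 table with total ≤ 50 and `scipy.stats.fisher_exact` elsewhere.
The odds ratio is the sample odds ratio ad/bc. Zero-margin tables are
flagged undefined rather than raising. Ka/Ks records with ratio > 1 are
discarded before a two-sample KS test. Target predictions keep 7mer-m8 and
8mer sites with context score < −0.25 (strict inequality) and count
distinct genes per miRNA. Group-comparison wrappers (Mann–Whitney, KS,
binomial) delegate to scipy; they are plumbing, not re-derived.

## Conservation

Scores come from a bedGraph track (constant-score runs). Uncovered bases
are excluded from means, not imputed as zero — conservation tracks
legitimately omit bases — and the covered-base count is reported so callers
can filter. The seed is mature positions 2–8 (7 bases) counted from the 5′
end: `[start+1, start+8)` on `+`, `[end−8, end−1)` on `-`; no standard
coordinate convention exists for the seed, so the positions-2–8 rule is
applied symmetrically on both strands. Backgrounds are 100 equal-length
regions per entity: uniform over the host's longest-transcript introns
(minus the entity) for intragenic miRNAs, uniform over the gene-free parts
of a ±10 kb window for intergenic ones; placements are sampled with
replacement, length-weighted across the valid gaps, and never overlap the
focal entity. Which multi-species track to score against (by age class) is
a caller concern — one track per invocation.

## Synthetic generator

Defaults encode the analysed study conditions: 61% intragenic, 84% of
those sense-oriented, 83% probability that an intragenic miRNA (age ≥ 2)
lands in a branch-1 host, gene ages 60% branch-1, miRNA ages concentrated
in primates (75% in branches 7–12, modes at 7–8; 85% after the placental
split), a 12-tissue panel containing the 5-tissue cross-species panel, and
planted conservation means of 2.0/1.5/1.0/0.5 by age class over a 0.0
background (phyloP-like arbitrary units, sd 0.3). Hosts always predate
their miRNAs (host branch ≤ miRNA branch), old (branch-1) genes are drawn
~1.6× longer via intron inflation, and ortholog hits are emitted only at
branches ≥ the planted age (no false positives unless enabled), with
per-method dropout and Normal(1, sd) length-ratio noise. Expression
profiles are Dirichlet draws whose concentration encodes the planted
breadth class (α = 2.0 broad / 0.15 narrow), scaled by log-normal levels
(~60 expected reads per miRNA per sample at default), realised as Poisson
counts and emitted as read records (a configurable fraction at two loci
with n_loci = 2); sense intragenic miRNA profiles are mixed with the host
profile by weight 0.7. One master seed fans out to per-stage
`SeedSequence` streams, so outputs are byte-identical under a fixed seed
and independent across stages.

What the generator does **not** emulate: sequence content (mature
sequences are random letters used only for family deduplication),
sequencing error and adaptor artefacts, mapping ambiguity beyond the
n_loci field, overdispersed counts (Poisson by default), correlated
study/batch effects, alternative transcript structures, and real phyloP
score autocorrelation. Passing tests therefore demonstrate correctness of
the statistical machinery under the planted model, not robustness to
real-data artefacts such as misannotation or batch confounding.

## Problem sizes and runtime choices

The bundled experiments run on one CPU in minutes: the default synthetic
data set uses 400 genes and 300 miRNAs on a 4-chromosome genome; the
resampling calibration uses 500 replicates of 200 miRNAs × 2,000 draws;
power uses 100 replicates; age recovery uses 10,000 simulated miRNAs
(5,000 in the acceptance script); the clustering equivalence sweep uses
500 random layouts of ≤ 200 precursors; exact-test validation enumerates
all 2×2 tables with total ≤ 50 and all binomial cases to n = 30. The
10,000-draw resampling and 3,000-shuffle defaults match the analysis
design and are fast because both nulls are vectorised.

## Known limitations

- Sequence work is out of scope: no homology search, no alignment, no
  lift-over; hit tables are assumed reciprocal-best.
- Between-sample normalisation is plain c.p.m.; externally computed scale
  factors can be injected but are not estimated.
- The χ² variant of the host-age test treats the null mean as a fixed
  expectation, ignoring null variance in that expectation (the empirical P
  is the primary inference).
- Conservation backgrounds do not exclude repeat-masked sequence (no
  sequence model exists to mask against).
- No multiple-testing correction layer: per-analysis raw P values are
  reported by design.
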