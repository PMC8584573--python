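# Methods

## Cohort table model

A variant record carries gene symbol, RefSeq transcript, HGVS cDNA and
protein changes, a consequence class (missense, nonsense, frameshift,
synonymous, splice donor/acceptor, in-frame deletion, whole-exon
duplication), dbSNP id, a novelty flag (defined as: no dbSNP id), gnomAD
exome allele frequency and a homozygote-reported marker. The score panel
holds ranked MetaLR, ranked MetaSVM, PHRED-scaled CADD, ranked REVEL and
Condel, plus an optional JSD conservation value; a panel is *complete* when
all five predictors are present. In the packaged cohort exactly the 83
missense rows are complete, and only complete rows can carry cluster
labels — the table validator enforces this, along with uniqueness of
(gene, cDNA change) and score ranges ([0, 1] for ranked scores and Condel,
[0, 99] for CADD).

Consequence classification from HGVS strings is deterministic:
protein-level evidence first (`Ter`/`*` → nonsense, `fs` → frameshift,
`=` → synonymous, codon-sized `del` → in-frame deletion, single-residue
substitution → missense), then cDNA-level (intron offset sign: `+` donor,
`-` acceptor; deletion/duplication length mod 3; whole-exon duplication).
When a table supplies a printed consequence label it overrides inference —
the two deep-intronic splice rows in the packaged cohort (offsets +1261 and
-23) are labelled splice variants by their source and are kept as such.
Novelty is likewise taken from the table, never recomputed against a live
database, because database versions drift.

## Clustering

The five-score matrix uses CADD/33 by default (`cadd_div33`), putting CADD's
~[0, 50] PHRED scale on the unit range of the other four scores; `raw` and
`zscore` modes are available. k-means is Lloyd's algorithm with greedy
farthest-point seeding from a random first centre, 25 restarts, a fixed
default seed (20211030), at most 300 iterations and an exact
assignment-fixed-point stopping rule; the within-cluster sum of squares is
asserted non-increasing at every iteration, and a cluster emptied during
iteration is re-seeded at the point farthest from its current centroid.
The restart count, not the seeding, carries the optimisation burden: on the
packaged cohort all 20 swept seeds reach one of two adjacent optima.

k-means indices are arbitrary, so semantic labels are assigned by the
members' mean Condel, descending: pathogenic (red), uncertain (blue),
benign (green). This one rule covers both views and the optional
cluster-in-MDS-space mode (`cluster_space="mds"`; the default clusters the
score matrix itself, with MDS used for visualisation).

Classical MDS double-centres the squared Euclidean distance matrix,
B = −½ J D² J, and uses the top two eigenpairs; coordinates are
eigenvectors scaled by the square roots of the (clipped non-negative)
eigenvalues. Eigenvector signs being arbitrary, axis 1 is flipped to
correlate negatively with Condel and axis 2 with REVEL, so pathogenic
variants plot lower-left. Concordance between a re-clustering and published
labels is the adjusted Rand index plus a color-pair confusion table.

## Group statistics

Per-cluster summaries report n, mean, sample SD (n−1 denominator; a
singleton group reports SD 0 with an `sd_undefined` flag) and the median
(midpoint of central order statistics for even n). The Kruskal–Wallis H
test uses mid-ranks, H = 12/(N(N+1)) Σ nᵢ R̄ᵢ² − 3(N+1), divided by the tie
correction 1 − Σ(t³−t)/(N³−N); p is the chi-square upper tail with k−1
degrees of freedom (scipy's regularised incomplete gamma). When all values
are tied the correction degenerates and the test reports H = 0, p = 1. No
post-hoc pairwise tests or multiplicity corrections are applied.

## Conservation scoring

Column distributions are weighted amino-acid frequencies with a 1e-7
pseudocount; position-based (Henikoff-style) sequence weights are the
default, with a uniform mode for hand-checkable arithmetic. Gaps are
excluded from the distribution but counted in the gap fraction; `X`
(unknown residue) is treated as a gap since it carries no conservation
signal. The column score is the base-2 Jensen–Shannon divergence against
BLOSUM62-marginal background frequencies — bounded by 1, zero iff the
column matches the background — multiplied by (1 − gap_fraction). Columns
with gap fraction above 0.3 are flagged `low-coverage` but still scored;
all-gap columns score 0 and are flagged. Window smoothing blends each
column with the mean of its neighbours,
(1 − λ)·raw(i) + λ·mean(window of ±w excluding i), defaults w = 3,
λ = 0.5; it is a convex combination, so smoothed scores never leave the raw
range. A site's `conserved` flag requires every sequence ungapped and equal
to the reference residue at that column. Reports use 1-based human residue
numbering (HGVS convention); internals are 0-based.

The packaged cohort's JSD column stores the published per-variant values
verbatim; they are not recomputed, because they depend on the exact
external RefSeq sequence versions behind the original 10-species
alignments, which were not deposited. The cohort-level statistic (median
JSD over scored missense rows) is recomputed from the stored column.

## Carrier-risk model

With both partners heterozygous for the same autosomal-recessive variant,
each pregnancy is affected for that condition with probability ¼. For k
shared variants in distinct genes, assumed independent (no linkage
modelling), the affected-condition count is Binomial(k, ¼), evaluated in
exact rational arithmetic; P(≥1) = 1 − (¾)ᵏ. k is caller-supplied and may
count variants or genes as the user prefers.

## Synthetic data

The score-table generator draws each predictor from a per-class truncated
normal (rejection sampling, so means remain interpretable near the bounds;
an infeasible mean/bound combination is an error). Defaults are the
published per-cluster statistics of the real cohort: class sizes
(24, 27, 32); Condel 0.790±0.186 / 0.500±0.225 / 0.070±0.117; CADD
25.5±3.2 / 22.8±3.0 / 13.7±5.8; REVEL 0.809±0.143 / 0.433±0.154 /
0.086±0.136. MetaLR/MetaSVM per-cluster statistics are not published, so
their defaults were fixed once from the packaged table's per-cluster values
(MetaLR 0.75±0.13 / 0.32±0.15 / 0.21±0.18; MetaSVM 0.77±0.12 / 0.27±0.17 /
0.31±0.12). Scores are drawn independently within a class; real predictor
scores are positively correlated within a class, so the generator is
conservative for any view that relies on redundancy between scores.
Latent class labels are returned (and written) separately from the table so
no pipeline stage can read them. Optional "non-coding" rows with entirely
missing panels mirror the real table's splice/nonsense rows.

The alignment generator emulates a 10-species orthologue alignment:
reference residues drawn from the BLOSUM62 background, each other sequence
copying the reference with the column's conservation probability and
drawing from the background otherwise, gapping i.i.d. at a configurable
rate (the reference row is never gapped). It does not emulate phylogenetic
correlation between species, indel blocks, or spatial autocorrelation of
conservation along the protein — so recovery tests validate the scorer's
ranking behaviour, not its calibration on real alignments, and the
validation uses unsmoothed scores (window = 0) because smoothing assumes
neighbouring columns share conservation, which is false for i.i.d.
simulated columns.

## Validation design and measured behaviour

Method properties are tested against independent oracles: k-means against
a vectorised exhaustive minimum-WCSS search over all 3¹² labelings of 12
hand-written points; MDS against exact isometry on 2-D-embeddable inputs;
the JSD scorer against a hand-coded entropy oracle and boundary cases;
Kruskal–Wallis against hand-computed ranks and scipy; the risk model
against exact fractions and Monte-Carlo frequencies.

At the default generator conditions, five-score k-means recovers the
generating classes with ARI ≥ 0.8 in 95% of 200 replicates. The two-score
REVEL × Condel view recovers them only moderately (median ARI ≈ 0.7):
with independent within-class draws, two dimensions at the published
separations genuinely overlap. On the real cohort the two-score view is
cleaner than this because of within-class score correlation, which the
generator deliberately omits.

Problem sizes throughout (83-row tables, 500-column alignments, 200
replicates, 10⁶ Monte-Carlo draws) were chosen as the smallest at which the
tested quantities are stable well inside their tolerances.

## Known limitations

- No genome coordinates: the cohort table is HGVS-level; VCF export is not
  attempted beyond what the records contain, and no liftover or
  re-annotation against live VEP/dbNSFP/gnomAD services is performed.
- The published JSD values are consumed, not reproduced bit-exactly
  (external sequence versions are unavailable).
- k = 3 is fixed; the clustering is a triage heuristic, not a calibrated
  classifier, and in-silico scores alone cannot establish pathogenicity —
  the packaged cohort itself contains a biopsy-confirmed pathogenic variant
  (CCDC40 p.Gly21Val) whose predictor panel looks benign.
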