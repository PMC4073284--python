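# Methods

This note records the models, statistics, parameter choices and known
limitations behind each rbpreg module, in the order data flows through
the pipeline.

## Coordinates and gene model

All intervals are 0-based half-open (BED-native); GTF input is shifted
on read. A gene, for per-gene statistics, is the union of all
transcript spans sharing a `gene_id` — the pre-mRNA span — so intronic
tags count toward their gene. Tag-to-gene assignment is same-strand
only, reflecting the strand specificity of CLIP library preparation.

When a position falls in different region types of overlapping
transcripts, one label is chosen by the fixed priority
3′UTR > 5′UTR > CDS > noncoding exon > intron > intergenic. The RBP's
signal classes of interest are 3′UTR and intron; the priority prevents
exonic evidence from being diluted by an overlapping intron of another
isoform. Ambiguous gene assignment resolves to the largest overlap,
then the lexicographically smallest gene id, so results are
deterministic.

## CLIP read processing

The modelled read layout is a 6-nt known index followed by a 6-nt
degenerate barcode at the read start, then the insert and an enzymatic
polyA tail (both hexamer lengths are configurable; published RT primer
layouts vary, so the layout object is explicit rather than hard-coded).
Index matching is exact by default (`index_mismatch_tolerance = 0`,
because 6-mers leave little edit-distance margin); unknown indices go
to a counted "undetermined" bucket. PolyA trimming removes the longest
trailing run with ≥ 90% A content and ≥ 6 nt — tailing enzymes produce
long but imperfect tails, so requiring a pure run would under-trim.
This rule can absorb up to 10% interior non-A bases adjacent to the
tail; inserts ending in genomic A runs lose those bases, a known cost
of tail-tolerant trimming. Inserts shorter than 18 nt after trimming
are discarded with a tally (too short to map uniquely).

PCR duplicates collapse on the key *(replicate, chrom, alignment start,
strand, barcode)*. The 5′ start rather than the full span defines the
clone because reverse-transcription truncation varies the 3′ end among
copies of one clone. The retained representative is the longest read
(ties broken by read id) and deletion offsets are unioned across
duplicates — duplicates derive from one molecule, so any observed
deletion is evidence for that clone. Collapse is idempotent and
input-order invariant, and the collapsed counts always sum to the input
read count.

## Clusters, peaks, and stringency tiers

Clusters are maximal runs of same-strand tags in which consecutive tags
overlap by ≥ 1 nt (merge gap 0 — the most conservative choice, and the
only one that needs no free parameter). Peak height is the maximum
per-base tag depth, computed by a difference-array pileup and verified
against a brute-force per-base oracle in the tests.

Peak significance is this package's own model (the published threshold
it stands in for is cited without a formula in the literature): under a
uniform-placement null the depth at a genic position is approximately
Poisson with λ = (gene tag total × mean tag length) / gene length, and
the upper-tail probability of the observed peak is Bonferroni-corrected
by the number of gene positions scanned. The stringency tier using it
also keeps the raw height ≥ 10 cutoff, so tier membership remains
interpretable if the significance model differs from the original.

The reproducibility score is likewise a defined reconstruction: a
chi-squared test of homogeneity on the R×2 table of per-replicate tags
inside vs outside the cluster (within its gene), df = R − 1. Low p
flags replicate-skewed clusters; the retained ("reproducible") set
keeps clusters with full replicate support whose proportions do not
differ at p ≤ 0.01. When any expected cell falls below 1 the
2-replicate case switches to Fisher's exact test (the exact test for
that table); designs with more replicates and such sparse tables raise
an error rather than silently approximating. Degenerate margins (a
replicate with no gene tags) return p = 1 — such clusters are excluded
by the BC filter anyway.

Tiers: T1 = BC 2 & tags ≥ 2; T2 = BC 2 & tags ≥ 10; T3 = T2 & peak ≥ 10
& peak p ≤ 0.01; T4 = T3 & balance p > 0.01. Nesting |T1| ≥ … ≥ |T4| is
structural and checked over 100 random simulations.

## CIMS

Only deletions are modelled (the substitution/truncation channels of
crosslink evidence are out of scope). For every position with ≥ 1
deletion, k = tags deleting there and m = tags covering it. The null
repositions each deletion uniformly within its own tag (conserving
per-tag deletion counts and the total), repeated `n_permutations = 100`
times (minimum 20 enforced). FDR(k, m) = mean permuted count of
positions in the coverage-m stratum with deletion count ≥ k, divided by
the observed count, clamped to [0, 1]. Coverage strata are exact in m
with m > 100 pooled — a stabilizer for small synthetic data. The raw
ratio is not guaranteed monotone in k, so a running maximum from large
k downward enforces non-increasing FDR (a q-value-style step); this is
conservative for small k. Reproducible sites require k ≥ 5 and
FDR ≤ 0.01.

Footprints are ±10 nt windows in transcript orientation (minus-strand
windows reverse-complemented), clipped and flagged at sequence ends.
The composition test compares per-window U (T in DNA space) fractions
between footprints and background windows from the same sequence with a
one-sided Mann–Whitney test, and additionally reports how many
footprints contain a run of ≥ 4 U. This is a defined substitute for
de-novo motif discovery: it tests the same polyU signal but its
run-count is not comparable to a motif-discovery site count.

## Cassette-exon statistics

IR averages the two inclusion junctions before forming the proportion
(I = (inc_up + inc_down)/2; IR = I/(I + skip)) so that inclusion
evidence is not double-counted against the single skip junction. IR is
scale-invariant; ΔI = mean IR(induced) − mean IR(control) over
replicates is antisymmetric under condition swap. The Fisher test pools
replicates within condition into a 2×2 isoform table (isoform 1 =
inc_up + inc_down, isoform 2 = skip), two-sided. Junction matching is
exact-coordinate; near-miss junctions are tallied, not counted. The
read-support filter (≥ 10 junction reads) applies to the per-event
total over samples; it is exposed as a parameter since a per-sample
reading is also defensible.

The binding flag for an event requires ≥ 10 tags summed over clusters
with BC 2 and ≥ 5 tags overlapping the span from the upstream
constitutive exon start to the downstream constitutive exon end — the
lower per-cluster tag bar (5 vs 10) accounts for the smaller intronic
clusters that dominate near splice sites.

The complexity map profiles four boundaries of a composite transcript
(5′CE donor, CA acceptor, CA donor, 3′CE acceptor), each with a 50-nt
exonic margin and up to 1 kb of intron, in transcript orientation. The
value at an offset is the fraction of events in the class with ≥ 1 tag
covering that position; intronic reach truncates at the midpoint of
short introns so the two boundaries of one intron never double-count
its interior. The exonic margin is a fixed design choice (profiles are
dominated by intronic signal); exons shorter than the margin are not
additionally truncated.

## Dose-response screen

Size factors use the median-of-ratios construction: for genes positive
in all samples, factor_j = median over genes of count_gj / geometric
mean_g, with factors rescaled to median 1 so the reference scale is
data-driven and a second application returns unit factors. The median
is taken on the ratio scale (the documented contract); implementations
that median in log space differ slightly for even gene counts.

Correlation is Pearson per clone with a two-sided t-transform p;
constant genes return r = NA, p = 1. Correlating raw expression
against raw dose is the function default, but the pipeline runs with
log1p(dose) and log2(expression + 1): an inducible system saturates in
dose, and on raw scales Pearson is strongly asymmetric — a repressed
gene's convex decay toward zero correlates poorly however strong the
effect, while an induced gene's growing response correlates well. On
log scales a saturating response is near-linear and the screen treats
UP and DOWN genes symmetrically. Both switches are plain keyword
arguments.

Screen criteria: (i) p < 0.01 with consistent r sign in both wild-type
clones; (ii) |log2 FC| ≥ 0.585 (1.5-fold, configurable) between dose 0
and the lowest nonzero dose, consistent sign in both wild-type clones,
computed on normalized means with pseudocount 0.5; (iii) mutant-clone
p > 0.05. No multiple-testing correction by default (raw p cutoffs are
the documented criteria); a Benjamini–Hochberg option exists. UP and
DOWN sets are disjoint by construction. Note the ceiling this implies:
criterion (iii) discards ~5% of true targets by chance, so expected
recovery cannot exceed ~95%.

`integrate_binding` crosses the screen sets with per-gene tag totals
from qualifying clusters (> 100 tags = strong binder) and runs a
two-sided Fisher test for binding preference between UP and DOWN.
`signature_score` sums z-scores over a gene set per sample, dropping
missing genes with a warning.

## Decay

With data normalized to t0 the model is ln N(t) = −λt, fit by least
squares with the intercept fixed at 0 (a free-intercept option serves
un-normalized input). Replicates are pooled into one joint fit rather
than averaged first, preserving the error structure. λ ≤ 0 flags a
non-decaying transcript with infinite half-life. Half-life ratios get
a percentile bootstrap CI from resampling replicates with replacement
(seeded). With triplicates this CI is coarse (ten distinct resamples);
it is adequate for the effect sizes here but should not be
over-interpreted at boundary cases.

## Synthetic data: what it emulates, and what it does not

The generator produces a single-chromosome toy genome (default 30
genes, 4–7 exons, exponential exon/intron lengths with floors of
120/200 nt, every transcript with 5′UTR/CDS/3′UTR and ≥ 1 intron,
alternating strands), CLIP tags as a mixture of site-enriched and
uniform background reads with geometric PCR duplication (mean 3),
crosslink deletions at planted site centers (probability 0.3), and
polyU footprints planted as T runs (A on the minus strand) at site
centers. Junction reads are independent binomials at the planted IR
per replicate (depth 200, triplicates). Dose counts are negative
binomial (dispersion 0.1) over 6 doses (0–250 ng/ml) × 3 replicates ×
3 clones, with planted genes responding only in the wild-type clones
via a saturating log-dose effect scaled to 4-fold at the lowest
nonzero dose ("clearly detectable", comfortably above the screen's
1.5-fold criterion); library sizes vary lognormally (σ = 0.25) to
exercise normalization. Decay courses use the clone half-life pairs
(2.3/9.8, 2.4/5.4, 2.1/2.2 h) with 5% multiplicative noise and exact
t0 = 1 rows.

Everything is driven by one integer seed and is byte-reproducible.
Truth tables (site positions, unique-tag counts, IRs, planted gene
lists, half-lives) accompany each output.

What passing tests on this data do **not** show: the generator has no
read-level sequencing errors, no mappability structure, no isoform
mixtures, no correlated genes, no batch effects, and depths orders of
magnitude below real experiments. Recovery rates and calibration
measured here validate the statistics and their implementation, not
performance on real libraries.

## Problem sizes and numerical checks

Acceptance-style checks run at desk scale: oracle equivalence on
hundreds of random reads/clusters and ~8,000 Fisher tables (exhaustive
for margins ≤ 12 plus 300 random tables with margins ≤ 30 — enumeration
of every table to margin 30 adds nothing but minutes); 100 simulations
for tier monotonicity and for CIMS detection power; 10 high-coverage
null simulations (~4,000 candidate positions) for FDR calibration;
1,200 cassette events (200 planted at |ΔI| = 0.4); the full 2,000-gene
dose matrix; 200 decay fits at 5% noise. The mutant decay pair (2.1 vs
2.2 h, true ratio 1.048) is checked at a qPCR-realistic 20%
multiplicative noise in aggregate over 30 simulated experiments —
at 5% noise the bootstrap CI (half-width ≈ 3%) resolves the 4.8%
planted difference, so "indistinguishable from no effect" is only the
expected reading at realistic noise.

Ties and degenerate inputs: leftmost position on peak ties; empty
tiers give empty distributions; zero junction counts give IR = NA;
zero-margin Fisher tables return p = 1; constant expression returns
r = NA; genes without annotation overlap carry NaN cluster statistics
and never reach significance-gated tiers.
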