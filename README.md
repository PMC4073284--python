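# rbpreg

Analysis toolkit for dissecting the regulatory program of an RNA-binding
protein (RBP), built around the kind of evidence an inducible-expression
study produces: HITS-CLIP binding maps, cassette-exon splicing changes,
dose-dependent mRNA abundance shifts, and mRNA decay kinetics.

The package is aimed at computational biologists who want each analysis
step as a tested, importable function — with a synthetic-data generator
that produces every input format alongside its ground truth, so the
whole pipeline can be exercised and validated without any sequencing
data.

## What it computes

**CLIP tag processing.** Raw reads follow the protocol layout
`[index][degenerate barcode][insert][polyA]`; reads are demultiplexed,
trimmed, and PCR duplicates collapsed by the clone key *(replicate,
chromosome, alignment start, strand, barcode)*. Unique tags are the
atomic binding evidence.

**Cluster and peak calling.** Overlapping same-strand tags merge into
clusters scored by biological complexity (BC = number of replicates with
≥ 1 tag), peak height *PH* = max per-base depth, a gene-level Poisson
peak significance (λ = gene tags × mean tag length / gene length,
Bonferroni-corrected over gene positions), and a replicate-balance
chi-squared score on the R×2 table of in-cluster vs out-of-cluster gene
tags. Four nested stringency tiers apply the thresholds BC = 2,
tags ≥ 2 / ≥ 10, PH ≥ 10 (significant), and balance p > 0.01.

**CIMS.** Crosslink-induced mutation sites are positions where *k* of
*m* covering tags carry a deletion. Significance comes from a
permutation null — every deletion repositioned uniformly within its own
tag — with FDR(k, m) estimated per coverage stratum; reproducible sites
require k ≥ 5 and FDR ≤ 0.01. Footprints (±10 nt) feed a
base-composition test (one-sided Mann–Whitney on per-window U fraction)
for polyU enrichment.

**Cassette-exon splicing.** With junction counts for the two inclusion
junctions and the skip junction, the inclusion rate is

    I = (inc_up + inc_down) / 2,    IR = I / (I + skip)

ΔI = mean IR(induced) − mean IR(control) over replicates; events are
screened by ≥ 10 junction reads, |ΔI| ≥ 0.2 and a two-sided Fisher exact
p ≤ 0.05 on pooled isoform counts, then flagged as RBP-bound when
clusters (BC 2, ≥ 5 tags) over the event span carry ≥ 10 tags. A
normalized complexity map profiles, per composite-transcript boundary,
the fraction of events with binding at each offset.

**Dose-response target screen.** Count matrices are normalized by
median-of-ratios size factors; per-gene Pearson correlation of
expression with inducer dose is computed per clone, and a direct target
must (i) correlate at p < 0.01 in both wild-type clones, (ii) change
≥ 1.5-fold at the lowest nonzero dose in both, and (iii) show no
correlation (p > 0.05) in the loss-of-function mutant clone.

**mRNA decay.** For t0-normalized shutoff time courses, ln(abundance)
is regressed on time through the origin; T½ = ln 2 / λ, with a
replicate-resampling bootstrap CI for half-life ratios.

## Worked example

```bash
python examples/05_mrna_decay.py
```

```
MUT3_Ctrl: T1/2 = 2.06 hr (truth 2.1 hr, r^2 = 0.999)
MUT3_Dox: T1/2 = 2.21 hr (truth 2.2 hr, r^2 = 0.999)
WT10_Ctrl: T1/2 = 2.43 hr (truth 2.4 hr, r^2 = 0.998)
WT10_Dox: T1/2 = 5.37 hr (truth 5.4 hr, r^2 = 0.986)
WT6_Ctrl: T1/2 = 2.30 hr (truth 2.3 hr, r^2 = 0.997)
WT6_Dox: T1/2 = 10.14 hr (truth 9.8 hr, r^2 = 0.969)
WT6: Dox/Ctrl half-life ratio 4.41 [4.11, 4.78]
WT10: Dox/Ctrl half-life ratio 2.21 [2.06, 2.37]
MUT3: Dox/Ctrl half-life ratio 1.07 [1.05, 1.10]
```

Each condition's time course (5 timepoints × 3 replicates, 5%
multiplicative noise) is fit jointly; the fold-change lines show that
induction in the wild-type clones stabilizes the transcript roughly
four- and two-fold while the truncation mutant has no effect — the
bracketed values are 95% bootstrap confidence intervals. The other
`examples/` scripts walk the CLIP → clusters, CIMS, splicing, and
dose-screen capabilities the same way.

A thin CLI wraps the pipeline: `rbpreg simulate | clip-dedup |
clip-cluster | cims | dose-screen | decay | all` (see `rbpreg --help`);
`rbpreg all --seed 7 --out run/` writes every stage output plus a
manifest enabling byte-identical re-runs.

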