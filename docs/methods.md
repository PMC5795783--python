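# Methods

## Coordinate model

All genomic coordinates are 0-based half-open internally (the BED
convention). GFF3 input (1-based inclusive) is converted at the reader
boundary, so a minus-strand gene annotated 5001..6000 has its TSS at
internal position 5999: the biological start of transcription is the last
base of the span on the minus strand (`end − 1`). Chromosome-name dialects
("1" vs "chr1") are never silently normalized; mismatched names simply
produce no links, which surfaces data errors instead of hiding them.

A gene may carry several TSS records (alternative promoters); all are kept,
and a gene counts as a target if **any** of its TSSs is linked. Set-level
outputs (partitions, signatures, overlaps) operate on unique gene ids.

## Target assignment

**Proximal rule.** A TSS is linked to a peak when the minimum over peak
bases of |base − tss| is ≤ `window` on the same chromosome — equivalently,
when the peak intersects the closed window [tss − w, tss + w]. The boundary
is inclusive: distance exactly `window` links. "Within w of a site" does
not define its measuring points; nearest-peak-base to TSS-base is the most
permissive standard reading, and the recorded evidence is that distance.
Default window: 2,000 bp.

**Contact rule.** A TSS is linked to a peak when some contact has one
anchor overlapping the peak by ≥ 1 bp and the other anchor containing the
TSS base (anchors optionally extended by `anchor_pad` per side, default 0).
The rule is binary and symmetric in anchor order; trans-chromosomal
contacts are honored because the rule is containment, not distance.
Remote sites are *not* required to be farther than the proximal window, so
the two categories may overlap; the combined call set deduplicates genes
and labels each proximal-only / contact-only / both, reporting the
intersection size explicitly. Consequently category sizes n_prox and
n_contact with an intersection of size b always union to
n_prox + n_contact − b, which is the additive bookkeeping the report
enforces at assembly time.

Interaction calling itself is out of scope: the contact list is an input
(pre-called significant interactions), not something re-derived from raw
contact matrices.

## Cross-assembly lifting

The chain lifter parses UCSC chain files, validating that block sizes plus
gaps reproduce the header spans on both sides (any mutation of the block
arithmetic is rejected, naming the chain). Negative-strand query chains are
normalized at parse time; lifted intervals are always reported in forward
coordinates with the strand flipped.

`lift_interval` computes the target image of every source base inside
aligned blocks. The result is `mapped` when all imaged bases come from a
single chain and cover at least `min_match` of the interval (default 0.95,
mirroring the UCSC liftOver default, configurable); the reported image
spans first to last image base. Coverage below threshold gives
`partial_below_threshold` (the fractional image is still reported), no
coverage gives `unmapped`, and images on more than one chain give `split`.
`mapped_fraction` is always exact: it equals a per-base walking oracle by
construction, and the test suite verifies this on random multi-block chains.
Chains can be inverted (`invert_chain`), which makes lift-then-back-lift an
identity for intervals fully inside aligned blocks. Whether peaks, anchors
or TSSs should be lifted depends on which inputs share an assembly, so the
pipeline allows lifting any single layer (`lift_layer`).

## Target-set partition and orthology

Two factors' target gene sets are partitioned as A∖B, A∩B, B∖A; the three
classes are pairwise disjoint and tile the union (checked at report time).
Cross-species comparison uses an explicit user-supplied two-column symbol
table — no remote lookups, so runs are reproducible. One-to-many pairs
expand to all images; genes without a pair are reported as unmapped.
Symbols compare case-sensitively, with an opt-in upper-casing toggle for
mouse/human conventions.

## Expression signatures and ΔCt

The signature rule selects genes whose focal/reference ratio **strictly
exceeds** the threshold (default 2.0) for **all** reference conditions
(configurable to "any"). Ratio exactly 2.0 is excluded — "greater than
x-fold" is read literally, and the boundary is tested. Values are
linear-scale; a flag converts log2 input at load. A zero reference raises
an error naming the gene unless a pseudo-count is configured: silent
infinite ratios are never produced. The table is assumed pre-aggregated to
one column per condition.

Relative transcript abundance from qPCR is 2^−(Ct_target − Ct_reference),
normalized to a housekeeping gene (e.g. GAPDH); ΔCt of 5 cycles gives
2⁻⁵ = 0.03125. Efficiency-corrected ΔΔCt is out of scope.

## Overlap statistics

Gene-set overlap significance is the exact hypergeometric **upper tail**
P(X ≥ k), inclusive — the enrichment convention (note R's `phyper` defaults
to the lower tail). It is computed via the scipy survival function, which
works in log space and is stable for genome-scale N; the test suite proves
agreement with exact rational arithmetic to ≤ 1e-12 over every parameter
combination with N ≤ 25. The universe size N (annotated genes of the
platform/assembly) is a required explicit argument — it changes p-values
materially and no default would be defensible. Bonferroni adjustment is
min(1, p·m) with m defaulting to the number of comparisons submitted in one
family, logged in the report.

Because the overlap count is discrete, null calibration compares p-values
to the exact discrete null via the randomized probability-integral
transform (F(p⁻) + V·Pr(P = p), V ~ U(0,1), exactly uniform under the
null) followed by a standard Kolmogorov–Smirnov test; a naive KS test
against the step CDF would reject valid discrete nulls.

## Synthetic scenarios

The generator emulates the statistical structure of the real inputs: a toy
genome of TSSs; two factors' peak sets with planted proximal, contact-only,
both-rule and shared target genes plus decoy peaks; a contact list with
decoy loops; a two-block chain file per chromosome; an expression table
with planted fold-changes; and an identity-pair ortholog table. Defaults:
200 genes on 2 chromosomes of 10 Mb; 30 A-proximal, 30 B-proximal, 10
contact-only per factor, 20 shared, 5 both-rule genes; 50 decoy peaks and
30 decoy contacts; 2 kb window; 5 kb contact anchors (typical Hi-C anchor
resolution); 300 bp peaks; a 40-gene signature planted at exactly 4-fold
over references with all other genes held below 1.8-fold; three conditions
(one myofibroblast-like focal, two references).

Placement guarantees *exact* recovery rather than probabilistic recovery:
TSSs sit ≥ 3 windows apart (spacing 3·window + anchor_width), planted
proximal peaks have their nearest edge at a uniform distance in [0, window]
from their own TSS only, and contact-only peaks, decoy peaks and decoy
anchors occupy exclusive slots in a distal zone > 3 windows from every TSS
and outside every planted anchor. Infeasible configurations (counts that
cannot be placed on the configured chromosome length) raise before any file
is written. A single pseudo-random stream seeded from the config drives all
placement, so one seed yields byte-identical bundles.

What the generator does **not** emulate — read-level noise, peak-calling
uncertainty, contact-frequency distance decay, multi-TSS isoform
complexity, many-to-many orthology, expression measurement noise — bounds
what passing tests show: they certify the correctness of the rules and
bookkeeping, not robustness to noisy real data, where the planted-recovery
guarantee does not apply.

The scenario's ortholog table is an identity mapping over the toy gene ids
(the toy genome is a single namespace); cross-namespace translation,
one-to-many expansion and unmapped handling are exercised separately in
unit tests.

## Pipeline and determinism

`run_pipeline` validates the whole configuration and all input files before
any stage runs, then executes simulate/load → lift → link (per factor) →
partition → signature → enrich, persisting intermediate TSVs and a JSON
report. Conservation identities (mode counts sum to totals; partition
classes tile the union) are asserted when the report is assembled, not only
in tests. All randomness flows from one config seed; identical config and
seed produce a byte-identical report, and the provenance block records a
hash of the analysis-relevant configuration (the output directory is
excluded from the hash).

Default enrichment comparisons test the expression signature against each
partition class with the TSS catalog's gene set as universe and m = 3.

## Problem sizes used in the checks

Acceptance-style checks run at desk scale: 200-gene scenarios over 20
seeds for exact recovery; an 800-gene scenario to plant the 65/725
category pattern with a 14-gene intersection (union 776); the exhaustive
hypergeometric sweep at N ≤ 25 (44,225 combinations); 1,000 random
intervals for the lift oracle; 1,000 replicates from a 2,000-gene universe
for null calibration. Each completes in seconds.

## Known limitations

Binary linkage only — no distance-decay or activity-by-contact weighting;
no peak calling or interaction calling; no ontology enrichment or FDR
procedures beyond Bonferroni; BED/GFF3/BEDPE/chain/TSV text formats only.
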