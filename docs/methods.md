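# Methods note

This note records the models implemented in cicerkit, the parameters and
their defaults, the realism and limits of the synthetic-data generator, and
the numerical choices that affect results.

## Assembly statistics and anchoring

N50 is computed by sorting the scaffold lengths in descending order and
scanning the cumulative sum; the N50 index is the first rank k at which the
cumulative sum reaches half the total assembled bases, and the N50 length is
the length at that rank. The comparison is `>=` against `total / 2` in exact
float arithmetic; for integer lengths this is equivalent to comparing
`2 * cumsum >= total` in integers, so no precision issue arises at genome
scale (sums < 2^63).

GC content is (G + C) / (A + C + G + T): ambiguous bases (normalized to N on
input) are excluded from the denominator, and an all-N sequence reports a
missing GC rather than 0.

Anchoring assigns each scaffold to the linkage group carrying the majority of
its markers (ties broken toward the lowest natural-sorted group), orders
scaffolds within a group by mean marker cM, and orients each scaffold by the
sign of the Spearman rank correlation between marker bp and cM (fewer than
two markers, or a zero correlation, defaults to "+"). Scaffolds are joined
with 100-N gaps (AGP component type U, "scaffold" gap). These rules are
deterministic and input-order invariant; the test suite checks byte-identical
pseudomolecules under input reversal.

## Annotation statistics

Gene models are removed when the total CDS is shorter than 150 bases or the
CDS ambiguity fraction is at least 10% N; both boundaries are pinned by tests
(a 150-base CDS is kept, exactly 10% N is removed). All per-gene averages
divide by the number of genes, not the number of mRNAs — this is what makes
the reference average CDS length 35,503,303 / 30,257 = 1173 come out, and it
is asserted in the acceptance tests. Intron averages exclude single-exon
genes. Printed percentages use round-half-away-from-zero at the requested
precision (Python's bankers rounding would print 76.02 → 76.0 the same way
but differs on exact halves); a `truncate` flag reproduces figures that were
evidently floored rather than rounded.

## Genome topography and pericentromere delineation

Window tracks use a 1 Mb window advanced every 200 kb. Gene density counts
gene midpoints per window; repeat density is the covered fraction. Genetic
length per window comes from a Marey map: marker cM as a function of bp,
forced monotone with a running maximum and interpolated piecewise-linearly
(`numpy.interp`), NaN outside the marker span.

A window is flagged pericentromeric when, after a centered 3-window moving
mean, its repeat coverage is above — and both its gene count and its genetic
length are below — the midpoint of the track's interquartile range (the mean
of the 25th and 75th percentiles). The core is the longest contiguous flagged
run, bridging unflagged gaps of up to 2 windows, reported from the center of
the first to the center of the last flagged window (the transition point at
which a window half-overlaps the core). If any track's interquartile range is
smaller than 25% of the midpoint (relative-IQR contrast guard), the
chromosome is declared coreless rather than segmented on noise; a synthetic
flat-track test pins this behavior.

Design decision — thresholds. Midpoint-of-IQR thresholds on the smoothed
tracks were chosen over genome-median thresholds because the median of a
track whose arm and core portions differ in length is biased toward the
longer compartment and shifts the recovered boundary by several window steps.
With the IQR midpoint, boundary recovery on the default synthetic layout is
within one window step (±100 kb) on both boundaries across 20 seeds; the
test suite requires ±200 kb.

Design decision — rate measurement. Per-region recombination rates are
measured on the called core trimmed by one window step (200 kb) per side, and
on arms shrunk by the same margin. The called boundary is only resolved to
one window step, so genetic distance accumulated in leaked arm sequence would
otherwise inflate the core kb/cM by tens of percent. With trimming, the
measured core/arm suppression ratio on synthetic data is 8.6–8.9 across
seeds, against a configured ratio of 1691/193 ≈ 8.76.

## Expression

RPM = count / library_size × 1e6. Tissue-specific: nonzero RPM in exactly one
tissue. Tissue-preferential at fold f (default 3): RPM in the top tissue ≥ f
× RPM in every other tissue, inclusive boundary, so (9, 3, 3, 3) qualifies at
f = 3 and (8.9, 3, 3, 3) does not. Comparisons against all-zero other tissues
succeed, which makes every specific gene also preferential (a set-inclusion
property asserted in tests); the fold margin is then reported as missing
rather than infinite.

## Homology classification

A hit is significant only when its e-value is strictly below 1e-5; the
synthetic hit generator plants hits at exactly 1e-5 among orphan genes so the
strict inequality is exercised. Orphan = no significant hit;
species-specific = at least one significant hit, all to the study species;
conserved = any significant foreign hit. Transcript coverage and
cross-assembly tiers use strict `>` thresholds throughout, and tiers nest:
identical ⊆ (cov>90, id>95) ⊆ (cov>50, id>95) ⊆ any significant.

## Ks and divergence dating

Ks uses Nei–Gojobori (1986) counting: the synonymous site count of a codon is
the fraction of its nine possible single-nucleotide changes that preserve the
amino acid (summed per position as syn/3); differences between two codons are
averaged with equal weight over all minimal mutational pathways, excluding
pathways through stop codons (if all are blocked, the changes count as
nonsynonymous). pS = Sd / S with S averaged between the two sequences, then
Jukes–Cantor corrected: Ks = −(3/4) ln(1 − (4/3) pS), undefined (saturated)
at pS ≥ 3/4, reported as a typed error rather than infinity. NG86 replaces
the maximum-likelihood codon-model estimation used in the original study;
for the small Ks values dated here (≤ 0.01) counting and ML estimates agree
to well within the dating precision.

Mode finding histograms the Ks values at a 0.0005 bin width from 0; a mode is
a bin strictly exceeding both neighbors (edges compare against an implicit
empty bin) and carrying at least 5% of the values. Dating is T = Ks / (2r)
with r = 6.1×10⁻⁹ synonymous substitutions per site per year; formatting
helpers round to the nearest thousand years (Ks 0.0001 → 8196.7 → 8000) or
to two decimals of million years (0.002 → 0.16, 0.003 → 0.25).

## SNP mining

A pooled group calls a SNP at a site iff exactly one non-reference base is
observed (at any depth — the strictest reading of "unique non-reference
allele") and that base's depth is ≥ 3 (inclusive: depth 3 qualifies). A
`strict_unique=False` flag relaxes uniqueness to "no second alt at calling
depth" for sensitivity analyses. Groups are called independently; the
combined count is group-keyed. Density is genome length / calls / 1000
(kb per SNP); genic assignment uses inclusive gene-span bounds. No minimum
reference depth or mapping-quality floor is imposed (the source protocol does
not state one); this is a known permissiveness.

## Synthetic-data generator

Each linkage group is arm + core + arm (defaults 3 + 3 + 3 Mb) with:

- gene densities 8.63 (arm) and 5.57 (core) genes/100 kb — genes are placed
  one per slot on a stratified grid so densities are exact in expectation and
  genes never overlap; each gene gets 1–5 exons and a CDS inside its span;
- repeat fractions 0.20 (arm) and 0.80 (core), laid down as ~5 kb blocks on a
  jittered grid;
- markers every 0.5 cM, walking in bp at the regional kb/cM rate (193 arm,
  1691 core) with ±2% step jitter. The 0.5 cM default (rather than 1 cM)
  guarantees several markers inside a 3 Mb core at 1691 kb/cM, without which
  the core rate would be unmeasurable;
- optional cutting into scaffolds at inter-gene gaps, with optional
  reverse-complement orientation flips (only applied to pieces carrying ≥ 2
  markers, since orientation is otherwise undetectable), plus unanchored
  marker-free scaffolds. Marker identifiers embed a seed-derived token so
  different seeds cannot be confused.

Expression counts are negative-binomial (dispersion 0.3) around a base mean
with library sizes of 0.8–1.2 M; planted preferential genes get a 4× margin
(above the 3× calling threshold, below nothing-else-comes-close), planted
specific genes are zeroed elsewhere. CDS pairs are generated by applying
synonymous substitutions one at a time and re-estimating Ks with the
package's own estimator until the target is hit within ±10% — a rejection
loop, so generator and estimator cannot drift apart; targets finer than one
substitution's worth of Ks raise an error advising longer genes. Allele
tables plant one positive per group at exactly depth 3 (boundary pinning) and
three negative classes: a unique alt at depth 2, two alts, and ref-only.

Realism limits: sequences are i.i.d. bases at 28% GC with no repeat families,
no paralogy, no assembly gaps inside scaffolds; the genetic map is noiseless
apart from step jitter; expression has no batch structure; allele depths are
not binomial draws from genotype frequencies. The generator's purpose is
truth-recovery validation of estimators, not biological realism.

## Problem sizes and runtime

The default study condition for topography is one 9 Mb chromosome
(~685 genes, ~63 markers); anchoring tests use two 5.5 Mb linkage groups cut
into four scaffolds each plus unanchored pieces. The full test suite,
including 20-seed pericentromere recovery and a 1000-multiset N50 oracle
sweep, runs in well under a minute on one CPU (target: < 10 min).

## Published values that are inputs, not outputs

The scaffold count (38,513), genome GC (27.95%), real pooled SNP counts
(2150 desi / 2199 kabuli), the 141.9 kb mean SNP spacing and the real 193 /
1691 kb/cM rates depend on raw data not reproducible at desk scale. They
appear only in `cicerkit.metadata` and as generator defaults; no analysis
claims to re-derive them, and an acceptance test asserts exactly this role.
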