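# Methods

## Scope and data model

The package re-implements, as a tested pipeline, the computational chain of
an endosperm-demethylation study: per-cytosine methylation maps are merged
across biological replicates, intersected per sequence context between two
samples, aggregated onto a fixed 200-bp grid, and thresholded into region
calls; region sets are then characterized against annotations, small-RNA
data, imprinting calls and expression categories; and a separate
bulked-segregant module maps a causal mutation from pooled variant tables.

Coordinates are 1-based in CGmap files and 0-based half-open (BED) for
every interval in memory and on disk; conversion happens only at I/O
boundaries. Sites are kept per-cytosine per-strand with no symmetric-CpG
collapsing. The floating-point level column of CGmap input is never
trusted: levels are recomputed from counts, because count sums are what the
weighted bin levels need.

## Region callers

All callers share one grid anchored at coordinate 0 of each chromosome
(the anchor is a convention; any fixed anchor gives an equivalent caller).
Defaults:

| parameter | value | meaning |
|---|---|---|
| bin_size | 200 bp | grid resolution of all region calls |
| min_count_c | 5 | informative cytosines per context per bin |
| min_cov (DMR) | 3 | mean depth over a bin's informative sites, both samples |
| min_abs_dif | 0.20 | absolute level difference, strict |
| fold | 2 | relative change, strict |
| min_cov (MR/UMR) | 2 | single-sample callers |
| min/max level (MR/UMR) | 0.2 | inclusive |
| control level | 0.2 | mCG and mCHG, inclusive, in ≥ 1 sample |

Decisions where the original tooling left room:

- "Mean coverage" is interpreted per context over a bin's informative
  (covered-in-both-samples) sites, not bin-wide over all positions.
- Bin levels are count-weighted (Σmeth/Σtotal), not means of per-site
  fractions; low-coverage sites therefore contribute proportionally.
- DMR thresholds are strict inequalities ("greater than"); eligibility,
  mCHH-region, UMR and control thresholds are inclusive ("at least"). The
  MR/UMR comparisons are configurable (`strict=`) since the original
  scripts do not document their convention.
- Zero denominators need no special case: with v₁ = 0 the strict fold
  condition v₂ > 2·v₁ degenerates to v₂ > 0, which is the limit of the
  fold rule; the absolute-difference guard still applies.
- The CG∩CHG combination is same-grid-bin identity. On a shared grid this
  equals any ≥ 1-bp interval intersection, which is what the original
  pipeline computed with a generic interval tool.
- Scaffold exclusion is applied to the final DMR sets only (the callers
  themselves are sequence-agnostic); the default allowed list is
  chr1–chr10.

Replicate merging sums counts over the union of positions — a site absent
from a replicate has zero coverage there, which is information, not
missingness. Context and strand must agree at shared positions.

## Annotation statistics

Overlap fraction is measured against the union of elements per query, so
several small overlaps accumulate (mirroring `-f` semantics of the classic
BED toolchain). Enrichment is always relative to methylated control
regions, which cancels the ascertainment of coverage-eligible bins.
End-anchored profiles count a region once per 100-bp offset bin it touches,
per anchor, in transcript orientation (minus-strand anchors mirrored);
bins with zero control counts are reported missing, never zero. Flanking
methylation profiles average count-weighted per-region bin levels across
regions, requiring site coverage ≥ 1; empty bins are NaN. Motif matching
replaces FIMO scoring with exact degenerate-consensus matching: the two
PHE1 motifs (TTWCCATATW, CCAWAAATGG) contain no ambiguity beyond W, so
p-value scoring adds nothing; this is a deliberate simplification.

## Exact tests

Fisher's exact test sums hypergeometric point probabilities over all
tables with the observed margins whose probability does not exceed the
observed table's ("sum of less-likely outcomes", the dominant two-sided
convention; definitions vary), with a 1 + 1e-7 relative slack to absorb
floating-point ties; degenerate margins give p = 1. The test suite checks
it against exact-integer enumeration on *all* 2×2 tables with N ≤ 60.
The Yates χ² uses the closed 2×2 formula with the correction clipped at
zero; the binomial test enumerates the full outcome distribution; the
two-sample t is pooled-variance Student by default with a Welch option.
scipy contributes only the χ² and t survival functions.

Segregation expectations come from a small cross model: phased parent
haplotypes, a Haldane linkage chain (map distance in Morgans between
adjacent loci, `None` = unlinked), exact gamete-class enumeration, and an
optional progeny selection rule with renormalization. This reproduces the
1 defective : 3 normal megagametophyte expectation and the 1/4
non-fluorescent control expectation for two unlinked marker insertions.

## The synthetic world

The generator's defaults are the stated conditions of the emulated study
wherever the study states them, scaled to desk size where it does not:

- **Genome**: 2 × 5 Mb chromosomes plus a 0.5-Mb unplaced scaffold
  (desk-scale; the real genome's 2.1 Gb is out of reach for CI).
- **Methylomes**: three biological replicates per sample at Poisson
  coverage 10 each (merged ≈ 30×); CG/CHG/CHH site densities 0.05 / 0.05 /
  0.06 per bp (≈ 10, 10, 12 informative sites per 200-bp bin); a
  two-compartment truth — heterochromatin mCG/mCHG/mCHH 0.85/0.75/0.08,
  euchromatin (genes ± 1 kb) 0.05/0.02/0.01; enzymatic conversion error
  0.005 folded into the binomial success probability.
- **Planted DMRs**: 300 grid-aligned bins with mCG/mCHG truth 0.80 in
  mutant endosperm and embryo, 0.05 in wild-type endosperm (Δ = 0.75,
  far above the 0.20 threshold by design). 40% sit inside Helitron-family
  copies (motif-carrying copies preferred 70:30), 30% in the
  heterochromatic margin 1.2–3 kb upstream of genes, the rest on random
  heterochromatic bins. 200 further bins carry endosperm mCHH 0.4.
- **siRNA libraries**: Poisson per-locus emission — housekeeping loci emit
  abundantly (removed by the classifier), background loci at rate 1, DMR
  loci at 2.5 reads/locus in wild type × 2.0 in the mutant; lengths
  dominated by 24 nt; 20% of reads tagged low-MAPQ to emulate
  multi-mappers. Library sizes (~10⁴ siRNAs) are a deliberate scale-down
  of the 2×10⁷-read subsampling target; the depth-matching logic is
  identical.
- **Imprinting**: 1,000 genes, 5% MEGs (maternal probability 0.97), 5%
  PEGs (0.03), the rest biallelic at exactly 2/3; ~200 informative reads
  per gene split over two reciprocal directions.
- **BSA**: 10 × 5 Mb chromosomes with markers every 50 kb, 1.5 Morgans of
  genetic length per chromosome (maize-like ~150 cM compressed onto the
  desk-scale physical length), causal locus near the distal tip of chr4
  (as in the mapped mutation), 500 selected mutant homozygotes, mutant
  pool at Poisson 30×, comparison bulk at 8×, sequencing error 0.001.
  Placing the causal locus at a tip and keeping per-chromosome genetic
  length realistic keeps the linked region a small fraction of the genome,
  so the genome-wide mean alternative allele frequency stays near the 0.75
  cross expectation even at desk scale. GQ/PL fields come from a diploid
  binomial genotype-likelihood model — internally consistent with the
  read counts, which is all the filters assume.

What the generator does **not** emulate: sequence composition of
demethylated regions (the real DMRs are AT-rich; synthetic DMR bins have
background GC, so the GC-content contrast is not reproduced), genome-scale
DMR counts (tens of thousands on 2.1 Gb), realistic TE landscapes and
nested insertions, chromatin-state autocorrelation along chromosomes, and
read-level artifacts (mapping bias, PCR duplicates). A green recovery test
therefore establishes correctness of the calling logic under the stated
sampling model, not real-data performance.

## Numerical choices

- Interval primitives use sorted-array binary search; "nearest" distance
  is gap distance (0 for overlapping or book-ended intervals), NaN when a
  chromosome has no target.
- Subsampling is uniform without replacement with an explicit seed.
- Window scans report unweighted mean frequencies by default
  (depth-weighting is exposed); empty windows are NaN, never 0.
- Candidate-region detection takes the longest run of ≥ 3 consecutive
  windows above background + 0.15, ties broken by pooled frequency then
  leftmost coordinate; the 0.75 background is a parameter of the cross
  design, not a constant.
- The BSA variant filters treat depth bounds as inclusive ("between 5–14"
  → [5, 14]) and the frequency bound as strict ("above 0.75").
- Imprinting needs ≥ 10 informative reads by default (the threshold is a
  configurable stand-in for the replicate-consistency criteria of the
  upstream allele-specific pipeline, which are not restated here);
  reciprocal directions are summed before the ratio.

## Known limitations

- The pipeline consumes methylation calls, aligned small-RNA intervals,
  allele counts and variant tables; alignment, methylation calling and
  genotype-likelihood computation are upstream and out of scope.
- DMR units are single 200-bp bins; adjacent significant bins are not
  merged (matching the emulated analysis, which reports bin counts).
- No statistical testing is attached to DMR calls — the caller is purely
  threshold-based by design.
- The Fisher/binomial tie slack (1 + 1e-7) means p-values within that
  relative distance of a point-probability tie are treated as ties, the
  same convention as the standard R implementation.
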