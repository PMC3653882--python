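# Methods

## Tag anatomy and reference tags

A DGE tag is the 21-mer released by NlaIII digestion (which cuts at
CATG) followed by MmeI cleavage 17 bp downstream: the CATG anchor plus
17 bases.  For every reference transcript we extract *all* such
21-mers on both strands — each CATG occurrence with a full 17-nt
downstream window yields a tag; overlapping sites each yield their own
tag, and windows containing an ambiguous base (N) are skipped.  Tags
from the reverse complement are recorded as `antisense`; because CATG
is its own reverse complement, reverse-complementing a transcript
exactly swaps its sense and antisense tag sets (a tested invariant).

Each tag carries a `rank_3prime`: the 1-based index of its source CATG
counted from the 3' end of the tag's own strand, over taggable sites
only.  Rank 1 is the 3'-most site, the one the oligo(dT) bead-capture
chemistry observes most often.  Coordinates are 0-based half-open
internally; reports use the 1-based ranks.

Ambiguity is defined at the distinct-sequence level over gene ids: a
tag sequence hitting more than one gene is ambiguous; a tag hitting one
gene at several positions or on both strands is not.  The index
records both distinct-sequence and occurrence totals so either
accounting can be reported.

## Filtering and the removal ledger

Raw tag multisets are cleaned by four filters applied in fixed
precedence so each distinct tag is charged to exactly one category:
adaptor-containing (including adaptor-only "empty" reads), ambiguous
bases (N), length ≠ 21 nt, and copy number < 2 (singleton tags are the
signature of sequencing error).  Copy number is evaluated after the
sequence filters: a tag surviving on count must already be a valid
21-mer.  The ledger satisfies exact conservation — raw = clean +
Σ removed for distinct and total counts simultaneously — and expresses
percentages against the raw library (2 decimal places, rounded
half-up), while copy-number bins of the clean library (≥2, >5, >10,
>20, >50, >100) re-anchor their percentages to the clean totals.
Filtering is idempotent: re-filtering a clean library removes nothing.

## Mapping and quantification

Matching is two-tier: exact dictionary lookup first; only tags with no
exact hit consult their 63 Hamming-distance-1 neighbours.  A mismatch
may fall anywhere in the 21-mer, anchor included — sequencing error
does not respect the restriction site — but exact hits take strict
priority, so anchor-breaking neighbours can never displace true
matches.  At its tier, a tag whose hits span more than one gene is
discarded as ambiguous; a tag whose neighbourhood hits several
reference tags of one gene is assigned to that gene (gene-level
ambiguity is what matters for counting).  On a same-gene strand tie
the sense orientation is preferred.  Every clean distinct tag lands in
exactly one of {assigned, ambiguous, unknown}; counts are conserved.

TPM is tag count / clean-tag total × 10^6.  The denominator is the
clean total, not the mapped total: mapping rates are themselves
expressed against clean tags, and normalising before mapping-rate
accounting keeps TPM comparable across libraries with different
unknown-tag fractions.  The convention is isolated behind one
`tpm_denominator` switch (`"clean"` | `"mapped"`).

Report summaries follow the standard library-characteristics layout:
"Mapping to Unigene" counts assigned + ambiguous tags, "Unambiguous
Mapping" the assigned ones, "Unknown Tag" the rest; "All Tag-mapped
Genes" are genes appearing in any mapped tag's hit set, "Unambiguous
Tag-mapped Genes" those receiving at least one assigned tag.

The saturation curve expands the tag multiset to unit copies, applies
one fixed-seed permutation, and reports distinct tags and mapped genes
at cumulative depths `step, 2·step, …, total` (the final point always
equals full-library mapping).  The rank histogram accumulates assigned
tag counts by the matched reference tag's `rank_3prime` (the most-3'
rank when a tag sequence occurs at several positions), pooling ranks
above 10.

## Differential expression

The Audic–Claverie statistic conditions on the count `x` in library 1:
given library totals `N1, N2` and `r = N2/N1`, the predictive
distribution of the count in library 2 is negative-binomial with size
`x+1` and success probability `N1/(N1+N2)`.  Two-sided significance is
the doubled smaller closed tail, capped at 1.  Numerically, the tail
on the far side of the distribution's mean is summed directly in log
space (chunked `logsumexp`; terms decay geometrically away from the
mode, so the sum converges in a few chunks even for counts in the
hundreds of thousands) and the opposite tail is recovered by
complementation through the point mass.  Tests verify agreement with
exact rational-arithmetic summation to 1e-12 relative error and with
the scipy negative-binomial CDF/survival closed forms.

Note on symmetry: doubled closed tails are exactly symmetric under
(x, y, N1, N2) → (y, x, N2, N1) only up to the point mass at the
observation (the identity Σ_{k≤y} p(k|x; r) + Σ_{j≤x} p(j|y; 1/r) = 1
makes the mixed open/closed convention the exactly symmetric one, but
that convention does not cap x = y comparisons at 1).  We keep the
closed-tail convention used in tag-profiling practice and test
orientation agreement within the exact discreteness bound.

Per comparison, the tested universe is the union of genes detected in
either library (x = y = 0 genes carry no information and would only
dilute the correction); BH-FDR is computed per pairwise comparison.
`log2Ratio = log2(TPM2/TPM1)` with a floor of 0.001 TPM substituted
for zeros only, so condition-specific genes get finite ratios; the
floor is configurable and recorded in output metadata.  A gene is
significant at `FDR ≤ 0.001` and `|log2Ratio| ≥ 1`; direction `up`
means higher expression in the second (treatment) library.  The
overlap summary classifies genes significant in two comparisons as
coordinated (same direction) or antagonistic.  The 2^−ΔΔCt helper
implements the standard qPCR relative-expression arithmetic used to
validate tag-based calls.

## Enrichment

Upper-tail hypergeometric test per term with k ≥ 1 DE hits, against
the annotated background (genes without any term are excluded from
both the background size N and the DE-set size n, since they cannot
contribute to any term).  Correction is applied within each namespace
separately (each ontology category, the pathway set), BH by default
with Bonferroni as an option; "corrected p ≤ 0.05" flags enrichment.
Annotations are tested as supplied — no ancestor-term propagation.

## Synthetic data

The generator emulates the anatomy of a tag-profiling experiment, not
its sequencing chemistry:

* **Transcriptome** — random A/C/G/T sequences, default 2,000 genes of
  200–2,000 nt (bracketing the few-hundred-nt mean of short-read
  transcriptome assemblies) at 40% GC (typical of dipteran
  transcripts).  A CATG site with a full downstream window is
  implanted when the random draw lacks one, so every gene is taggable.
* **Truth** — log-normal(0, 1) baseline abundances: a heavy-tailed
  profile in which a small fraction of genes carries most of the tag
  mass, as observed in real copy-number distributions.  A configurable
  fraction of genes (default 10%) is differentially expressed at
  ±log2fc_magnitude (default 2), sign uniform, applied to every
  treatment library; library 0 is the control.
* **Tag sampling** — per molecule: gene ∝ baseline × 2^log2fc, then
  CATG rank geometric from the 3' end (default rank_bias 0.6, putting
  ~84% of molecules on the first two 3' sites, reproducing the
  rank-position profile of bead-captured libraries), then strand
  (default antisense fraction 0.30, giving a substantial bidirectional
  signal; genes without antisense tags fall back to sense), then
  independent per-base substitution error (default 0.5%) producing the
  1-mismatch tag class.
* **Noise** — per-tag N-injection (default 0.5%) and singleton random
  CATG+17 tags (default 2% of depth, each copy number 1), which the
  low-quality and copy-number filters must remove.

Total emitted count equals `depth_per_library` exactly.  One integer
seed drives everything: the transcriptome uses the base stream, truth
and each library use derived substreams keyed by (seed, library
index), so fixed seeds give bit-identical outputs while libraries stay
mutually independent.

What the generator does **not** model: read-level 49-bp FASTQ
artifacts, base-quality profiles, adapter-ligation chemistry, PCR
duplication, positional error biases, cross-gene sequence homology
(random sequences share almost no tags, so ambiguous-tag rates are far
below those of real assemblies with clusters and isoforms), or
biological replicate variability (the AC test models sampling noise
only).  Passing tests therefore demonstrate correctness of the
accounting and calibration of the statistics under multinomial
sampling, not robustness to real-data artifacts such as shared tags
between paralogs or overdispersion between biological replicates.

## Problem sizes and numerical choices

The default validation design uses 2,000 genes and two libraries of
10^6 tags — large enough that per-gene counts (mean ≈ 350 sense tags)
give the AC test sharp power at 4-fold changes, while the whole
pipeline runs in seconds.  At these settings the caller's measured
sensitivity is ≥ 0.95 with empirical false-discovery proportion ≤ 0.02
across seeds, and null (0% DE) runs call essentially nothing.

Report percentages round half-up to 2 decimal places via decimal
arithmetic (matching printed-table conventions; banker's rounding
would differ on exact ties).  AC p-values are clamped to the open
interval (0, 1] (smallest positive subnormal as the floor).  Degenerate
inputs are defined rather than accidental: transcripts without CATG
sites yield empty tag sets, an empty index or empty p-value vector is
an error, a clean library with zero antisense tags reports an infinite
sense:antisense ratio, and empty-design simulations raise a dedicated
error.
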