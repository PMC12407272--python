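# Methods

This note documents the models, algorithms and numerical choices behind
`subdom`, what the synthetic data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3 I/O converts at the
boundary (1-based closed on disk), and BED/TSV formats pass through
unchanged. Subgenome membership (A or B) is a property of the chromosome
and is inherited by every feature. Each gene carries one representative
transcript — the mRNA with the longest summed CDS — used for feature
annotation and transcript-coordinate work; when a GFF3 lacks explicit
UTR features they are derived as exon-minus-CDS split at the CDS span.

## Statistical primitives

* **BH adjustment** is the standard step-up with monotonicity enforced
  from the largest p downward; output preserves input order.
* **Fisher exact (two-sided)** uses the point-probability rule: the
  two-sided p is the sum of hypergeometric probabilities of all tables
  with the observed margins whose probability does not exceed the
  observed table's (relative tolerance 1e-7, as in R). The pmf is
  computed from log-gamma functions, which vectorizes over hundreds of
  thousands of tables; the effect is the sample odds ratio, infinite
  when a zero off-diagonal makes it so.
* **Rank-sum test**: exact when both samples have ≤ 25 observations and
  no ties, via a dynamic program over subset rank sums (identical to
  full permutation enumeration); otherwise the normal approximation with
  midranks, tie-corrected variance and a 0.5 continuity correction. The
  effect is the Hodges–Lehmann shift (median of pairwise differences;
  for very large samples, difference of medians).
* **Enrichment** is the upper hypergeometric tail with fold enrichment
  as effect.
* **Root activity** (TTC assay) defaults to the conventional
  mg·g⁻¹·h⁻¹ reading, TTC/(weight × time). The alternative
  TTC/(weight / time) reading — which has units mg·h·g⁻¹ and the
  opposite time dependence — is available behind `literal=True`; the two
  coincide at t = 1 h.

## Negative-binomial differential testing

Counts are normalized by DESeq-style median-of-ratios size factors
(identifiable under the usual assumption that most genes do not change).
Per-gene dispersion is estimated by method of moments on normalized
counts, `(s² − m̄)/m̄²` floored at 1e-8, then shrunk toward a global
prior (the trimmed mean of positive gene-wise estimates) with prior
weight 10 against the residual degrees of freedom. With 3 replicates per
group the raw gene-wise estimator has 4 df and is far too unstable for a
Wald test — unshrunk it produces type-I rates above 30%; the moderated
estimator keeps the empirical type-I rate at ~5.6% at nominal 5%
(measured on 10,000 null genes) while retaining > 99% power for
four-fold changes at mean 100 and dispersion 0.05. The Wald statistic is
log2FC over its delta-method standard error with 0.5 pseudocounts;
DEG calls require |log2FC| > 1 (strict) and BH-FDR < 0.05 (strict).

**Homoeolog bias** reuses the same engine per tissue, treating the A and
B counts of each pair as the two conditions with replicates as units.
Because both members are measured in the same libraries, no
between-condition normalization is applied (size factors would otherwise
absorb a genuine genome-wide bias toward one subgenome). A pair is
biased in a tissue at BH-adjusted p < 0.01; the pooled per-pair class is
"biased in ≥ 1 tissue" by default (a majority rule is available), with
direction taken from the most significant tissue.

## Homoeolog pairing and fractionation

Anchor hits are chained greedily in gene-rank space: consecutive anchors
must advance by at most `max_gap` (default 10) intervening genes on both
chromosomes in a consistent orientation, so inversions form their own
blocks; blocks need `min_block` (default 5) anchors. Within a block,
hits are assigned one-to-one by descending similarity; block-spanned
genes left unpaired become singletons of their subgenome, genes outside
all blocks stay unassigned (this is where tandem extra copies end up).
Retention profiles count, per window of 100 ancestral gene slots, the
fraction of slots retained in A, in B, and in both; the balance test is
a paired Wilcoxon signed-rank across windows.

## Methylation

All averaging is read-weighted (Σ methylated reads / Σ total reads),
robust to coverage variation; zero-coverage sites contribute nothing and
empty bins are reported as missing, never zero-filled. Metaprofiles use
fixed-bp flank bins (default 20 bins over 2 kb) and length-normalized
body bins (default 20), flipped for minus-strand regions.

## Accessible chromatin

Positional classes use a strict priority: genic (any gene-body overlap)
beats proximal (within 5 kb upstream of the nearest TSS, strand-aware,
boundary inclusive) beats distal. An optional `flank_mode="both"`
extends the proximal window to both sides of the TSS. Each ACR is
attributed to the gene with the nearest TSS only. Conservation calling
projects an ACR into the partner subgenome through its anchor gene's
homoeolog, preserving the TSS offset along the gene orientation, and
requires a same-tissue partner ACR overlapping the projection by ≥ 1 bp;
ACRs anchored on singletons are specific with a "no-anchor" flag.
Variant density is variants per kb over the ACR plus its projection.
Ancestry attribution compares, per variant in a subgenome-specific ACR
region, the carrying subgenome's allele with its own progenitor's
(progA for A, progB for B); missing genotypes leave both numerator and
denominator.

## m6A peak calling

Transcripts are tiled with 50-bp windows. Each window's (IP, input)
counts are tested against the remaining library mass by Fisher exact;
windows with library-size-normalized IP/input ≥ 2 (inclusive, raw
counts) and p < 0.05 (strict) are significant, and adjacent significant
windows merge into peaks (count-weighted mean log2 ratio with 0.5
pseudocounts, minimum window p). Feature assignment is by maximal bp
overlap with priority 3'UTR > 5'UTR > CDS on ties; transcripts without
UTRs map to CDS. Homoeolog sharing is scored at the pair level: a pair
with both members methylated is shared, otherwise specific to the
methylated side, fractions over pairs with ≥ 1 methylated member.
Differential methylation tests, over the per-gene union of called peak
spans, the 2×2 of summed (IP, input) counts between conditions, flagging
regions at BH-FDR < 0.05 and |Δlog2 ratio| ≥ 1 (both configurable — no
canonical threshold exists for this contrast). Peaks whose enrichment
vanishes in one condition are, correctly, reported as differential by
this test as well as missing from that condition's peak list.

## The synthetic data generator

The generator is the package's test bed: it produces a full bundle
(genome table, GFF3 genes, TE/ACR intervals, per-cytosine methylation,
count matrices, m6A windows, VCF variants, anchor hits) plus truth
tables sufficient to score every downstream classification. Every
generator is a pure function of (config, seed) — each component draws
from its own named RNG substream, so adding one generator never
perturbs the others, and bundles are byte-identical across runs.

Defaults encode the study conditions: ~70% of homoeolog pairs biased,
80% of those toward subgenome A; five tissues × three replicates plus a
control/waterlogging root contrast with per-subgenome DEG rates of
0.20/0.19; TE density higher in B than A; methylation spreading from TE
edges as `background + (plateau − background)·exp(−d/λ)` with λ = 500 bp
and CG/CHG/CHH plateaus 0.85/0.65/0.12; proximal-ACR probabilities 0.6
(A) vs 0.5 (B) with 10% of conserved ACRs destroyed in B by a recorded
126-bp insertion; progenitor genotypes matching the ACR-carrying
subgenome at 0.773; m6A peaks on 60% of genes, pair-structured
82/15/3 shared/A-only/B-only, 80% in 3'UTRs, losing 16% of peaks under
waterlogging.

Structural choices, made for testability where no empirical model was
available:

* genes sit on a uniform grid (default 1 kb genes, 4 kb spacing) with
  jitter, single-exon, fixed UTR lengths; TEs are a Poisson process
  (fixed 800 bp length) placed uniformly in intergenic space;
* fractionation is unbiased by construction (lost slots split evenly);
* biased pairs receive a log2 offset drawn around the configured mean
  (clipped below at 1.0) split symmetrically between the homoeologs —
  planted effects sit clearly above the calling threshold so that truth
  classes are identifiable;
* DEG effects are |log2FC| ≥ 2 (threshold + exponential tail), again
  clearly above the fold-change gate; differential m6A levels shift by
  2.0 log2 units — an effect equal to the |Δ| ≥ 1 flag threshold would
  by construction be detected only half the time;
* differential m6A peaks are planted preferentially (prob. 0.7) on
  waterlogging DEGs with the opposite expression direction, emulating
  the predominantly repressive coupling between m6A and transcription;
* counts are gamma-Poisson (NB) with dispersion 0.05; m6A input depth
  10 reads/window, IP background 3, peak enrichment 10× (IP mean 30 in
  peak windows).

What the generator does **not** emulate: real sequence content (no
FASTA; the insertion mechanism is a variant record plus ACR deletion),
multi-exon transcript structure, spatially clustered TEs or genes,
expression-coupled methylation, batch effects, mapping artifacts, or
library-size imbalance. Passing tests therefore demonstrate that the
statistical machinery recovers known structure under the stated noise
models — not that it is robust to every failure mode of real
sequencing data.

## Problem sizes and determinism

The default bundle is 2 × 5 chromosomes with 1,000 ancestral gene slots
each (~8,000 genes after fractionation, ~3,000 pairs); recovery
experiments use ~20,000 pairs (bias), ~50,000 variants (ancestry) and
~5,000 planted peaks (m6A loss). The full pipeline over the default
bundle runs in well under a minute on one CPU. All outputs are pure
functions of (inputs, config, seed); TSV floats are written with a fixed
`%.6g` format so repeated runs are byte-identical.

## Known limitations

* The greedy anchor chainer is not an optimal collinear-chain solver;
  on heavily rearranged genomes a DP chainer (MCScanX-style) would
  recover more blocks. At the simulated rearrangement rates recovery
  F1 is ≥ 0.98.
* The NB engine tests one contrast at a time; no GLM with covariates or
  batch terms.
* ACR projection assumes the TSS offset is conserved between
  homoeologs; whole-genome-alignment lift-over would be more faithful
  for distal ACRs.
* Exact rank-sum p-values require tie-free data; tied small samples fall
  back to the normal approximation.
* The m6A caller's window-level Fisher test is anti-conservative for
  single isolated windows at very shallow depth; peak-level precision
  at the default depths is ≥ 0.9 because planted peaks span several
  windows and the IP library is peak-dominated.
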