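# subdom

Multi-omic subgenome-dominance analysis for allopolyploid genomes.

Allotetraploid plants carry two complete diploid genomes — two
*subgenomes*, here labelled A and B — inherited from different progenitor
species. A recurring observation in such genomes is **subgenome
dominance**: one subgenome's gene copies (*homoeologs*) are expressed more
highly, sit farther from transposable elements (TEs), are less
methylated, carry more accessible chromatin, and respond more strongly to
stress. `subdom` implements the full analysis chain used to characterize
this phenomenon from summary-level omics data:

* **homoeology** — collinear anchor chaining in gene-rank space to pair
  homoeologs and identify singletons, and sliding-window gene-retention
  (fractionation) profiles along an ancestral gene order;
* **expression** — TPM normalization, the expressed-gene filter
  (TPM > 0.1 in ≥ 1 tissue), a vectorized negative-binomial Wald test
  with median-of-ratios size factors and moderated method-of-moments
  dispersion, homoeolog expression-bias classification (adjusted
  *p* < 0.01), singleton comparisons, and per-subgenome differential
  expression accounting (fold change > 2, FDR < 0.05);
* **repeats / methylome** — TE content and gene–TE distances, solo:intact
  LTR ratios, LTR insertion ages (*T* = *K*/2µ), read-weighted global
  methylation levels per CG/CHG/CHH context, and length-normalized
  metaprofiles over TE/gene bodies with 2 kb flanks;
* **chromatin** — accessible-chromatin-region (ACR) positional classes
  (genic > proximal within 5 kb upstream of a TSS > distal),
  per-gene proximal-ACR rates, conserved vs subgenome-specific calling by
  homoeolog-anchored projection, variant-density divergence, and
  progenitor ancestry attribution of specific-ACR variants;
* **m6a** — windowed MeRIP IP-vs-input peak calling (normalized
  IP/input ≥ 2, Fisher *p* < 0.05, adjacent significant windows merged),
  transcript-feature annotation (3'UTR-dominant), homoeolog sharing,
  condition comparisons of peak number and level, differential
  methylation, and integration with differential expression;
* **synthetic** — a seeded generator that emits a complete, mutually
  consistent bundle (GFF3, BED, TSV, VCF) with truth tables, so every
  stage can be exercised and scored without raw sequencing data;
* **stats** — the shared primitives: Benjamini–Hochberg step-up,
  two-sided Fisher exact (point-probability rule), exact/approximate
  Wilcoxon rank-sum, hypergeometric enrichment, and the TTC root-activity
  formula.

## Worked example

```python
from subdom.synthetic import SimConfig, generate_dataset
from subdom.pipeline import PipelineInputs, run_pipeline
from subdom.model import AnalysisConfig

sim = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=300, seed=7)
bundle = generate_dataset(sim, outdir="demo_bundle")
summary = run_pipeline(AnalysisConfig(),
                       PipelineInputs.from_bundle_dir("demo_bundle"),
                       "demo_out")
for k in ("n_pairs", "biased_pair_percent", "biased_toward_A_percent",
          "acr_per_gene_A", "acr_per_gene_B", "ancestry_match_percent",
          "m6a_peak_change_percent", "m6a_utr3_fraction_CTL"):
    print(f"{k:28s} {summary[k]}")
```

prints

```
n_pairs                      360
biased_pair_percent          72.222
biased_toward_A_percent      82.692
acr_per_gene_A               0.603
acr_per_gene_B               0.508
ancestry_match_percent       79.842
m6a_peak_change_percent      -18.662
m6a_utr3_fraction_CTL        0.775
```

Reading: of 360 homoeolog pairs recovered by anchor chaining, 72% show
significant expression bias (adjusted *p* < 0.01), ~83% of those toward
subgenome A; subgenome A carries more proximal ACRs per gene; ~80% of
variants in subgenome-specific ACR regions match the corresponding
progenitor genotype (so most regulatory divergence predates
polyploidization); and m6A peak numbers drop ~19% under the waterlogging
condition, with peaks concentrated in 3'UTRs. The same pipeline runs from
the shell:

```bash
subdom simulate --outdir bundle --seed 7
subdom report --bundle bundle --outdir results
```

Every stage writes plain TSV tables plus a `summary.json`; outputs are
byte-identical across runs at a fixed seed.

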