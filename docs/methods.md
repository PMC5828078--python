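# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `methyltrx`.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`. GTF
(1-based inclusive) is converted on read and write; BED passes through.
The promoter window spans `upstream` bp upstream and `downstream` bp
downstream of the TSS (defaults 5000 and 200), with the TSS base counted on
the downstream side; the minus-strand window mirrors the plus-strand rule
around the TSS base: `[tss − downstream + 1, tss + upstream + 1)`. Widths
are therefore exactly `upstream + downstream` except where clipped at
chromosome edges. Positions (e.g. read starts) are assigned to regions by
point membership, not span overlap: fragment lengths are not modelled.

## Differential count test

Both arms (gene expression, region methylation) use the same engine:

- **Normalization.** Median-of-ratios size factors: for sample *j*,
  `f_j = median_i(c_ij / (∏_j c_ij)^(1/n))` over features positive in every
  sample, rescaled to geometric mean 1. Note the rescale means multiplying
  one library by a constant shifts the global normalized scale by
  `c^(1/n)`; fold-changes and p-value rankings are invariant, p-values to
  about 1e-4.
- **Dispersion.** A per-feature common dispersion `α` from the
  method-of-moments identity `Var = μ + αμ²`, pooling within-group sample
  variances with their degrees of freedom as weights, floored at 1e-8
  (Poisson limit). No shrinkage across features: the test stays fully
  specified and self-contained.
- **Effect and inference.** `log2FC = log2((μ̄₁+½)/(μ̄₂+½))` on the
  normalized scale (the pseudo-count keeps zero-mean features finite);
  `SE` by the delta method from `Var(μ̄_g) = (μ_g + αμ_g²)/n_g`; two-sided
  p from a **t reference with n₁+n₂−2 degrees of freedom**. With five
  samples per group the dispersion estimate is noisy, and a normal
  reference inflates the null rejection rate to ~8–9%; the t reference
  keeps it at the nominal 5% (measured 4.4–6.1% across null simulations).
- **Multiplicity.** BH step-up over tested features; features below the
  optional normalized-mean threshold or with all-zero counts are reported
  with missing p/q and excluded from the BH denominator (independent
  filtering practice).
- The regression stage additionally filters genes with mean raw expression
  count below 50 (strict `<`: a mean of exactly 50 is kept).

## Preranked GSEA

The ranking score is `sign(log2FC) · (−log10 p)` (p clamped at the smallest
positive double; an integer-rank variant preserving the same order is
available behind a flag). Ties break lexicographically by gene id. The
enrichment score is the classic weighted-KS statistic with weight 1: hits
add `|s|^w / Σ_hits |s|^w`, misses subtract `1/(N − N_H)`, the ES is the
running-sum extremum (sign ties resolved positive), and the leading edge
collects hits at/before (after, for negative ES) the extremum. The running
sum ends at 0 by construction; `|ES| ≤ 1` with equality iff all hits
precede all misses.

Significance uses gene-tag permutation — uniformly resampled same-size
sets — rather than phenotype permutation: with five samples per group the
phenotype-label null is far too coarse. The p-value is computed among
same-sign null scores with +1 smoothing,
`p = (1 + #{|ES_null| ≥ |ES|}) / (1 + #same-sign)`, `NES = ES /
mean(|same-sign nulls|)`, and BH runs across the sets evaluated in one
call. Defaults: 1000 permutations, weight 1.

## Mediation model

On `log2(normalized count + 1)` values, per gene:
stage 1 `methylation ~ group` gives `a`; stage 2 `expression ~ methylation
+ group` gives `b` and the direct effect; the indirect effect is `a·b`, and
by OLS algebra `total = direct + indirect` exactly (verified to 1e-8).
Inference is a percentile bootstrap resampling samples with replacement
*within* groups (2000 replicates by default, seed-deterministic); the
two-sided p is twice the smaller tail proportion of replicates on either
side of zero, +1-smoothed. Zero-variance mediators yield missing results.
Under a planted Gaussian chain (a=1, b=−0.5, noise sd 0.2, n=5+5) the mean
indirect estimate is within 0.02 of truth and the 95% CI covers it ~94% of
the time; under the null the false-positive rate is well below 5% (the
product-of-coefficients null is conservative).

## TF-network overlay

TFs are network nodes with out-degree ≥ 1. Dysregulation requires FDR
< 0.05 **and** |log2FC| > 1, both strict. "Nearest downstream neighbors"
means direct out-neighbors (path length 1; multi-hop closure is
deliberately not the default). A target counts as altered on FDR < 0.05
alone — no fold-change threshold on targets — classified up/down by the
sign of its log2FC; targets absent from the differential table count in
the total but never as altered. Ranking is by altered-target count, ties
by altered fraction then id.

## Compound query

Replicate signatures are z-scored per replicate (population sd over genes)
and collapsed by the per-gene median — reproducibility is expressed as a
consensus rather than as a filter that discards compounds, keeping the
query deterministic and testable. Membership: rank genes by descending
consensus score (ties lexicographic); "up" iff rank ≤ k from the top,
"down" iff rank ≤ k from the bottom; k must be < n/2 so the tails cannot
overlap, and membership is invariant under any strictly monotone transform
of the scores. Under exchangeable null scores the per-(compound, context)
hit probability is 2k/n.

## Synthetic-data generator

The generator emulates the statistical structure of the emulated study
design, not its sequences: two groups of five, negative-binomial counts
with dispersion 0.1 (a standard RNA-seq/MBD-seq overdispersion level),
per-gene baselines log-normal around 200 (expression) and 100 (methylation)
counts, library size factors in 2^±0.25, 10% of genes differentially
expressed at |log2FC| 1.5, 5% of promoters hypermethylated at log2FC 1.5.
With `coupling="anti"` the hypermethylated genes are *by construction* the
downregulated ones (a shared gene subset, not a mechanistic
methylation→expression function — set-level anticorrelation is what the
GSEA stage consumes; it also means the count-level mediation null holds on
these data, and mediation calibration is exercised on directly simulated
Gaussian chains instead). The TF layer plants 4 TFs at |log2FC| 1.5 with
50-gene regulons of which 30% are altered, against 8 background TFs with
2% altered regulons; regulons are mutually disjoint and disjoint from the
methylation truth set so planted truth stays unambiguous. The compound
layer plants 5 hit compounds among 200 (effect size 10 added to the target
TF's score in every replicate of one context, three contexts, three
replicates).

Genes are tiled on one synthetic chromosome with TSSs on a 15 kb grid
(promoter windows can never collide), alternating strands, 1–5 exons.
Every stage draws from its own `default_rng([seed, stage_code])` stream, so
outputs are bit-reproducible and independent of call order.

What the generator does **not** emulate: batch effects, GC/repeat
structure, fragment-level read placement, per-CpG methylation, correlated
genes, multi-TSS isoforms, or dose–response in compound signatures.
Passing tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to real-data artefacts.

## Pipeline

One run seed fans out to per-stage sub-seeds through a stage-name SHA-256
hash, so stage results do not depend on execution order. Each stage records
a hash of its parameter slice; re-running with an unchanged configuration
skips all stages, and changing one parameter re-runs only the stages whose
slice contains it. The JSON report excludes the output directory and is
byte-identical across runs and locations.

Problem sizes used by the test suite and the acceptance script — 2000
genes, 5 vs 5 samples, 10–20 simulation seeds per property, 500–10,000
permutations, 500–2000 bootstrap replicates — were chosen so each property
is measured with comfortable Monte-Carlo margin while a full run stays in
the minutes range on a single core.

## Known limitations

- The differential test has no dispersion shrinkage and no covariates;
  designs beyond two groups are rejected.
- Mediation is single-mediator, no sensitivity analysis for unmeasured
  confounding.
- The GSEA null is gene-tag permutation; inter-gene correlation present in
  real data would make it anti-conservative there.
- Promoter windows are not clipped against neighboring genes.
- The compound query trusts the provided score matrices; it does not model
  moderated z-scores, dose, or time.
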