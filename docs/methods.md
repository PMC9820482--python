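# Methods

This note records the models behind each stage of `telex`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Coordinates and annotation model

All intervals are 0-based half-open internally. GTF input (1-based,
inclusive) is converted on read; BED is native. A gene model is a body
interval, a list of exons, and optional start/stop codon intervals; when
a GTF lacks an explicit `gene` line, the body is the span of the gene's
exons and codons. Multiple codon lines for one gene (split codons) are
collapsed to their span.

### Classification rules

A TE locus is DISCARDED iff it is fully contained in the merged
exon + start-codon + stop-codon union of a *single* overlapping gene.
The union is per-gene, not across genes, because the discard rule exists
to remove loci whose reads are attributable to one host transcript;
requiring coverage by a patchwork of different genes would not have that
interpretation. Otherwise the locus is labeled by priority
START_CODON > STOP_CODON > EXON > INTRONIC, evaluated on its associated
gene. Codons are subsets of exons, so they must outrank EXON to ever be
assigned. When a locus overlaps several gene bodies, the associated gene
is the one with the largest overlap in bp, ties broken to the
lexicographically smaller `gene_id`; the same tie-break applies to
equidistant nearest genes for intergenic loci. Strand is ignored
throughout — the classification is purely positional — and intergenic
distance is the gap to the gene *body*, not the TSS. Exon sets are
merged per gene before the containment test, i.e. isoform structure is
flattened.

## EM read assignment

Reads are modeled as draws from a multinomial mixture over loci; reads
with identical compatibility sets are grouped first (a sufficient
statistic — the result is identical to per-read iteration). Abundances
initialize *uniformly* over the locus universe rather than proportional
to unique counts, so that fully symmetric zero-unique cases resolve to
even splits deterministically. A group whose compatible loci currently
all have zero abundance is split uniformly for that iteration (avoids
0/0). Defaults: `tol = 1e-6` on the maximum absolute abundance change,
`max_iter = 100`; desk-scale instances with interior fixed points
converge in well under 100 iterations. Instances whose fixed point lies
on the boundary (a locus driven to zero abundance) converge sublinearly;
the `converged` flag reports this honestly rather than masking it. The
EM here is the standard multinomial-mixture formulation without priors
or read-length weighting.

## Differential expression

Size factors are DESeq2's median-of-ratios: per sample, the median over
features (with strictly positive counts in all samples) of the ratio of
the count to the feature's geometric mean. If no feature is all-positive
a `poscounts`-style fallback computes geometric means over positive
entries only; the fallback can be disabled.

Dispersion is per-feature method of moments on normalized counts with
variance pooled *within conditions* (so a true between-group difference
does not masquerade as dispersion), `α = (v − m̄) / m̄²`-style with the
group-size-weighted mean and squared-mean, floored at 1e-8. Features
with variance ≤ mean (Poisson-like or constant) sit at the floor. This
deliberately omits DESeq2's shrinkage, independent filtering, and
outlier refitting: at desk scale those add hidden nondeterminism without
changing the qualitative behavior, and the simplification is visible
here rather than buried. With fewer than 2 replicates per condition the
estimator refuses to run; `pooled=True` falls back to a blind,
condition-ignorant (conservative) estimate.

Each feature is fitted as an NB GLM with log link, a treated indicator,
and a log-size-factor offset (statsmodels IRLS). log₂FC is the condition
coefficient / ln 2, positive = higher under treatment. The Wald
statistic is referred to a **t distribution with n_samples − 2 degrees
of freedom**, not the normal: with ~11 replicates per group and a
moment-estimated dispersion, the normal reference is mildly
anticonservative (empirically ~0.065 rejections at nominal 0.05 on null
NB data), while the t reference sits at the nominal level. All-zero
features get log₂FC 0 and p 1; non-converging fits get p 1 and a
`flagged` mark with a logged warning.

Multiple testing is Benjamini–Hochberg (the "adjusted p-value" procedure
is otherwise unnamed; BH matches the DESeq2 default). Calls use
|log₂FC| ≥ 1.5 on the log₂ scale (fold change ≈ 2.83) and adjusted
p ≤ 0.05, both boundaries inclusive.

## Gene–TE association

Expression is transformed to log₂(CPM + 1) with library sizes taken
from the full count matrix before the OLS fit and correlation. Raw NB
counts are strongly heteroscedastic and give unreliable OLS p-values;
the `raw_counts: true` flag reproduces the naive behavior for
comparison. The fit is ordinary least squares of gene on TE with an
intercept; the slope p-value is the two-sided t-test, which for a single
predictor coincides with the correlation test
t = r·√((n−2)/(1−r²)) — an identity the tests assert numerically.
Correlation is Pearson (the conventional default; Spearman would be a
one-line extension). Pairs use all samples of the contrast (control and
treated together), since the model is meant to explain expression
variation across the treatment. Pair selection keeps lm p ≤ 0.05,
inclusive, with **no** multiple-testing correction across pairs — that
matches the analysis this pipeline operationalizes; a stricter BH mode
would be easy to add but is intentionally not the default. A pair with a
constant gene or TE vector is dropped with a warning (slope and
correlation undefined). `sign = ZERO` is kept for the measure-zero case
of an exactly zero correlation, for totality.

Percentages in all summaries are rounded half-up to one decimal; this
reproduces exactly the printed percentages for the worked-example counts
(461/865 → 34.8/65.2; 313/37 of 350 → 89.4/10.6).

## Synthetic data

The generator emulates the statistical structure of a two-condition
statin-style contrast with 11 samples per condition (22 populations).
Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `n_genes`, `n_te` | 120, 240 | enough loci for stable stage statistics at interactive runtimes |
| `n_samples_per_condition` | 11 | the analyzed design size |
| `nb_dispersion` α | 0.05 | typical within-group biological CV ≈ 22% for cell-line RNA-seq |
| `mean_log_expression` | 5.0 (ln scale, ≈ 150 counts) | moderately expressed features; down-regulated loci stay above zero counts |
| planted TE \|log₂FC\| | 3.0, 35% up / 65% down | clearly detectable effects with the observed down-skew of a repressive stress response |
| `de_fraction` | 0.15 of TE loci | DE features sparse enough not to distort median-of-ratios normalization |
| coupling effect | 1.5 (log₂-scale latent amplitude), 50/50 sign split | \|standardized effect\| > 1 at n = 22; even split exercises both sign classes |
| `intergenic_fraction` | 0.3 | most loci genic, as in the class of contrasts emulated |
| `ambiguity_rate` | 0.3 | a meaningful multimapping burden for the EM stage |
| TE class weights | SINE .45, LINE .30, LTR .15, DNA .10 | SINE-predominant, then LINE |

Genes are non-overlapping on one synthetic chromosome, with 2–4 exons of
300–800 bp, introns of 0.8–2 kb, and 4–9 kb intergenic gaps; codons sit
just inside the terminal exons. TE loci are *placed to realize known
labels* (including discard cases), so the classification truth table is
exact by construction and independently re-derived by the classifier in
tests. Library sizes vary ±30%. Gene–TE couplings are induced by a
shared lognormal latent factor (gene gets loading +effect, TE ±effect in
log₂ units) rather than by copying counts, which preserves approximately
NB marginals while planting the correlation sign. All randomness flows
through numpy's PCG64 seeded streams; identical configurations produce
byte-identical files.

What the generator does **not** emulate: genome-scale annotation
(isoforms, overlapping genes, nested TEs), read-sequence-level effects
(GC bias, positional coverage), batch structure, and subfamily-specific
mappability. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated generative assumptions,
not performance on real sequencing data.

## Problem sizes and determinism

Test and acceptance-script simulations use 2,000 features for DE
calibration, 10,000 pairs for the association null, 20 random
annotations (up to 100 genes / 500 TEs) for the classification oracle,
and the default 120-gene/240-TE dataset end-to-end — sizes at which the
measured rates are stable to well within the asserted bands while the
whole suite runs in well under a minute. Reruns of the pipeline with the
same configuration are byte-identical (fixed float formatting, sorted
orderings, seeded generators); the output manifest records a hash of the
analysis-relevant configuration, the seed, and the package version.

## Known limitations

- The DE stage is a desk-scale NB workflow, not a DESeq2 re-derivation:
  no dispersion shrinkage means lower power at very small counts, and no
  Cook's-distance handling means single-sample outliers are not trimmed.
- EM convergence to boundary fixed points (loci with no unique support
  being squeezed out) is sublinear; such loci report `converged=False`
  at the default iteration cap rather than a resolved zero.
- The association stage is correlational by design; a significant
  negative pair is a regulatory *candidate*, not evidence of causation.
- Classification is isoform-flattened and strand-agnostic; an antisense
  exonic TE is treated the same as a sense one.
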