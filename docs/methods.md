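# Methods

`tregmeth` re-implements, as a tested Python library, the DNA-methylation
time-course analysis used to characterize in-vitro expanded regulatory T-cell
(Treg) products: array-style preprocessing, differential methylation at the
CpG (DMP) and region (DMR) level, cross-run shared-DMR matching with
Early/Late kinetic classification, proliferation- and identity-linked
signature scoring, exhaustion-DMR concordance from bisulfite counts, and
enrichment statistics. Every stage is exercisable on synthetic data with
planted ground truth; this note records the models, defaults and the design
choices that were genuinely open.

## Preprocessing

Probes are removed when their detection p-value fails (p >= 0.05) in **any**
sample (the conservative convention for small cohorts), when flagged
cross-reactive or vendor-dropped, or when the CpG lies within 3 nt of a
SNP. Chromosome-X/Y probes are dropped before differential analysis.
Quantile normalization forces every sample onto the cross-sample mean
distribution (ties by average rank). Statistics are computed on M values,
`M = log2(b / (1 - b))` with symmetric clipping at a configurable offset
(default 1e-3); the transform round-trips beta values to 1e-6 inside the
clipped range.

Batch adjustment is the parametric empirical-Bayes location/scale model:
per-probe standardization given covariates, per-batch additive (normal
prior) and multiplicative (inverse-gamma prior, moment-matched) effects
estimated by the standard iterative fixed point and removed, covariate
effects restored. A test verifies numerical parity with the R reference
implementation (`sva::ComBat`) to 1e-4. With one batch the function is the
identity; singleton batches and batch-confounded covariates are errors.
When both a production-run and a processing-site factor are present the
pipeline corrects their interaction as a single batch factor.

## Differential methylation

Per-CpG tests use a linear model on M values (group effect, optional donor
blocking — the default, since donors are paired across time points) with
empirical-Bayes variance shrinkage: residual variances are shrunk toward a
prior `(d0, s0^2)` moment-matched on log variances (the prior df solved by
trigamma inversion, infinite when the observed spread is no wider than
sampling noise; the total df is capped at the pooled df). A test verifies
parity with `limma::eBayes` to 1e-5. Delta-beta is reported on the beta
scale; BH adjustment at FDR 0.05 defines DMPs.

DMRs follow the kernel-smoothing approach with the published parameters
lambda = 500 bp and C = 3 (sigma = lambda/C, kernel truncated at
+/- lambda): per-CpG squared statistics are kernel-averaged, the null is a
scaled chi-square with Satterthwaite moment matching under a chi-square(1)
member assumption (an isolated CpG reduces exactly to a chi-square(1)
tail), smoothed p-values are BH-selected at 0.05, consecutive significant
CpGs within lambda form regions, mixed-direction regions are split at
delta-beta sign changes, regions keep >= 3 CpGs, and a region-level
Stouffer combination of the member **DMP** p-values (not the smoothed ones,
which are dependent by construction) below 0.05 is required. Stouffer
converts two-sided p to direction-aligned z via `z = sign * Phi^-1(1 - p/2)`
and combines as `Z = sum(z) / sqrt(n)`.

## Kinetics

A run-1 DMR is *shared* when same-direction run-2 DMRs cover >= 50% of its
length (coverage counts the union; the match is the largest single
contributor; direction-discordant qualifying matches are excluded and
counted). A DMR is *Early* when a matching region (>= 50% overlap, same
direction) exists in both the day10-vs-day0 and day23-vs-day0 DMR sets of
its run, *Late* when only in day23-vs-day0. The published analysis states
the 50% rule one-directionally (on the run-1 DMR's length); a symmetric
mode is available by flag.

## Signatures

*PMDs*: the core set is the base-pair intersection of the per-subset BED
inputs; the per-sample median beta over core probes is tracked against
log10 cumulative expansion rate.

*Treg-DR stability*: for every array CpG inside the Treg-DR set, ordinary
least squares of beta on log10(expansion). Expansion rather than days
adjusts for donor-specific proliferation differences. The regression is
described in the source analysis with log10 expansion as the "dependent
variable"; we regress beta on log10(expansion) because R^2 and the
stability interpretation are unchanged by exchanging axes and this
orientation yields a slope in beta per log10 unit. A locus is
*destabilized* when slope > 0 (methylation gain), R^2 > 0.4 and p < 0.05.
The positive-slope condition is deliberate: the phenomenon of interest is
remethylation of Treg-selective demethylated loci, and without the sign
condition an expansion-stable locus (an exact null) would be flagged at
exactly the 5% type-I rate.

*WGBS*: CpGs need >= 10x coverage in both groups; replicate counts are
group-collapsed; the per-CpG test is the pooled two-proportion z
(an approximation to a count-level model, BH-corrected, cross-checked
against exact binomial enumeration); exhaustion DMRs reuse the array DMR
machinery on z^2 with the same lambda/C/min-CpG/Stouffer settings. At the
benchmark depth (delta 0.3, 30x, 10 CpGs) the per-CpG z is ~2.4 and block
detection is partial (~65%, direction always correct); the tests encode
that measured behavior rather than an idealized 100%.

*Exhaustion concordance*: a Late shared DMR counts as overlapping when an
exhDMR covers >= 50% of its length (same denominator convention as
shared-DMR matching); the summary reports the overlap fraction,
per-direction sign concordance and the promoter fraction among
concordant-hyper regions.

## Enrichment

Over-representation is the upper-tail hypergeometric test; a gene is "in
query" when >= 1 DMR of the stratum annotates to it, and the universe is
the set of genes annotatable from probes surviving preprocessing (array
coverage-bias control; flagged in the output header). Preranked GSEA is
the weighted running-sum enrichment score with a gene-label permutation
null, sign-stratified NES normalization and a +1-corrected empirical p
(bounded below by 1/(n_perm+1)); the deterministic ES is cross-checked
against gseapy.

## Annotation

Features are assigned with one call per query, priority promoter > 5'UTR >
3'UTR > exon > intron > downstream > distal intergenic, ties across genes
broken by the smallest |distance to TSS|. The promoter window is TSS +/-
3000 bp and the immediate-downstream window 300 bp (the peak-annotation
tool defaults; the source analysis does not state them; both are
configurable and recorded in output headers). Regions are annotated by
their midpoint; an any-overlap priority mode is available. All internal
coordinates are 0-based half-open; GFF3 (1-based inclusive) and array
manifests (1-based positions) are converted at load time, and "chr1"/"1"
chromosome labels are normalized.

## Synthetic data

The generator emulates the statistical structure of an EPIC-style Treg
manufacturing time course. Baselines are bimodal (low mode ~0.1 from
Beta(2,18), high mode ~0.85 from Beta(17,3), 55% high). Noise is generated
on the M scale — Gaussian residual SD 0.2, donor random intercepts SD 0.15,
run-specific additive shift 0.6 (per-probe spread 0.3) and multiplicative
factor 1.3 — so batch effects are additive exactly where the correction
model assumes. Planted DMRs occupy dedicated probe clusters isolated by
more than lambda, with early kinetics `1 - exp(-d/tau)` normalized to 1 at
the final day (92% of the effect by day 10 of 23) and late kinetics
`(d/23)^2.2` (16% by day 10), satisfying the >= 80% / <= 20% day-10
constraints. Cumulative expansion is `10^(rate * day)` with rate ~
N(0.13, 0.015)/day for products (~1000-fold by day 23; sorted Tregs expand
more slowly at 0.10/day). PMD probes lose 0.08 beta per log10 expansion;
Treg-DR probes in Treg samples start at ~0.08 and gain 0.15 beta per log10
expansion except for FOXP3-like and TNFRSF1B-like anchors, which stay flat
(beta-scale noise ~0.03 at these loci via a local delta-method SD on the M
scale). Detection p-values fail (p in (0.05, 0.6]) at rate 0.002. WGBS
coverage is negative-binomial (size 5) with binomial methylated counts.
None of these magnitudes are claims about the source data — the study
reports no noise scales — they are fixed, documented free parameters.

With one seed the generator is byte-deterministic. What passing benchmarks
do **not** show about real arrays: probe-type chemistry differences,
spatially varying probe affinity, cell-composition shifts, and
non-Gaussian outliers are not emulated, so the benchmarks measure the
statistics under their own assumptions, not array physics.

## Benchmark design choices

Two interactions discovered during calibration are handled deliberately:

1. **Quantile normalization on synthetic data.** The generator produces
   samples that are exchangeable up to the modeled batch/donor effects, so
   QN has nothing to correct; instead it (a) redistributes genuine global
   shifts (the PMD drift) into null probes and (b) makes per-probe noise
   heteroskedastic by rank-mapping through the reference distribution,
   which shrinks the EB prior df and invalidates the chi-square(1) member
   assumption of the smoothing null. The truth-table benchmarks therefore
   preprocess without QN; the pipeline applies QN by default (the published
   order) and exposes `params.quantile_normalize`.
2. **Recovery benchmark design.** The planted-recovery and null-calibration
   designs disable PMD drift and Treg-DR coupling: those loci carry genuine
   (non-planted) differential signal and have their own benchmarks, so
   counting them against the planted truth table would mis-measure
   precision.

## Numerical notes and limitations

Degenerate inputs: constant probes get p = 1; constant methylation in the
stability regression returns slope 0 / R^2 0; zero-variance identical
groups in the t-test return t = 0, p = 1; the pooled two-proportion z is 0
when the pooled proportion is 0 or 1. The smoothing accepts tied genomic
positions (equal weights) and rejects only unsorted input. The
chi-square(1) member assumption of the smoothing null is mildly optimistic
when the EB prior df is small; the null-simulation benchmark bounds the
practical consequence (< 10% of null datasets yield any region, measured
1%). Benchmark problem sizes (10k probes, 25-100 seeds, 2k-CpG WGBS
tables) were chosen so the whole suite runs in about a minute on one core
while keeping Monte-Carlo error well below the asserted margins.
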