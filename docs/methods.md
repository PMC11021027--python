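# Methods

`precond` implements the statistical chain of a genetically variable
stress-preconditioning screen on an inbred strain panel: per-strain survival
phenotyping, mixed-model association mapping, variant-to-gene annotation,
gene-set enrichment, expression-sample QC and relative qPCR quantification.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Survival phenotyping

Each strain contributes two arms of `flies_per_arm` flies (preconditioned vs
control, both subsequently placed on ER-stress food). The phenotype is the
Cox proportional-hazards ratio of the preconditioned arm relative to
control, fit by maximizing the partial likelihood of a single binary
covariate. HR < 1 means preconditioning slowed death.

- **Ties.** Deaths are recorded on a 2-hour monitoring grid, so tied event
  times are the norm, not the exception. The default tie correction is
  Efron's, matching the default of the standard survival software; Breslow
  is available by flag.
- **Censoring convention.** Deaths are treated as exact at the recorded
  check time (right-endpoint convention), not interval-censored. This
  mirrors how screen data of this kind are analyzed in practice; the
  discretization bias at a 2-h interval against ~50 h mean lifetimes is
  negligible relative to sampling error (verified by the recovery and
  coverage tests).
- **Numerics.** Newton–Raphson with step-halving, convergence |Δβ| < 1e-8,
  at most 50 iterations. Monotone likelihoods (all events in one arm,
  complete separation) drive β to ±∞; any |β| > 15 is reported as a flagged
  non-convergent estimate with an infinite log-HR bound, never as a silent
  finite number.
- **Replicate variance test.** The F test of variance equality between two
  HR replicate sets is two-sided, computed on raw hazard ratios by default
  (log-scale by flag), with (n₁−1, n₂−1) df.
- **Phenotype correlations.** Pearson r on strains shared after an inner
  join, with the two-sided t-based P and the n used.

## Mixed-model association

The model is the standard kinship LMM for strain panels:

    y = α + xβ + u + ε,   u ~ MVN_n(0, λ τ⁻¹ K),   ε ~ MVN_n(0, τ⁻¹ I_n)

with y the per-strain hazard ratio, x a variant's 0/1 dosage (inbred lines
are homozygous), K the centered marker-based relatedness matrix
K = W Wᵀ / p over the column-centered dosage matrix W, and λ the ratio of
the two variance components.

- **Filters.** Non-biallelic sites removed; MAF computed on non-missing
  calls; the 0.05 boundary is inclusive. Missing dosages are mean-imputed
  per variant for both the GRM and testing.
- **λ estimation.** REML under the intercept-only null, computed in K's
  eigenbasis where each rotated coordinate is independent with variance
  τ⁻¹(λδᵢ + 1). λ is scanned on a 100-point log grid over [1e-5, 1e5] and
  refined by bounded scalar optimization (tolerance 1e-6 in log λ); a flat
  restricted likelihood (e.g. K = 0) reports the lower grid boundary. The
  residual variance and intercept are profiled analytically.
- **Score test.** λ is estimated once and held fixed for every variant (the
  "P_score" convention of GEMMA-class software). After whitening, the score
  statistic uses the null-model residuals and the ML null variance and is
  referred to χ²₁. At λ = 0 the whole pipeline collapses exactly to simple
  linear regression (T = n·r²), which is tested as an oracle equivalence.
  Monomorphic variants are skipped with a log entry, not silently dropped.
- **QQ summary.** λ_GC = median(χ²)/median(χ²₁). Under a null phenotype the
  P_score distribution is uniform (KS-tested); note that with one phenotype
  vector and LD-correlated variants the *median*-based λ_GC itself has a
  small effective sample and fluctuates by roughly ±0.1 around 1 across
  phenotype draws.

## Variant-to-gene annotation

A variant is assigned to at most one gene among those whose interval ±1 kb
(inclusive, 1-based coordinates, strand ignored) contains it, by site-class
priority **exon > UTR > intron > flank**, with upstream and downstream
sharing the lowest tier. Class ties are broken by smaller variant-to-gene
distance, then lexicographic gene id — the priority rule itself does not
determine multi-gene ties, so the tie-break is a documented package choice.
Positions inside a gene body covered by no typed sub-interval are intronic.
Candidate genes are ranked by the minimum variant P among their assigned
variants passing the reporting threshold; orthologs attach by maximal
confidence score with a minimum of 5 and lexicographic tie-break with a
logged warning.

## Gene-set enrichment

Variant P-values are collapsed to one gene-based P per gene; the default
collapse is the Šidák-corrected minimum, 1 − (1 − p_min)^m, which is
uniform under the null for independent variants and therefore does not
favor variant-rich genes. Fisher and Stouffer combinations are selectable;
the collapse used is recorded in the output. Genes are ranked by −log₁₀ of
the gene P (floored at 1e-300 to keep the metric finite).

The enrichment score walks the ranked list, adding |metric|^w (normalized
over in-set genes, w = 1 by default) at hits and subtracting 1/(N − N_set)
at misses; ES is the running sum's maximum signed deviation, bounded in
[−1, 1], and equals the classical Kolmogorov–Smirnov statistic at w = 0.

**Permutation null and nominal P.** The null for a set of in-list size k is
the ES of k genes drawn uniformly without replacement (gene-label
permutation — phenotype permutation would require re-running the GWAS per
draw, which this procedure does not do). The nominal P compares magnitudes
two-sidedly:

    p = (1 + #{|ES_null| ≥ |ES_obs|}) / (1 + n_perm)

This add-one form floors p at 1/(n_perm+1) and, because |ES_obs| is
exchangeable with the null draws under a null ranking, is calibrated: the
rate of p ≤ α is α (a one-sided count against a sign-symmetric null would
double it). The corrected P is Benjamini–Hochberg across all tested sets.
Reporting keeps sets with corrected P ≤ 0.05, ES ≥ 0.50 and ≥ 5 in-list
genes (all inclusive), sorted by descending ES.

A practical consequence of the same-size permutation null: significance
requires the ranked list to be much longer than the set. The planted-signal
recovery tests therefore run on the full-width simulated panel (~250 ranked
genes for 10-gene sets) rather than a narrower one.

## Expression QC

Size factors are DESeq2-style median-of-ratios: per sample, the median over
genes expressed in every sample of count / gene geometric mean. Outlier
detection log₂(x+1)-transforms the normalized matrix, projects samples onto
PC1/PC2 (SVD), and flags any sample exceeding a mean + 2·SD threshold on
any of three statistics: |PC1 − mean|, |PC2 − mean|, and Euclidean distance
from the PC1–PC2 centroid. Absolute deviations are used for the PC criteria
because principal components are sign-ambiguous — a signed rule would not
be reproducible. Criteria with (numerically) zero variance flag nothing,
and exclusion is single-pass: flagged samples are removed once and the rest
renormalized, with no iterative re-fitting.

## qPCR quantification

ΔCt = Ct_target − Ct_housekeeping within each sample; ΔΔCt subtracts the
genotype's mean baseline ΔCt; fold = E^(−ΔΔCt) with amplification
efficiency E fixed at 2 (configurable). The aggregate fold at a timepoint
is E^(−mean ΔΔCt) — the exponent-scale mean — so the baseline mean fold is
exactly 1 by construction; the arithmetic mean of per-replicate folds would
exceed 1 under replicate noise. Per-replicate linear folds carry the SEM
and the paired two-sided t-test between genotypes at each timepoint
(replicates paired by collection batch index; log-scale option available).
Zero-variance difference vectors are flagged degenerate with a definite P
(1 for identical vectors, 0 for a constant nonzero shift), never NaN.

## Synthetic data generator

The generator is first-class, tested code: every downstream stage is
exercised without external downloads.

- **Genotypes.** 177 strains × 2000 variants by default, dosages 0/1
  (inbred homozygotes; heterozygotes excluded by construction). Each
  variant has a target MAF; 10% of variants are drawn below the 0.05 filter
  and 5% flagged non-biallelic so both filters have work to do. Relatedness
  comes from block-shared alleles: a strain inherits its block's allele
  with probability 0.6, else draws independently — enough structure to make
  the GRM non-trivial and test confounding control, with no coalescent or
  recombination realism claimed.
- **Causal architecture.** 8 causal variants by default with alternating
  ±0.5 log-HR effects; each strain's true preconditioning log-HR is exactly
  the effect-weighted dosage sum (an optional strain-level noise SD exists
  and defaults to 0, since the screen's fly-level variance is not a
  published quantity). The default spread of strain HRs (~0.2–4.5) mirrors
  a screen in which some strains benefit and some are harmed roughly
  half-to-five-fold.
- **Survival.** Exponential baseline hazard, 0.02 deaths/h (mean ~50 h on
  stress food); Weibull shape configurable, exponential kept as default
  because it makes the Cox recovery oracle analytic. The preconditioned
  arm's hazard is multiplied by exp(true log-HR). Raw times are rounded up
  to the next check on a 2-h grid inside a daily 8 AM–8 PM window; deaths
  after the last evening check are recorded at the next morning's first
  check (the only discretization consistent with recording only check
  times). Right-censoring at 168 h.
- **Annotation.** Genes are tiled over the simulated variant positions with
  typed exon/UTR/intron sub-intervals placed so that every structural case
  the assignment rule must face exists by construction: variants in each
  class, a variant in one gene's exon within 1 kb of the next gene, a
  variant inside two overlapping genes, flank variants, and intergenic
  variants more than 1 kb from any gene. Causal variants are forced into
  exons (or given a small rescue gene) so every causal effect maps to a
  gene. Gene sets include the causal-gene `enriched_set` (padded to 10) and
  a `random_set`.
- **Expression / qPCR.** Negative-binomial counts (dispersion 0.1) with
  two groups, optional planted outlier sample (mean shift on 30% of genes),
  and Ct tables generated from known fold changes around a housekeeping
  gene at ~18 cycles with configurable replicate noise.

Everything is a pure function of the config seed; fixed seed means
byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage from recombination history, Wolbachia or
inversion covariates, fly-level frailty beyond the arm/strain structure,
sequencing or alignment noise, GO-ontology topology, and real annotation
dialects (the loader reads this package's documented TSV schema; adapting
the real DGRP annotation file format is an optional extra).

## Problem sizes in the test suite and acceptance script

Simulation-heavy checks use documented scaled sizes chosen for statistical
adequacy: Cox recovery/coverage at 100+100 flies with 200/1,000 replicates;
null LMM calibration at 300 strains × 5,000 variants; causal-variant
recovery at 100 strains × 400 variants × 50 seeds; planted gene-set
recovery at 100 strains × 2,000 variants × 50 seeds (full panel width, for
the permutation-null reason above); enrichment null calibration over 200
shuffled rankings at 199 permutations.

## Known limitations

- The score test fixes λ at its null estimate; strongly structured
  phenotypes can make it mildly conservative for variants tracking the
  relatedness blocks (the standard trade-off of this convention).
- Gene-based P-values treat within-gene variants as independent in the
  Šidák collapse; LD within a gene makes the collapse conservative.
- The F test on raw hazard ratios inherits the HR's skew; the log-scale
  flag is the better-behaved alternative when replicate counts are small.
- Differential expression itself (negative-binomial Wald tests) is out of
  scope; expression handling ends at normalized matrices and the outlier
  report.
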