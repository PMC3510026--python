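# Methods

## Overview

`lungeqtl` re-implements, as a tested pipeline on synthetic data, the
analysis pattern of a multi-site expression-QTL study of human lung tissue
used to interpret asthma GWAS signals: per-cohort cis/trans eQTL mapping
with permutation-based FDR control, inverse-variance meta-analysis across
cohorts with heterogeneity statistics, integration of the resulting eSNP
list with GWAS summary statistics, and enrichment analyses on a directed
gene-regulatory network (key-driver analysis and locus-candidate ranking).

The package is organized around a model object,
`LungEqtlStudy` (data + annotations), whose `fit()` returns a
`LungEqtlResults` carrying thresholds, calls, meta-analysis records,
replication and a `summary()` table — the convention of statistical
modelling libraries. The network and GWAS-integration stages are
functional modules consumed by the end-to-end driver
(`lungeqtl.pipeline.run_all`, CLI `eqtlnet run-all`).

## Per-cohort eQTL mapping

**Genotype QC.** SNPs are dropped when their call rate is below 0.9 or the
exact Hardy–Weinberg test gives P < 1e-6. The HWE test enumerates the
conditional distribution of the heterozygote count given the allele counts
(stable ratio recurrence) and sums the probabilities of configurations no
more likely than the one observed.

**Covariate adjustment.** Each probeset is residualized on age (years),
sex (0/1) and smoking status (two indicator columns, ex and current,
against never) with Huber M-estimation (tuning constant 1.345, IRLS,
tolerance 1e-8, at most 50 iterations; `statsmodels.RLM`), so a handful of
outlying expression values cannot drag the fit. Residuals are
mean-centered. Constant expression rows yield all-zero residuals with a
warning.

**Association.** Additive single-SNP OLS of the adjusted residual on the
alt-allele dosage (0/1/2): two-sided t-test P, effect β in expression
units per allele, and R² the squared Pearson correlation. The full
SNP × probeset scan is evaluated as a matrix cross-product; missing
dosages are handled pairwise per SNP; monomorphic or under-sampled
(n < 30) SNPs are skipped and logged.

**cis/trans classification.** A pair is cis when the SNP lies on the same
chromosome within 1 Mb (inclusive at both boundaries) of the probeset
interval `[start, end]`; anything else — including other chromosomes — is
trans. The window is measured from the annotated probeset interval rather
than the TSS, which keeps the predicate closed and symmetric.

**Permutation FDR.** Expression sample labels are permuted (whole columns,
the same replicate index across cohorts), the scan repeated, and the FDR at
threshold t estimated as
(mean permuted count ≤ t) / (observed count ≤ t).
The cutoff is the largest observed P value with estimated FDR at or below
the 10% target; cis and trans are thresholded separately. Because calls are
declared per transcript (best SNP), the lists fed to the estimator are the
per-probeset minimum cis P values and the per-(probeset × chromosome)
minimum trans P values, so the FDR is controlled at the level at which
discoveries are counted. Five permutations are the default — the null
minimum-P distributions pool hundreds of strata per permutation, so few
replicates suffice at this scale.

**Calls.** cis: per probeset, the lowest-P cis SNP (the eSNP), at most one
cis-eQTL per transcript. trans: per probeset × SNP-chromosome, the lowest-P
distal SNP — bounding double-counting, since trans multiplicity is
otherwise unbounded. Ties in P break by (genomic position, SNP id) for
reproducibility.

## Meta-analysis

Fixed effect: inverse-variance weights w_i = 1/se_i²,
β_FE = Σw_iβ_i/Σw_i, se_FE = (Σw_i)^(-1/2), two-sided normal P.
Cochran's Q = Σw_i(β_i − β_FE)², chi-square with k−1 df under homogeneity
(its P value reported as Q.pvalue). Between-study variance by the
DerSimonian–Laird moment estimator
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), reported with τ = √τ².
Random effects re-weight with 1/(se_i² + τ²). Pairs missing from some
cohorts are combined over the k cohorts that carry them; k = 1 degenerates
to the single cohort's estimate with Q undefined. Meta-level FDR thresholds
come from permutation meta-scans sharing the per-replicate permutations
with the cohort scans. Fixed-effect results drive all downstream stages.

Meta P values are z-based (no small-k t correction), the standard choice
for inverse-variance meta-analysis; per-cohort P values are t-based, so a
k = 1 meta record reproduces the cohort's β and se exactly and its P to
O(1/n) — not bit-identically.

**Replication rule.** A SNP–transcript association is replicated when at
least two cohorts show it with the same β sign at P ≤ 1e-4. Per-cohort
replication rates are the fraction of that cohort's declared eQTLs
supported by at least one *other* cohort under the same rule.

## GWAS integration

The eSNP set is *all* cis pairs at or below the meta cis cutoff — not just
the best SNP per transcript — with gene symbols attached through the
probeset annotation. Enrichment of eSNPs for small GWAS P values is shown
as expected-vs-observed −log10 P quantiles and tested with a one-sided
Mann–Whitney U (alternative: eSNP P values stochastically smaller), chosen
over Kolmogorov–Smirnov for determinism of convention; rank tests are also
what produce the characteristic 2.2e-16 floor in reported enrichment P
values. GWAS SNPs with P strictly below 0.01 that are eSNPs are translated
into their gene sets; the unique-gene union is reported.

## Network stage

Networks are directed acyclic graphs over gene symbols (uppercased on
load; duplicate edges dropped with a warning; cycles rejected naming an
offending path).

Two traversal conventions coexist deliberately. *Neighborhood* enrichment
(locus ranking) ignores edge direction — the question is what milieu a gene
sits in. *Key-driver analysis* follows direction downstream within h edges
— the question is what a gene can influence. h defaults to 3: two edges
give too few genes for annotation, four give diffuse sets.

Enrichment is the hypergeometric upper tail P(X ≥ x) with population
m + n, m successes and k draws, where m is the target/canonical list size,
n the network-minus-target remainder (an explicit larger background can be
supplied), k the neighborhood or downstream-set size and x its overlap
with the targets; x = 0 gives exactly 1. KDA tests every network gene,
applies Bonferroni across tested genes, and flags drivers at adjusted
P < 0.05. The coherent subnetwork around a seed set is the weakly
connected component of the induced h-neighborhood union with the highest
seed proportion (ties to the larger component).

The structure learner (`learn_network_standin`) is a deliberately simple,
deterministic stand-in — the original study's Bayesian-network learner is
out of scope here: greedy hill climbing over single-edge additions,
deletions and reversals maximizing a BIC-penalized linear-Gaussian
likelihood, with acyclicity enforced, in-degree capped, ties broken by
lexicographic edge order, requiring at least 50 samples. It recovers
strong-signal skeletons (chains) and stays near-edgeless on independent
noise, which is all downstream stages need.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with defaults standing in for a three-site lung study:

| parameter | default | meaning |
|---|---|---|
| cohorts | 3 × 300 samples | three sites of a few hundred subjects |
| n_snps / n_probesets | 2,000 / 500 | 5 chromosomes of 10 Mb |
| maf_range | (0.2, 0.5) | alt-allele frequency per LD-free SNP |
| frac_cis / frac_trans | 0.30 / 0.05 | probesets with a planted effect |
| beta_cis / beta_trans | 0.65 | expression units per allele |
| tau_het | 0.10 | between-cohort SD of the true β |
| covariate effects | age 0.04/yr, sex 0.5, smoking 0.3/0.6 | ~0.5 × noise SD in aggregate |
| noise_sd | 1.0 | residual SD |
| network | 100 genes, ≤3 parents, 2 hubs × 10 children | regulatory DAG |
| canonical_size | 119 | curated gene list for enrichment |
| gwas_enriched_frac | 0.30 | planted eSNPs with Beta(0.2, 1) GWAS P |

Genotypes are Hardy–Weinberg draws (dosage ~ Binomial(2, MAF)) at LD-free
SNPs. With β = 0.65, σ = 1 and MAF in (0.2, 0.5), a planted SNP explains
roughly 12–17% of the adjusted expression variance at n = 300 — the regime
where a single eQTL peak explains 10–20% of a transcript's variance.
Heterogeneity enters as per-cohort β_c = β ± N(0, τ_het²). The regulatory
DAG adds each parent's centered expression, weighted by Uniform(0.4, 0.8),
to its children in topological order — so a parent's cis SNP is a genuine
trans-eQTL for its descendants, and `Dataset.true_pairs()` closes the
planted truth over network ancestry for honest false-discovery accounting.
Planted hubs with forced out-degree give key-driver analysis signal; the
canonical list is seeded with hub descendants and padded at random. GWAS P
values are Uniform(0, 1) except for the configured fraction of planted
eSNPs, which draw from Beta(0.2, 1).

All randomness flows from the seed through labelled `SeedSequence`
streams: identical configurations produce byte-identical output files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium (each SNP is independent,
so there are no proxy associations and "wrong-SNP" calls are unambiguous
errors), genotype imputation, array normalization and batch effects,
X-chromosome dosage, population structure, case/control ascertainment, and
realistic GWAS architecture (effect-size/frequency coupling). FDR
calibration and recovery rates on this generator therefore characterize
the procedure, not any particular tissue dataset.

## Problem sizes used by the test suite

The default study conditions (3 × 300 samples, 2,000 SNPs × 500 probesets)
are used for the mixed-data calibration, meta-gain, heterogeneity and
integration checks. The 20-seed null-FDR calibration runs the same sample
sizes on an 800 × 200 marker/probeset grid — the calibration properties do
not depend on the grid, and this keeps the full suite in the minutes
range. KDA recovery uses 50 seeded 40-node DAGs; the structure-learner
checks use 3–20 genes at 400–500 samples.

## Numerical choices

- P values are floored at the smallest positive double to keep logs finite.
- Degenerate DL denominators (Σw − Σw²/Σw ≤ 0) return τ² = 0 with a warning.
- FDR cutoffs with no attainable target return 0 discoveries with a warning.
- Association skips monomorphic SNPs; `test_association` raises on them.
- Tie-breaks: calls by (position, snp_id); learner moves by edge order;
  subnetwork components by (seed proportion, size).

## Known limitations

- **Reported locus-table values.** The literature table this analysis
  pattern comes from prints enrichment P values of 0.0049 (x=7, k=130),
  1.88e-7 (x=19, k=283) and 0.0004 (x=16, k=381) for m=119, n=7000. The
  standard upper tail P(X ≥ x) at population 7119 gives 0.0059, 1.81e-7
  and 5.6e-4; no single hypergeometric parameterization (population 7000
  vs 7119, strict inequality, k ± x, binomial/Poisson approximations)
  reproduces all printed rows, suggesting row-specific backgrounds that
  were not reported. The implementation keeps the standard
  parameterization; the degenerate row (x=0, k=0 → 1) is exact.
- **DL median bias at k = 3.** The median of the DerSimonian–Laird
  estimator across pairs is ≈ 0.69 τ² − 0.31 se² at k = 3 (the median of
  χ²₂ is 2 ln 2), an estimator property, not an implementation defect.
  Median-based recovery checks are therefore run at k = 12; the estimator
  is mean-consistent at any k.
- The permutation FDR assumes exchangeable samples within a cohort; it
  would not be valid under within-cohort structure (relatedness, batches).
- The eSNP set inherits the cis cutoff from the meta scan by default;
  per-cohort eSNP sets are available but not wired into `run_all`.
- No LD means no colocalization logic is needed or provided; applying the
  integration stage to real GWAS data would require proxy-SNP handling.
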