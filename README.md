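# lungeqtl

Multi-cohort expression-QTL mapping with meta-analysis, GWAS integration
and directed-network enrichment — the analysis pattern used to move from
"this locus is associated with asthma" to "this gene in lung tissue most
likely drives the association".

## The problem

Genome-wide association studies find loci, not genes: linkage and gene
density leave several candidates under each association peak. One way to
resolve them is through the genetics of gene expression. If a disease-
associated SNP also controls the expression of a nearby transcript in the
relevant tissue (a *cis*-eQTL), that transcript becomes the prime suspect;
and if a gene's network neighborhood is packed with known disease genes,
that gene is more likely to be a disease gene itself.

This package implements that whole chain for a multi-site study design,
exercised end to end on a bundled synthetic-data generator (the generator
is first-class, seeded and tested — every statistical property downstream
stages assume is planted and recoverable):

1. **Per-cohort eQTL mapping** — genotype QC (call rate, exact
   Hardy–Weinberg test), robust covariate adjustment (Huber M-estimation
   on age, sex, smoking), additive OLS association of every SNP × probeset
   pair, cis/trans classification by a 1 Mb window, permutation-based FDR
   thresholds (10% target, cis and trans separately), and best-eSNP calls
   (at most one cis-eQTL per transcript).
2. **Meta-analysis** — inverse-variance fixed effect
   (β_FE = Σw_iβ_i/Σw_i, w_i = 1/se_i²), Cochran's Q with its χ²_{k−1}
   P value, DerSimonian–Laird τ² = max(0, (Q−df)/(Σw−Σw²/Σw)), random
   effects with weights 1/(se_i²+τ²), and a replication rule (same sign,
   P ≤ 1e-4, in more than one cohort).
3. **GWAS integration** — the eSNP set (every cis pair passing the FDR
   cutoff), a Q-Q enrichment of eSNPs among GWAS P values (one-sided
   Mann–Whitney), and translation of GWAS SNPs at P < 0.01 into genes.
4. **Network stage** — validated directed acyclic gene networks, 3-edge
   neighborhoods, largest coherent subnetwork, Key Driver Analysis
   (hypergeometric enrichment of targets among a gene's directed
   downstream set, Bonferroni-adjusted) and locus-candidate ranking
   (hypergeometric upper tail P(X ≥ x) with population m+n, m canonical
   genes, k neighborhood draws), plus a greedy BIC hill-climbing
   structure-learner stand-in.

## Worked example

```python
from lungeqtl import SimConfig, LungEqtlStudy

study = LungEqtlStudy.from_simulation(SimConfig(seed=11))
results = study.fit(fdr_target=0.10, n_permutations=5, seed=11)
print(results.summary())
```

```
Lung eQTL study summary
  10% FDR (5 permutations, seed 11, window 1 Mb)

                       cohort1       cohort2       cohort3          meta
      cis cutoff       4.1e-04       4.1e-04       3.6e-04       3.8e-04
    trans cutoff       1.1e-05       6.2e-06       3.1e-06       7.2e-06
      n cis-eQTL           161           162           161           176
    n trans-eQTL            71            56            24            91

  Replication (same sign, P <= 0.0001 in another cohort):
    cohort1: 84.5%
    cohort2: 89.4%
    cohort3: 91.4%
  Heterogeneity: 5.1% of pairs with Q P<0.05, 0.1% with Q P<0.001
```

The generator planted 150 cis and 25 trans effects (plus network-mediated
trans signal: a parent gene's cis SNP is a true trans-eQTL for its
regulatory children). Reading the table: each cohort alone recovers ~161
cis-eQTLs at a data-dependent P cutoff near 4e-4, the pooled meta-analysis
recovers more (176) than any single cohort, trans discovery demands far
smaller P values than cis, and 84–91% of per-cohort calls are seen with
the same effect sign at P ≤ 1e-4 in another cohort.

Downstream, in the same session:

```python
esnps = results.esnp_set()              # all cis pairs under the meta cutoff
records = results.meta_records(max_p=1e-6)   # β_FE, Q, Q.pvalue, τ², τ per pair
```

Network enrichment uses the hypergeometric upper tail. A candidate gene
whose 3-edge neighborhood of k = 130 genes contains x = 7 of m = 119
canonical asthma genes, against a background remainder of n = 7000:

```python
from lungeqtl.network import hypergeom_upper
hypergeom_upper(7, 130, m=119, n=7000)    # 0.005935466449261943
hypergeom_upper(19, 283, m=119, n=7000)   # 1.8071492123627705e-07
hypergeom_upper(0, 0, m=119, n=7000)      # 1.0  (empty neighborhood)
```

The first candidate's milieu is modestly enriched (P ≈ 0.006); the second
(x = 19 of k = 283) is decisively enriched (P ≈ 1.8e-7) — the pattern used
to pick the likely causal gene at a GWAS locus.

The whole pipeline, with every output file and a JSON summary:

```bash
eqtlnet run-all --out results_dir --seed 11
eqtlnet report --summary results_dir/summary.json
```

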