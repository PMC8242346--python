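# panitg

Pan-cancer multi-omics landscape screening for the integrin subunit
gene (ITG) family — and, through its configurable gene panel, any other
small gene family — aimed at computational cancer biologists who want a
tested, reproducible version of the standard TCGA-style characterization
workflow:

1. **Dysregulation screen** — per cancer type, tumor-vs-normal log2
   fold change with a two-sided Mann–Whitney test and Benjamini–Hochberg
   FDR across the panel; a gene is called up/down only when
   FDR < 0.05 **and** |log2FC| ≥ 1.
2. **Gene-set enrichment** — weighted Kolmogorov–Smirnov running-sum
   enrichment score of the panel against the full gene universe, ranked
   by the tumor/normal signal-to-noise ratio, with phenotype-permutation
   p-values and a sign-matched normalized score (NES).
3. **Driver attribution** — a dysregulated gene is *CNV-driven* when
   (i) >40% of tumors carry CNV > 0.1 (gain) or < −0.1 (loss) with <40%
   carrying the opposite alteration, (ii) |mean tumor CNV| > 0.1, and
   (iii) Pearson r(CNV, expression) > 0.3 at FDR < 0.05; it is
   *methylation-driven* when |Δβ| = |mean β_tumor − mean β_normal| > 0.05
   (Mann–Whitney FDR < 0.05) and r(β, expression) < −0.3 at FDR < 0.05.
4. **Mutation landscape** — nonsynonymous MAF filtering, per-gene and
   per-cohort mutation rates, the six pyrimidine-reference substitution
   categories (C>A … T>G), and normal / wild-type / mutant expression
   comparisons.
5. **Survival screen** — per gene and horizon (total/10-year/5-year
   overall survival with administrative censoring), the minimum-p
   cutpoint scan: every expression split whose low group holds 10–90%
   of samples is tested by log-rank, the minimum-p split is kept, and
   the Cox hazard ratio at that split labels the gene *poor* (HR > 1,
   p < 0.05 at 5 years) or *favorable* (0 < HR < 1, p < 0.05).
6. **Risk model** — multivariate Cox model (own Newton–Raphson
   maximizer with Efron tie handling) over the dysregulated
   prognosis-related genes plus ordinal T/N/M indexes; median risk-score
   split, Kaplan–Meier comparison, and the 5-year ROC AUC.
7. **Clinical associations** — rank-based effects of expression on TNM
   stage, gender and age.

Because desk-scale reproduction of consortium downloads is impossible,
the package ships a **synthetic cohort generator** that emulates the
statistical structure of those inputs (log2 expression shifts,
CNV–expression and β–expression coupling, Weibull proportional-hazards
survival, MAF-style mutations, TNM covariates) and emits a truth table,
so every stage can be scored for recall and false-discovery proportion.

## Worked example

```python
from panitg import CohortConfig, generate_cohort, CoxRiskModel
from panitg.expression import differential_expression
from panitg.survival import survival_screen, prognostic_dysregulated

cfg = CohortConfig(
    cancer_code="DEMO", n_tumor=100, n_normal=50, n_genes=120, seed=7,
    planted_up={"ITGA11": 2.0, "ITGB4": 1.5},
    planted_down={"ITGA8": 1.5},
    planted_cnv_drivers={"ITGB8": ("gain", 0.6, 0.5, 0.7)},
    planted_prognostic={"ITGA11": 0.8, "ITGA9": -0.6},
)
cohort, truth = generate_cohort(cfg)

de = differential_expression(cohort)
print(de[de.direction != "ns"][["gene", "log2fc", "fdr", "direction"]])

sv = survival_screen(cohort, genes=["ITGA11", "ITGA9", "ITGB4"])
prog = prognostic_dysregulated(de, sv)

results = CoxRiskModel.from_cohort(cohort, list(prog.gene)).fit()
print(results.summary().round(3))
print(f"5-year AUC: {results.auc():.3f}")
```

prints

```
      gene    log2fc           fdr direction
2   ITGA11  2.300687  3.245777e-17        up
10   ITGA8 -1.468047  9.487188e-11      down
24   ITGB4  1.420925  9.487188e-11        up
          coef     hr     se      p  ci_low  ci_high
ITGA11   0.830  2.294  0.148  0.000   0.540    1.121
ITGB4   -0.176  0.838  0.126  0.162  -0.423    0.071
t_index -0.154  0.857  0.126  0.221  -0.401    0.093
n_index -0.135  0.873  0.155  0.382  -0.439    0.168
m_index  0.398  1.489  0.362  0.270  -0.310    1.107
5-year AUC: 0.823
```

All three planted dysregulated genes are recovered with the right
directions and fold changes near their planted effects (+2.0, −1.5,
+1.5); the Cox model assigns the planted prognostic gene ITGA11 a
positive log-hazard (0.83, HR ≈ 2.3) and the risk score discriminates
5-year death status with AUC 0.82. A false "favorable" label on ITGB4
illustrates the scan's selection optimism, which the package documents
and tests rather than correcting away (see `docs/methods.md`).

The same workflow is scriptable from the shell:

```bash
panitg run-all --seed 7 --out results/           # bundled 3-cancer run
panitg simulate --seed 7 --out cohorts/          # write the raw bundles
panitg screen-survival --cohort-dir cohorts/SYN-DIG \
    --cancer-code SYN-DIG --out survival.tsv
```

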