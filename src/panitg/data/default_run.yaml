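# Bundled three-cancer synthetic run.
#
# Three cohorts emulate recurring pan-cancer ITG motifs: a digestive-type
# cancer dominated by upregulated, poor-prognosis ITGs (SYN-DIG), a
# renal-type cancer dominated by downregulated, copy-number-loss-driven
# ITGs (SYN-REN), and a smoking-associated cancer with mixed dysregulation
# and the highest panel mutation rates (SYN-LNG). Each cohort carries 30
# panel genes plus 90 null background genes (the enrichment-test universe),
# 100 tumor and 50 normal samples.
seed: 0
n_perm: 200
thresholds:
  de_fdr: 0.05
  de_log2fc: 1.0
cohorts:
  - cancer_code: SYN-DIG
    seed: 11
    n_tumor: 100
    n_normal: 50
    n_genes: 120
    censoring_rate: 0.3
    planted_up:
      ITGA11: 2.0
      ITGA3: 1.6
      ITGB4: 1.5
      ITGB6: 1.8
      ITGA2: 1.3
    planted_down:
      ITGA8: 1.5
    planted_cnv_drivers:
      ITGB8: {direction: gain, alteration_fraction: 0.6, cnv_magnitude: 0.5, coupling_strength: 0.7}
    planted_meth_drivers:
      ITGA11: {direction: hypo, delta_beta: 0.2, coupling_strength: 0.7}
    planted_prognostic:
      ITGA11: 0.8
      ITGB4: 0.5
      ITGA9: -0.6
    mutation_rate_per_gene:
      ITGAV: 0.08
      ITGB4: 0.07
      ITGA2: 0.03
      ITGA11: 0.02
  - cancer_code: SYN-REN
    seed: 22
    n_tumor: 100
    n_normal: 50
    n_genes: 120
    censoring_rate: 0.3
    planted_down:
      ITGA1: 1.5
      ITGA7: 1.4
      ITGA8: 2.0
      ITGA9: 1.6
      ITGB3: 1.3
      ITGA4: 1.2
    planted_cnv_drivers:
      ITGA7: {direction: loss, alteration_fraction: 0.6, cnv_magnitude: 0.5, coupling_strength: 0.7}
      ITGA8: {direction: loss, alteration_fraction: 0.6, cnv_magnitude: 0.5, coupling_strength: 0.7}
      ITGA9: {direction: loss, alteration_fraction: 0.6, cnv_magnitude: 0.5, coupling_strength: 0.7}
    planted_meth_drivers:
      ITGA4: {direction: hyper, delta_beta: 0.2, coupling_strength: 0.7}
    planted_prognostic:
      ITGA9: -0.7
    mutation_rate_per_gene:
      ITGB1: 0.03
      ITGA1: 0.02
  - cancer_code: SYN-LNG
    seed: 33
    n_tumor: 100
    n_normal: 50
    n_genes: 120
    censoring_rate: 0.3
    planted_up:
      ITGB4: 1.4
      ITGB6: 1.3
    planted_down:
      ITGAL: 1.2
      ITGAM: 1.1
      ITGA8: 1.3
    planted_cnv_drivers:
      ITGB8: {direction: gain, alteration_fraction: 0.6, cnv_magnitude: 0.5, coupling_strength: 0.7}
    planted_meth_drivers:
      ITGB6: {direction: hypo, delta_beta: 0.2, coupling_strength: 0.7}
    planted_prognostic:
      ITGB4: 0.6
      ITGA8: -0.5
    mutation_rate_per_gene:
      ITGA8: 0.09
      ITGAX: 0.08
      ITGB4: 0.08
      ITGAV: 0.04
      ITGA1: 0.03
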