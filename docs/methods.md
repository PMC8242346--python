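# Methods

This note documents the statistical procedures implemented in `panitg`,
the design choices made where the procedure left room, and what the
synthetic-data tests do and do not establish about real cohorts.

## Inputs and containers

One `OmicsCohort` holds a cancer type's log2 expression matrix
(genes × samples) with tumor/normal labels, and optionally: per-gene
continuous copy-number values (segment-mean-like, tumor samples only),
per-gene methylation β-values in [0, 1], MAF-style mutation records
(minimal column dialect: Hugo_Symbol, Tumor_Sample_Barcode,
Variant_Classification, Variant_Type, Reference_Allele,
Tumor_Seq_Allele2), and a clinical table (overall-survival time in
months, event indicator, ordinal T/N/M, stage, gender, age). Sample
identifiers are aligned against the expression columns; identifiers
appearing only in an optional omic are reported as orphans, not errors.
Gene matching is exact and case-sensitive. Flat files are
tab-separated, floats serialized with 17 significant digits so
write→read round trips are lossless, missing values written as `NA`.

## Dysregulation screen

Per gene: log2FC = mean log2(tumor) − mean log2(normal) (inputs are
already log2 scale), two-sided Mann–Whitney p, BH FDR across the
screened panel within one cancer type. Direction is assigned only when
FDR < 0.05 **and** |log2FC| ≥ 1 (both configurable); otherwise "ns".
The rank test needs ≥3 samples per group. The dual gate matters: a
large fold change produced by a single outlier at small n stays "ns".

## Enrichment score

Weighted Kolmogorov–Smirnov running sum over a ranked gene list: hits
increment by |statistic|^w normalized over set members (w = 1 default),
misses decrement by 1/(N − N_hit); the score is the running sum's
maximum deviation from zero. On an effective magnitude tie between the
positive and negative extremes (within 1e−12) the positive deviation is
returned — ties are real for small universes and the convention must be
fixed for oracle comparisons. The phenotype-permutation test ranks
genes by signal-to-noise, (mean_t − mean_n)/(sd_t + sd_n), with each
group SD floored at 10% of |group mean| (and 1e−8 absolutely) to
stabilize near-constant genes; the permutation p uses the add-one
estimator (1 + #{|null| ≥ |obs|})/(1 + n_perm), so p = 0 is impossible,
and NES divides the observed score by the mean |null score| of matching
sign. Default n_perm = 1000 (200 in the bundled run, which trades
permutation resolution for runtime).

## Driver attribution

CNV-driven (gain branch; loss mirrors with signs flipped), all strict
inequalities:

1. frac(CNV > 0.1) > 0.4 and frac(CNV < −0.1) < 0.4 over tumor samples;
2. mean tumor CNV > 0.1;
3. Pearson r(CNV, expression) > 0.3 with BH FDR < 0.05, the FDR taken
   across all genes screened in that cancer type (the correlation
   criterion carries the FDR qualifier).

Methylation-driven: Δβ = mean tumor β − mean normal β with |Δβ| > 0.05
and a Mann–Whitney BH FDR < 0.05 on the β difference, plus
r(β, expression) < −0.3 at FDR < 0.05 over tumor samples.
Δβ > 0 ⇒ hypermethylation (expected downregulation), Δβ < 0 ⇒
hypomethylation (expected upregulation). Correlations use tumor samples
only, matching data availability (CNV exists only for tumors). The gain
and loss branches are mutually exclusive by construction. Driver
calling is independent of the dysregulation call; a concordance flag
(gain/hypomethylation with "up", loss/hypermethylation with "down") is
annotated, never enforced.

## Mutation landscape

The nonsynonymous filter keeps the canonical protein-altering classes
(missense, nonsense, nonstop, frameshift ins/del, in-frame ins/del,
splice site, translation start site) and drops Silent and non-coding
classes; unknown classifications are dropped with a warning and the
allowlist is configurable. Substitutions are collapsed to the
pyrimidine-reference frame by complementing purine-reference pairs,
giving the six categories C>A, C>G, C>T, T>A, T>C, T>G; the spectrum is
computed over single-nucleotide records only (multi-allelic/MNP records
count toward rates but not the spectrum). Rate denominators are the
samples *with mutation data*, not all expression samples; a record
referencing a sample outside that universe is an error, because it
means the denominator is wrong. The cohort rate counts samples with ≥1
mutated panel gene once, so cohort_rate ≥ max per-gene rate and
cohort_rate ≤ Σ per-gene rates.

## Survival screen

Horizons: total, 10-year (120 months), 5-year (60 months). Horizon
censoring truncates times at the horizon and converts later events to
censorings; an event exactly at the horizon remains an event (closed
interval). Times are months; days can be converted at 365.25/12.

The log-rank statistic is the standard two-group form: at each distinct
event time, observed-minus-expected events in group A accumulate with
the hypergeometric variance; (ΣO−E)²/ΣV is referred to χ²₁. The
implementation is a vectorized suffix-sum formulation because the
cutpoint scan evaluates it at every admissible split; it is checked to
1e−8 against a literal per-time tabulation and against lifelines.

Cutpoint scan: the "10th to 90th percentiles" window is read as a
constraint on admissible group sizes — the low group (expression ≤ cut)
must hold between 10% and 90% of samples — the standard min-p
convention and the only reading that guarantees non-degenerate groups.
Candidates are the distinct expression values; the minimum-p split
wins, with ties broken toward the cut closest to the median expression.
The hazard ratio (high vs low) at the winning split is a univariate Cox
estimate (lifelines, Efron ties). Labels: poor (HR > 1, p < 0.05) or
favorable (0 < HR < 1, p < 0.05) at the 5-year horizon; total/10-year
calls are annotation. When one group has no events the HR is not
estimable: an inf/0 sentinel is returned and the label is forced to
"ns"; a monotone likelihood with events in both groups caps the
coefficient at ±15 instead.

**No correction is applied across the scanned cutpoints.** Scanning
~n admissible splits and keeping the minimum p inflates the type-I
error severely: on null data at n = 200 the fraction of genes with
min-p < 0.05 is roughly an order of magnitude above nominal (the
acceptance script measures ≈0.4–0.5). The screen is therefore a
*ranking/triage* tool; per-gene labels on real data should be treated
as optimistic, and the package characterizes the inflation in its test
suite rather than hiding it.

Dysregulated prognosis-related genes are the per-cancer intersection of
direction ≠ ns and 5-year label ≠ ns, annotated with a concordance flag
(up ∧ poor, down ∧ favorable).

## Risk model

Covariates: the dysregulated prognosis-related genes (expression
z-scored within the cancer so coefficients are comparable) plus ordinal
T/N/M codes; samples missing any covariate are excluded. The partial
likelihood is maximized by Newton–Raphson with Efron's tie correction,
step-halving on likelihood decreases, convergence when the largest
update falls below 1e−8 (≤100 iterations). Rank-deficient designs raise
an error naming the dependent columns (QR with column pivoting) rather
than silently dropping covariates; monotone likelihoods are capped at
|β| = 20 with a warning. Standard errors come from the inverse observed
information. This fitter is cross-checked against lifelines to 1e−6 in
the tests.

The risk score is the linear predictor. The cohort splits at the median
score (percentile configurable; heavy ties fall back to an order-based
half split with a warning), groups are compared by Kaplan–Meier curves
and log-rank. Discrimination: AUC for 5-year death status — events at
or before 60 months are positives, samples followed past 60 months
without an event are negatives, samples censored before 60 months are
excluded because their status is indeterminable. (Time-dependent ROC,
which uses censored samples via inverse-probability weights, is a
deliberate non-goal.) AUC uses pair counting with half credit for ties,
i.e. Mann–Whitney U/(n₊ n₋).

## Clinical associations

Rank-based measures put all three covariates on a signed [−1, 1] scale:
Spearman ρ for ordinal stage (≥3 populated levels required) and for
continuous age (≥10 samples), rank-biserial correlation
2U/(n₁n₂) − 1 with a two-sided Mann–Whitney p for gender (positive =
higher expression in the reference category, MALE by default). An
optional age cut dichotomizes age and uses the rank-biserial form
instead. BH FDR is applied across genes per covariate per cancer.

## Synthetic cohort generator

The generator produces, per cancer type, the five-omic bundle plus a
truth table, from a single integer seed; per-omic substreams are
derived through fixed spawn keys so omics are independent and the whole
bundle is bit-reproducible.

- **Expression**: per-gene baselines ~ U(4, 10) log2 units, Gaussian
  noise (SD 1.0 default); planted dysregulation adds the signed log2
  effect to tumor samples.
- **CNV**: background N(0, 0.05); a planted driver draws, for each
  tumor sample, an alteration with the configured probability
  (alteration fraction 0.6 in the recovery conditions) at
  N(±magnitude, 0.1).
- **Coupling**: coupling strength is specified as the *target Pearson
  correlation* |r| between the omic value and tumor expression; it is
  converted to an additive coefficient c = r/√(1−r²) applied to the
  standardized omic value scaled by the noise SD, so the realized
  sample correlation concentrates near the target. The β–expression
  coupling enters with a negative sign.
- **Methylation**: logit-normal β (logit SD 0.5), which respects the
  [0, 1] support. A planted Δβ centers the normal-group mean at
  0.5 ∓ Δβ/2 and shifts the tumor logit by
  (logit(target_t) − logit(target_n))·√(1 + πσ²/8) — the standard
  variance-corrected sigmoid-mean approximation — so the realized mean
  difference lands near the configured Δβ (within a few hundredths;
  exactness is immaterial against the 0.05 calling threshold).
- **Survival**: Weibull proportional hazards (scale 60 months, shape
  1.2 default), linear predictor Σ effect × z-scored tumor expression,
  inverse-CDF sampling. Censoring is independent exponential truncated
  administratively at 240 months, with the exponential rate calibrated
  by root-finding so the expected censoring fraction on the generated
  event times matches the configured rate (0.3 default).
- **Clinical covariates**: T/N/M drawn from fixed multinomials with
  stage derived deterministically from them; gender Bernoulli(0.5); age
  ~ N(63, 10) clipped to [25, 90]. They are independent of survival
  unless a prognostic gene correlates with them by chance, so TNM
  coefficients in the risk model are null checks.
- **Mutations**: Bernoulli per gene per tumor sample at the configured
  rate; classes drawn from a fixed mix (60% missense, 10% nonsense, 7%
  splice site, 5% frameshift deletion, 3% in-frame insertion, 15%
  silent); SNV alleles drawn from a C>T-dominated six-category spectrum
  (40% C>T) with random strand, emulating the transition excess of
  solid tumors.

**What the generator does not emulate**: batch effects, tumor purity,
probe-level methylation structure, genomic coordinates, copy-number
segmentation artifacts, between-gene correlation beyond the planted
couplings, non-proportional hazards, informative censoring. Passing
recovery tests therefore demonstrates that the screens implement their
criteria correctly and have the expected operating characteristics
under clean proportional-hazards Gaussian conditions — not that those
operating characteristics transfer to real TCGA data.

## Problem sizes and defaults

The bundled run uses three cohorts of 100 tumor / 50 normal samples and
120 genes (30-gene ITG panel + 90 null background genes that serve as
the enrichment universe and null calibration), 200 permutations for the
enrichment test. Recovery tests use 200 tumors / 100 normals with 200
genes and 30 planted drivers per mechanism; Cox recovery uses n = 1000
with 100 replicates; null calibrations use 10–20 seeds. These sizes
were chosen so the entire analysis is comfortably interactive on a
laptop while keeping every power/calibration property measurable.

## Known limitations

- The min-p scan's labels are not selection-corrected (see above).
- The enrichment test reports one set at a time; no multi-set FWER/FDR.
- The ROC construction discards early-censored samples; with heavy
  early censoring the AUC estimate loses efficiency and can be biased
  if censoring is informative.
- The risk model performs no variable selection or penalization; with
  more covariates than events per variable the Wald intervals are
  anti-conservative.
- Gene-level CNV input is accepted as any continuous per-gene value;
  no distinction between focal and arm-level events.
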