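# Methods

## Data model

A cohort is a flat table: one row per individual with a binary phenotype
(1 = case), a genotype per locus, covariates (age in years; sex; 0/1
histories of hypertension, diabetes, and family ischemic stroke), and a
TOAST subtype label for cases. Loci are categorical assay results — a
biallelic SNP or the ACE insertion/deletion has three genotype
categories, the three-allele ApoE polymorphism six — with an explicit
category→allele-pair map that drives allele counting. The on-disk dialect
is wide CSV, UTF-8, header row, `NA` missing code. Missing genotypes are
handled per analysis (complete case on exactly the loci the analysis
touches); subtype strata always keep **all** controls and restrict cases
to the subtype.

## Classical statistics

* **Hardy–Weinberg**: allele frequencies by counting, expected genotype
  counts *np²ᵢ* / *2npᵢpⱼ*, chi-square with df = (#genotypes − #alleles):
  1 for biallelic loci, 3 for ApoE. Monomorphic loci are an error.
* **Association**: Pearson chi-square of the genotype × status table with
  **no continuity correction** — recomputing the published single-locus
  p-values from the printed counts (ACE 0.024, FGB T148C 0.026) confirms
  the uncorrected test is the one in use. All-zero genotype rows are
  dropped with a warning (an unobserved category carries no information;
  the published CE-subtype tables, which contain empty rows, are only
  computable this way). A zero column or fewer than two remaining rows is
  an error. Significance in reports is flagged at the Bonferroni level
  α/m (0.05/6 ≈ 0.0083 for the six-locus panel).
* **Odds ratios**: cross-product with Woolf (log-normal) CI; the
  Haldane–Anscombe +0.5 correction is applied to all four cells iff any
  cell is zero, and flagged.
* **Logistic regression**: maximum likelihood via iteratively reweighted
  least squares (statsmodels GLM/Binomial), Wald intervals
  exp(β ± 1.96·SE), max 100 iterations at tolerance 1e-10. Collinear
  designs raise a rank error; any |β| > 15 raises a separation error
  naming the predictor. Genotype terms use codominant (dummy) coding
  against a stated reference by default, with dominant / recessive /
  additive collapsings available; age enters linearly in years.

## MDR engine

Cell labeling compares `cases_cell · n_controls ≥ n_cases · controls_cell`
in exact integer arithmetic, so threshold ties (labeled high — the rule
is a closed half-line) are decided identically at any scale. Model
selection likewise compares balanced accuracies as exact rationals built
from the integer confusion counts: float rounding of (sens + spec)/2 can
differ from the correctly-rounded rational by one ulp, which is enough to
flip a fold winner on small data. The reported accuracy columns are
ordinary floats.

Folds are stratified by phenotype: within each class a seeded permutation
is dealt round-robin, so class-wise fold sizes differ by at most one.
Fold winners are chosen by training balanced accuracy (first combination
in lexicographic locus order on exact ties); per-order models by fold
wins, then smaller prediction error, then lexicographic order; the
overall model by CV consistency, then prediction error. Empty training
cells predict low-risk at test time (conservative toward the null) and
are counted. The sign test is the exact binomial upper tail of
#{folds with testing accuracy > 0.5} at p = ½, folds exactly at 0.5
counting as failures. The permutation test re-runs the full search on
each phenotype shuffle with folds re-stratified from the same fold seed,
and uses the add-one estimator, so its smallest attainable p is
1/(n_perm + 1).

Under the global null the testing accuracy of a *fixed* combination is
unbiased at 0.5, but the testing accuracy of the search-selected best
model is optimistically biased (≈ 0.56 at n = 200 with 21 candidate
combinations), because chance genotype-phenotype association is a
property of the whole dataset realization and is shared by the training
and testing splits. This is by design the bias the permutation reference
distribution absorbs; the type-I rate of the permutation test is the
calibrated quantity, and measures ≈ 5% in the acceptance run.

## Synthetic cohort generator

The generator emulates the study's sampling design prospectively:

* genotypes independent per locus (linkage equilibrium), Hardy–Weinberg
  proportions at the control-population allele frequencies obtained by
  allele counting from the published control genotype counts (e.g.
  ACE D = 479/1548 ≈ 0.309);
* covariates drawn from the control-class marginals (age ~ N(51.5, 16.9²)
  truncated to [18, 100] and rounded to years; male 54%; hypertension
  19%; diabetes 7.1%; family history 0.6%), treated as the population
  distribution under the rare-disease design;
* disease assigned by a logistic penetrance:
  logit P(case) = β₀ + β_int·1[(ACE, FGB T148C) ∈ high-risk cells]
  + optional per-locus main effects (default 0) + covariate terms. The
  covariate coefficients are derived from the per-class marginals — the
  log cross-ratio of prevalences for binary covariates, the
  linear-discriminant slope (μ₁ − μ₀)/σ₀² for age — so the simulated
  case profile reproduces the published clinical table;
* β₀ calibrated by bisection to a population case fraction of 10%
  (fixed; rare enough that control marginals ≈ population marginals);
* population batches are simulated until the requested cases and
  controls exist, then exactly n_cases and n_controls are sampled.
  Default sizes are the study's 774/712; default planted interaction is
  the published high-risk cell set {DD×CC, DD×CT, ID×CC} at OR 1.57.

Because case-control sampling leaves odds ratios invariant and the
penetrance model is well-specified, the covariate-**adjusted** logistic
OR of the planted indicator targets exp(β_int) exactly (acceptance: 95%
CI coverage ≈ 95% over 50 cohorts at OR 3.0). The **crude** OR is
attenuated by non-collapsibility whenever covariate effects are present;
with `include_covariates=False` the crude OR recovers the planted value.
All randomness flows from one seeded generator (default master seed
20151228); identical seeds give identical cohorts. Subtype labels are
assigned to cases at the study's subtype proportions, independent of
genotype. Not modeled: linkage disequilibrium, haplotype phase,
population stratification, genotype-dependent subtype structure.

`null_shuffle` permutes phenotype and subtype jointly (the subtype
annotates the case label), leaving genotypes and covariates in place.

## The margin-exact reconstruction

`reconstructed_cohort` builds a per-individual cohort consistent with the
published summary tables: the (ACE, FGB T148C) joint genotype tables per
stratum are integer-feasible solutions matching the published row/column
margins (overall, LAA, SAO, CE) and the published high/low-risk totals;
the other four loci match the class margins but are assigned
independently; covariates are drawn per class from the clinical
marginals. It is synthetic — the study's individual-level data is not
redistributed — so quantities determined by the constrained margins
(single-locus tables, the high-risk cell set, risk-combination counts,
crude ORs) are exact, while anything depending on the unconstrained joint
structure (adjusted ORs, cross-validated accuracies) is only
approximately reproduced and is reported as computed. Two published
entries are internally inconsistent and were corrected from the
constraints themselves: the overall-case FGB T148C TT count (printed 29;
56 fits the case total and reproduces the printed p-value) and the
control low-risk count (printed 542; 541 fits the 774 controls and the
printed 69.9%).

## Problem sizes and tolerances

The acceptance run uses: oracle equivalence on 100 random cohorts of
12–30 individuals × 2–3 loci against a brute-force Fraction/set
enumeration (exact agreement required); planted-pair recovery and CI
coverage on 50 cohorts of 2,000/2,000 at OR 3.0 (recovery ≥ 80%,
coverage within a 3σ binomial band of 95%); null calibration on 200
cohorts of 100/100 with 99 permutations over orders 1–2 (rejection rate
within a 3σ binomial band of 5%; fixed-pair accuracy within 0.01 of
0.5). Simulation loops search orders 1–2 — planted-pair recovery is an
order-2 question — while the reconstruction and pipeline runs exercise
the full order 1–4 search.

## Known limitations

* No exact HWE test, Firth correction, or conditional/exact OR CIs.
* No generalized or covariate-adjusted MDR variants; covariates enter
  only at the logistic stage.
* The pipeline drops a covariate from a stratum's adjusted model (with a
  logged warning and a report note) if it is quasi-separated there —
  rare covariates such as the 0.6%-prevalence family history otherwise
  make small-stratum fits fail.
* Per-individual supplementary tables are ingested through the same
  schema/column mapping as the CSV dialect; `.xlsx` workbooks are read
  directly (via openpyxl), legacy binary `.xls` files should be
  re-exported first.
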