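# Methods

`drmetanet` implements an analysis pipeline for inbred-panel studies of the
dietary-restriction (DR) lifespan response, where each genotype (fully inbred
fly line) is measured under an ad libitum (AL) and a DR diet, with a targeted
metabolite panel, per-fly lifespans, and line-level genotypes.  This note
documents the models, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Lifespan-response traits

Per-fly ages at death are summarized to per-line means under each diet.  Two
response traits are derived:

* **ΔLS** = mean DR lifespan − mean AL lifespan (days).  ΔLS is correlated
  with AL lifespan, so associations with ΔLS can be driven by baseline
  longevity.
* **rLS** (relative change in lifespan): the residual of the ordinary
  least-squares regression of mean DR lifespan on mean AL lifespan across
  lines.  By the normal equations the residuals sum to zero and are exactly
  uncorrelated with the regressor, so rLS is an AL-adjusted response
  phenotype.  Lines missing either diet are excluded from the fit and carry
  no rLS.

Per-line response classes (longer / no_change / shorter) come from
two-sample Student's t-tests (equal-variance by default; Welch behind a
flag) of DR vs AL flies, FDR-adjusted across lines at 5%.  The FDR procedure
defaults to Benjamini–Yekutieli (BY), matching the pipeline-wide default,
with Benjamini–Hochberg available; with hundreds of dependent line tests BY
is the conservative choice.

## Metabolome normalization

The raw table (samples = line × diet, columns = metabolite features) passes
through a fixed order:

1. natural-log transform (raw abundances must be positive);
2. exclusion of metabolites with **strictly more than 5%** missing cells;
3. K-nearest-neighbor imputation with **metabolites as neighbor objects**:
   distance is Euclidean over co-observed samples, the imputed value is the
   mean of the k = 10 nearest metabolites observed at that sample, with a
   fallback to the metabolite mean when fewer than 3 co-observed samples
   support any neighbor;
4. per-sample mean-centering and unit-scaling (SD with n−1 denominator),
   normalizing for total analyte amount (fly size/weight);
5. batch regression: per metabolite, value ~ intercept + batch indicators by
   least squares, keeping residual + stratum grand mean.  Because one-way
   ANOVA fitted values are the batch means, this is computed in closed form
   as batch-mean removal; it is idempotent and equalizes batch means within
   each stratum.

Two batch modes exist because different analyses need different strata:
**within_diet** (separate fit per diet) feeds the association models and the
differential network; **across_diet** (one pooled fit) feeds PCA and the
paired diet-effect tests, where the diet contrast itself is the signal and
must not be absorbed stratum-wise.  The pipeline order (scaling before batch
regression, imputation before scaling) is fixed by this package for
reproducibility; it is a declared convention, not a law of the data.

## Metabolite–trait association

Each lifespan trait y ∈ {mean AL, mean DR, rLS} is modeled per metabolite m
measured under diet d ∈ {AL, DR}:

    y = α + β·m_d + γ·body_mass + ε,

with genotype-wide mean body mass as covariate, and a two-sided t-test on β.
A constant covariate is dropped with a warning; perfect collinearity is an
error.  BY adjustment is applied **within each (trait, diet) family**,
mirroring per-panel FDR cutoffs (α = 0.01 default).  The change-in-abundance
model replaces m_d with Δmz = m_DR − m_AL per line (α = 0.05 family).  The
"rLS-associated" metabolite set for a diet is the q ≤ α set in that diet's
family; Δmz uses within-diet normalized values (a declared choice — the
alternative, across-diet values, differs only by batch strata).

Paired Student's t-tests per metabolite (DR vs AL across lines, across-diet
normalized data) summarize the diet main effect; PCA (per-metabolite
centering) summarizes global structure.  Numerically constant difference
columns are reported as exact shifts (p forced to 0 with a flag) rather than
letting the paired t underflow.

## Diet-differential correlation network

Per diet, a midrank Spearman correlation matrix over metabolites is computed
from line-level within-diet-normalized values.  Each ρ with n samples is
mapped to the scaled statistic

    s = ρ·√((n−2)/(1−ρ²)),

the t-form of a correlation, approximately standard normal under the null.
With independent samples per diet, D = s_AL − s_DR is approximately
Normal(0, 2) under equal correlation, so z = D/√2 gives a two-sided p per
metabolite pair; BY across all pairs.  |ρ| = 1 would make s infinite and is
capped at ±10⁶ with a flag.  Each diet uses its own n (the formula
generalizes to unequal sample sizes).

Edge categories follow fixed display rules: **AL_gain** (red) when q ≤ α and
ρ_AL − ρ_DR > 0.4; **DR_gain** (blue) symmetrically; **shared** (yellow) when
|ρ| > 0.8 under both diets (a pure threshold, no test).  Red/blue apply only
when the larger correlation is positive; differential edges between negative
correlations are flagged, not colored.  Exchanging diet labels maps red
edges to blue exactly (tested).  Hub metabolites are ranked by
category-specific degree, ties broken lexicographically.

Monte-Carlo calibration: at n = 178 per diet, the sample variance of D over
10,000 independent-null pairs is ≈ 2.0 (the acceptance script recomputes
this), and the |z| > 1.96 type-I rate is ≈ 0.05.

## Gene-level GWAS score

Per-variant association is OLS: phenotype ~ intercept + dosage + Wolbachia +
inversion indicators, with a t-test on the dosage slope.  Inbred lines are
homozygous, so dosage is 0/1 carrier coding; variants with MAF strictly
above 0.05 are kept.  Variants map to a gene when they lie within the gene
interval ± 1,000 bp (1-based inclusive internally; BED input is converted on
read); a variant may map to several genes.  A gene's raw statistic is the
minimum p over its assigned variants.

Genes with more variants reach smaller min-P by chance, so the statistic is
calibrated by permutation: genotype **rows** are shuffled relative to
(phenotype, covariates) jointly — preserving between-variant correlation
(LD) within each permuted genome — and per-gene min-P is recomputed.  The
score is the add-one estimator (hits + 1)/(n_perm + 1), with ties counted as
hits.  Add-one keeps the score positive and makes a cutoff of 10⁻⁴·⁵
attainable only with ≥ ~31,623 permutations, which is why the full-scale
analysis escalates from 10,000 initial permutations to 1,000,000 for genes
whose initial score is ≤ 10⁻³ (both counts are configurable; desk-scale runs
here use 2,000 → 50,000 with a 10⁻³ network cutoff).

Implementation: the covariate block is orthonormalized once (QR); phenotype
and permuted dosages are residualized against it (Frisch–Waugh–Lovell), and
per-variant t² comes from residual cross-products.  Missing dosages are
mean-imputed per variant before the permutation rounds so every permutation
sees the same design and the same residual degrees of freedom; comparing
min-P is then equivalent to comparing max t², so no p-values are computed
inside the loop.  Hit comparisons carry a 10⁻⁹ relative slack so
mathematically tied statistics reached by different summation orders still
count as ties.  An independent brute-force oracle (`exhaustive_gene_score`,
all n! relabelings via `numpy.linalg.lstsq` with explicit p-values) verifies
the fast path exactly on ≤ 8-line fixtures.

## Bipartite gene–metabolite–phenotype network

For one diet context, the network contains: metabolite–phenotype edges for
metabolites with rLS-association q ≤ α (default 0.01); gene–metabolite edges
for gene scores ≤ cutoff (default 10⁻⁴·⁵), computed against the
rLS-associated metabolite set of that diet; and gene–phenotype edges for
genes scored directly on rLS.  Gene–gene and metabolite–metabolite edges
never occur; there is exactly one phenotype node.  Metabolites correlated
with rLS but with no passing gene remain as phenotype-connected orphans.
Edge weight is −log₁₀ of the defining statistic (for downstream sizing;
node degree is the quantity of interest).  Export formats are GraphML
(round-trippable attributes), SIF and edge TSV, all Cytoscape-readable.
Lowering α or the gene cutoff never adds edges.

## Synthetic cohort generator

The generator produces the study design end-to-end with known ground truth:

* **Genotypes**: independent biallelic variants for n_lines inbred lines,
  MAF drawn per variant from `maf_range` (exact-count mode available);
  monomorphic redraws are bounded and then flagged.  No LD beyond the
  trivial (a non-goal).
* **Metabolome**: per diet, line-level latent z values from a multivariate
  normal with per-diet equicorrelated blocks (non-PSD specs rejected);
  planted per-allele shifts `beta_gm` (z-units) added for carrier lines under
  the effect diet; measurement noise (SD 0.1); one additive offset per
  (batch, metabolite) (SD 0.5) shared across diets, with balanced
  within-diet batch assignment; optional per-metabolite diet main effect
  (`diet_shift_sd`, default off); a per-metabolite baseline; exponentiation
  (so raw data are log-normal and the log step is meaningful); missing cells
  completely at random (MCAR — the missingness mechanism of real LC-MS data
  is not emulated), default rate 2%, capped below the 5% filter.
* **Lifespans**: line mean AL ~ Normal(40, 7) days; line mean DR =
  10 + 1.0·AL + Σ beta_m_rls·(latent metabolite z) + Normal(0, 6); per-fly
  ages truncated-normal at 0 around the line × diet mean with SD 10 days
  (Gompertz with matched mean behind a flag — per-fly age distributions are
  a declared default, not an inference from data).  Defaults give a mean DR
  extension of ~10 days with line responses spanning roughly −10 to +30
  days, the scale reported for this design.
* **Covariates**: body mass ~ Normal(1.2, 0.15) mg, Wolbachia Bernoulli(½),
  two inversion indicators (0.2, 0.1).  None of these influence simulated
  phenotypes, so covariate adjustment is exercised but never load-bearing.

Everything is deterministic given `SimConfig.seed` (sub-generators use
spawned seed sequences).  The default config is desk-scale (40 lines, 500
variants, 30 metabolites, 50 flies per line × diet); `full_scale_config()`
mirrors the full design (178 lines × 2 diets, 105 metabolites, 200 flies
per cell).

What passing tests on synthetic cohorts do **not** show about real data:
there is no LD structure, no lipid-class or pathway structure beyond the
planted correlation blocks, MCAR missingness only, no QC drift, and
covariates are pure noise — so recovery results here demonstrate that the
statistical machinery is correct and calibrated, not that real effect sizes
are detectable.

## Problem sizes used in the test and acceptance runs

Null-calibration checks use 178 lines with 10,000 variants and 150
metabolites (≥ 10,000 variant tests and ≥ 11,000 metabolite pairs); gene
score uniformity uses 200 genes at 500 permutations.  The planted-path
recovery study uses 178 lines, 105 metabolites, and a 12-gene × 4-variant
genome (3 kb variant spacing keeps ±1 kb windows within genes), with a
causal variant at MAF 0.3, an AL-specific 0.8 z-unit metabolite shift, and a
4 day/z-unit metabolite→rLS slope, scored with 2,000 initial / 50,000
escalated permutations at the 10⁻³ desk-scale cutoff over 50 seeds.  These
sizes are the package's chosen desk-scale study conditions.

## Known limitations

* The gene score treats the covariate set as fixed across permutations and
  mean-imputes missing dosages; with heavy genotype missingness the
  reported per-variant table (which drops lines instead) and the
  permutation machinery can disagree slightly.
* The Normal(0, 2) null for D is asymptotic; at small n (≲ 30) the t-tails
  make the test mildly anticonservative, and the within-line diet-label
  permutation reference is the safer check (provided as a test).
* No mixed-model/kinship correction: the association model is plain OLS
  with fixed covariates, appropriate for the panel design it mirrors but
  not for structured populations.
* BY control within hand-chosen families is a convention; family
  definitions (per trait × diet) are exposed, not discovered.
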