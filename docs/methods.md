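# Methods

## Measurement model

A bisulfite-converted (BS) array probe reads the sum of 5mC and 5hmC; an
oxidative-bisulfite (oxBS) probe reads 5mC alone. Writing m and h for the
true modification fractions at a probe in a sample, the observed betas
are modelled as

    β_oxBS = clip(m + e₁, 0, 1),      β_BS = clip(m + h + e₂, 0, 1),

with e₁, e₂ independent Gaussian technical noise. The 5hmC estimate is
Δβ = β_BS − β_oxBS = h + (e₂ − e₁). The noise difference is symmetric
with standard deviation σ√2, so at probes with h = 0, Δβ is symmetric
around zero and the negative values trace the pure noise distribution.

The Gaussian choice is a modelling decision: the data only constrain the
noise to be a symmetric source of negative Δβ. Nothing downstream depends
on Gaussianity except the power calculations in the test suite.

## Detection threshold

τ is the 95th percentile of |Δβ| over all negative cells, pooled across
probes and samples, using linear interpolation between order statistics
("type 7" — the convention is stated because the value is reproduced to
full precision, not to a rounded display value). Detection is strict:
Δβ > τ. For symmetric noise, τ approximates the two-sided 97.5% noise
quantile, so at a zero-5hmC probe at most ~2.5% of cells can be flagged;
the test suite asserts this bound. τ is computed on the post-QC matrix
and probes with no detected sample are removed from further analysis.

## Normalization

Between-sample quantile normalization is applied to the BS and oxBS
matrices separately (never mixed, since the BS−oxBS shift *is* the
signal). Intensity-level normalization that stratifies by probe design
chemistry needs raw intensities, which are outside this package's input
contract; the beta-level quantile method preserves the "normalized
separately" structure of the design and is declared in the calibration
report.

## Site-level differential models

Per probe, ordinary least squares of the signal on days post-conception
(DPC) and sex jointly: `y ~ 1 + DPC + sex`, sex coded 0 = female,
1 = male (a positive sex coefficient means higher in males). p-values
are two-sided t-tests with n − 3 df. Developmental (DPC) results cover
autosomal probes; sex results cover autosomes + X; Y probes are excluded
throughout. Probes with missing cells use per-probe complete cases and
probes with < 4 complete cases are skipped with a flag; an exactly-fit
probe (zero residual) is flagged degenerate and reported with p = 1
rather than an unstable tiny p.

Thresholds: Bonferroni 0.05/n at the actual probe count, plus a fixed
discovery threshold of 5×10⁻⁵. Direction enrichment among significant
probes uses the exact two-sided binomial test against 0.5; its null
construction is recorded in the output rather than asserted to match any
particular external convention.

## Region calling

The region procedure follows the two-pass spatial-combination design:

1. **ACF estimation.** p-values are probit-transformed (z = Φ⁻¹(1−p));
   for every intra-chromosome pair within 500 bp, the Pearson
   correlation of z-pairs is computed in 50-bp distance bins
   (symmetrised; bins with < 10 pairs inherit the nearest estimated
   bin).
2. **Smoothing.** Each site's p is replaced by the Stouffer–Liptak
   combination over its ≤ 500 bp neighbourhood, with pairwise
   correlations read off the binned ACF.
3. **Seeding/extension.** Maximal runs of smoothed p < 10⁻⁴ with
   inter-site gaps ≤ 500 bp and ≥ 3 probes become candidate regions.
4. **Scoring.** Candidates are re-scored with the Stouffer–Liptak
   statistic on the *original* p-values, then Šidák-corrected with
   exponent n_a/n_r (probes tested over probes in the region), computed
   as −expm1((n_a/n_r)·log1p(−p)) for numerical stability.

p-values are clamped to [1e-300, 1−1e-16] before the probit. Correlation
matrices are shrunk toward the identity (λ doubling from 10⁻⁶) until
positive semi-definite. Coordinates are 1-based inclusive in memory and
0-based half-open in BED output.

## 5mC/5hmC slope interaction

For each probe the oxBS (5mC) and Δβ (5hmC) values of the same
individuals are stacked; fixed effects are DPC, sex, a modification
indicator and DPC × indicator, with a random intercept per individual
absorbing the within-person correlation between the two marks. The
interaction coefficient equals the 5hmC slope minus the 5mC slope, and
its p-value is a 1-df likelihood-ratio test between ML fits with and
without the interaction (the Wald p is also reported; the two agree in
rank ordering on balanced data).

Because every individual contributes exactly two rows, the marginal
likelihood factorises over per-individual sum and difference contrasts
into two heteroscedastic least-squares blocks sharing the coefficient
vector. The fitter exploits this: iterated GLS with closed-form variance
updates, the boundary σ_b² = 0 handled as pooled OLS. This is exact ML
for the stated model — it matches a generic mixed-model optimiser to
~10⁻⁹ in log-likelihood on well-conditioned data — and remains stable on
the variance boundary, where generic optimisers fail; that robustness is
what makes the large null-calibration suites feasible. Residual variance
is shared between the modifications (the minimal model consistent with
the stated design); modification-specific residual variance is a known
limitation. When the two marks are numerically identical the within-pair
variance degenerates and p = 1 is reported with a flag.

Trajectory classification uses nominal per-slope Wald tests at p < 0.05:
parallel (both significant, same sign), opposed (both, opposite signs),
hmc-only (5hmC only), none.

## Co-hydroxymethylation networks

Signed adjacency a_ij = ((1 + r_ij)/2)^5 on probe-probe Pearson
correlations of Δβ; unsigned topological overlap on top (configurable
off). Modules come from average-linkage hierarchical clustering of the
TOM dissimilarity with a static height cut: the 0.99 quantile of merge
heights, capped at 0.90 — the cap matters because joins between distinct
modules and among background probes both sit near the top of the tree.
Clusters below the minimum size become grey. Two declared additions make
the static cut behave like the dynamic tree-cut it approximates:

- **Membership pruning**: members with |cor(probe, module eigengene)|
  below 0.30 are returned to grey and the eigengene is recomputed (up to
  10 rounds). A static cut is greedy and otherwise absorbs uncorrelated
  probes into large clusters.
- **Eigengene merging**: module pairs with eigengene dissimilarity
  1 − cor < 0.30 are merged iteratively, closest pair first, keeping the
  larger module's label; the fixed point is order-independent.

The module eigengene is the first principal component of the
probe-standardised module block, unit variance, oriented to correlate
positively with the module's mean profile (falling back to the first
probe, flagged, when the mean profile vanishes). Module membership (MM)
and probe significance (PS) are absolute Pearson correlations; sex is
coded 0/1 so its "correlation" is point-biserial. `min_module_size`
defaults to the array-scale 1000 only at ≥ 100,000 probes and to
max(20, n/100) below that, since synthetic studies are far smaller.

## Enrichment

Feature enrichment is the exact two-sided Fisher/hypergeometric test on
the 2×2 table of feature membership × significance; "relative
enrichment" is the in-feature significant fraction over the overall
significant fraction. Group-level 5hmC summaries are means of per-probe
mean Δβ, compared against the complement by Welch's t-test (the test is
named in the output because the choice is ours).

Pathway enrichment regresses pathway membership (over all genes with ≥ 1
tested probe and ≥ 1 pathway) on an in-test-list indicator plus
log(1 + probes per gene); the p-value is a 1-df likelihood-ratio test,
which is better calibrated than the Wald test at small overlap counts.
Genes annotated to several probes count each probe; intergenic probes
are dropped. Pathways outside 10–2000 genes are excluded. Constant
covariate columns are dropped (they duplicate the intercept and
destabilise the IRLS deviance). Complete separation falls back to the
Fisher exact test with a flag; a pathway perfectly predicted by the
covariates alone yields p = 1 (the indicator can add nothing) — this is
what makes refinement group duplicated pathways deterministically.

Refinement: take the most significant remaining pathway as a lead, refit
every other remaining significant pathway with lead membership as an
extra covariate, group those no longer significant (p ≥ 0.05) under the
lead, repeat. Every pathway is labelled exactly once.

## QTL mapping

SNP QC: missingness ≤ 1%, Hardy–Weinberg 1-df chi-square p ≥ 10⁻⁴, MAF
≥ 5%, and every present genotype group ≥ 5 observations (both groups
when only two exist). Genotype PCs come from the mean-imputed centred
dosage matrix with a deterministic sign convention. Association is OLS
per cis pair (default window 1 Mb; all-pairs for small synthetic sets):
`modification ~ dosage + age + sex + PC1 + PC2`, with case-wise deletion
of missing dosages and skip-with-flag for collinear designs.
Significance thresholds are 0.05 over the actual pair count — array-
scale published thresholds are dataset-specific and are not hard-coded.
Pairs significant for either modification are carried into the
heterogeneity test: the same balanced paired mixed model as the
interaction stage, fixed effects genotype, age, sex, PCs, modification
indicator and genotype × indicator, random intercept per individual,
1-df LRT. The LRT is invariant to swapping the indicator coding.

## Synthetic data generator

The generator emulates the target study design and is the package's
test bed. Defaults (all in `SimulationConfig`, units in brackets):

- 71 samples, 35 male / 36 female, DPC uniform on 23–184 [days].
- 2000 probes on 4 autosomes + X (6% X-linked), laid out in islands of
  1–8 probes at 30–150 bp spacing separated by multi-kb gaps, with
  genic-feature and CpG-island annotation and run-structured gene
  symbols.
- True 5mC: bimodal Beta mixture baselines (the classic two-peak array
  density) with small per-sample jitter.
- True 5hmC: zero-inflated (30% of probes carry none) exponential
  background; the background is rescaled so the genome-wide mean honours
  `global_mean_5hmc` = 0.03 despite planted probes' elevated baselines.
- Technical noise: additive Gaussian per array, σ = 0.013 [beta units],
  with per-probe scale heterogeneity uniform on 0.5–1.5×σ. The base σ
  follows from the half-normal quantile identity 1.96·σ·√2 ≈ 0.036, the
  detection threshold typical of oxBS array data; the heterogeneity is
  what leaves a sizeable class of zero-5hmC probes never detected in any
  sample, as on real arrays.
- 50 developmental probes with linear slopes ±(2–6)×10⁻⁴ [Δβ/day],
  58.6% negative, half planted as runs of 3–5 consecutive probes so the
  region caller has true clusters; 20 X-linked sex probes (offset 0.05,
  90% higher in males); 4 modules of 50 probes driven by latent sample
  profiles (loadings 0.03–0.05, all positive — a signed network defines
  modules as sign-coherent), half the latents correlated ±0.6 with DPC;
  20 cis QTL (10 kb from their probe) with effect 0.07 [beta/allele],
  alternating between the 5mC and 5hmC target; 64 of 71 samples
  genotyped, dosages Binomial(2, MAF) with MAF uniform 0.1–0.5 and 0.2%
  missingness.
- Pathway maps with sizes spanning the 10–2000 filter and two planted
  enriched pathways (odds multiplier 5) among developmental-probe genes.

Everything is driven by one seed through named child streams, so
identical configs give byte-identical datasets; pre-clamp matrices and
every planted signal live in the `GroundTruth` ledger for
parameter-recovery tests.

What the generator does *not* emulate: Infinium I/II chemistry
differences, batch/chip effects, cell-composition heterogeneity,
nonlinear age trajectories, linkage disequilibrium between SNPs, and
genotype-correlated population structure beyond what random dosages
induce. Passing tests therefore demonstrate correctness of the
statistical machinery under the declared generative model, not
robustness to those real-data complications.

## Problem sizes and numerical choices

The default test suite and the acceptance script run the full pipeline
at 600–2000 probes and 30–71 samples, with 200-seed recovery batches and
500–600-fit null-calibration batches; these sizes give Monte-Carlo
errors comfortably inside the asserted tolerances. Tolerances: OLS
against normal-equation oracles at 10⁻¹⁰; Stouffer against the classical
closed form at 10⁻¹²; quantiles against the sort oracle at relative
10⁻¹²; calibration fractions within 3 binomial standard errors;
parameter recovery within 10% (15% for the interaction contrast, whose
variance is doubled). Ties in module merging resolve to the pair with
the smallest dissimilarity, then the larger module's label wins; all
colour labels are assigned in decreasing size order for determinism.
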