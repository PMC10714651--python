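# Methods

## The liability model and design power

The design calculations treat the standardised polygenic score `y` and a
residual `x` as independent standard normals and define the quantitative
phenotype as

    z = b * y + x

so `b^2` is the phenotypic variance the score explains and the population
correlation is `rho = b / sqrt(1 + b^2)`. The default `b = sqrt(0.095)`
comes from the PRS-explained variance in case/control discrimination
(AUC 0.677 / R^2 = 0.095) for individuals under 80; with it,
`rho ≈ 0.295`.

Power is the Monte-Carlo rejection rate of the two-sided Pearson correlation
test of `y` against `z` in the *selected* sample, using the exact t
reference with df = n − 2 (the same test `cor.test` performs). Two selection
rules are implemented:

- **extreme(k_low, k_high)** — the k_low lowest and k_high highest scores in
  a freshly simulated population per replicate (default 10 and 6 from
  4,504). This mirrors recruiting the most extreme available individuals.
- **random(n)** — an opportunistic simple random sample. Since a simple
  random sample of iid draws is itself iid, the implementation simulates the
  n selected pairs directly.

A Fisher-z closed form, `power = Phi(sqrt(n-3)*atanh(r) - z_{1-a/2}) +
Phi(-sqrt(n-3)*atanh(r) - z_{1-a/2})`, provides the analytic random-sampling
curve; simulation and the analytic curve agree within Monte-Carlo error on a
grid of n (tested). The **effective sample size** is the smallest random-n
whose power comes within a tolerance (default 5 points) of the extreme
design's estimated power; it is bracketed on the analytic curve by bisection
and refined by simulation. Monte-Carlo standard errors
(`sqrt(p(1-p)/reps)`) accompany every power estimate.

### Known discrepancy: extreme-selection power

Under the defaults the extreme(10, 6) design has ~94–95% power, not the 85%
sometimes quoted for this configuration. The reason is that conditioning on
the two extreme clusters (mean |y| ≈ 3) fixes the design and concentrates
the sample correlation near `b*sd(y|selected)/sqrt(1 + b^2 var(y|selected))
≈ 0.67`; the exact conditional test then rejects far more often than a
bivariate-normal sample with the same nominal correlation would (a Fisher-z
calculation at rho = 0.67, n = 16 gives ≈ 0.84, and sampling *at random*
from beyond ±2 SD gives ≈ 0.75). Real recruitment sits between "the 16 most
extreme" and "random beyond ±2 SD" — volunteers are scattered over the
2–3 SD tails — so quoted design powers in that range are consistent with
intermediate recruitment patterns. The package reports what the specified
selection rule actually yields rather than interpolating; the opportunistic
n = 16 value (~20–21%) and the type-I calibration are unaffected.

Effect-size helpers: `or_to_d` uses the logit conversion
`d = ln(OR) * sqrt(3) / pi` (OR = 30.58 → d = 1.886; 1.875 has also been
quoted for this contrast from an unstated formula — the package surfaces the
logit value only). `two_sample_t_power` evaluates the noncentral-t power
with `ncp = d * sqrt(n1*n2/(n1+n2))`; at d = 1.875 and groups of 10/6 it
gives 0.921.

## Synthetic data

The generators define the study conditions once; they are not tuned per
test.

**Genotypes.** Each variant draws a MAF uniformly on (0.05, 0.5) — a
conventional common-variant spectrum; no array-specific spectrum is claimed.
A standard-normal latent per variant is cut at the Hardy–Weinberg quantiles
`(1-p)^2` and `(1-p)^2 + 2p(1-p)`, so marginal genotype frequencies are in
exact HWE. Within blocks of 10 adjacent variants the latents follow an AR(1)
chain with lag-one correlation `ld_rho`; blocks are independent, chains
reset at block boundaries. Variants sit 50 kb apart on one chromosome by
default, so a 1000-kb clumping window spans two blocks. Missingness is
completely at random. This emulates enough LD structure to exercise
clumping/pruning; it does not emulate human LD maps, MAF-dependent
missingness, or genotyping batch effects, so passing tests demonstrate
algorithmic correctness, not robustness to real-array artefacts.

**Exposure summary statistics.** A `causal_fraction` of variants receives
true betas ~ N(0, effect_sd^2); observed betas add noise with
`se = 1/sqrt(2*N*f*(1-f))` (the large-sample SE of a per-allele regression
coefficient for a standardised trait), and p-values follow from beta/se.
The default training-sample size, 54,162, is an AD-GWAS-scale cohort
(17,008 cases + 37,154 controls). Outcome panels set
`by = true_beta * bx + N(0, se_y^2)` with `se_y` within ±20% of `se_scale`,
alleles copied from the exposure.

**Recall cohort.** The cohort takes the 10 lowest and 6 highest of 4,504
simulated scores. Each outcome is `z = b*y + x` plus a high-group shift
chosen so that, given the realised y values, the expected pooled-SD
standardised difference equals the requested Cohen's d — the shift tops up
whatever difference the `b*y` component already induces, making d the single
calibration knob. Default planted effects: SAM_total −1.66, SAM_semantic
−1.99, cingulate_thickness −1.55, hippocampal_volume 0; all other outcomes
0. Covariates follow the recall sample's descriptive profile (age
69.2 ± 6.01 low / 64.3 ± 6.62 high; sex 7F/3M vs 4F/2M; APOE isoforms 8
ε3ε3 + 2 ε3ε4 vs 1 ε2ε3 + 5 ε3ε3; qualification levels 2/3/6/7). Optional
`covariate_effects` add covariate slopes (e.g. an age slope on hippocampal
volume) on the mean-centred covariate; they default off so the planted d is
exact. Outcomes are on unit-variance latent scales, not questionnaire points
or millimetres.

Recovery note: the plain Cohen's d estimator is biased upward by the factor
`1/J`, `J = 1 - 3/(4*df - 1)` (≈ 5.8% at df = 14), so "the planted d is
recovered in expectation" is asserted on the Hedges-corrected mean `J * d_hat`,
which is exactly unbiased under normality. `compare_groups` itself reports
plain Cohen's d, matching common reporting practice; a `hedges` flag is
available.

## Quality control

Filter order: sample call rate → relatedness → variant call rate → HWE →
MAF → heterozygosity. Order matters (each filter recomputes frequencies on
the surviving set); this order deals with bad samples before judging
variants. The exact HWE test enumerates all heterozygote counts compatible
with the observed allele counts and sums probabilities ≤ that of the
observed table (no mid-p); it matches a direct enumeration oracle to 1e-12
on every table with ≤ 30 alleles. The heterozygosity statistic is the
method-of-moments inbreeding coefficient
`F = (obs_hom - exp_hom)/(typed - exp_hom)` with expected homozygosity from
cohort allele frequencies; "± 3 SD" is applied two-tailed on F by default
(`tail="upper"` restricts to excess heterozygosity). Relatedness exclusion
is greedy-by-degree on the π̂ > 0.2 graph with lexicographic tie-break; on
random graphs of ≤ 8 nodes it stays within one of the exhaustive minimum
vertex cover (tested).

## PRS construction

Harmonisation matches on variant id, flips beta (and complements the
frequency) when the target coding is swapped, resolves strand flips by
complementing, and drops strand-ambiguous A/T and C/G variants. Clumping is
greedy by ascending p (ties by position then id); a missing LD value for an
in-window pair is treated as r² = 0 and logged. LD defaults to dosage
correlation computed from the target genotypes (mean-imputed); a precomputed
r² table is accepted. Missing dosages are mean-imputed as `2 * f_hat` from
the scored sample by default; `omit` drops the term and rescales by the
per-sample scored-variant count. Standardisation uses the full scored
population (never the recall subset), mean 0 / SD 1 (ddof = 1). Deciles are
rank-based with ties assigned to the lower decile — deterministic and
reproducible. Recall selection takes the k lowest/highest standardised
scores and *requires* |z| ≥ 2 and membership of deciles 1/10, raising a
shortfall error rather than relaxing.

## Cohort statistics

Welch is the default t-test (printed descriptive statistics of 10/6 samples
are reproduced from their summary means/SDs to within input rounding);
pooled is available. The 2×2 chi-square applies the Yates correction with
each `|O - E| - 0.5` truncated at zero — without truncation a near-null
table (e.g. sex counts 4/2 vs 7/3, |O−E| = 0.125) would *gain* a positive
statistic from the correction. r×c tables are plain Pearson. Effect sizes
are computed on OLS residuals ("residualise-then-d") per outcome family
(questionnaire family adjusted for age and sex; MRI family for age, sex and
global thickness), with BH-FDR within family. The d confidence interval
defaults to the noncentral-t pivot (which reproduces printed intervals such
as d = −1.66 → [−2.82, −0.46] at n = (10, 6)); the normal approximation
is available and agrees on the lower bound to < 0.1 for |d| ≤ 2 at these
sizes. Residualising on estimated covariates slightly deflates the residual
SD at n = 16 (≈ sqrt(n/(n-k)) on d); this matches standard practice and is
left uncorrected.

## IVW summary-statistic association

`beta = sum(bx*by/se_y^2) / sum(bx^2/se_y^2)`, `se = 1/sqrt(sum(bx^2/se_y^2))`
— first-order weights only (exposure SEs do not enter), numerically
identical to weighted least squares through the origin (tested as an
algebraic identity). QC order: MAF ≥ 1%, INFO ≥ 0.9, MHC
(chr6:26–34 Mb) + APOE (chr19:44.4–46.5 Mb) exclusion, P ≤ 0.5; pruning
reuses the clumping algorithm at r² = 0.01 / 10 Mb. The estimator is
scale-agnostic in the outcome units. Real restricted-data replications are
outside the test surface; the acceptance surface is parameter recovery and
CI coverage on synthetic panels (planted slope recovered within 2 SE,
~95% coverage over repeats).

## Problem sizes and numerical choices

Monte-Carlo defaults: 1,000 replicates per power estimate (3 MC SE ≈ 3.4
points at p = 0.85), 10,000 for type-I calibration, 2,000 synthetic cohorts
for d-vector recovery, 300 repeats for IVW coverage; populations of 4,504
are simulated in ~450-replicate chunks to bound memory. Correlation r is
clipped to [−1, 1] before the t transform; the noncentral-t pivot brackets
the noncentrality within |t| + 20 and treats underflowed CDF values as 0;
monomorphic variants get r = 0 against everything; deciles of tied scores
collapse to the lower decile. All generators and simulations are
reproducible under a fixed integer seed.

## Limitations

Synthetic LD is block-diagonal AR(1), far simpler than real haplotype
structure; the recall-cohort outcomes are unit-variance latents, so absolute
units (mm, mm³, questionnaire points) are not emulated; sex-check,
ancestry PCA and kinship estimation are consumed, not computed; binary-trait
liability-threshold power and MR sensitivity estimators (Egger, median,
heterogeneity) are out of scope.
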