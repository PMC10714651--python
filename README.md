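# rbgkit

A toolkit for **recall-by-genotype (RbG)** study pipelines built on polygenic
risk scores (PRS). RbG designs recruit a small number of participants from
the extreme tails of a genotype-derived score in a large genotyped
population, concentrating exposure variance so that expensive deep
phenotyping (questionnaires, structural MRI, cellular assays) becomes
informative at n = 16 instead of n ≈ 90.

`rbgkit` implements the full chain for such a study and ships synthetic-data
generators for every input, so the whole pipeline is testable without
restricted genotype or GWAS data:

- **`synthgen`** — HWE genotypes with block LD (Gaussian copula, AR(1) within
  block), GWAS summary statistics with a causal fraction, outcome GWAS panels,
  and a 10-low/6-high recall cohort with calibrated group effect sizes.
- **`genoqc`** — call-rate, exact Hardy–Weinberg (enumeration test,
  p < 10⁻⁶), MAF < 1%, ±3 SD heterozygosity (method-of-moments F), and greedy
  relatedness exclusion at π̂ > 0.2 from a kinship table.
- **`prs`** — allele harmonisation, p-value-ordered LD clumping
  (kb = 1000, r² = 0.2, P ≤ 0.5), APOE region exclusion
  (chr19:44.4–46.5 Mb), weighted allele-count scoring, standardisation,
  decile binning, and extreme-tail recall selection (|z| ≥ 2, deciles 1/10).
- **`design`** — power of the design under the liability model
  **z = b·y + x** (y, x iid standard normal; b² the PRS-explained variance,
  default b = √0.095): Monte-Carlo power for extreme vs opportunistic
  selection with a two-sided Pearson test, a Fisher-z analytic curve,
  effective sample size, OR→d conversion (ln OR·√3/π) and noncentral-t
  two-sample power.
- **`cohort`** — Welch/pooled t-tests (raw or summary input), Pearson χ²
  with truncated Yates correction for 2×2, OLS covariate residualisation,
  Cohen's d with noncentral-t (or normal) CIs, Benjamini–Hochberg FDR within
  outcome families, brain–behaviour association, and Desikan–Killiany
  region→lobe pooling.
- **`sumivw`** — the gtx-style inverse-variance-weighted summary-statistic
  association, β̂ = Σ bₓb_y/se_y² / Σ bₓ²/se_y², with MAF/INFO/region QC and
  LD pruning (r² = 0.01, 10 Mb).

## Worked example

```python
from rbgkit import synthgen, genoqc, prs, design, cohort, apoe_mask

G = synthgen.gen_genotypes(1200, 400, ld_block_size=10, ld_rho=0.7,
                           missing_rate=0.01, seed=7)
G, report = genoqc.qc_pipeline(G)
ss = synthgen.gen_exposure_sumstats(G.variants, causal_fraction=0.2,
                                    effect_sd=0.08, gwas_n=54_162, seed=8)
w = prs.exclude_regions(prs.harmonize(G.variants, ss), apoe_mask())
kept = prs.clump(w, prs.GenotypeLd(G))
scores = prs.compute_prs(G, w[w["id"].isin(kept)])

est = design.estimate_power(design.DesignSpec(reps=1000, seed=9))
coh = synthgen.gen_recall_cohort(seed=10)
results = cohort.compare_groups(coh)
```

prints (abridged):

```
           filter  removed  remaining
 sample_call_rate        0       1200
   heterozygosity        4       1196
scored 1196 samples over 125 clumped variants
extreme 10/6 power: 0.938 +/- 0.008
random n=16 power:  0.196 +/- 0.013
SAM_total              d= -1.32 [-2.42, -0.18] p_fdr=0.052
cingulate_thickness    d= -1.43 [-2.55, -0.27] p_fdr=0.170
hippocampal_volume     d= -0.05 [-1.06, 0.96] p_fdr=0.952
```

The QC report lists what each filter removed; the power lines contrast the
recall design with an opportunistic sample of the same size under the same
generative model; the comparison lines are covariate-adjusted standardised
group differences (high-PRS minus low-PRS) with noncentral-t 95% CIs —
at n = 16 a single simulated cohort estimates the planted effects (−1.66,
−1.99, −1.55, 0) with wide intervals, which is the point of reporting the
CIs.

The same stages are scriptable through the CLI:

```bash
rbgkit simulate genotypes --n-samples 1200 --n-variants 400 --seed 7 --out-prefix raw
rbgkit qc --bfile raw --out-prefix clean
rbgkit prs --bfile clean --sumstats ss.tsv --out scores.tsv
rbgkit power --r2 0.095 --extreme 10,6 --reps 1000 --seed 9 --effective-n
rbgkit compare --cohort cohort.tsv --out comparisons.tsv
```

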