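"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators: Hardy-Weinberg genotypes with block LD (Gaussian copula,
AR(1) within block), exposure GWAS summary statistics with a causal fraction,
an outcome GWAS linearly related to the exposure, and a 16-person
recall-by-genotype cohort whose outcomes follow the liability model
``z = b*y + x`` with calibrated group effect sizes.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, GenotypeMatrix, validate_sumstats

#: Standardised group differences (Cohen's d, high minus low) planted by
#: default in the recall cohort: strong reductions in total and semantic
#: autobiographical-memory score and cingulate thickness, and a null
#: hippocampal effect.
DEFAULT_GROUP_EFFECTS = {
    "SAM_total": -1.66,
    "SAM_semantic": -1.99,
    "cingulate_thickness": -1.55,
    "hippocampal_volume": 0.0,
}

#: Outcome measures carried by the simulated cohort (unit-variance latent
#: scales; real-world units are out of scope for the generator).
COHORT_OUTCOMES = (
    "SAM_total",
    "SAM_episodic",
    "SAM_semantic",
    "SAM_spatial",
    "SAM_future",
    "frontal_thickness",
    "parietal_thickness",
    "temporal_thickness",
    "occipital_thickness",
    "cingulate_thickness",
    "hippocampal_volume",
    "global_thickness",
)

# Recall-sample covariate profile: age mean/SD and sex counts per group.
_AGE_LOW = (69.2, 6.01)
_AGE_HIGH = (64.3, 6.62)
_SEX_LOW = ["F"] * 7 + ["M"] * 3
_SEX_HIGH = ["F"] * 4 + ["M"] * 2
_APOE_LOW = ["e3e3"] * 8 + ["e3e4"] * 2
_APOE_HIGH = ["e2e3"] + ["e3e3"] * 5
_QUAL_LOW = [2, 2, 3, 6, 6, 6, 6, 6, 7, 7]
_QUAL_HIGH = [2, 3, 6, 6, 6, 7]

_BASES = ("A", "C", "G", "T")


def gen_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 10,
    ld_rho: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    bp_spacing: int = 50_000,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes with AR(1) block LD.

    Each variant's latent liability is standard normal; within a block of
    ``ld_block_size`` adjacent variants, latents follow an AR(1) process with
    lag-one correlation ``ld_rho``.  The latent is cut at the HWE quantiles of
    the variant's MAF, so every variant is in exact HWE marginally while
    within-block dosages are correlated.  Missingness is completely at random.
    """
    if n_samples < 1 or n_variants < 1:
        raise ValueError("n_samples and n_variants must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if not 0 <= ld_rho < 1:
        raise ValueError(f"ld_rho must lie in [0, 1), got {ld_rho}")
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must lie in [0, 1), got {missing_rate}")
    if ld_block_size < 1:
        raise ValueError(f"ld_block_size must be >= 1, got {ld_block_size}")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, n_variants)

    z = rng.standard_normal((n_samples, n_variants))
    if ld_rho > 0 and ld_block_size > 1:
        w = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, n_variants):
            if j % ld_block_size != 0:  # block boundary resets the chain
                z[:, j] = ld_rho * z[:, j - 1] + w * z[:, j]

    # HWE cut points: P(0)=(1-p)^2, P(1)=2p(1-p), P(2)=p^2 for effect allele p
    q0 = stats.norm.ppf((1.0 - mafs) ** 2)
    q1 = stats.norm.ppf((1.0 - mafs) ** 2 + 2.0 * mafs * (1.0 - mafs))
    dosages = ((z > q0).astype(np.int8) + (z > q1).astype(np.int8))

    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = MISSING

    a_idx = rng.integers(0, 4, n_variants)
    b_idx = (a_idx + rng.integers(1, 4, n_variants)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_variants + 1, dtype=np.int64) * bp_spacing,
            "id": [f"rs{j + 1}" for j in range(n_variants)],
            "a1": [_BASES[i] for i in a_idx],
            "a2": [_BASES[i] for i in b_idx],
        }
    )
    samples = pd.DataFrame(
        {
            "iid": [f"S{i + 1:05d}" for i in range(n_samples)],
            "sex": rng.choice(["F", "M"], n_samples),
        }
    )
    return GenotypeMatrix(dosages, variants, samples)


def gen_exposure_sumstats(
    variants: pd.DataFrame,
    causal_fraction: float = 0.1,
    effect_sd: float = 0.05,
    gwas_n: int = 54_162,
    seed: int = 0,
    info_range: tuple[float, float] = (0.9, 1.0),
) -> pd.DataFrame:
    """Exposure GWAS summary statistics over the given variants.

    A ``causal_fraction`` subset receives true effects ~ Normal(0,
    ``effect_sd``^2); observed betas add sampling noise with the standard
    error implied by ``gwas_n`` and the allele frequency
    (``se = 1/sqrt(2*n*f*(1-f))``), and p-values follow from beta/se.
    """
    if len(variants) == 0:
        raise ValueError("variants frame is empty")
    if not 0 < causal_fraction <= 1:
        raise ValueError(f"causal_fraction must lie in (0, 1], got {causal_fraction}")
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")

    rng = np.random.default_rng(seed)
    m = len(variants)
    if "freq" in variants.columns:
        freq = variants["freq"].to_numpy(float)
    else:
        freq = rng.uniform(0.05, 0.5, m)
    se = 1.0 / np.sqrt(2.0 * gwas_n * freq * (1.0 - freq))
    true_beta = np.zeros(m)
    n_causal = max(1, int(round(causal_fraction * m)))
    causal = rng.choice(m, n_causal, replace=False)
    true_beta[causal] = rng.normal(0.0, effect_sd, n_causal)
    beta = true_beta + rng.normal(0.0, se)
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "id": variants["id"].to_numpy(),
            "a1": variants["a1"].to_numpy(),
            "a2": variants["a2"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "freq": freq,
            "info": rng.uniform(*info_range, m),
        }
    )
    return validate_sumstats(out)


def gen_outcome_sumstats(
    exposure: pd.DataFrame,
    true_beta: float,
    se_scale: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Outcome GWAS whose betas are ``true_beta`` times the exposure betas.

    Outcome ``beta_j = true_beta * bx_j + e_j`` with ``e_j ~ N(0, se_j^2)``
    and ``se_j`` drawn uniformly within 20% of ``se_scale``.  Alleles,
    positions, frequencies and imputation quality are copied from the
    exposure panel (i.e. the pair is pre-harmonised).
    """
    if len(exposure) == 0:
        raise ValueError("exposure panel is empty")
    if se_scale <= 0:
        raise ValueError(f"se_scale must be > 0, got {se_scale}")
    rng = np.random.default_rng(seed)
    m = len(exposure)
    se = se_scale * rng.uniform(0.8, 1.2, m)
    beta = true_beta * exposure["beta"].to_numpy(float) + rng.normal(0.0, se)
    out = exposure.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
    return validate_sumstats(out)


def _calibrated_outcome(
    y_low: np.ndarray, y_high: np.ndarray, b: float, d: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One outcome z = b*y + x with a high-group shift set so the population
    standardised difference (given the realised y values) equals ``d``.

    The within-group variance of z is b^2 * var(y within group) + 1; the
    shift tops up the difference the b*y component already induces.
    """
    n1, n2 = len(y_high), len(y_low)
    v_low = y_low.var(ddof=1) if n2 > 1 else 0.0
    v_high = y_high.var(ddof=1) if n1 > 1 else 0.0
    pooled = ((n1 - 1) * (b * b * v_high + 1.0) + (n2 - 1) * (b * b * v_low + 1.0)) / (
        n1 + n2 - 2
    )
    shift = d * np.sqrt(pooled) - b * (y_high.mean() - y_low.mean())
    z_low = b * y_low + rng.standard_normal(n2)
    z_high = b * y_high + rng.standard_normal(n1) + shift
    return z_low, z_high


def gen_recall_cohort(
    scores=None,
    b: float = float(np.sqrt(0.095)),
    group_effects: dict | None = None,
    covariate_effects: dict | None = None,
    n_low: int = 10,
    n_high: int = 6,
    population_n: int = 4504,
    seed: int = 0,
) -> pd.DataFrame:
    """A recall cohort of ``n_low`` low-PRS and ``n_high`` high-PRS members.

    Parameters
    ----------
    scores
        Standardised PRS values for the whole population (array-like), or
        None to draw ``population_n`` standard normals.  The ``n_low`` lowest
        and ``n_high`` highest values become the recall groups.
    b
        PRS-to-phenotype coefficient of the liability model ``z = b*y + x``;
        the default is the square root of the PRS-explained variance
        R^2 = 0.095.
    group_effects
        Outcome name -> target Cohen's d (high minus low).  Unlisted outcomes
        get 0.  Defaults to :data:`DEFAULT_GROUP_EFFECTS`.
    covariate_effects
        Optional outcome -> {covariate: slope} map adding covariate signal on
        the mean-centred covariate (e.g. an age slope on hippocampal volume).
        Default none, so the planted d values are exact.
    """
    effects = dict(DEFAULT_GROUP_EFFECTS if group_effects is None else group_effects)
    unknown = set(effects) - set(COHORT_OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcome name(s) in group_effects: {sorted(unknown)}")
    cov_eff = covariate_effects or {}
    unknown = set(cov_eff) - set(COHORT_OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcome name(s) in covariate_effects: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    if scores is None:
        y_pop = np.sort(rng.standard_normal(population_n))
    else:
        y_pop = np.sort(np.asarray(scores, dtype=float))
    if n_low + n_high > len(y_pop):
        raise ValueError("recall groups larger than the population")
    y_low, y_high = y_pop[:n_low], y_pop[-n_high:]

    age = np.concatenate(
        [
            rng.normal(*_AGE_LOW, n_low),
            rng.normal(*_AGE_HIGH, n_high),
        ]
    )
    n = n_low + n_high
    if (n_low, n_high) == (10, 6):
        sex, apoe, qual = _SEX_LOW + _SEX_HIGH, _APOE_LOW + _APOE_HIGH, _QUAL_LOW + _QUAL_HIGH
    else:  # resample the default profile for non-default sizes
        sex = list(rng.choice(_SEX_LOW + _SEX_HIGH, n))
        apoe = list(rng.choice(_APOE_LOW + _APOE_HIGH, n))
        qual = list(rng.choice(_QUAL_LOW + _QUAL_HIGH, n))

    cohort = pd.DataFrame(
        {
            "id": [f"RBG{i + 1:03d}" for i in range(n)],
            "group": ["low"] * n_low + ["high"] * n_high,
            "prs_z": np.concatenate([y_low, y_high]),
            "age": age,
            "sex": sex,
            "apoe": apoe,
            "qualification": qual,
        }
    )
    for name in COHORT_OUTCOMES:
        d = effects.get(name, 0.0)
        z_low, z_high = _calibrated_outcome(y_low, y_high, b, d, rng)
        vals = np.concatenate([z_low, z_high])
        for cov, slope in cov_eff.get(name, {}).items():
            c = cohort[cov].to_numpy(float)
            vals = vals + slope * (c - c.mean())
        cohort[name] = vals
    return cohort
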