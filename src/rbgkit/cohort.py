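"""Group-comparison statistics for the 16-person recall sample.

Descriptive two-sample t and chi-square tests, covariate residualisation,
Cohen's d with noncentral-t (or normal) confidence intervals,
Benjamini-Hochberg FDR within outcome families, brain-behaviour association,
and pooling of atlas regions into bilateral lobes.

Conventions: groups are ordered (high, low), so a negative d means the high
polygenic-risk group scores lower.  Effect sizes are computed on covariate
residuals ("residualise-then-d"); Welch is the default t-test.  The 2x2
chi-square applies the Yates continuity correction with each |O-E| - 0.5
truncated at zero (the truncation matters for near-null tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


class TestResult(NamedTuple):
    statistic: float
    df: float
    p: float


@dataclass(frozen=True)
class ComparisonResult:
    """One outcome's adjusted group contrast."""

    outcome: str
    d: float
    ci: tuple[float, float]
    t: float
    df: float
    p: float
    p_fdr: float
    covariates: tuple[str, ...]

    def __post_init__(self):
        if not self.ci[0] <= self.d <= self.ci[1]:
            raise ValueError("d must lie inside its confidence interval")
        if self.p_fdr + 1e-12 < self.p:
            raise ValueError("p_fdr cannot be smaller than p")


def _as_summary(x) -> tuple[float, float, int]:
    """(mean, sd, n) from either a raw sample or a summary triple."""
    if isinstance(x, tuple) and len(x) == 3:
        m, s, n = x
        return float(m), float(s), int(n)
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations per group")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def t_test(x1, x2, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test from raw samples or (mean, sd, n) summaries.

    ``variant="welch"`` (default) uses the Welch-Satterthwaite df; ``pooled``
    assumes equal variances.
    """
    m1, s1, n1 = _as_summary(x1)
    m2, s2, n2 = _as_summary(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if s1 == 0 and s2 == 0:
        raise ValueError("zero variance in both groups")
    if variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = (m1 - m2) / se
    return TestResult(float(t), float(df), float(2 * stats.t.sf(abs(t), df)))


def chisq_test(table, correction: str = "auto") -> TestResult:
    """Pearson chi-square for an r x c count table.

    ``correction="auto"`` applies the Yates continuity correction to 2x2
    tables only; ``"yates"`` forces it, ``"none"`` disables it.  The
    correction truncates each ``|O - E| - 0.5`` at zero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")
    exp = np.outer(rows, cols) / obs.sum()
    use_yates = correction == "yates" or (correction == "auto" and obs.shape == (2, 2))
    if correction not in ("auto", "yates", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    dev = np.abs(obs - exp)
    if use_yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(chi2, float(df), float(stats.chi2.sf(chi2, df)))


def adjust_covariates(y, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of y on an intercept plus the covariate columns.

    Categorical/object columns are dummy-coded (first level dropped).  A
    rank-deficient design raises, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = pd.get_dummies(covariates, drop_first=True).astype(float)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few rows for the covariate design")
    design = np.column_stack([np.ones(len(y)), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            col
            for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def cohens_d(x1, x2, hedges: bool = False) -> float:
    """Pooled-SD standardised mean difference, mean(x1) - mean(x2).

    By convention x1 is the high-risk group.  ``hedges=True`` applies the
    small-sample bias correction J = 1 - 3/(4 df - 1).
    """
    m1, s1, n1 = _as_summary(x1)
    m2, s2, n2 = _as_summary(x2)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    d = (m1 - m2) / np.sqrt(sp2)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float(d)


def d_confint(
    d: float, n1: int, n2: int, level: float = 0.95, method: str = "nct"
) -> tuple[float, float]:
    """Confidence interval for Cohen's d.

    ``nct`` (default) pivots the noncentral-t CDF on the noncentrality
    parameter and converts back through sqrt(n1*n2/(n1+n2)); ``normal`` uses
    the large-sample variance d^2/(2N) + N/(n1 n2).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    a = (1.0 - level) / 2.0
    f = np.sqrt(n1 * n2 / (n1 + n2))
    if method == "normal":
        se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
        z = stats.norm.ppf(1.0 - a)
        return (float(d - z * se), float(d + z * se))
    if method != "nct":
        raise ValueError(f"unknown method {method!r}")
    t = d * f
    df = n1 + n2 - 2

    def pivot(q: float) -> float:
        # cdf is decreasing in ncp; underflowed NaNs behave like 0
        fun = lambda nc: np.nan_to_num(stats.nct.cdf(t, df, nc), nan=0.0) - q
        lim = abs(t) + 20.0
        return optimize.brentq(fun, -lim, lim, xtol=1e-10)

    return (float(pivot(1.0 - a) / f), float(pivot(a) / f))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


#: Default outcome families and their covariate sets, mirroring a
#: questionnaire panel adjusted for age and sex and an MRI panel additionally
#: adjusted for global cortical thickness.
DEFAULT_FAMILIES = {
    "SAM": {
        "outcomes": ["SAM_total", "SAM_episodic", "SAM_semantic", "SAM_spatial", "SAM_future"],
        "covariates": ["age", "sex"],
    },
    "MRI": {
        "outcomes": [
            "frontal_thickness",
            "parietal_thickness",
            "temporal_thickness",
            "occipital_thickness",
            "cingulate_thickness",
            "hippocampal_volume",
        ],
        "covariates": ["age", "sex", "global_thickness"],
    },
}


def compare_groups(
    cohort: pd.DataFrame,
    families: dict | None = None,
    group_col: str = "group",
    ci_method: str = "nct",
) -> list[ComparisonResult]:
    """Adjusted group contrast for every outcome, FDR-corrected within family.

    Per outcome: residualise on the family's covariates, compute Cohen's d
    (high minus low) with its CI on the residuals, a Welch t-test for the
    p-value, then Benjamini-Hochberg across the family's outcomes.
    ``families`` maps family name -> {"outcomes": [...], "covariates": [...]};
    an empty covariate list skips residualisation.
    """
    families = DEFAULT_FAMILIES if families is None else families
    is_high = cohort[group_col].astype(str).to_numpy() == "high"
    results: list[ComparisonResult] = []
    for fam in families.values():
        missing = [o for o in fam["outcomes"] if o not in cohort.columns]
        if missing:
            raise ValueError(f"outcomes absent from the cohort table: {missing}")
        fam_results = []
        for outcome in fam["outcomes"]:
            y = cohort[outcome].to_numpy(float)
            covs = tuple(fam.get("covariates", ()))
            resid = adjust_covariates(y, cohort[list(covs)]) if covs else y
            hi, lo = resid[is_high], resid[~is_high]
            d = cohens_d(hi, lo)
            ci = d_confint(d, len(hi), len(lo), method=ci_method)
            t, df, p = t_test(hi, lo, variant="welch")
            fam_results.append((outcome, d, ci, t, df, p, covs))
        p_adj = bh_fdr([r[5] for r in fam_results])
        for (outcome, d, ci, t, df, p, covs), pf in zip(fam_results, p_adj):
            results.append(
                ComparisonResult(
                    outcome=outcome, d=d, ci=ci, t=t, df=df, p=p,
                    p_fdr=float(pf), covariates=covs,
                )
            )
    return results


def association(y1, y2, covariates: pd.DataFrame | None = None) -> TestResult:
    """t-statistic and p for y2's slope in OLS of y1 on y2 plus covariates."""
    import statsmodels.api as sm

    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    X = pd.DataFrame({"_y2": y2})
    if covariates is not None and len(covariates.columns):
        X = pd.concat(
            [X, pd.get_dummies(covariates.reset_index(drop=True), drop_first=True).astype(float)],
            axis=1,
        )
    if len(y1) < X.shape[1] + 3:
        raise ValueError("too few complete observations for the design")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design in association model")
    fit = sm.OLS(y1, design).fit()
    return TestResult(float(fit.tvalues["_y2"]), float(fit.df_resid), float(fit.pvalues["_y2"]))


def pool_regions(
    region_table: pd.DataFrame,
    lobe_map: dict[str, str],
    measure: str = "thickness",
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Pool per-region columns into lobes: thickness averages, volume sums.

    ``region_table`` has one row per participant and one column per region;
    ``lobe_map`` assigns every column to a lobe.  ``weights`` (e.g. surface
    areas) turn the thickness average into a weighted mean.
    """
    if measure not in ("thickness", "volume"):
        raise ValueError(f"measure must be 'thickness' or 'volume', got {measure!r}")
    unmapped = [c for c in region_table.columns if c not in lobe_map]
    if unmapped:
        raise ValueError(f"regions missing from lobe_map: {unmapped}")
    out = {}
    lobes = {}
    for region, lobe in lobe_map.items():
        if region in region_table.columns:
            lobes.setdefault(lobe, []).append(region)
    for lobe, regions in lobes.items():
        block = region_table[regions].to_numpy(float)
        if measure == "volume":
            out[lobe] = block.sum(axis=1)
        elif weights is not None:
            w = np.array([weights[r] for r in regions], dtype=float)
            out[lobe] = block @ (w / w.sum())
        else:
            out[lobe] = block.mean(axis=1)
    return pd.DataFrame(out, index=region_table.index)
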