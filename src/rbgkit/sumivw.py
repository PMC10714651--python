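"""Inverse-variance-weighted summary-statistic PRS association.

The gtx-style estimator regresses outcome GWAS betas on exposure GWAS betas
through the origin with weights 1/se_y^2:

    beta = sum(bx * by / se_y^2) / sum(bx^2 / se_y^2)
    se   = 1 / sqrt(sum(bx^2 / se_y^2))

It is the summary-statistic analogue of an individual-level PRS association
and coincides with the IVW estimator of Mendelian randomisation, but with no
instrument-strength filter: variants enter at P <= 0.5 after MAF/INFO/region
QC and LD pruning.  Exposure standard errors do not enter the weights
(first-order form).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prs import ClumpConfig, clump
from .types import AMBIGUOUS_PAIRS, RegionMask, apoe_mhc_mask, complement, validate_sumstats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IvwResult:
    beta: float
    se: float
    z: float
    p: float
    n_variants: int
    filter_log: tuple = ()

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be > 0")

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return (self.beta - zq * self.se, self.beta + zq * self.se)


def harmonize_pair(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Intersect two GWAS panels on variant id and align outcome betas to the
    exposure's effect allele.

    Swapped alleles flip the outcome beta's sign (strand flips resolved by
    complementing); strand-ambiguous A/T and C/G variants and allele
    mismatches are dropped.  Returns a frame with the exposure columns plus
    ``beta_out`` and ``se_out``.
    """
    validate_sumstats(exposure)
    validate_sumstats(outcome)
    out = outcome.set_index("id")
    rows = []
    n_dropped = 0
    for e in exposure.itertuples(index=False):
        if e.id not in out.index:
            continue
        ea1, ea2 = str(e.a1), str(e.a2)
        if (ea1, ea2) in AMBIGUOUS_PAIRS:
            n_dropped += 1
            continue
        o = out.loc[e.id]
        oa1, oa2 = str(o["a1"]), str(o["a2"])
        if (ea1, ea2) == (oa1, oa2) or (ea1, ea2) == (complement(oa1), complement(oa2)):
            sign = 1.0
        elif (ea1, ea2) == (oa2, oa1) or (ea1, ea2) == (complement(oa2), complement(oa1)):
            sign = -1.0
        else:
            n_dropped += 1
            continue
        rows.append((*e, sign * float(o["beta"]), float(o["se"])))
    if not rows:
        raise ValueError("no usable variants shared between exposure and outcome panels")
    cols = list(exposure.columns) + ["beta_out", "se_out"]
    log.info("harmonised pair: %d variants kept, %d dropped", len(rows), n_dropped)
    return pd.DataFrame(rows, columns=cols)


def qc_filter(
    sumstats: pd.DataFrame,
    min_maf: float = 0.01,
    min_info: float = 0.9,
    mask: RegionMask | None = None,
    p_threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """MAF, INFO, region and p-value filters, applied in that order.

    Returns the filtered frame and a per-filter removal log.
    """
    for col in ("freq", "info", "chrom", "pos", "p"):
        if col not in sumstats.columns:
            raise ValueError(f"summary statistics missing column {col!r}")
    mask = apoe_mhc_mask() if mask is None else mask
    df = sumstats
    removed = []
    maf = np.minimum(df["freq"], 1.0 - df["freq"])
    step = df.loc[maf >= min_maf]
    removed.append(("maf", len(df) - len(step)))
    df = step
    step = df.loc[df["info"] >= min_info]
    removed.append(("info", len(df) - len(step)))
    df = step
    step = df.loc[~mask.contains(df["chrom"], df["pos"])]
    removed.append(("region", len(df) - len(step)))
    df = step
    step = df.loc[df["p"] <= p_threshold]
    removed.append(("p_threshold", len(df) - len(step)))
    for name, n in removed:
        log.info("qc_filter %s removed %d variants", name, n)
    return step.reset_index(drop=True), removed


def prune(
    sumstats: pd.DataFrame, ld, r2: float = 0.01, window_mb: float = 10.0
) -> list[str]:
    """Greedy LD pruning; same algorithm as PRS clumping with wide defaults."""
    cfg = ClumpConfig(window_kb=window_mb * 1000.0, r2_threshold=r2, p_threshold=1.0)
    return clump(sumstats, ld, cfg)


def ivw(bx, by, se_y) -> IvwResult:
    """First-order IVW estimate of the outcome-per-exposure-beta slope."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if not (len(bx) == len(by) == len(se_y)) or len(bx) == 0:
        raise ValueError("bx, by and se_y must be equal-length and non-empty")
    if (se_y <= 0).any():
        raise ValueError("se_y must be > 0")
    w = 1.0 / se_y**2
    denom = float((bx**2 * w).sum())
    if denom == 0:
        raise ValueError("all exposure betas are zero; IVW estimate undefined")
    beta = float((bx * by * w).sum()) / denom
    se = 1.0 / math.sqrt(denom)
    z = beta / se
    return IvwResult(
        beta=beta, se=se, z=z, p=float(2.0 * stats.norm.sf(abs(z))), n_variants=len(bx)
    )


def ivw_from_pair(pair: pd.DataFrame) -> IvwResult:
    """Convenience wrapper over a harmonised exposure/outcome frame."""
    return ivw(pair["beta"], pair["beta_out"], pair["se_out"])
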