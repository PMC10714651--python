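"""Sample- and variant-level genotype quality control.

Filters follow the usual array-QC battery: call rate (samples before
variants), an exact Hardy-Weinberg test, minor allele frequency, a
method-of-moments heterozygosity outlier screen, and greedy removal of
related individuals from a precomputed kinship table.  Kinship estimation
itself and ancestry clustering are consumed, not computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Inclusion thresholds; defaults are the conventional array-QC values."""

    min_sample_call_rate: float = 0.95
    min_variant_call_rate: float = 0.95
    hwe_alpha: float = 1e-6
    min_maf: float = 0.01
    het_sd: float = 3.0
    max_pi_hat: float = 0.2

    def __post_init__(self):
        for name in ("min_sample_call_rate", "min_variant_call_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must lie in (0, 1)")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.het_sd <= 0:
            raise ValueError("het_sd must be > 0")
        if not 0 <= self.max_pi_hat <= 1:
            raise ValueError("max_pi_hat must lie in [0, 1]")


@dataclass
class QcReport:
    """Ordered log of (filter name, items removed, items remaining)."""

    steps: list = field(default_factory=list)
    result: GenotypeMatrix | None = None

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.steps.append((name, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "removed", "remaining"])


def call_rate_filter(G: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()) -> GenotypeMatrix:
    """Drop samples, then variants, whose non-missing fraction is below threshold.

    Samples are filtered first so a handful of badly typed samples cannot
    drag otherwise good variants under the variant threshold.
    """
    if G.n_samples == 0 or G.n_variants == 0:
        raise ValueError("genotype matrix is empty")
    keep_s = np.flatnonzero(G.sample_call_rate() >= thresholds.min_sample_call_rate)
    if len(keep_s) == 0:
        raise ValueError("call-rate filter removed every sample")
    G = G.subset(sample_idx=keep_s)
    keep_v = np.flatnonzero(G.variant_call_rate() >= thresholds.min_variant_call_rate)
    return G.subset(variant_idx=keep_v)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one variant.

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one (the standard exact test, no mid-p).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotyped sample is required")
    n_a = 2 * n_hom_alt + n_het  # minor-side allele count (either side works)
    n_b = 2 * n - n_a
    n_rare = min(n_a, n_b)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def hwe_filter(G: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()) -> GenotypeMatrix:
    """Remove variants whose exact HWE p-value falls below ``hwe_alpha``."""
    counts = G.genotype_counts()
    keep = []
    for j, (n0, n1, n2) in enumerate(counts):
        if n0 + n1 + n2 == 0:
            log.warning("variant %s all-missing; removed by HWE filter", G.variants["id"].iloc[j])
            continue
        if hwe_exact_test(n0, n1, n2) >= thresholds.hwe_alpha:
            keep.append(j)
    return G.subset(variant_idx=keep)


def maf_filter(G: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()) -> GenotypeMatrix:
    """Remove variants with MAF strictly below ``min_maf`` (undefined MAF removed)."""
    maf = G.maf()
    undefined = np.isnan(maf)
    if undefined.any():
        log.warning(
            "%d variant(s) with all-missing dosages removed (MAF undefined)", undefined.sum()
        )
    keep = np.flatnonzero(~undefined & (maf >= thresholds.min_maf))
    return G.subset(variant_idx=keep)


def inbreeding_coefficient(G: GenotypeMatrix) -> np.ndarray:
    """Per-sample method-of-moments inbreeding coefficient F.

    ``F = (observed hom - expected hom) / (typed - expected hom)`` with the
    expected homozygote count accumulated over each sample's typed variants
    from the cohort allele frequencies (``1 - 2 f (1 - f)`` per variant).
    Fully homozygous samples give F = 1.
    """
    freq = G.effect_allele_freq()
    exp_hom_per_variant = 1.0 - 2.0 * freq * (1.0 - freq)
    typed = G.dosages != MISSING
    obs_hom = ((G.dosages == 0) | (G.dosages == 2)).sum(axis=1)
    exp_hom = typed @ np.nan_to_num(exp_hom_per_variant)
    n_typed = typed.sum(axis=1)
    denom = n_typed - exp_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (obs_hom - exp_hom) / denom, 0.0)


def het_outlier_filter(
    G: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    tail: str = "both",
) -> GenotypeMatrix:
    """Remove heterozygosity outliers: |F - mean(F)| > het_sd * SD(F).

    ``tail="upper"`` removes only excess-heterozygosity samples (low F);
    the default keeps both tails.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if tail not in ("both", "upper"):
        raise ValueError(f"tail must be 'both' or 'upper', got {tail!r}")
    F = inbreeding_coefficient(G)
    sd = F.std(ddof=1)
    if sd == 0:
        log.warning("zero variance in inbreeding coefficients; no samples removed")
        return G
    dev = (F - F.mean()) / sd
    if tail == "both":
        keep = np.flatnonzero(np.abs(dev) <= thresholds.het_sd)
    else:  # excess heterozygosity only: F far BELOW the mean
        keep = np.flatnonzero(dev >= -thresholds.het_sd)
    return G.subset(sample_idx=keep)


def relatedness_filter(
    kinship: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> set[str]:
    """Greedy exclusion set leaving no pair with pi_hat above threshold.

    Repeatedly drops the individual involved in the most violating pairs
    (ties broken toward the lexicographically smaller id) until none remain.
    Returns the set of excluded ids.
    """
    if ((kinship["pi_hat"] < 0) | (kinship["pi_hat"] > 1)).any():
        raise ValueError("pi_hat must lie in [0, 1]")
    if (kinship["id1"] == kinship["id2"]).any():
        raise ValueError("self-pairs are not allowed in the kinship table")
    pairs = [
        (str(a), str(b))
        for a, b, k in kinship[["id1", "id2", "pi_hat"]].itertuples(index=False)
        if k > thresholds.max_pi_hat
    ]
    excluded: set[str] = set()
    while pairs:
        degree: dict[str, int] = {}
        for a, b in pairs:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        worst = min(degree, key=lambda i: (-degree[i], i))
        excluded.add(worst)
        pairs = [(a, b) for a, b in pairs if worst not in (a, b)]
    return excluded


def qc_pipeline(
    G: GenotypeMatrix,
    kinship: pd.DataFrame | None = None,
    thresholds: QcThresholds = QcThresholds(),
    het_tail: str = "both",
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC battery in the documented order.

    Sample call rate -> relatedness -> variant call rate -> HWE -> MAF ->
    heterozygosity.  Returns the filtered matrix and a step-by-step report.
    """
    report = QcReport()

    keep_s = np.flatnonzero(G.sample_call_rate() >= thresholds.min_sample_call_rate)
    if len(keep_s) == 0:
        raise ValueError("call-rate filter removed every sample")
    report.add("sample_call_rate", G.n_samples - len(keep_s), len(keep_s))
    G = G.subset(sample_idx=keep_s)

    if kinship is not None and len(kinship):
        excluded = relatedness_filter(kinship, thresholds)
        keep_s = np.flatnonzero(~G.samples["iid"].isin(excluded))
        report.add("relatedness", G.n_samples - len(keep_s), len(keep_s))
        G = G.subset(sample_idx=keep_s)

    keep_v = np.flatnonzero(G.variant_call_rate() >= thresholds.min_variant_call_rate)
    report.add("variant_call_rate", G.n_variants - len(keep_v), len(keep_v))
    G = G.subset(variant_idx=keep_v)

    before = G.n_variants
    G = hwe_filter(G, thresholds)
    report.add("hwe", before - G.n_variants, G.n_variants)

    before = G.n_variants
    G = maf_filter(G, thresholds)
    report.add("maf", before - G.n_variants, G.n_variants)

    before = G.n_samples
    G = het_outlier_filter(G, thresholds, tail=het_tail)
    report.add("heterozygosity", before - G.n_samples, G.n_samples)

    report.result = G
    return G, report
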