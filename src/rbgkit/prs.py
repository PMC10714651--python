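"""Polygenic risk score construction and extreme-tail recall selection.

The score is the classic weighted allele count: harmonise GWAS weights to the
target coding, thin by p-value-ordered LD clumping (window 1000 kb,
r^2 > 0.2, P <= 0.5 by default), drop the APOE region, sum beta x dosage per
sample, standardise over the scored population, bin into deciles, and pick
the score tails for recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    AMBIGUOUS_PAIRS,
    MISSING,
    GenotypeMatrix,
    RegionMask,
    ScoreSet,
    complement,
    validate_sumstats,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpConfig:
    """LD-clumping parameters (defaults: kb=1000, r^2=0.2, P<=0.5)."""

    window_kb: float = 1000.0
    r2_threshold: float = 0.2
    p_threshold: float = 0.5

    def __post_init__(self):
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")


class GenotypeLd:
    """Pairwise dosage r^2 computed from a target genotype panel.

    Missing dosages are mean-imputed before correlation.  Lookup is by
    variant id; pairs not present in the panel yield r^2 = 0 (logged).
    """

    def __init__(self, G: GenotypeMatrix):
        d = G.dosages.astype(float)
        d[G.dosages == MISSING] = np.nan
        col_mean = np.nanmean(d, axis=0)
        inds = np.where(np.isnan(d))
        d[inds] = np.take(col_mean, inds[1])
        d -= d.mean(axis=0)
        sd = d.std(axis=0)
        sd[sd == 0] = np.inf  # monomorphic: define r = 0 against anything
        self._std = d / sd
        self._n = d.shape[0]
        self._index = {vid: j for j, vid in enumerate(G.variants["id"])}

    def r2(self, id_a: str, id_b: str) -> float:
        ja, jb = self._index.get(id_a), self._index.get(id_b)
        if ja is None or jb is None:
            log.debug("no LD available for pair (%s, %s); treating r^2 as 0", id_a, id_b)
            return 0.0
        r = float(self._std[:, ja] @ self._std[:, jb]) / self._n
        return r * r


class TableLd:
    """Pairwise r^2 from a precomputed symmetric table (ID_A, ID_B, R2)."""

    def __init__(self, table: pd.DataFrame):
        cols = {c.lower(): c for c in table.columns}
        a, b, r2 = cols["id_a"], cols["id_b"], cols["r2"]
        self._r2 = {}
        for ia, ib, v in table[[a, b, r2]].itertuples(index=False):
            self._r2[(str(ia), str(ib))] = float(v)
            self._r2[(str(ib), str(ia))] = float(v)

    def r2(self, id_a: str, id_b: str) -> float:
        v = self._r2.get((id_a, id_b))
        if v is None:
            log.debug("no LD entry for pair (%s, %s); treating r^2 as 0", id_a, id_b)
            return 0.0
        return v


def harmonize(variants: pd.DataFrame, sumstats: pd.DataFrame) -> pd.DataFrame:
    """Align GWAS weights to the target panel's allele coding.

    Matches on variant id.  Where the target's (a1, a2) equals the summary
    statistics' (other, effect) pair the beta sign is flipped (and the
    frequency complemented); strand flips are resolved by complementing;
    strand-ambiguous A/T and C/G variants are removed; anything unmatched is
    dropped and counted.  The returned frame carries the target coding:
    ``beta`` is the effect per copy of the target ``a1``.
    """
    validate_sumstats(sumstats)
    ss = sumstats.set_index("id")
    rows = []
    n_ambiguous = n_mismatch = n_unmatched = 0
    for v in variants.itertuples(index=False):
        if v.id not in ss.index:
            n_unmatched += 1
            continue
        s = ss.loc[v.id]
        ta1, ta2 = str(v.a1), str(v.a2)
        if (ta1, ta2) in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        sa1, sa2 = str(s["a1"]), str(s["a2"])
        flip = None
        if (ta1, ta2) == (sa1, sa2) or (ta1, ta2) == (complement(sa1), complement(sa2)):
            flip = False
        elif (ta1, ta2) == (sa2, sa1) or (ta1, ta2) == (complement(sa2), complement(sa1)):
            flip = True
        if flip is None:
            n_mismatch += 1
            continue
        beta = -s["beta"] if flip else s["beta"]
        freq = 1.0 - s["freq"] if flip else s["freq"]
        rows.append((v.chrom, v.pos, v.id, ta1, ta2, beta, s["se"], s["p"], freq, s["info"]))
    if not rows:
        raise ValueError("no variants overlap between the panel and the summary statistics")
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "a1", "a2", "beta", "se", "p", "freq", "info"]
    )
    log.info(
        "harmonised %d variants (%d unmatched, %d allele-mismatched, %d strand-ambiguous dropped)",
        len(out), n_unmatched, n_mismatch, n_ambiguous,
    )
    return out


def clump(sumstats: pd.DataFrame, ld, config: ClumpConfig = ClumpConfig()) -> list[str]:
    """Greedy p-value-ordered LD clumping; returns retained variant ids.

    Variants with p above ``p_threshold`` are never retained.  Each retained
    index variant discards all not-yet-retained same-chromosome variants
    within ``window_kb`` whose r^2 with it exceeds ``r2_threshold``.  Ties in
    p break by position then id.
    """
    df = sumstats.loc[sumstats["p"] <= config.p_threshold]
    order = df.sort_values(["p", "pos", "id"], kind="mergesort")
    window_bp = config.window_kb * 1000.0
    alive = dict.fromkeys(order["id"], True)
    by_id = order.set_index("id")
    retained: list[str] = []
    for row in order.itertuples(index=False):
        if not alive[row.id]:
            continue
        retained.append(row.id)
        alive[row.id] = False
        near = by_id[
            (by_id["chrom"] == row.chrom) & (np.abs(by_id["pos"] - row.pos) <= window_bp)
        ].index
        for other in near:
            if alive.get(other) and ld.r2(row.id, other) > config.r2_threshold:
                alive[other] = False
    return retained


def exclude_regions(variants: pd.DataFrame, mask: RegionMask) -> pd.DataFrame:
    """Drop variants falling inside any masked half-open [start, end) interval.

    Rows on chromosomes the mask does not name pass through untouched.
    """
    hit = mask.contains(variants["chrom"], variants["pos"])
    masked_chroms = {str(c) for c, _, _ in mask.regions.values()}
    unknown = set(variants["chrom"].astype(str)) - masked_chroms
    if unknown:
        log.debug("chromosomes %s not covered by the region mask; passed through", sorted(unknown))
    return variants.loc[~hit].reset_index(drop=True)


def compute_prs(
    G: GenotypeMatrix, weights: pd.DataFrame, missing_policy: str = "mean_impute"
) -> ScoreSet:
    """Score each sample: raw = sum_j beta_j * dosage_ij, then standardise.

    ``mean_impute`` (default) replaces a missing dosage by twice the sample
    effect-allele frequency; ``omit`` drops the term and rescales the sum by
    (total weights / observed weights) per sample.  Standardised scores have
    mean 0 and SD 1 (ddof=1) over the scored population; deciles are
    rank-based with ties assigned to the lower decile.
    """
    if len(weights) == 0:
        raise ValueError("empty weight set")
    if missing_policy not in ("mean_impute", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    idx = {vid: j for j, vid in enumerate(G.variants["id"])}
    cols = [idx[v] for v in weights["id"] if v in idx]
    if len(cols) != len(weights):
        raise ValueError("weights contain variants absent from the genotype panel")
    beta = weights["beta"].to_numpy(float)
    d = G.dosages[:, cols].astype(float)
    miss = d == MISSING
    if missing_policy == "mean_impute":
        d[miss] = np.nan
        freq_hat = np.nanmean(d, axis=0) / 2.0
        fill = 2.0 * np.nan_to_num(freq_hat)
        inds = np.where(miss)
        d[inds] = np.take(fill, inds[1])
        raw = d @ beta
    else:
        d[miss] = 0.0
        raw = d @ beta
        n_obs = (~miss).sum(axis=1)
        if (n_obs == 0).any():
            raise ValueError("sample with no observed scored variants under omit policy")
        raw *= len(beta) / n_obs

    mu, sd = raw.mean(), raw.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(raw)
    else:
        z = (raw - mu) / sd
    scores = pd.DataFrame({"iid": G.samples["iid"].to_numpy(), "raw": raw, "z": z})
    scores["decile"] = _rank_deciles(raw)
    return ScoreSet(
        scores=scores,
        n_variants=len(beta),
        config={"missing_policy": missing_policy},
    )


def _rank_deciles(values: np.ndarray) -> np.ndarray:
    """Decile labels 1..10 with near-equal bins; tied values share the lower decile."""
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    dec = np.empty(n, dtype=np.int64)
    dec[order] = np.arange(n) * 10 // n + 1
    # collapse ties onto the smallest decile among them
    s = pd.Series(dec).groupby(pd.Series(values)).transform("min")
    return s.to_numpy()


def select_recall(
    scores: ScoreSet, k_low: int = 10, k_high: int = 6, min_sd: float = 2.0
) -> pd.DataFrame:
    """The k_low lowest and k_high highest standardised scores, labelled low/high.

    Every selected member must sit at least ``min_sd`` standard deviations
    from the population mean and in the outermost decile for its tail; a
    shortfall raises rather than silently relaxing the criteria.
    """
    if k_low <= 0 or k_high <= 0:
        raise ValueError("k_low and k_high must be positive")
    df = scores.scores
    if k_low + k_high > len(df):
        raise ValueError("recall groups larger than the scored population")
    asc = df.sort_values("z", kind="mergesort")
    low = asc.head(k_low)
    high = asc.tail(k_high)
    ok_low = (low["z"] <= -min_sd) & (low["decile"] == 1)
    ok_high = (high["z"] >= min_sd) & (high["decile"] == 10)
    if not ok_low.all() or not ok_high.all():
        raise ValueError(
            f"recall shortfall: only {int(ok_low.sum())}/{k_low} low and "
            f"{int(ok_high.sum())}/{k_high} high candidates beyond {min_sd} SD "
            "in the outer deciles"
        )
    out = pd.concat(
        [
            pd.DataFrame({"iid": low["iid"], "group": "low", "z": low["z"]}),
            pd.DataFrame({"iid": high["iid"], "group": "high", "z": high["z"]}),
        ]
    )
    return out.reset_index(drop=True)
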