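"""Core containers shared across the pipeline.

Genotypes are held as an integer dosage matrix (samples x variants, values in
{0, 1, 2} counting copies of the effect allele, ``MISSING`` = -1) together with
variant and sample metadata tables.  GWAS summary statistics and cohort tables
are plain :class:`pandas.DataFrame` objects with documented column schemas;
light validators enforce them at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Missing-dosage sentinel used throughout.
MISSING: int = -1

#: Required columns of a GWAS summary-statistics frame.
SUMSTATS_COLUMNS = ("chrom", "pos", "id", "a1", "a2", "beta", "se", "p", "freq", "info")

#: Strand-ambiguous allele pairs (indistinguishable under strand flip).
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Complement of a single-base allele string."""
    return "".join(_COMPLEMENT.get(b, b) for b in allele)


class GenotypeMatrix:
    """Samples x variants dosage matrix with variant/sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` integer array with values in
        ``{0, 1, 2, MISSING}``; entry counts copies of the variant's effect
        allele (``a1``).
    variants
        Frame with columns ``chrom`` (str), ``pos`` (1-based int), ``id``
        (str), ``a1`` (effect allele), ``a2`` (other allele).
    samples
        Frame with columns ``iid`` (str) and ``sex`` (``"F"``/``"M"``/``"0"``).
    """

    def __init__(self, dosages: np.ndarray, variants: pd.DataFrame, samples: pd.DataFrame):
        self.dosages = np.asarray(dosages, dtype=np.int8)
        self.variants = variants.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        d = self.dosages
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if d.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {d.shape} does not match metadata "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        bad = ~np.isin(d, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING (-1)")
        v = self.variants
        for col in ("chrom", "pos", "id", "a1", "a2"):
            if col not in v.columns:
                raise ValueError(f"variants frame missing column {col!r}")
        if (v["a1"].astype(str).str.len() == 0).any() or (v["a2"].astype(str).str.len() == 0).any():
            raise ValueError("allele strings must be non-empty")
        if (v["a1"].astype(str) == v["a2"].astype(str)).any():
            raise ValueError("effect and other allele must differ per variant")
        for chrom, grp in v.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        if "iid" not in self.samples.columns:
            raise ValueError("samples frame missing column 'iid'")

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def sample_call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def variant_call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele (a1) frequency on non-missing dosages.

        NaN where every dosage is missing.
        """
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing -> NaN
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency (NaN where undefined)."""
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self) -> np.ndarray:
        """Per-variant (n_hom_other, n_het, n_hom_effect) counts, shape (m, 3)."""
        out = np.empty((self.n_variants, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.dosages == g).sum(axis=0)
        return out

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """New matrix restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            self.dosages[np.ix_(si, vi)],
            self.variants.iloc[vi],
            self.samples.iloc[si],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check a summary-statistics frame against the schema and invariants.

    Returns the (unmodified) frame so the call can be chained.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("se must be > 0")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("p must lie in (0, 1]")
    if ((df["freq"] <= 0) | (df["freq"] >= 1)).any():
        raise ValueError("freq must lie in (0, 1)")
    if ((df["info"] < 0) | (df["info"] > 1)).any():
        raise ValueError("info must lie in [0, 1]")
    return df


@dataclass(frozen=True)
class ScoreSet:
    """Per-sample polygenic scores.

    ``scores`` has columns ``iid``, ``raw``, ``z`` (standardised to mean 0 and
    SD 1 over the scored population) and ``decile`` in 1..10 (rank-based, ties
    to the lower decile).
    """

    scores: pd.DataFrame
    n_variants: int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        z = self.scores["z"].to_numpy(float)
        if len(z) > 1 and z.std(ddof=1) > 0:  # degenerate constant scores stay at 0
            if abs(z.mean()) > 1e-8 or abs(z.std(ddof=1) - 1.0) > 1e-8:
                raise ValueError("standardised scores must have mean 0 and SD 1")
        dec = self.scores["decile"].to_numpy()
        if ((dec < 1) | (dec > 10)).any():
            raise ValueError("deciles must lie in 1..10")


@dataclass(frozen=True)
class RegionMask:
    """Named half-open base-pair intervals, keyed by chromosome label.

    ``regions`` maps a name to ``(chrom, start, end)`` with the interval
    interpreted as ``[start, end)``.
    """

    regions: dict

    def __post_init__(self):
        for name, (chrom, start, end) in self.regions.items():
            if not start < end:
                raise ValueError(f"region {name!r}: start must be < end")

    def contains(self, chrom, pos) -> np.ndarray:
        """Boolean mask, True where (chrom, pos) falls inside any interval."""
        chrom = np.asarray(chrom).astype(str)
        pos = np.asarray(pos)
        hit = np.zeros(chrom.shape, dtype=bool)
        for _, (c, start, end) in self.regions.items():
            hit |= (chrom == str(c)) & (pos >= start) & (pos < end)
        return hit


#: APOE region on chromosome 19 (kb 44,400-46,500), excluded from the AD PRS.
APOE_REGION = ("19", 44_400_000, 46_500_000)
#: Extended MHC on chromosome 6 (kb 26,000-34,000).
MHC_REGION = ("6", 26_000_000, 34_000_000)


def apoe_mask() -> RegionMask:
    return RegionMask({"APOE": APOE_REGION})


def apoe_mhc_mask() -> RegionMask:
    return RegionMask({"APOE": APOE_REGION, "MHC": MHC_REGION})
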