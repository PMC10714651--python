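"""Readers and writers for the plain formats the pipeline exchanges.

PLINK-1 bed/bim/fam triplets (SNP-major two-bit encoding), a TSV dosage
alternative, GWAS summary statistics TSV (CHR, BP, SNP, A1, A2, BETA, SE, P,
FRQ, INFO), kinship TSV (ID1, ID2, PI_HAT) and cohort TSV.

The bed codec is implemented here directly: per variant, samples are packed
four to a byte, least-significant pair first, with 00 = homozygous A1,
01 = missing, 10 = heterozygous, 11 = homozygous A2.  A1 is taken as the
effect allele, so the stored code maps to dosages 2 / missing / 1 / 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING, SUMSTATS_COLUMNS, GenotypeMatrix, validate_sumstats

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))  # PLINK 1.9 SNP-major

# dosage (copies of A1) -> 2-bit code and back
_DOSE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam for a genotype matrix."""
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": G.variants["chrom"],
            "id": G.variants["id"],
            "cm": 0,
            "pos": G.variants["pos"],
            "a1": G.variants["a1"],
            "a2": G.variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    sex = G.samples.get("sex", pd.Series(["0"] * G.n_samples))
    sex_code = sex.map({"M": 1, "F": 2}).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "fid": G.samples["iid"],
            "iid": G.samples["iid"],
            "father": 0,
            "mother": 0,
            "sex": sex_code,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = G.n_samples
    codes = np.empty_like(G.dosages, dtype=np.uint8)
    for dose, code in _DOSE_TO_CODE.items():
        codes[G.dosages == dose] = code
    # pad sample axis to a multiple of 4, pack 4 samples per byte per variant
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, G.n_variants), dtype=np.uint8)])
    c = codes.T.reshape(G.n_variants, -1, 4)  # variant-major
    packed = (c[..., 0] | (c[..., 1] << 2) | (c[..., 2] << 4) | (c[..., 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK-1 bed/bim/fam triplet into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK-1 bed file")
    body = raw[3:]
    stride = (n + 3) // 4
    if len(body) != stride * m:
        raise ValueError("bed payload size inconsistent with bim/fam dimensions")
    body = body.reshape(m, stride)
    codes = np.empty((m, stride * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSE[codes[:, :n]].T
    variants = bim[["chrom", "pos", "id", "a1", "a2"]]
    samples = pd.DataFrame(
        {"iid": fam["iid"], "sex": fam["sex"].map({1: "M", 2: "F"}).fillna("0")}
    )
    return GenotypeMatrix(dosages, variants, samples)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text alternative: variant metadata columns then one column per sample.

    Missing dosages are written as ``NA``.
    """
    df = G.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    dos = G.dosages.T.astype(object)
    dos[dos == MISSING] = "NA"
    for j, iid in enumerate(G.samples["iid"]):
        df[iid] = dos[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    meta_cols = ["chrom", "pos", "id", "a1", "a2"]
    iids = [c for c in df.columns if c not in meta_cols]
    dos = df[iids].to_numpy(dtype=object).T
    out = np.empty(dos.shape, dtype=np.int8)
    mask_na = pd.isna(dos) | (dos == "NA")
    out[mask_na] = MISSING
    out[~mask_na] = dos[~mask_na].astype(np.int8)
    samples = pd.DataFrame({"iid": iids, "sex": "0"})
    return GenotypeMatrix(out, df[meta_cols], samples)


_SUMSTATS_HEADER = {"chrom": "CHR", "pos": "BP", "id": "SNP", "a1": "A1", "a2": "A2",
                    "beta": "BETA", "se": "SE", "p": "P", "freq": "FRQ", "info": "INFO"}


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    validate_sumstats(df)
    df[list(SUMSTATS_COLUMNS)].rename(columns=_SUMSTATS_HEADER).to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str, "A1": str, "A2": str})
    inv = {v: k for k, v in _SUMSTATS_HEADER.items()}
    df = df.rename(columns=inv)
    return validate_sumstats(df[list(SUMSTATS_COLUMNS)])


def write_kinship(df: pd.DataFrame, path: str | Path) -> None:
    df.rename(columns={"id1": "ID1", "id2": "ID2", "pi_hat": "PI_HAT"}).to_csv(
        path, sep="\t", index=False
    )


def read_kinship(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ID1": str, "ID2": str})
    return df.rename(columns={"ID1": "id1", "ID2": "id2", "PI_HAT": "pi_hat"})


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "group": str, "sex": str})
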