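import numpy as np
import pandas as pd
import pytest

from rbgkit import synthgen
from rbgkit.types import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genotypes():
    """200 samples x 60 variants, MAF ~ 0.3, LD blocks of 10 at rho 0.8."""
    return synthgen.gen_genotypes(
        200, 60, maf_range=(0.2, 0.4), ld_block_size=10, ld_rho=0.8, seed=11
    )


def make_genotypes(dosages, chrom="1", pos=None, a1=None, a2=None):
    """Hand-built GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "id": [f"v{j}" for j in range(m)],
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
        }
    )
    samples = pd.DataFrame({"iid": [f"s{i}" for i in range(n)], "sex": "F"})
    return GenotypeMatrix(dosages, variants, samples)


@pytest.fixture
def sumstats_frame():
    """Tiny well-formed summary-statistics frame."""
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "pos": [1000, 2000, 1500],
            "id": ["v0", "v1", "v2"],
            "a1": ["A", "C", "G"],
            "a2": ["G", "T", "A"],
            "beta": [0.1, -0.2, 0.05],
            "se": [0.02, 0.03, 0.04],
            "p": [1e-6, 1e-10, 0.2],
            "freq": [0.3, 0.4, 0.2],
            "info": [0.99, 0.95, 0.92],
        }
    )
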