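"""PRS construction: harmonisation, clumping, scoring, recall selection."""

import numpy as np
import pandas as pd
import pytest

from rbgkit import prs, synthgen
from rbgkit.prs import ClumpConfig, GenotypeLd, TableLd
from rbgkit.types import MISSING, apoe_mask, apoe_mhc_mask

from conftest import make_genotypes


def naive_clump(sumstats, r2_lookup, window_kb, r2_threshold, p_threshold):
    """Step-by-step reference clumping, independent of the implementation."""
    rows = sumstats[sumstats["p"] <= p_threshold]
    rows = rows.sort_values(["p", "pos", "id"]).to_dict("records")
    retained, discarded = [], set()
    while rows:
        best = rows.pop(0)
        if best["id"] in discarded:
            continue
        retained.append(best["id"])
        for other in rows:
            if other["id"] in discarded or other["chrom"] != best["chrom"]:
                continue
            if abs(other["pos"] - best["pos"]) <= window_kb * 1000:
                if r2_lookup(best["id"], other["id"]) > r2_threshold:
                    discarded.add(other["id"])
    return retained


class TestHarmonize:
    def setup_method(self):
        self.variants = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [100, 200, 300],
                "id": ["v1", "v2", "v3"],
                "a1": ["A", "C", "A"],
                "a2": ["G", "A", "T"],
            }
        )
        self.ss = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [100, 200, 300],
                "id": ["v1", "v2", "v3"],
                "a1": ["A", "A", "A"],
                "a2": ["G", "C", "T"],
                "beta": [0.5, 0.3, 0.2],
                "se": [0.1, 0.1, 0.1],
                "p": [0.01, 0.02, 0.03],
                "freq": [0.3, 0.4, 0.2],
                "info": [1.0, 1.0, 1.0],
            }
        )

    def test_identical_swapped_and_ambiguous(self):
        out = prs.harmonize(self.variants, self.ss)
        # v1 same coding, v2 swapped (beta negated, freq complemented), v3 A/T dropped
        assert out["id"].tolist() == ["v1", "v2"]
        assert out["beta"].tolist() == [0.5, -0.3]
        assert out["freq"].tolist() == [0.3, 0.6]

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            prs.harmonize(self.variants.assign(id=["x1", "x2", "x3"]), self.ss)


class TestClump:
    def test_independent_variants_all_retained(self, sumstats_frame):
        ld = TableLd(pd.DataFrame({"ID_A": [], "ID_B": [], "R2": []}))
        assert set(prs.clump(sumstats_frame, ld)) == set(sumstats_frame["id"])

    def test_correlated_pair_keeps_smaller_p(self):
        ss = pd.DataFrame(
            {
                "chrom": ["1", "1"], "pos": [1_000_000, 1_500_000],
                "id": ["a", "b"], "a1": ["A", "A"], "a2": ["G", "G"],
                "beta": [0.1, 0.1], "se": [0.02, 0.02],
                "p": [1e-8, 1e-4], "freq": [0.3, 0.3], "info": [1.0, 1.0],
            }
        )
        ld = TableLd(pd.DataFrame({"ID_A": ["a"], "ID_B": ["b"], "R2": [0.5]}))
        assert prs.clump(ss, ld) == ["a"]

    def test_p_threshold_excludes(self, sumstats_frame):
        ld = TableLd(pd.DataFrame({"ID_A": [], "ID_B": [], "R2": []}))
        kept = prs.clump(sumstats_frame, ld, ClumpConfig(p_threshold=0.1))
        assert "v2" not in kept  # p = 0.2

    def test_random_instances_match_naive_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(30):
            m = int(rng.integers(3, 13))
            pos = np.sort(rng.choice(np.arange(1, 4000) * 1000, m, replace=False))
            ss = pd.DataFrame(
                {
                    "chrom": rng.choice(["1", "2"], m), "pos": pos,
                    "id": [f"v{j}" for j in range(m)],
                    "a1": "A", "a2": "G",
                    "beta": rng.normal(0, 0.1, m), "se": 0.02,
                    "p": rng.uniform(0, 1, m), "freq": 0.3, "info": 1.0,
                }
            )
            pairs = []
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.5:
                        pairs.append((f"v{i}", f"v{j}", rng.uniform(0, 1)))
            table = pd.DataFrame(pairs, columns=["ID_A", "ID_B", "R2"])
            ld = TableLd(table)
            got = prs.clump(ss, ld, ClumpConfig(window_kb=1000, r2_threshold=0.2))
            want = naive_clump(ss, ld.r2, 1000, 0.2, 0.5)
            assert got == want, f"trial {trial}"

    def test_retained_set_internally_independent(self, small_genotypes):
        ss = synthgen.gen_exposure_sumstats(small_genotypes.variants, 0.3, 0.1,
                                            20_000, seed=22)
        ld = GenotypeLd(small_genotypes)
        kept = prs.clump(ss, ld)
        pos = ss.set_index("id")["pos"]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if abs(pos[a] - pos[b]) <= 1_000_000:
                    assert ld.r2(a, b) <= 0.2


class TestExcludeRegions:
    def test_apoe_and_mhc_boundaries(self):
        variants = pd.DataFrame(
            {
                "chrom": ["19", "19", "6", "1"],
                "pos": [45_000_000, 46_500_000, 30_000_000, 45_000_000],
                "id": ["in_apoe", "at_end", "in_mhc", "elsewhere"],
                "a1": "A", "a2": "G",
            }
        )
        out = prs.exclude_regions(variants, apoe_mhc_mask())
        assert out["id"].tolist() == ["at_end", "elsewhere"]


class TestComputePrs:
    def test_zero_betas_and_single_variant(self, small_genotypes):
        ss = synthgen.gen_exposure_sumstats(small_genotypes.variants, 1.0, 0.1,
                                            10_000, seed=23)
        w = prs.harmonize(small_genotypes.variants, ss)
        w0 = w.assign(beta=0.0)
        assert np.allclose(prs.compute_prs(small_genotypes, w0).scores["raw"], 0.0)
        w1 = w.iloc[[0]].assign(beta=1.0)
        sc = prs.compute_prs(small_genotypes, w1)
        col = small_genotypes.variants["id"].tolist().index(w1["id"].iloc[0])
        assert np.allclose(sc.scores["raw"], small_genotypes.dosages[:, col])

    def test_matches_direct_dot_product(self):
        rng = np.random.default_rng(24)
        G = synthgen.gen_genotypes(50, 30, seed=25)
        w = pd.DataFrame(
            {
                "chrom": G.variants["chrom"], "pos": G.variants["pos"],
                "id": G.variants["id"], "a1": G.variants["a1"],
                "a2": G.variants["a2"], "beta": rng.normal(0, 0.2, 30),
                "se": 0.01, "p": 0.01, "freq": 0.3, "info": 1.0,
            }
        )
        sc = prs.compute_prs(G, w)
        want = G.dosages.astype(float) @ w["beta"].to_numpy()
        assert np.allclose(sc.scores["raw"], want, atol=1e-12)

    def test_standardisation_and_decile_partition(self, small_genotypes):
        ss = synthgen.gen_exposure_sumstats(small_genotypes.variants, 1.0, 0.1,
                                            10_000, seed=26)
        w = prs.harmonize(small_genotypes.variants, ss)
        sc = prs.compute_prs(small_genotypes, w)
        z = sc.scores["z"]
        assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=1) - 1) < 1e-10
        sizes = sc.scores["decile"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        d = sc.scores.groupby("decile")["z"].mean()
        assert d[10] > d[1]

    def test_allele_flip_invariance(self):
        """Flipping a variant's coding and negating its beta leaves scores fixed."""
        G = synthgen.gen_genotypes(80, 25, seed=27)
        ss = synthgen.gen_exposure_sumstats(G.variants, 1.0, 0.1, 10_000, seed=28)
        w = prs.harmonize(G.variants, ss)
        sc = prs.compute_prs(G, w)

        j = G.variants["id"].tolist().index(w["id"].iloc[0])
        d2 = G.dosages.copy()
        typed = d2[:, j] != MISSING
        d2[typed, j] = 2 - d2[typed, j]
        v2 = G.variants.copy()
        v2.loc[j, ["a1", "a2"]] = v2.loc[j, ["a2", "a1"]].to_numpy()
        from rbgkit.types import GenotypeMatrix

        G2 = GenotypeMatrix(d2, v2, G.samples)
        w2 = prs.harmonize(G2.variants, ss)
        sc2 = prs.compute_prs(G2, w2)
        assert np.allclose(sc.scores["z"], sc2.scores["z"], atol=1e-10)

    def test_missing_policies(self):
        d = np.array([[0, 1], [2, MISSING], [1, 1], [2, 0]], dtype=np.int8)
        G = make_genotypes(d)
        w = pd.DataFrame(
            {"chrom": "1", "pos": [1000, 2000], "id": ["v0", "v1"],
             "a1": "A", "a2": "G", "beta": [1.0, 2.0], "se": 0.1, "p": 0.1,
             "freq": 0.5, "info": 1.0}
        )
        raw_mi = prs.compute_prs(G, w, "mean_impute").scores["raw"]
        # missing dosage -> 2 * (observed a1 freq = 2/6), term = 2 * 2/3
        assert raw_mi[1] == pytest.approx(2 + 2 * 2 / 3)
        raw_om = prs.compute_prs(G, w, "omit").scores["raw"]
        assert raw_om[1] == pytest.approx(2 * 2)  # (beta*2) * (2 weights / 1 observed)


class TestSelectRecall:
    def test_tail_selection_from_large_population(self, rng):
        raw = rng.standard_normal(4504)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        from rbgkit.prs import _rank_deciles
        from rbgkit.types import ScoreSet

        scores = ScoreSet(
            pd.DataFrame({"iid": [f"s{i}" for i in range(4504)], "raw": raw,
                          "z": z, "decile": _rank_deciles(raw)}),
            n_variants=1,
        )
        sel = prs.select_recall(scores)
        assert (sel["group"] == "low").sum() == 10
        assert (sel["group"] == "high").sum() == 6
        assert (sel["z"].abs() >= 2).all()

    def test_shortfall_raises(self, rng):
        raw = rng.standard_normal(20)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        from rbgkit.prs import _rank_deciles
        from rbgkit.types import ScoreSet

        scores = ScoreSet(
            pd.DataFrame({"iid": [f"s{i}" for i in range(20)], "raw": raw,
                          "z": z, "decile": _rank_deciles(raw)}),
            n_variants=1,
        )
        with pytest.raises(ValueError, match="shortfall"):
            prs.select_recall(scores)
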