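import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from hybzone.repeatability import (
    compare_blockiness,
    genes_for_snps,
    intersect_scans,
    morans_i,
    overlap_enrichment,
    read_bed,
    read_gff3_genes,
    scan_correlations,
)


def _scan(keys, **stats):
    df = pd.DataFrame(keys, columns=["scaffold", "pos"])
    for name, vals in stats.items():
        df[name] = vals
    return df


class TestIntersectScans:
    def test_disjoint_inputs_empty(self):
        a = _scan([("s1", 1), ("s1", 2)], fst=[0.1, 0.2])
        b = _scan([("s2", 1)], fst=[0.3])
        assert len(intersect_scans(a, b)) == 0

    def test_identical_inputs_full(self):
        a = _scan([("s1", 1), ("s1", 2), ("s2", 5)], fst=[0.1, 0.2, 0.3])
        out = intersect_scans(a, a.copy())
        assert len(out) == 3
        assert np.allclose(out["fst_a"], out["fst_b"])

    def test_planted_shared_keys(self):
        shared = [("s1", i) for i in range(5)]
        a = _scan(shared + [("s9", 1), ("s9", 2), ("s9", 3)], fst=np.arange(8.0))
        b = _scan(shared + [("s8", 1), ("s8", 2)], fst=np.arange(7.0))
        out = intersect_scans(a, b)
        assert sorted(zip(out["scaffold"], out["pos"])) == sorted(shared)

    def test_duplicate_keys_rejected(self):
        a = _scan([("s1", 1), ("s1", 1)], fst=[0.1, 0.2])
        with pytest.raises(ValueError, match="duplicate"):
            intersect_scans(a, a)


class TestScanCorrelations:
    def test_perfect_agreement(self):
        x = np.linspace(0, 1, 30)
        shared = _scan([("s", i) for i in range(30)])
        shared["fst_a"] = x
        shared["fst_b"] = x
        out = scan_correlations(shared, "fst")
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["kendall_tau"] == pytest.approx(1.0)
        assert out["p_values_overestimated"]

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        shared = _scan([("s", i) for i in range(3000)])
        shared["fst_a"] = rng.normal(size=3000)
        shared["fst_b"] = rng.normal(size=3000)
        assert abs(scan_correlations(shared, "fst")["pearson_r"]) < 0.05

    def test_nan_pairs_dropped(self):
        shared = _scan([("s", i) for i in range(5)])
        shared["fst_a"] = [0.1, np.nan, 0.3, 0.4, 0.5]
        shared["fst_b"] = [0.2, 0.2, np.nan, 0.5, 0.6]
        assert scan_correlations(shared, "fst")["n"] == 3


class TestMoransI:
    def test_matches_brute_force_double_loop(self):
        vals = np.array([1.0, 1, 1, -1, -1, -1])
        pos = np.arange(1, 7, dtype=float)
        z = vals - vals.mean()
        num = W = 0.0
        for i in range(6):
            for j in range(6):
                if i != j:
                    w = 1.0 / abs(pos[i] - pos[j])
                    W += w
                    num += w * z[i] * z[j]
        expected = 6 / W * num / (z @ z).item()
        assert morans_i(vals, pos) == pytest.approx(expected, abs=1e-14)

    def test_shuffled_null_expectation(self):
        rng = np.random.default_rng(1)
        vals = np.repeat([3.0, -3.0], 15)
        pos = np.arange(30, dtype=float)
        shuffles = [morans_i(rng.permutation(vals), pos) for _ in range(400)]
        assert np.mean(shuffles) == pytest.approx(-1.0 / 29.0, abs=0.02)

    def test_blocky_exceeds_shuffles(self):
        rng = np.random.default_rng(2)
        vals = np.repeat([2.0, -2.0, 2.0], 10) + rng.normal(0, 0.3, 30)
        pos = np.arange(30, dtype=float)
        blocky = morans_i(vals, pos)
        exceed = sum(blocky > morans_i(rng.permutation(vals), pos) for _ in range(200))
        assert exceed >= 190

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=25)
        pos = np.arange(25, dtype=float)
        base = morans_i(vals, pos)
        assert morans_i(vals + 100.0, pos) == pytest.approx(base, abs=1e-10)
        assert morans_i(vals * 7.5, pos) == pytest.approx(base, abs=1e-10)

    def test_degenerate_inputs(self):
        assert np.isnan(morans_i(np.ones(5), np.arange(5)))
        with pytest.raises(ValueError):
            morans_i([1.0, 2.0], [1, 2])

    def test_binary_weighting_supported(self):
        vals = np.array([1.0, 1, -1, -1])
        out = morans_i(vals, np.arange(4), weighting="binary")
        assert np.isfinite(out)


class TestCompareBlockiness:
    def _paired_scans(self, seed=0, blocky_a=True):
        rng = np.random.default_rng(seed)
        rows_a, rows_b = [], []
        for u in range(12):
            n = 30
            ordinal = np.arange(n)
            if blocky_a:
                sig_a = np.repeat(rng.normal(size=3), 10) + rng.normal(0, 0.3, n)
            else:
                sig_a = rng.normal(size=n)
            sig_b = rng.normal(size=n)
            rows_a.append(pd.DataFrame({"scaffold": f"u{u}", "ordinal": ordinal, "p": sig_a}))
            rows_b.append(pd.DataFrame({"scaffold": f"u{u}", "ordinal": ordinal, "p": sig_b}))
        return pd.concat(rows_a), pd.concat(rows_b)

    def test_identical_scans_give_zero_differences(self):
        a, _ = self._paired_scans()
        out = compare_blockiness(a, a.copy(), "p")
        assert out["mean_diff"] == 0.0
        assert out["p"] == 1.0

    def test_blockier_scan_detected_one_sided(self):
        a, b = self._paired_scans(seed=5, blocky_a=True)
        out = compare_blockiness(a, b, "p", alternative="greater")
        assert out["mean_diff"] > 0
        assert out["p"] < 0.05

    def test_hand_computed_paired_t(self):
        rng = np.random.default_rng(9)
        a, b = self._paired_scans(seed=9)
        out = compare_blockiness(a, b, "p")
        d = out["table"]["diff"].to_numpy()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["t"] == pytest.approx(t_hand, abs=1e-10)

    def test_too_few_units_rejected(self):
        a, b = self._paired_scans()
        small_a = a[a["scaffold"].isin(["u0", "u1"])]
        small_b = b[b["scaffold"].isin(["u0", "u1"])]
        with pytest.raises(ValueError):
            compare_blockiness(small_a, small_b, "p")


class TestGenesForSnps:
    def _genes(self):
        return pd.DataFrame(
            {
                "scaffold": ["s1", "s1"],
                "start": [10_000, 13_000],
                "end": [12_000, 14_000],
                "gene_id": ["gA", "gB"],
            }
        )

    def test_flank_boundaries(self):
        # gene gA spans [10000, 12000); flank 5000 -> [5000, 17000)
        snps = pd.DataFrame({"scaffold": ["s1", "s1"], "pos": [5_002, 4_999]})
        out = genes_for_snps(snps, self._genes(), flank=5000)
        assert (out["pos"] == 5_002).all()  # 0-based 5001 inside, 4998 outside
        snps2 = pd.DataFrame({"scaffold": ["s1"], "pos": [10_000 - 5_000]})  # 0-based 4999
        assert len(genes_for_snps(snps2, self._genes(), flank=5000)) == 0

    def test_overlapping_flanked_genes_both_assigned(self):
        snps = pd.DataFrame({"scaffold": ["s1"], "pos": [12_500]})
        out = genes_for_snps(snps, self._genes(), flank=5000)
        assert set(out["gene_id"]) == {"gA", "gB"}

    def test_malformed_interval_rejected(self):
        genes = pd.DataFrame(
            {"scaffold": ["s1"], "start": [100], "end": [100], "gene_id": ["g"]}
        )
        with pytest.raises(ValueError, match="row"):
            genes_for_snps(pd.DataFrame({"scaffold": ["s1"], "pos": [50]}), genes)

    def test_bed_and_gff3_readers(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("s1\t10\t50\tgX\ns2\t5\t9\tgY\n")
        df = read_bed(bed)
        assert list(df["gene_id"]) == ["gX", "gY"]
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "s1\tsrc\tgene\t11\t50\t.\t+\t.\tID=gX;Name=foo\n"
            "s1\tsrc\tmRNA\t11\t50\t.\t+\t.\tID=t1;Parent=gX\n"
        )
        gf = read_gff3_genes(gff)
        assert list(gf["gene_id"]) == ["gX"]
        assert gf["start"].iloc[0] == 10 and gf["end"].iloc[0] == 50  # converted to 0-based


class TestOverlapEnrichment:
    def test_sets_equal_to_universe(self):
        uni = [f"g{i}" for i in range(12)]
        out = overlap_enrichment([uni, uni, uni], uni, n_permutations=100, seed=0)
        assert out["observed"] == 12
        assert out["expected"] == pytest.approx(12.0)
        assert out["p"] == 1.0

    def test_expected_value_formula_exact(self):
        uni = [f"g{i}" for i in range(200)]
        sets = [uni[:20], uni[10:40], uni[:50], uni[5:30]]
        out = overlap_enrichment(sets, uni, n_permutations=10, seed=0)
        assert out["expected"] == pytest.approx(
            200 * (20 / 200) * (30 / 200) * (50 / 200) * (25 / 200)
        )

    def test_pairwise_matches_hypergeometric_tail(self):
        uni = [f"g{i}" for i in range(100)]
        A = uni[:10]
        B = uni[6:16]  # observed overlap 4
        out = overlap_enrichment([A, B], uni, n_permutations=40_000, seed=1)
        exact = hypergeom.sf(3, 100, 10, 10)  # P(X >= 4)
        assert out["observed"] == 4
        assert out["p"] == pytest.approx(exact, abs=4 * np.sqrt(exact / 40_000) + 1e-4)

    def test_small_four_set_case_matches_exhaustive_enumeration(self):
        uni = [f"g{i}" for i in range(6)]
        sets = [["g0", "g1"], ["g0", "g2"], ["g0", "g3"], ["g0", "g4"]]
        out = overlap_enrichment(sets, uni, n_permutations=30_000, seed=2)
        assert out["observed"] == 1
        # exhaustive enumeration: all 15^4 equally likely 2-subset draws
        combos = list(itertools.combinations(range(6), 2))
        hits = 0
        total = 0
        for c1 in combos:
            for c2 in combos:
                inter12 = set(c1) & set(c2)
                for c3 in combos:
                    inter123 = inter12 & set(c3)
                    for c4 in combos:
                        total += 1
                        if inter123 & set(c4):
                            hits += 1
        exact = hits / total
        assert out["p"] == pytest.approx(exact, abs=4 * np.sqrt(exact / 30_000) + 1e-4)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment([["x"], ["y"]], ["y"], n_permutations=10)
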