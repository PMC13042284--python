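import itertools

import numpy as np
import pytest

from hybzone.divergence import pi_dxy, species_fst, summarize_divergence, wc_fst
from hybzone.sim import simulate_parental_freqs

from .conftest import make_matrix


def _wc_scalar(pop_dosages):
    """Independent scalar transcription of the 1984 variance components.

    Direct loops over populations for one biallelic site; used as the
    brute-force oracle against the vectorized implementation.
    """
    ns, ps, hs = [], [], []
    for dos in pop_dosages:
        called = [d for d in dos if not np.isnan(d)]
        if not called:
            continue
        ns.append(len(called))
        ps.append(sum(called) / (2 * len(called)))
        hs.append(sum(1 for d in called if d == 1) / len(called))
    r = len(ns)
    if r < 2:
        return np.nan
    nbar = sum(ns) / r
    if nbar <= 1:
        return np.nan
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return np.nan if a + b + c == 0 else a / (a + b + c)


class TestWcFst:
    def test_fixed_alternative_alleles_give_theta_one(self):
        dos = np.vstack([np.full((20, 1), 2.0), np.zeros((20, 1))])
        labels = np.array(["p1"] * 20 + ["p2"] * 20)
        out = wc_fst(make_matrix(dos), labels)
        assert out["theta"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_give_theta_near_zero(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, size=(400, 50)).astype(float)
        labels = np.array(["p1", "p2"] * 200)
        out = wc_fst(make_matrix(dos), labels)
        assert abs(np.nanmean(out["theta"])) < 0.01

    def test_hand_computed_toy_counts(self):
        # pop1: 7 hom-alt, 2 het, 1 hom-ref (p = 0.8, het = 0.2)
        # pop2: mirrored (p = 0.2, het = 0.2)
        pop1 = [2.0] * 7 + [1.0] * 2 + [0.0]
        pop2 = [0.0] * 7 + [1.0] * 2 + [2.0]
        dos = np.array(pop1 + pop2)[:, None]
        labels = np.array(["p1"] * 10 + ["p2"] * 10)
        out = wc_fst(make_matrix(dos), labels)
        expected = _wc_scalar([pop1, pop2])
        assert out["theta"].iloc[0] == pytest.approx(expected, abs=1e-12)
        # and the components themselves agree with a hand evaluation
        nbar, r = 10.0, 2.0
        nc = (20 - (100 + 100) / 20) / 1  # = 10
        s2 = (10 * 0.09 + 10 * 0.09) / (1 * 10)
        inner = 0.5 * 0.5 - 0.5 * s2
        a_hand = (nbar / nc) * (s2 - (inner - 0.2 / 4) / 9)
        assert out["a"].iloc[0] == pytest.approx(a_hand, abs=1e-12)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 30), size=(60, 30)).astype(float)
        labels = np.repeat(["a", "b", "c"], 20)
        t1 = wc_fst(make_matrix(dos), labels)["theta"]
        t2 = wc_fst(make_matrix(2.0 - dos), labels)["theta"]
        assert np.allclose(t1, t2, equal_nan=True)

    def test_mean_pairwise_equals_multipop_for_two_pops(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.4, size=(30, 20)).astype(float)
        labels = np.array(["x"] * 15 + ["y"] * 15)
        m = make_matrix(dos)
        t1 = wc_fst(m, labels, mode="multipop")["theta"]
        t2 = wc_fst(m, labels, mode="mean_pairwise")["theta"]
        assert np.allclose(t1, t2, equal_nan=True)

    def test_brute_force_oracle_small_cases_with_missing(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            r = rng.integers(2, 4)
            sizes = rng.integers(3, 7, size=r)
            pops, rows, labels = [], [], []
            for k in range(r):
                dos = rng.binomial(2, rng.uniform(0.1, 0.9), size=sizes[k]).astype(float)
                dos[rng.random(sizes[k]) < 0.2] = np.nan
                pops.append(list(dos))
                rows.extend(dos)
                labels.extend([f"p{k}"] * sizes[k])
            out = wc_fst(make_matrix(np.array(rows)[:, None]), np.array(labels))
            expected = _wc_scalar(pops)
            got = out["theta"].iloc[0]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_site_with_no_calls_in_every_population_undefined(self):
        dos = np.full((6, 1), np.nan)
        out = wc_fst(make_matrix(dos), np.array(["a"] * 3 + ["b"] * 3))
        assert np.isnan(out["theta"].iloc[0])


class TestSpeciesFst:
    def test_divergence_parameter_recovered(self):
        pf = simulate_parental_freqs(3000, 0.14, seed=11)
        rng = np.random.default_rng(7)
        n = 200
        dos = np.concatenate(
            [rng.binomial(2, np.tile(pf.p_a, (n, 1))), rng.binomial(2, np.tile(pf.p_b, (n, 1)))]
        ).astype(float)
        labels = np.array(["pureA"] * n + ["pureB"] * n)
        fst = species_fst(make_matrix(dos, positions=np.arange(3000) + 1), labels)
        summary = summarize_divergence(fst)
        assert summary["weighted_mean"] == pytest.approx(0.14, abs=0.03)

    def test_identical_panels_near_zero(self):
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, 0.5, size=(40, 100)).astype(float)
        labels = np.array(["pureA", "pureB"] * 20)
        fst = species_fst(make_matrix(dos), labels)
        assert abs(np.nanmean(fst["theta"])) < 0.05

    def test_fixed_vs_polymorphic_site_matches_hand_computation(self):
        pop1 = [2.0] * 10  # fixed ALT
        pop2 = [2.0] * 2 + [1.0] * 6 + [0.0] * 2  # p = 0.5 with 6 hets
        dos = np.array(pop1 + pop2)[:, None]
        labels = np.array(["pureA"] * 10 + ["pureB"] * 10)
        out = species_fst(make_matrix(dos), labels)
        assert out["theta"].iloc[0] == pytest.approx(_wc_scalar([pop1, pop2]), abs=1e-12)

    def test_empty_panel_rejected(self):
        dos = np.ones((4, 3))
        with pytest.raises(ValueError):
            species_fst(make_matrix(dos), np.array(["pureA"] * 4))


class TestPiDxy:
    def _brute(self, group_a, group_b):
        """Enumerate allele pairs explicitly (missing genotypes excluded)."""
        def alleles(group):
            out = []
            for d in group:
                if not np.isnan(d):
                    out += [1] * int(d) + [0] * (2 - int(d))
            return out

        a, b = alleles(group_a), alleles(group_b)
        def pi(al):
            pairs = list(itertools.combinations(al, 2))
            return np.nan if not pairs else sum(x != y for x, y in pairs) / len(pairs)

        dxy = np.nan
        if a and b:
            cross = [(x, y) for x in a for y in b]
            dxy = sum(x != y for x, y in cross) / len(cross)
        return pi(a), pi(b), dxy

    def test_monomorphic_same_allele(self):
        m = make_matrix(np.zeros((8, 1)))
        out = pi_dxy(m, {"A": np.arange(4), "B": np.arange(4, 8)})
        assert out["pi_A"].iloc[0] == 0 and out["pi_B"].iloc[0] == 0 and out["dxy"].iloc[0] == 0

    def test_fixed_alternative_alleles(self):
        dos = np.vstack([np.full((4, 1), 2.0), np.zeros((4, 1))])
        out = pi_dxy(make_matrix(dos), {"A": np.arange(4), "B": np.arange(4, 8)})
        assert out["dxy"].iloc[0] == 1.0
        assert out["pi_A"].iloc[0] == 0.0 and out["pi_B"].iloc[0] == 0.0

    def test_brute_force_pair_enumeration_with_missing(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            ga = rng.binomial(2, rng.uniform(0.2, 0.8), 4).astype(float)
            gb = rng.binomial(2, rng.uniform(0.2, 0.8), 4).astype(float)
            ga[rng.random(4) < 0.25] = np.nan
            gb[rng.random(4) < 0.25] = np.nan
            dos = np.concatenate([ga, gb])[:, None]
            out = pi_dxy(make_matrix(dos), {"A": np.arange(4), "B": np.arange(4, 8)})
            ea, eb, ed = self._brute(ga, gb)
            for got, exp in [
                (out["pi_A"].iloc[0], ea),
                (out["pi_B"].iloc[0], eb),
                (out["dxy"].iloc[0], ed),
            ]:
                if np.isnan(exp):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(exp, abs=1e-12)

    def test_symmetry_and_group_independence(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, 0.5, size=(12, 10)).astype(float)
        m = make_matrix(dos)
        out1 = pi_dxy(m, {"A": np.arange(6), "B": np.arange(6, 12)})
        out2 = pi_dxy(m, {"B": np.arange(6, 12), "A": np.arange(6)})
        assert np.allclose(out1["dxy"], out2["dxy"], equal_nan=True)
        assert np.allclose(out1["pi_A"], out2["pi_A"], equal_nan=True)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            pi_dxy(make_matrix(np.zeros((4, 1))), {"A": np.arange(3), "B": np.arange(2, 4)})


class TestSummarize:
    def test_single_site(self):
        import pandas as pd

        df = pd.DataFrame({"theta": [0.5], "a": [1.0], "b": [0.5], "c": [0.5]})
        s = summarize_divergence(df)
        assert s["mean"] == s["median"] == 0.5 and s["sd"] == 0.0

    def test_low_divergence_recovered(self):
        pf = simulate_parental_freqs(3000, 0.07, seed=21)
        rng = np.random.default_rng(9)
        n = 300
        dos = np.concatenate(
            [rng.binomial(2, np.tile(pf.p_a, (n, 1))), rng.binomial(2, np.tile(pf.p_b, (n, 1)))]
        ).astype(float)
        fst = wc_fst(
            make_matrix(dos, positions=np.arange(3000) + 1), np.array(["A"] * n + ["B"] * n)
        )
        assert summarize_divergence(fst)["weighted_mean"] == pytest.approx(0.07, abs=0.02)

    def test_fixed_panel_has_zero_polymorphism_fraction(self):
        dos = np.vstack([np.full((5, 4), 2.0), np.zeros((5, 4))])
        m = make_matrix(dos)
        fst = wc_fst(m, np.array(["A"] * 5 + ["B"] * 5))
        s = summarize_divergence(fst, m, {"A": np.arange(10) < 5, "B": np.arange(10) >= 5})
        assert s["polymorphic_fraction_A"] == 0.0
        assert s["polymorphic_fraction_B"] == 0.0
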