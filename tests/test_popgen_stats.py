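"""Diversity/differentiation estimators against brute-force and hand
oracles, plus neutral-simulation calibration properties."""

import math

import numpy as np
import pytest

from popdiv import (
    GenotypeMatrix,
    SimulationConfig,
    fst,
    ld_decay,
    simulate_coalescent,
    sliding_windows,
    tajimas_d,
    theta_pi,
    theta_w,
)
from popdiv.simulate import panmictic_model

from conftest import brute_force_pi_per_site


def make_gm(genotypes, pos=None, pops=None, chrom="chr1"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, s = genotypes.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        pop_labels=pops or ["p1"] * n,
        chrom=np.array([chrom] * s, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, s + 1)),
        genotypes=genotypes,
    )


class TestThetaPi:
    def test_monomorphic_is_zero(self):
        gm = make_gm([[0, 2], [0, 2], [0, 2]])
        assert theta_pi(gm, None, 100) == 0.0

    def test_single_pair_one_diff_in_100(self):
        # a single diploid carries one pair of gene copies; het at 1 of
        # 100 sites -> pairwise difference 0.01 per site
        gm = make_gm([[1]])
        assert theta_pi(gm, None, 100) == pytest.approx(0.01)

    def test_matches_brute_force_pairwise_oracle(self, toy_matrix):
        expected = brute_force_pi_per_site(toy_matrix.genotypes) / 6
        assert theta_pi(toy_matrix, None, 6) == pytest.approx(expected)

    def test_brute_force_with_missing_data(self, missing_matrix):
        expected = brute_force_pi_per_site(missing_matrix.genotypes) / 5
        assert theta_pi(missing_matrix, None, 5) == pytest.approx(expected)


class TestThetaW:
    def test_two_haploid_copies_a1_is_one(self):
        gm = make_gm([[1], [1]])  # hets: 4 copies... use one diploid instead
        one = make_gm([[1, 1, 0]])
        # one diploid = 2 copies, a1 = 1: theta_w = S / span
        assert theta_w(one, None, 100) == pytest.approx(2 / 100)

    def test_direct_a1_summation(self):
        # n = 10 copies (5 diploids), S = 17, span 1e4
        rng = np.random.default_rng(0)
        cols = []
        for _ in range(17):
            while True:
                c = rng.integers(0, 3, size=5)
                if 0 < c.sum() < 10:
                    break
            cols.append(c)
        gm = make_gm(np.array(cols).T)
        a1 = sum(1 / i for i in range(1, 10))
        assert a1 == pytest.approx(2.8289682539682537)
        assert theta_w(gm, None, 1e4) == pytest.approx(17 / (a1 * 1e4))

    def test_no_segregating_sites_gives_zero(self):
        gm = make_gm([[2, 0], [2, 0]])
        assert theta_w(gm, None, 50) == 0.0


def tajima_reference(n, genotype_cols):
    """Independent spreadsheet-style evaluation of Tajima's D (oracle)."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    S = 0
    pi = 0.0
    for col in genotype_cols:
        d = sum(col)
        if 0 < d < n:
            S += 1
            pi += 2 * d * (n - d) / (n * (n - 1))
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregation_is_missing(self):
        gm = make_gm([[0, 0], [0, 0], [0, 0]])
        assert math.isnan(tajimas_d(gm))

    def test_matches_independent_formula_evaluation(self, toy_matrix):
        cols = toy_matrix.genotypes.T.tolist()
        assert tajimas_d(toy_matrix) == pytest.approx(tajima_reference(8, cols))

    def test_complete_case_drops_sites_with_missing(self, missing_matrix):
        complete = [
            col for col in missing_matrix.genotypes.T.tolist() if -1 not in col
        ]
        assert tajimas_d(missing_matrix) == pytest.approx(
            tajima_reference(8, complete)
        )

    def test_neutral_constant_size_mean_near_zero(self):
        # 500 neutral loci, 12 diploids (n=24), theta*L = 10
        N = 10 / (4 * 6.5e-9 * 10_000)
        cfg = SimulationConfig(n1=12, n2=0, n_loci=500, locus_length=10_000, seed=17)
        gm = simulate_coalescent(panmictic_model(N), cfg)
        ds = []
        for c in dict.fromkeys(gm.chrom):
            d = tajimas_d(gm.take_sites(np.nonzero(gm.chrom == c)[0]))
            if not math.isnan(d):
                ds.append(d)
        assert abs(np.mean(ds)) < 0.15

    def test_sign_response_to_demography(self):
        # sharp recent bottleneck -> excess intermediate frequencies -> D > 0
        # (simulated as a long-deep, recently-tiny population); growth -> D < 0
        from popdiv import DemographicModel

        bottleneck = DemographicModel(
            model_id=1, N_anc=100_000, N1=800, N2=800, T_div=1_000
        )
        growth = DemographicModel(
            model_id=1, N_anc=800, N1=100_000, N2=100_000, T_div=40_000
        )
        out = {}
        for name, model in [("bottleneck", bottleneck), ("growth", growth)]:
            cfg = SimulationConfig(
                n1=6, n2=6, n_loci=300, locus_length=20_000, seed=23
            )
            gm = simulate_coalescent(model, cfg)
            ds = []
            for c in dict.fromkeys(gm.chrom):
                d = tajimas_d(gm.take_sites(np.nonzero(gm.chrom == c)[0]))
                if not math.isnan(d):
                    ds.append(d)
            out[name] = np.mean(ds)
        assert out["bottleneck"] > 0 > out["growth"]


def wc_theta_reference(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) theta-hat by direct variance-component
    algebra for one site, two populations of diploids (oracle)."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


class TestFst:
    def test_fixed_difference_is_one_under_both_estimators(self):
        g = [[0] * 4, [0] * 4, [2] * 4, [2] * 4]
        gm = make_gm(g, pops=["p1", "p1", "p2", "p2"])
        assert fst(gm, "p1", "p2", "weir_cockerham") == pytest.approx(1.0)
        assert fst(gm, "p1", "p2", "hudson") == pytest.approx(1.0)

    def test_weir_cockerham_matches_hand_algebra(self):
        # 10 diploids per pop; p1=0.2 via 4 hets, p2=0.8 via 4 hets + 6 homs
        pop1 = [[1]] * 4 + [[0]] * 6
        pop2 = [[1]] * 4 + [[2]] * 6
        gm = make_gm(pop1 + pop2, pops=["p1"] * 10 + ["p2"] * 10)
        expected = wc_theta_reference(10, 0.2, 0.4, 10, 0.8, 0.4)
        assert fst(gm, "p1", "p2", "weir_cockerham") == pytest.approx(expected)

    def test_random_split_of_panmictic_pool_is_near_zero(self):
        cfg = SimulationConfig(n1=10, n2=10, n_loci=300, locus_length=10_000, seed=31)
        gm = simulate_coalescent(panmictic_model(50_000), cfg)
        assert gm.n_sites > 5_000
        assert abs(fst(gm, "basalt", "chalk", "weir_cockerham")) < 0.01

    def test_estimators_agree_on_balanced_designs(self):
        from popdiv import DemographicModel

        model = DemographicModel(
            model_id=1, N_anc=20_000, N1=20_000, N2=20_000, T_div=30_000
        )
        cfg = SimulationConfig(n1=10, n2=10, n_loci=200, locus_length=5_000, seed=37)
        gm = simulate_coalescent(model, cfg)
        wc = fst(gm, "basalt", "chalk", "weir_cockerham")
        hu = fst(gm, "basalt", "chalk", "hudson")
        assert abs(wc - hu) < 0.02

    def test_invariant_to_allele_label_swap(self, toy_matrix):
        swapped = toy_matrix.take_sites(np.arange(6))
        g = swapped.genotypes.copy()
        g[:, ::2] = 2 - g[:, ::2]  # swap labels at alternating sites
        swapped.genotypes = g
        for est in ("weir_cockerham", "hudson"):
            assert fst(toy_matrix, "basalt", "chalk", est) == pytest.approx(
                fst(swapped, "basalt", "chalk", est)
            )


class TestSlidingWindows:
    def test_single_window_reproduces_global_theta_pi(self, toy_matrix):
        table = sliding_windows(
            toy_matrix, size_bp=100, step_bp=100,
            pop1="basalt", pop2="chalk",
            contig_lengths={"chr1": 100},
        )
        assert len(table) == 1
        global_pi = theta_pi(toy_matrix, "basalt", 100)
        assert table["theta_pi_basalt"][0] == pytest.approx(global_pi)

    def test_hand_enumerated_window_membership(self):
        pos = np.array([1, 40, 41, 99, 100, 101, 140, 180, 181, 220])
        gm = make_gm(np.ones((2, 10), dtype=np.int8), pos=pos)
        table = sliding_windows(
            gm, size_bp=100, step_bp=40, pop1="p1",
            contig_lengths={"chr1": 220},
        )
        # 0-based half-open windows [0,100) [40,140) [80,180) [120,220)
        # over 0-based sites {0,39,40,98,99,100,139,179,180,219}; the
        # boundary site 100 is excluded from [0,100)
        assert list(table["start"]) == [0, 40, 80, 120]
        assert list(table["n_sites"]) == [5, 5, 5, 4]

    def test_default_starts_follow_step(self):
        gm = make_gm(
            np.ones((2, 3), dtype=np.int8), pos=[1, 100_001, 190_000]
        )
        table = sliding_windows(gm, pop1="p1")
        assert list(table["start"])[:3] == [0, 40_000, 80_000]


class TestLdDecay:
    def test_duplicated_site_has_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=np.int8)
        gm = make_gm(np.stack([col, col], axis=1), pos=[100, 5_100])
        dec = ld_decay(gm, min_maf=0.05, max_dist_bp=20_000, window_avg_bp=20_000)
        assert dec.mean_r2[0] == pytest.approx(1.0)
        assert dec.n_pairs[0] == 1

    def test_matches_direct_correlation(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        b = np.array([0, 1, 1, 2, 1, 2], dtype=np.int8)
        gm = make_gm(np.stack([a, b], axis=1), pos=[10, 1_000])
        r = np.corrcoef(a, b)[0, 1]
        dec = ld_decay(gm, min_maf=0.05, max_dist_bp=20_000, window_avg_bp=20_000)
        assert dec.mean_r2[0] == pytest.approx(r**2)

    def test_independent_loci_have_background_r2(self):
        # sites on different loci are unlinked; sample-size background
        # level of r^2 is about 1/n
        cfg = SimulationConfig(n1=12, n2=0, n_loci=60, locus_length=1_000, seed=41)
        gm = simulate_coalescent(panmictic_model(50_000), cfg)
        # place loci on one contig far apart, then measure between-locus r2
        offsets = {c: 100_000 * i for i, c in enumerate(dict.fromkeys(gm.chrom))}
        pos = np.array([offsets[c] + p for c, p in zip(gm.chrom, gm.pos)])
        flat = GenotypeMatrix(
            gm.sample_ids, gm.pop_labels,
            np.array(["chr1"] * gm.n_sites, dtype=object), pos, gm.genotypes,
        )
        dec = ld_decay(
            flat, min_maf=0.1, max_dist_bp=400_000, window_avg_bp=100_000
        )
        between = dec.mean_r2[1:][dec.n_pairs[1:] > 50]
        assert (between < 2 / 12 + 0.05).all()

    def test_no_qualifying_pairs_gives_empty_table(self):
        gm = make_gm([[0, 1], [0, 1], [0, 0], [0, 1]], pos=[1, 90_000])
        dec = ld_decay(gm, min_maf=0.4, max_dist_bp=20_000, window_avg_bp=20_000)
        assert dec.n_pairs.sum() == 0
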