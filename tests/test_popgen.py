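import numpy as np
import pandas as pd
import pytest

from riverhap.distances import DistanceMatrix, pairwise_diff_matrix
from riverhap.errors import InputError, InsufficientDataError
from riverhap.io import Alignment, HaplotypeTable
from riverhap.popgen import (amova, diversity, net_population_distance,
                             pairwise_fst, polymorphic_sites)


def brute_diversity(hap_of_sample, D, L):
    """Independent oracle: explicit enumeration over individual samples."""
    n = len(hap_of_sample)
    haps = sorted(set(hap_of_sample))
    p = np.array([hap_of_sample.count(h) / n for h in haps])
    h = n / (n - 1) * (1 - (p ** 2).sum())
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pi = np.mean([D[hap_of_sample[i]][hap_of_sample[j]] for i, j in pairs])
    return h, pi, pi / L


def brute_amova(hap_of_sample, group_of_sample, D):
    """Independent oracle: sums of squared distances over individuals."""
    n = len(hap_of_sample)
    groups = sorted(set(group_of_sample))
    ssd_t = sum(D[hap_of_sample[i]][hap_of_sample[j]]
                for i in range(n) for j in range(i + 1, n)) / n
    ssd_w = 0.0
    for g in groups:
        members = [i for i in range(n) if group_of_sample[i] == g]
        ng = len(members)
        ssd_w += sum(D[hap_of_sample[i]][hap_of_sample[j]]
                     for a, i in enumerate(members)
                     for j in members[a + 1:]) / ng
    ssd_a = ssd_t - ssd_w
    P = len(groups)
    s2w = ssd_w / (n - P)
    sizes = [group_of_sample.count(g) for g in groups]
    nbar = (n - sum(s ** 2 for s in sizes) / n) / (P - 1)
    s2a = (ssd_a / (P - 1) - s2w) / nbar
    phi = s2a / (s2a + s2w)
    return ssd_a, ssd_w, s2a, s2w, phi


def make_table(hap_of_sample, group_of_sample, D_dict):
    haps = sorted(D_dict)
    pops = sorted(set(group_of_sample))
    counts = pd.DataFrame(0, index=haps, columns=pops)
    for h, g in zip(hap_of_sample, group_of_sample):
        counts.loc[h, g] += 1
    table = HaplotypeTable(haps, ["A" * 4] * len(haps), counts)
    vals = np.array([[D_dict[a][b] for b in haps] for a in haps], float)
    return table, DistanceMatrix(haps, vals, "diff_count")


class TestDiversity:
    def test_hand_example_two_haplotypes(self, two_pop_table):
        # counts (2,2), n=4, distance 3 between the two haplotypes
        counts = pd.DataFrame({"pop": [2, 2]}, index=["H001", "H002"])
        table = HaplotypeTable(["H001", "H002"], ["AAA", "ATT"], counts)
        d = DistanceMatrix(["H001", "H002"],
                           np.array([[0., 3.], [3., 0.]]), "diff_count")
        est = diversity(table, "pop", d, L=100)
        assert est.h == pytest.approx(4 / 3 * 0.5)       # 0.6667
        assert est.pi_count == pytest.approx(2.0)        # (2*2*3)/6
        assert est.pi_site == pytest.approx(0.02)

    def test_monomorphic_population(self):
        counts = pd.DataFrame({"pop": [5]}, index=["H001"])
        table = HaplotypeTable(["H001"], ["AAAA"], counts)
        d = DistanceMatrix(["H001"], np.zeros((1, 1)), "diff_count")
        est = diversity(table, "pop", d, L=4)
        assert est.h == 0 and est.pi_count == 0 and est.pi_site == 0

    def test_requires_two_samples(self):
        counts = pd.DataFrame({"pop": [1]}, index=["H001"])
        table = HaplotypeTable(["H001"], ["AAAA"], counts)
        d = DistanceMatrix(["H001"], np.zeros((1, 1)), "diff_count")
        with pytest.raises(InsufficientDataError):
            diversity(table, "pop", d, L=4)

    def test_matches_bruteforce_enumeration(self, rng):
        D = {"a": {"a": 0, "b": 2.5, "c": 7}, "b": {"a": 2.5, "b": 0, "c": 3},
             "c": {"a": 7, "b": 3, "c": 0}}
        samples = list(rng.choice(["a", "b", "c"], 11))
        table, d = make_table(samples, ["pop"] * 11, D)
        est = diversity(table, "pop", d, L=50)
        h, pi, pi_site = brute_diversity(samples, D, 50)
        assert est.h == pytest.approx(h, abs=1e-9)
        assert est.pi_count == pytest.approx(pi, abs=1e-9)
        assert est.pi_site == pytest.approx(pi_site, abs=1e-9)

    def test_invariant_under_relabeling_and_evenness(self):
        d0 = np.array([[0., 1.], [1., 0.]])
        for c_even, c_skew in (((5, 5), (8, 2)),):
            counts = pd.DataFrame({"pop": list(c_even)}, index=["h1", "h2"])
            t = HaplotypeTable(["h1", "h2"], ["A", "T"], counts)
            he = diversity(t, "pop", DistanceMatrix(["h1", "h2"], d0,
                                                    "diff_count"), 1).h
            counts = pd.DataFrame({"pop": list(c_skew)}, index=["h1", "h2"])
            t = HaplotypeTable(["h1", "h2"], ["A", "T"], counts)
            hs = diversity(t, "pop", DistanceMatrix(["h1", "h2"], d0,
                                                    "diff_count"), 1).h
            assert he > hs


class TestPolymorphicSites:
    def test_examples(self):
        aln = Alignment(["h1", "h2", "h3", "h4"],
                        ["AAAAAAA", "ATTTTTA", "CAAAAAA", "GAAAAAA"])
        assert polymorphic_sites(aln, ["h1"]) == 0
        assert polymorphic_sites(aln, ["h1", "h2"]) == 5
        # all four bases at site 0, rest constant
        assert polymorphic_sites(aln, ["h1", "h3", "h4"]) == 1

    def test_missing_data_excluded(self):
        aln = Alignment(["h1", "h2"], ["A-N", "AT-"])
        assert polymorphic_sites(aln, ["h1", "h2"]) == 0


class TestFst:
    def test_identical_frequencies_give_zero(self):
        D = {"a": {"a": 0, "b": 4}, "b": {"a": 4, "b": 0}}
        samples = ["a", "a", "b", "b"] * 2
        groups = ["p1"] * 4 + ["p2"] * 4
        table, d = make_table(samples, groups, D)
        res = pairwise_fst(table, d, n_perm=99, seed=1)
        assert res.fst[("p1", "p2")] <= 0 + 1e-12
        assert res.p_values.loc["p1", "p2"] > 0.5

    def test_fixed_distinct_haplotypes_give_one(self):
        D = {"a": {"a": 0, "b": 4}, "b": {"a": 4, "b": 0}}
        samples = ["a"] * 5 + ["b"] * 5
        groups = ["p1"] * 5 + ["p2"] * 5
        table, d = make_table(samples, groups, D)
        res = pairwise_fst(table, d, n_perm=99, seed=1)
        assert res.fst[("p1", "p2")] == pytest.approx(1.0)
        assert res.p_values.loc["p1", "p2"] < 0.05

    def test_matches_bruteforce_phi(self, rng):
        D = {h: {} for h in "abcd"}
        base = rng.uniform(1, 9, (4, 4))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                D[x][y] = base[i, j]
        samples = list(rng.choice(list("abcd"), 12))
        groups = ["p1"] * 7 + ["p2"] * 5
        table, d = make_table(samples, groups, D)
        res = pairwise_fst(table, d, n_perm=9, seed=0)
        *_, phi = brute_amova(samples, groups, D)
        assert res.fst[("p1", "p2")] == pytest.approx(phi, abs=1e-9)

    def test_p_value_bounds(self, two_pop_table):
        table, d = two_pop_table
        res = pairwise_fst(table, d, n_perm=49, seed=5)
        p = res.p_values.loc["popA", "popB"]
        assert 1 / 50 <= p <= 1


class TestAmova:
    def test_fixed_difference_is_all_among(self):
        D = {"a": {"a": 0, "b": 1}, "b": {"a": 1, "b": 0}}
        samples = ["a"] * 4 + ["b"] * 4
        groups = ["p1"] * 4 + ["p2"] * 4
        table, d = make_table(samples, groups, D)
        res = amova(table, d)
        assert res.percent_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_duplicated_population_is_near_zero(self):
        D = {"a": {"a": 0, "b": 2}, "b": {"a": 2, "b": 0}}
        samples = ["a", "b", "a", "b", "a", "b"]
        groups = ["p1", "p1", "p1", "p2", "p2", "p2"]
        table, d = make_table(samples, groups, D)
        res = amova(table, d)
        assert abs(res.percent_among) < 25  # exchangeable split, small sample

    def test_matches_bruteforce_decomposition(self, rng):
        for _ in range(5):
            k = int(rng.integers(2, 5))
            haps = [f"h{i}" for i in range(k)]
            base = rng.uniform(0.5, 8, (k, k))
            base = (base + base.T) / 2
            np.fill_diagonal(base, 0)
            D = {a: {b: base[i, j] for j, b in enumerate(haps)}
                 for i, a in enumerate(haps)}
            n = int(rng.integers(6, 13))
            samples = list(rng.choice(haps, n))
            groups = list(rng.choice(["p1", "p2", "p3"], n))
            # ensure >= 2 non-empty strata and within-df > 0
            groups[0], groups[1], groups[2] = "p1", "p2", "p3"
            table, d = make_table(samples, groups, D)
            res = amova(table, d)
            ssd_a, ssd_w, s2a, s2w, phi = brute_amova(samples, groups, D)
            assert res.ssd_among == pytest.approx(ssd_a, abs=1e-9)
            assert res.ssd_within == pytest.approx(ssd_w, abs=1e-9)
            assert res.sigma2_among == pytest.approx(s2a, abs=1e-9)
            assert res.phi_st == pytest.approx(phi, abs=1e-9)
            assert res.percent_among + res.percent_within == \
                pytest.approx(100.0)
            assert res.df_among + res.df_within == res.n - 1

    def test_single_stratum_rejected(self, two_pop_table):
        table, d = two_pop_table
        with pytest.raises(InputError):
            amova(table, d, grouping={"popA": "x", "popB": "x"})

    def test_cohort_grouping_pools_populations(self, two_pop_table):
        table, d = two_pop_table
        res = amova(table, d, grouping={"popA": "g1", "popB": "g2"})
        assert res.strata == ["g1", "g2"]
        assert res.n == 8


class TestNetDistance:
    def test_identical_composition_is_zero(self):
        D = {"a": {"a": 0, "b": 6}, "b": {"a": 6, "b": 0}}
        samples = ["a", "b", "a", "b"]
        groups = ["p1", "p1", "p2", "p2"]
        table, d = make_table(samples, groups, D)
        net = net_population_distance(table, d)
        assert net[("p1", "p2")] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_pops_give_raw_distance(self):
        D = {"a": {"a": 0, "b": 4}, "b": {"a": 4, "b": 0}}
        samples = ["a", "a", "b", "b"]
        groups = ["p1", "p1", "p2", "p2"]
        table, d = make_table(samples, groups, D)
        net = net_population_distance(table, d)
        assert net[("p1", "p2")] == pytest.approx(4.0)

    def test_negative_values_retained(self, rng):
        # a deliberately diverse pop vs a subset pop can go slightly negative
        D = {"a": {"a": 0, "b": 10}, "b": {"a": 10, "b": 0}}
        samples = ["a", "b", "a", "a"]
        groups = ["p1", "p1", "p2", "p2"]
        table, d = make_table(samples, groups, D)
        net = net_population_distance(table, d)
        # within p1 = 10*(2*2)/(3*2)... just assert symmetry and finiteness
        assert net.values[0, 1] == net.values[1, 0]
        assert np.isfinite(net.values).all()
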