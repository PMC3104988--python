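import itertools
import math

import numpy as np
import pytest

from clonepop.clonal import (
    AlleleFrequencyTable,
    clonal_stats,
    expected_g_analytic,
    gd_ratio,
    genotypic_richness,
    loci_needed,
    p_gen,
    p_sex,
    partition_mlmg,
    pid_locus,
    plain_freqs,
    round_robin_freqs,
)
from clonepop.simulate import PopulationSpec, simulate_obligate

from conftest import make_dataset, random_dataset


# -- independent oracles ------------------------------------------------


def pid_bruteforce(p):
    """Enumerate genotype probabilities for unrelated and sibling pairs."""
    k = len(p)
    genotypes = [(i, j) for i in range(k) for j in range(i, k)]
    hw = {g: (p[g[0]] ** 2 if g[0] == g[1] else 2 * p[g[0]] * p[g[1]])
          for g in genotypes}
    pid = sum(q ** 2 for q in hw.values())
    # siblings: enumerate ordered parent genotype pairs, then the
    # Mendelian offspring distribution shared by both sibs
    pid_sib = 0.0
    for g1 in genotypes:
        for g2 in genotypes:
            off = {}
            for a in g1:
                for b in g2:
                    key = tuple(sorted((a, b)))
                    off[key] = off.get(key, 0.0) + 0.25
            pid_sib += hw[g1] * hw[g2] * sum(q ** 2 for q in off.values())
    return pid, pid_sib


def binom_tail_oracle(n, N, p):
    return math.fsum(math.comb(N, i) * p ** i * (1 - p) ** (N - i)
                     for i in range(n, N + 1))


# -- partition / richness ----------------------------------------------


class TestPartition:
    def test_all_identical(self):
        ds = make_dataset([[("001", "002")]] * 5)
        part = partition_mlmg(ds)
        assert part.G == 1
        assert part.copy_numbers() == {next(iter(part.members)): 5}

    def test_all_distinct(self):
        rows = [[(f"{k:03d}", f"{k:03d}")] for k in range(1, 6)]
        part = partition_mlmg(make_dataset(rows))
        assert part.G == 5
        assert genotypic_richness(part) == 1.0

    def test_simulated_copy_numbers(self):
        spec = PopulationSpec(mode="obligate", n=30, clone_count=5,
                              mutation_rate=0.0, seed=7)
        ds, truth = simulate_obligate(spec)
        part = partition_mlmg(ds)
        expected = np.bincount(truth["assignment"], minlength=5)
        # founders may coincide by chance; count distinct founder genotypes
        distinct = {tuple(tuple(c) for c in f) for f in truth["founders"]}
        assert part.G == len(distinct)
        if len(distinct) == 5:
            assert sorted(part.copy_numbers().values()) == sorted(expected)

    def test_missing_rejected(self):
        ds = make_dataset([[None]])
        with pytest.raises(ValueError, match="complete"):
            partition_mlmg(ds)

    def test_deterministic_ids(self):
        rows = [[("002", "002")], [("001", "001")], [("002", "002")]]
        part = partition_mlmg(make_dataset(rows))
        # lexicographically first genotype gets the first id
        first = sorted(part.members)[0]
        assert part.members[first] == ["i002"]


class TestRichness:
    def test_monoclonal_zero(self):
        part = partition_mlmg(make_dataset([[("001", "001")]] * 10))
        assert genotypic_richness(part) == 0.0

    def test_arithmetic(self):
        rows = ([[("001", "001")]] * 15
                + [[(f"{k:03d}", f"{k:03d}")] for k in range(2, 16)])
        part = partition_mlmg(make_dataset(rows))
        assert part.G == 15 and part.N == 29
        assert genotypic_richness(part) == pytest.approx(0.5)

    def test_single_individual_na(self):
        part = partition_mlmg(make_dataset([[("001", "001")]]))
        assert genotypic_richness(part) is None


# -- P_ID ---------------------------------------------------------------


class TestPid:
    def test_monomorphic(self):
        assert pid_locus({"A": 1.0}) == (1.0, 1.0)

    def test_two_equifrequent(self):
        pid, sib = pid_locus({"A": 0.5, "B": 0.5})
        assert pid == pytest.approx(0.375, abs=1e-15)
        assert sib == pytest.approx(0.59375, abs=1e-15)

    def test_four_equifrequent_vs_bruteforce(self):
        p = [0.25] * 4
        pid, sib = pid_locus({f"A{i}": 0.25 for i in range(4)})
        opid, osib = pid_bruteforce(p)
        assert pid == pytest.approx(opid, abs=1e-12)
        assert sib == pytest.approx(osib, abs=1e-12)

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            pid_locus({"A": 0.5, "B": 0.4})

    def test_sib_dominates(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(k))
            pid, sib = pid_locus({f"a{i}": float(x) for i, x in enumerate(p)})
            assert 0 < pid <= sib <= 1


class TestLociNeeded:
    def test_single_locus_enough(self):
        ds = make_dataset([[("001", "002")], [("001", "001")]])
        res = loci_needed(ds, threshold=0.7)
        assert res.m == 1

    def test_closed_form_seven_loci(self):
        from clonepop.clonal import loci_needed_from_sibs
        res = loci_needed_from_sibs({f"L{j}": 0.5 for j in range(8)},
                                    threshold=0.01)
        assert res.m == 7  # 0.5^7 ~ 0.0078 < 0.01

    def test_eight_trisomic_loci_need_six(self):
        # 3 equifrequent alleles per locus: P_ID_sib = 0.46296...;
        # the product first undercuts 0.01 at rank 6
        genos = [("001", "001"), ("002", "002"), ("003", "003"),
                 ("001", "002"), ("001", "003"), ("002", "003")]
        rows = [[g] * 8 for g in genos]  # each allele has 4 of 12 copies
        res = loci_needed(make_dataset(rows), threshold=0.01)
        assert res.m == 6

    def test_insufficient_flag(self):
        # two near-monomorphic loci cannot reach 0.0001
        rows = [[("001", "001"), ("001", "001")],
                [("001", "002"), ("001", "002")]]
        res = loci_needed(make_dataset(rows), threshold=1e-6)
        assert res.insufficient
        assert res.m is None

    def test_cumulative_curve_monotone(self, rng):
        ds = random_dataset(rng, n_ind=30, n_loci=6, n_alleles=8)
        res = loci_needed(ds)
        assert all(a >= b for a, b in zip(res.cumulative, res.cumulative[1:]))


# -- round-robin frequencies -------------------------------------------


class TestRoundRobin:
    def test_all_distinct_equals_plain(self, rng):
        # individuals distinct on every 7-locus subset: round robin keeps
        # every individual once, so frequencies match plain estimation
        ds = random_dataset(rng, n_ind=25, n_loci=8, n_alleles=12)
        rr = round_robin_freqs(ds)
        pl = plain_freqs(ds)
        for locus in ds.loci:
            sub = ds.subset(ds.individuals)
            # only compare when all individuals really are distinct MLMGs
            # on the complementary loci
            others = [j for j, l in enumerate(ds.loci) if l != locus]
            keys = {tuple(row[j] for j in others) for row in ds.calls}
            if len(keys) == ds.n_individuals:
                assert rr.freqs[locus] == pytest.approx(pl.freqs[locus])

    def test_clone_counted_once(self):
        # 3-locus toy: one clone x4 plus two singletons
        clone = [("001", "001"), ("002", "002"), ("003", "003")]
        s1 = [("001", "002"), ("002", "003"), ("003", "004")]
        s2 = [("002", "002"), ("003", "003"), ("004", "004")]
        ds = make_dataset([clone] * 4 + [s1, s2])
        rr = round_robin_freqs(ds)
        # at L1 the clone's (002,003)/(003,004) complement key appears once;
        # representatives: clone, s1, s2 -> alleles 001,001, 001,002, 002,002
        assert rr.freqs["L1"] == pytest.approx({"001": 0.5, "002": 0.5})

    def test_frequencies_sum_to_one(self, rng):
        ds = random_dataset(rng, n_ind=20, n_loci=4, n_alleles=6)
        rr = round_robin_freqs(ds)
        for locus, table in rr.freqs.items():
            assert sum(table.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_clone_duplication(self, rng):
        ds = random_dataset(rng, n_ind=10, n_loci=3, n_alleles=5)
        rr1 = round_robin_freqs(ds)
        dup = make_dataset(ds.calls + [ds.calls[0]] * 5, loci=ds.loci)
        rr2 = round_robin_freqs(dup)
        for locus in ds.loci:
            assert rr1.freqs[locus] == pytest.approx(rr2.freqs[locus])


# -- P_gen / P_sex ------------------------------------------------------


class TestPGen:
    def _freqs(self):
        return AlleleFrequencyTable(freqs={"L1": {"A": 0.5, "B": 0.5}})

    def test_het_hw(self):
        assert p_gen([("A", "B")], ["L1"], self._freqs()) == pytest.approx(0.5)

    def test_het_full_inbreeding(self):
        assert p_gen([("A", "B")], ["L1"], self._freqs(), fis=1.0) == 0.0

    def test_double_het_product(self):
        freqs = AlleleFrequencyTable(freqs={"L1": {"A": 0.5, "B": 0.5},
                                            "L2": {"A": 0.5, "B": 0.5}})
        got = p_gen([("A", "B"), ("A", "B")], ["L1", "L2"], freqs)
        assert got == pytest.approx(0.25)

    def test_absent_allele_raises(self):
        with pytest.raises(KeyError, match="basis mismatch"):
            p_gen([("A", "C")], ["L1"], self._freqs())

    def test_homozygote_with_fis(self):
        got = p_gen([("A", "A")], ["L1"], self._freqs(), fis=0.2)
        assert got == pytest.approx(0.25 + 0.25 * 0.2)


class TestPSex:
    def test_small_enumeration(self):
        assert p_sex(2, 2, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_zero_probability(self):
        assert p_sex(2, 10, 0.0) == 0.0

    def test_certain(self):
        assert p_sex(5, 5, 1.0) == pytest.approx(1.0)

    def test_not_applicable(self):
        assert p_sex(1, 10, 0.3) is None

    def test_oracle_grid(self):
        for N in (2, 5, 17, 33, 60):
            for n in range(2, N + 1, max(1, N // 7)):
                for p in (0.001, 0.05, 0.3, 0.77):
                    assert p_sex(n, N, p) == pytest.approx(
                        binom_tail_oracle(n, N, p), abs=1e-12)

    def test_monotonicity(self):
        values = [p_sex(n, 20, 0.3) for n in range(2, 21)]
        assert all(a >= b for a, b in zip(values, values[1:]))


# -- GD ratio -----------------------------------------------------------


def expected_g_oracle(freq_tables, n):
    """Brute-force E[G]: iterate the full multilocus genotype space."""
    spaces = []
    for table in freq_tables:
        alleles = sorted(table)
        genos = []
        for i, a in enumerate(alleles):
            for b in alleles[i:]:
                pr = table[a] ** 2 if a == b else 2 * table[a] * table[b]
                genos.append(pr)
        spaces.append(genos)
    total = 0.0
    for combo in itertools.product(*spaces):
        pg = math.prod(combo)
        total += 1.0 - (1.0 - pg) ** n
    return total


class TestGdRatio:
    def test_monoclonal_one_locus(self):
        ds = make_dataset([[("001", "002")]] * 30)
        part = partition_mlmg(ds)
        res = gd_ratio(ds, part, n_replicates=2000, seed=1, method="mc")
        oracle = expected_g_oracle([{"001": 0.5, "002": 0.5}], 30)
        assert oracle == pytest.approx(2.9997, abs=1e-3)
        assert res.ratio == pytest.approx(1 / oracle, rel=0.05)

    def test_mc_within_3se_of_oracle(self):
        # N small enough that the replicate G count actually varies
        ds = make_dataset([[("001", "002")]] * 8)
        part = partition_mlmg(ds)
        res = gd_ratio(ds, part, n_replicates=2000, seed=6, method="mc")
        oracle = expected_g_oracle([{"001": 0.5, "002": 0.5}], 8)
        assert res.se_e_g > 0
        assert abs(res.e_g - oracle) < 3 * res.se_e_g

    def test_analytic_route_matches_oracle(self, rng):
        ds = random_dataset(rng, n_ind=25, n_loci=2, n_alleles=3)
        part = partition_mlmg(ds)
        res = gd_ratio(ds, part, n_replicates=500, seed=2, method="analytic")
        tables = [plain_freqs(ds).freqs[l] for l in ds.loci]
        assert res.e_g == pytest.approx(expected_g_oracle(tables, 25),
                                        abs=1e-9)

    def test_all_distinct_ratio_near_one(self, rng):
        ds = random_dataset(rng, n_ind=20, n_loci=8, n_alleles=15)
        part = partition_mlmg(ds)
        assert part.G == 20
        res = gd_ratio(ds, part, n_replicates=500, seed=3, method="mc")
        assert res.ratio == pytest.approx(1.0, abs=0.05)

    def test_obligate_below_and_cyclic_above_rule_threshold(self):
        from clonepop.simulate import simulate_cyclic
        ob, _ = simulate_obligate(PopulationSpec(mode="obligate", n=30,
                                                 clone_count=5, seed=11))
        part = partition_mlmg(ob)
        res = gd_ratio(ob, part, n_replicates=300, seed=4, method="mc")
        assert res.ratio < 0.75
        cy, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=30, seed=12))
        part = partition_mlmg(cy)
        res = gd_ratio(cy, part, n_replicates=300, seed=5, method="mc")
        assert res.ratio > 0.75

    def test_replicate_floor(self):
        ds = make_dataset([[("001", "002")]] * 5)
        with pytest.raises(ValueError):
            gd_ratio(ds, partition_mlmg(ds), n_replicates=50)


class TestClonalStats:
    def test_table_layout(self):
        spec = PopulationSpec(mode="obligate", n=20, clone_count=3, seed=5)
        ds, _ = simulate_obligate(spec)
        st = clonal_stats(ds, fis=-0.5, n_replicates=200, seed=1)
        assert st.N == 20
        assert st.G >= 1
        for _mlmg, n, ps, psf in st.repeated_mlmgs:
            assert n >= 2
            assert 0 <= ps <= 1
            assert 0 <= psf <= 1
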