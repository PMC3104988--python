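import itertools
import math

import numpy as np
import pytest

from clonepop.hwe_ld import (
    combine_pvalues_fisher,
    fis_permutation_test,
    fis_wc,
    global_hwe_score_test,
    het_stats,
    hwe_score_test,
    multilocus_hwe,
    rbar_d,
)
from clonepop.simulate import PopulationSpec, simulate_cyclic, simulate_obligate

from conftest import make_dataset, random_dataset


# -- independent oracle: complete enumeration of genotype tables --------


def levene_tables(allele_counts):
    """All genotype tables with the given allele copy counts, with their
    exact conditional probabilities (independent itertools construction)."""
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    n = sum(allele_counts) // 2
    ranges = []
    for i, j in cells:
        cap = allele_counts[i] // 2 if i == j else min(allele_counts[i],
                                                       allele_counts[j])
        ranges.append(range(cap + 1))
    tables = []
    for combo in itertools.product(*ranges):
        used = [0] * k
        for (i, j), g in zip(cells, combo):
            used[i] += 2 * g if i == j else g
            if i != j:
                used[j] += g
        if used != list(allele_counts):
            continue
        h = sum(g for (i, j), g in zip(cells, combo) if i != j)
        logw = h * math.log(2) - sum(math.lgamma(g + 1) for g in combo)
        tables.append((dict(zip(cells, combo)), h, logw))
    total = math.fsum(math.exp(w) for _, _, w in tables)
    return [(t, h, math.exp(w) / total) for t, h, w in tables]


def exact_tail_p(allele_counts, h_obs, tail, ties="inclusive"):
    p = 0.0
    for _t, h, prob in levene_tables(allele_counts):
        if tail == "excess":
            if h > h_obs:
                p += prob
            elif h == h_obs:
                p += prob * (1.0 if ties == "inclusive" else 0.5)
        else:
            if h < h_obs:
                p += prob
            elif h == h_obs:
                p += prob * (1.0 if ties == "inclusive" else 0.5)
    return p


def random_genotype_table(rng, n=10, k=3):
    counts = {}
    labels = [chr(ord("A") + i) for i in range(k)]
    for _ in range(n):
        g = tuple(sorted(rng.choice(labels, 2)))
        counts[g] = counts.get(g, 0) + 1
    return counts


def table_allele_counts(genotype_counts):
    ac = {}
    for (a, b), c in genotype_counts.items():
        ac[a] = ac.get(a, 0) + c
        ac[b] = ac.get(b, 0) + c
    return [ac[k] for k in sorted(ac)]


def table_h(genotype_counts):
    return sum(c for (a, b), c in genotype_counts.items() if a != b)


# -- heterozygosity -----------------------------------------------------


class TestHetStats:
    def test_all_het_unbiased_he(self):
        ds = make_dataset([[("A", "B")]] * 10)
        hs = het_stats(ds)
        ho, he, n = hs.per_locus["L1"]
        assert ho == 1.0
        assert he == pytest.approx((20 / 19) * 0.5)
        assert n == 10

    def test_monomorphic(self):
        ds = make_dataset([[("A", "A")]] * 5)
        ho, he, _ = het_stats(ds).per_locus["L1"]
        assert ho == 0.0
        assert he == pytest.approx(0.0)

    def test_hwe_simulation_ho_matches_he(self):
        ds, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=500,
                                               n_loci=4, seed=42))
        hs = het_stats(ds)
        assert abs(hs.ho_overall - hs.he_overall) < 0.05
        assert abs(fis_wc(ds).multilocus) < 0.06


class TestFisWc:
    def test_fixed_heterozygotes(self):
        ds = make_dataset([[("A", "B")]] * 12)
        assert fis_wc(ds).multilocus == pytest.approx(-1.0)

    def test_hw_exact_proportions_large_n(self):
        # counts exactly at HW proportions: 2500 AA, 5000 AB, 2500 BB
        rows = ([[("A", "A")]] * 2500 + [[("A", "B")]] * 5000
                + [[("B", "B")]] * 2500)
        ds = make_dataset(rows)
        assert fis_wc(ds).multilocus == pytest.approx(0.0, abs=1e-3)

    def test_monomorphic_locus_skipped(self):
        ds = make_dataset([[("A", "A"), ("A", "B")]] * 4)
        res = fis_wc(ds)
        assert res.per_locus["L1"] is None
        assert res.skipped_monomorphic == ["L1"]

    def test_selfing_parameter_recovery(self):
        ests = []
        for s in range(30):
            ds, _ = simulate_cyclic(PopulationSpec(
                mode="cyclic", n=200, n_loci=8, inbreeding_f=0.2,
                seed=1000 + s))
            ests.append(fis_wc(ds).multilocus)
        assert np.mean(ests) == pytest.approx(0.2, abs=0.05)


class TestFisPermutation:
    def test_fixed_het_minimal_p(self):
        ds = make_dataset([[("A", "B"), ("C", "D")]] * 15)
        res = fis_permutation_test(ds, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_type_i_calibration(self):
        rej = 0
        reps = 120
        for s in range(reps):
            ds, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=30,
                                                   n_loci=4, seed=2000 + s))
            res = fis_permutation_test(ds, n_perm=199, seed=s)
            rej += res.p_value < 0.05
        assert 0.01 <= rej / reps <= 0.10

    def test_monomorphic_na(self):
        ds = make_dataset([[("A", "A")]] * 5)
        res = fis_permutation_test(ds, n_perm=199, seed=0)
        assert res.p_value is None

    def test_seed_reproducible(self):
        ds, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=20,
                                               n_loci=3, seed=9))
        a = fis_permutation_test(ds, n_perm=199, seed=7)
        b = fis_permutation_test(ds, n_perm=199, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic


# -- exact HWE score test ----------------------------------------------


SMALL_CHAIN = {"dememorization": 2000, "batches": 100, "iters_per_batch": 2000}


class TestHweScoreTest:
    def test_all_het_excess_enumeration(self):
        res = hwe_score_test({("A", "B"): 5}, "excess", method="enumerate")
        assert res.p_value == pytest.approx(0.126984126984127, abs=1e-12)
        assert res.statistic == pytest.approx(-1.0)

    def test_all_het_deficiency_is_one(self):
        res = hwe_score_test({("A", "B"): 5}, "deficiency",
                             method="enumerate")
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_na(self):
        res = hwe_score_test({("A", "A"): 7}, "excess")
        assert res.p_value is None

    def test_enumeration_matches_independent_oracle(self, rng):
        for _case in range(15):
            gc = random_genotype_table(rng, n=8, k=3)
            if len({a for g in gc for a in g}) < 2:
                continue
            for tail in ("excess", "deficiency"):
                for ties in ("inclusive", "midp"):
                    res = hwe_score_test(gc, tail, method="enumerate",
                                         ties=ties)
                    oracle = exact_tail_p(table_allele_counts(gc),
                                          table_h(gc), tail, ties)
                    assert res.p_value == pytest.approx(oracle, abs=1e-10)

    def test_chain_within_3se_of_enumeration(self, rng):
        for case in range(5):
            gc = random_genotype_table(rng, n=10, k=3)
            if len({a for g in gc for a in g}) < 2:
                continue
            res = hwe_score_test(gc, "excess", method="chain",
                                 chain=SMALL_CHAIN, seed=case)
            oracle = exact_tail_p(table_allele_counts(gc), table_h(gc),
                                  "excess")
            assert abs(res.p_value - oracle) <= 3 * res.se + 1e-9

    def test_sampling_within_3se(self, rng):
        gc = random_genotype_table(rng, n=10, k=3)
        res = hwe_score_test(gc, "deficiency", method="sampling",
                             n_samples=20000, seed=3)
        oracle = exact_tail_p(table_allele_counts(gc), table_h(gc),
                              "deficiency")
        assert abs(res.p_value - oracle) <= 3 * res.se + 1e-9

    def test_chain_reproducible(self):
        gc = {("A", "B"): 4, ("A", "A"): 3, ("B", "B"): 3}
        a = hwe_score_test(gc, "excess", method="chain", chain=SMALL_CHAIN,
                           seed=11)
        b = hwe_score_test(gc, "excess", method="chain", chain=SMALL_CHAIN,
                           seed=11)
        assert a.p_value == b.p_value and a.se == b.se

    def test_chain_minimum_parameters(self):
        with pytest.raises(ValueError, match="minimum"):
            hwe_score_test({("A", "B"): 5}, "excess", method="chain",
                           chain={"dememorization": 10, "batches": 5,
                                  "iters_per_batch": 10})


class TestMultilocusHwe:
    def test_fisher_reference_values(self):
        from scipy.stats import chi2
        stat = -2 * 8 * math.log(0.5)
        assert combine_pvalues_fisher([0.5] * 8) == pytest.approx(
            chi2.sf(stat, 16), abs=1e-12)
        stat = -2 * math.log(1e-6)
        assert combine_pvalues_fisher([1e-6] + [1.0] * 7) == pytest.approx(
            chi2.sf(stat, 16), abs=1e-12)

    def test_tiny_p_dominates_moderate_ones(self):
        assert (combine_pvalues_fisher([1e-6] + [0.5] * 7)
                < combine_pvalues_fisher([0.05] + [0.5] * 7))

    def test_zero_p_propagates(self):
        assert combine_pvalues_fisher([0.0, 0.5]) == 0.0

    def test_no_testable_loci(self):
        ds = make_dataset([[("A", "A")]] * 6)
        res = multilocus_hwe(ds, method="enumerate")
        assert math.isnan(res.combined["excess"])

    def test_obligate_population_excess_significant(self):
        ds, _ = simulate_obligate(PopulationSpec(mode="obligate", n=30,
                                                 clone_count=2, seed=3))
        res = multilocus_hwe(ds, method="sampling", n_samples=2000, seed=1)
        assert res.combined["excess"] < 0.001


class TestGlobalHweScoreTest:
    def test_fixed_het_clones(self):
        ds = make_dataset([[("A", "B"), ("C", "D")]] * 20)
        exc = global_hwe_score_test(ds, "excess", n_samples=2000, seed=1)
        dfc = global_hwe_score_test(ds, "deficiency", n_samples=2000, seed=1)
        assert exc.p_value < 0.01
        assert dfc.p_value > 0.99
        assert exc.statistic == pytest.approx(-1.0)

    def test_no_polymorphic_locus_na(self):
        ds = make_dataset([[("A", "A")]] * 8)
        res = global_hwe_score_test(ds, "excess", n_samples=500, seed=0)
        assert res.p_value is None

    def test_reproducible(self):
        ds, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=25,
                                               n_loci=4, seed=31))
        a = global_hwe_score_test(ds, "excess", n_samples=1000, seed=5)
        b = global_hwe_score_test(ds, "excess", n_samples=1000, seed=5)
        assert a.p_value == b.p_value

    def test_tails_complementary(self):
        ds, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=25,
                                               n_loci=4, seed=32))
        exc = global_hwe_score_test(ds, "excess", n_samples=4000, seed=6)
        dfc = global_hwe_score_test(ds, "deficiency", n_samples=4000, seed=6)
        # mid-p tails on the same null sum to 1 exactly per sample set
        assert exc.p_value + dfc.p_value == pytest.approx(1.0, abs=1e-9)


# -- r_d ----------------------------------------------------------------


class TestRbarD:
    def test_duplicated_locus_equals_one(self, rng):
        ds = random_dataset(rng, n_ind=15, n_loci=1, n_alleles=4)
        dup = make_dataset([[row[0], row[0]] for row in ds.calls])
        res = rbar_d(dup, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        ds = random_dataset(rng, n_ind=12, n_loci=4, n_alleles=4)
        res1 = rbar_d(ds, n_perm=99, seed=5)
        relabeled = make_dataset(
            [[tuple(sorted(("z" + a, "z" + b))) for a, b in row]
             for row in ds.calls],
            loci=[f"X{j}" for j in range(4)])
        res2 = rbar_d(relabeled, n_perm=99, seed=5)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_type_i_calibration(self):
        rej = 0
        reps = 120
        for s in range(reps):
            ds, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=30,
                                                   n_loci=8, seed=3000 + s))
            res = rbar_d(ds, n_perm=199, seed=s)
            if res.p_value is not None and res.p_value < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.10

    def test_clonal_population_loses_significance_after_correction(self):
        # one big clone + sexual noise: raw r_d significant, corrected not
        hits_raw = 0
        hits_cc = 0
        reps = 20
        for s in range(reps):
            cy, _ = simulate_cyclic(PopulationSpec(mode="cyclic", n=10,
                                                   n_loci=6, seed=4000 + s))
            clone_row = cy.calls[0]
            rows = [list(r) for r in cy.calls] + [list(clone_row)] * 30
            ds = make_dataset(rows, loci=cy.loci)
            raw = rbar_d(ds, n_perm=199, seed=s)
            cc = rbar_d(ds, n_perm=199, seed=s, clone_correct=True)
            hits_raw += raw.p_value is not None and raw.p_value < 0.05
            hits_cc += cc.p_value is not None and cc.p_value < 0.05
        assert hits_raw >= reps * 0.8
        assert hits_cc <= reps * 0.3

    def test_too_few_loci_na(self):
        ds = make_dataset([[("A", "B")], [("A", "A")], [("B", "B")]])
        res = rbar_d(ds, n_perm=99, seed=0)
        assert res.p_value is None

    def test_seeded_reproducibility(self, rng):
        ds = random_dataset(rng, n_ind=12, n_loci=4, n_alleles=5)
        a = rbar_d(ds, n_perm=199, seed=21)
        b = rbar_d(ds, n_perm=199, seed=21)
        assert a.p_value == b.p_value
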