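"""HWE exact tests (enumeration + Markov chain) and the LD permutation G-test."""

import math

import numpy as np
import pytest

from isopop.datasets import GenotypeDataset, Individual
from isopop.equilibrium import (_enumerate_tables,
                                _log_table_prob_const, _log_table_prob_var,
                                bonferroni_alpha, genotype_counts,
                                hwe_exact_enumeration, hwe_mcmc, hwe_test,
                                ld_gtest_mc)
from isopop.synth import SynthSpec, gen_allele_freqs, gen_genotypes


def _random_counts(rng, n=12, kmax=4):
    k = int(rng.integers(2, kmax + 1))
    g = {}
    draws = rng.integers(1, k + 1, size=(n, 2))
    for a, b in draws:
        key = (min(a, b), max(a, b))
        g[key] = g.get(key, 0) + 1
    return g


def test_enumeration_two_by_two():
    # allele counts 2A,2B admit two tables: {AB:2} w.p. 2/3, {AA,BB} w.p. 1/3
    r = hwe_exact_enumeration({(1, 1): 1, (2, 2): 1})
    assert r.p_value == pytest.approx(1 / 3, abs=1e-12)
    r2 = hwe_exact_enumeration({(1, 2): 2})
    assert r2.p_value == pytest.approx(1.0, abs=1e-12)


def test_enumeration_monomorphic():
    r = hwe_exact_enumeration({(1, 1): 10})
    assert r.p_value == 1.0 and r.monomorphic


def test_enumeration_probabilities_sum_to_one(rng):
    for _ in range(10):
        g = _random_counts(rng)
        from isopop.equilibrium import _allele_counts
        ac = _allele_counts(g)
        n = sum(g.values())
        alleles = sorted(ac)
        tables = _enumerate_tables(alleles, [ac[a] for a in alleles], 10 ** 6)
        const = _log_table_prob_const(ac, n)
        total = sum(math.exp(const + _log_table_prob_var(t)) for t in tables)
        assert total == pytest.approx(1.0, abs=1e-10)


def test_mcmc_matches_enumeration(rng):
    for trial in range(5):
        g = _random_counts(rng)
        e = hwe_exact_enumeration(g)
        m = hwe_mcmc(g, dememorizations=1000, batches=40,
                     iterations_per_batch=500, seed=trial)
        if m.p_se == 0:  # degenerate: single achievable table
            assert m.p_value == pytest.approx(e.p_value, abs=1e-12)
        else:
            assert abs(m.p_value - e.p_value) <= 3.5 * m.p_se


def test_mcmc_reproducible_under_seed():
    g = {(1, 1): 4, (1, 2): 2, (2, 2): 4, (1, 3): 1, (3, 3): 1}
    a = hwe_mcmc(g, dememorizations=200, batches=10, iterations_per_batch=200,
                 seed=99)
    b = hwe_mcmc(g, dememorizations=200, batches=10, iterations_per_batch=200,
                 seed=99)
    assert a.p_value == b.p_value and a.p_se == b.p_se
    assert a.chain_params == dict(dememorizations=200, batches=10,
                                  iterations_per_batch=200)


def test_hwe_test_dispatch(rng):
    spec = SynthSpec(n_loci=1, alleles_min=3, alleles_max=3)
    freqs = gen_allele_freqs(spec, rng)
    ds = gen_genotypes(freqs, 30, 0.0, rng)
    r = hwe_test(ds, ds.loci[0], "P1")
    assert r.method == "enumeration"  # 3 alleles stays enumerable
    assert 0.0 <= r.p_value <= 1.0


def test_genotype_counts(two_period_dataset):
    gc = genotype_counts(two_period_dataset, "LocB", "1960-65")
    assert gc == {(200, 200): 1, (200, 202): 1}


def test_ld_detects_duplicated_locus(rng):
    spec = SynthSpec(n_loci=1, alleles_min=3, alleles_max=4)
    freqs = gen_allele_freqs(spec, rng)
    ds1 = gen_genotypes(freqs, 30, 0.0, rng)
    inds = [Individual(id=i.id, period="P1",
                       genotype=[i.genotype[0], i.genotype[0]])
            for i in ds1.individuals]
    ds = GenotypeDataset(loci=["A", "B"], individuals=inds)
    r = ld_gtest_mc(ds, "A", "B", "P1", permutations=999, seed=0)
    assert r.p_value <= 0.01
    assert r.g_stat > 0


def test_ld_monomorphic_not_testable():
    inds = [Individual(id=f"i{k}", period="P1",
                       genotype=[(101, 101), (200, 202 if k % 2 else 200)])
            for k in range(10)]
    ds = GenotypeDataset(loci=["A", "B"], individuals=inds)
    r = ld_gtest_mc(ds, "A", "B", "P1", permutations=99, seed=0)
    assert not r.testable and r.p_value == 1.0


def test_ld_g_invariant_to_relabeling(rng):
    spec = SynthSpec(n_loci=2)
    freqs = gen_allele_freqs(spec, rng)
    ds = gen_genotypes(freqs, 40, 0.0, rng)
    la, lb = ds.loci[:2]
    g1 = ld_gtest_mc(ds, la, lb, "P1", permutations=9, seed=1).g_stat
    # shift all allele labels at locus b by a constant
    jb = ds.locus_index(lb)
    inds = [Individual(id=i.id, period=i.period,
                       genotype=[g if j != jb else (g[0] + 50, g[1] + 50)
                                 for j, g in enumerate(i.genotype)])
            for i in ds.individuals]
    ds2 = GenotypeDataset(loci=ds.loci, individuals=inds)
    g2 = ld_gtest_mc(ds2, la, lb, "P1", permutations=9, seed=1).g_stat
    assert g1 == pytest.approx(g2, abs=1e-9)


def test_ld_type_one_error_calibrated(rng):
    # independent loci: rejection rate at alpha=0.05 should be near 0.05
    spec = SynthSpec(n_loci=2, alleles_min=2, alleles_max=4)
    rej = 0
    n_pairs = 200
    for i in range(n_pairs):
        freqs = gen_allele_freqs(spec, rng)
        ds = gen_genotypes(freqs, 40, 0.0, rng)
        r = ld_gtest_mc(ds, ds.loci[0], ds.loci[1], "P1", permutations=199,
                        seed=i)
        if r.testable and r.p_value <= 0.05:
            rej += 1
    assert 0.02 <= rej / n_pairs <= 0.09


def test_bonferroni():
    assert bonferroni_alpha(0.05, 36) == pytest.approx(0.0013889, abs=1e-6)
    assert bonferroni_alpha(0.05, 9) == pytest.approx(0.0055556, abs=1e-6)
    assert bonferroni_alpha(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


def test_hwe_p_uniform_under_null(rng):
    # KS sanity check of p-value uniformity on HWE-true data
    from scipy import stats
    ps = []
    p = np.array([0.5, 0.3, 0.2])
    for _ in range(300):
        draws = rng.choice(3, size=(40, 2), p=p) + 1
        g = {}
        for a, b in draws:
            key = (min(a, b), max(a, b))
            g[key] = g.get(key, 0) + 1
        ps.append(hwe_exact_enumeration(g).p_value)
    # discrete p-values are stochastically >= uniform; check the one-sided
    # departure is not anti-conservative at the 1% level
    d = stats.kstest(ps, "uniform", alternative="greater")
    assert d.pvalue > 0.01
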