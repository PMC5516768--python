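"""Forward simulator: census adherence, transmission oracle, drift behaviour."""

import numpy as np
import pytest

from isopop.datasets import CensusSeries
from isopop.simulate import (ExtinctionError, Population, SimConfig,
                             advance_year, init_population, run_replicates,
                             stylized_census, transmit_allele,
                             wf_expected_het)

TWO_ALLELE = {"L1": {10: 0.5, 11: 0.5}}


def _const_census(n, years=50, start=2000):
    return CensusSeries(np.arange(start, start + years + 1),
                        np.full(years + 1, n))


def test_init_population_size_and_ages():
    cfg = SimConfig(census=_const_census(564), initial_freqs=TWO_ALLELE, seed=0)
    pop = init_population(cfg, np.random.default_rng(0))
    assert len(pop) == 564
    assert pop.ages.min() >= 1 and pop.ages.max() <= 15
    assert set(np.unique(pop.sexes)) <= {0, 1}


def test_init_monomorphic_gives_zero_ho():
    cfg = SimConfig(census=_const_census(100),
                    initial_freqs={"L1": {10: 1.0}}, seed=0)
    pop = init_population(cfg, np.random.default_rng(0))
    assert np.all(pop.genotypes[:, :, 0] == pop.genotypes[:, :, 1])


def test_init_ho_matches_hardy_weinberg_expectation():
    # E[Ho] at p=(0.5,0.5) is 0.5; binomial SE over n*reps draws
    cfg = SimConfig(census=_const_census(500), initial_freqs=TWO_ALLELE, seed=0)
    rng = np.random.default_rng(1)
    hets = []
    for _ in range(30):
        pop = init_population(cfg, rng)
        hets.append(np.mean(pop.genotypes[:, 0, 0] != pop.genotypes[:, 0, 1]))
    n_tot = 500 * 30
    se = np.sqrt(0.5 * 0.5 / n_tot)
    assert abs(np.mean(hets) - 0.5) < 4 * se


class TestTransmitAllele:
    def test_no_mutation_homozygote(self):
        rng = np.random.default_rng(0)
        assert all(transmit_allele((7, 7), 0.0, rng) == 7 for _ in range(100))

    def test_mendelian_ratio(self):
        rng = np.random.default_rng(1)
        n = 10_000
        draws = [transmit_allele((7, 9), 0.0, rng) for _ in range(n)]
        frac7 = draws.count(7) / n
        se = np.sqrt(0.25 / n)
        assert abs(frac7 - 0.5) < 3 * se

    def test_forced_mutation_steps_by_one(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = transmit_allele((7, 7), 1.0 - 1e-12, rng)
            assert a in (6, 8)


def test_advance_year_census_adherence():
    cfg = SimConfig(census=stylized_census(), initial_freqs=TWO_ALLELE, seed=3)
    rng = np.random.default_rng(3)
    pop = init_population(cfg, rng)
    for year in cfg.census.years[1:]:
        pop, _, _ = advance_year(pop, cfg.census.count(year), cfg, rng,
                                 year=year)
        assert len(pop) == cfg.census.count(year)
        assert pop.ages.max() <= cfg.max_age


def test_advance_year_no_change_when_target_matches():
    cfg = SimConfig(census=_const_census(100), initial_freqs=TWO_ALLELE, seed=0)
    rng = np.random.default_rng(0)
    pop = Population(ages=np.full(50, 5), sexes=np.tile([0, 1], 25),
                     genotypes=np.full((50, 1, 2), 10))
    out, _, ndraw = advance_year(pop, 50, cfg, rng)
    assert len(out) == 50 and ndraw == 0  # no births needed


def test_all_age_fifteen_extinction():
    cfg = SimConfig(census=_const_census(50), initial_freqs=TWO_ALLELE, seed=0)
    rng = np.random.default_rng(0)
    pop = Population(ages=np.full(50, 15), sexes=np.tile([0, 1], 25),
                     genotypes=np.full((50, 1, 2), 10))
    with pytest.raises(ExtinctionError):
        advance_year(pop, 50, cfg, rng, year=2001)


def test_allele_conservation_without_mutation():
    freqs = {"L1": {10: 0.4, 11: 0.3, 12: 0.3}, "L2": {20: 0.9, 21: 0.1}}
    cfg = SimConfig(census=_const_census(80, years=60), initial_freqs=freqs,
                    mutation_rate=0.0, n_iterations=3, seed=11)
    res = run_replicates(cfg)
    for _, grp in res.trajectories.groupby("replicate"):
        na = grp.sort_values("year").Na.to_numpy()
        assert np.all(np.diff(na) <= 1e-12)


def test_run_replicates_deterministic():
    cfg = SimConfig(census=_const_census(60, years=20),
                    initial_freqs=TWO_ALLELE, n_iterations=5, seed=77)
    a = run_replicates(cfg)
    b = run_replicates(cfg)
    assert a.summary.equals(b.summary)
    assert a.trajectories.equals(b.trajectories)


def test_single_replicate_band_collapses():
    cfg = SimConfig(census=_const_census(60, years=10),
                    initial_freqs=TWO_ALLELE, n_iterations=1, seed=5)
    res = run_replicates(cfg)
    s = res.summary
    assert np.allclose(s.ho_lo, s.mean_Ho) and np.allclose(s.ho_hi, s.mean_Ho)


def test_constant_census_birth_death_balance():
    # stationary bookkeeping: yearly births ~ yearly deaths on average
    cfg = SimConfig(census=_const_census(160, years=50),
                    initial_freqs=TWO_ALLELE, n_iterations=1, seed=9)
    rng = np.random.default_rng(np.random.SeedSequence(9))
    pop = init_population(cfg, rng)
    births = deaths = 0
    for year in cfg.census.years[1:]:
        pre = len(pop)
        died = int(np.sum(pop.ages + 1 > cfg.max_age))
        pop, _, ndraw = advance_year(pop, cfg.census.count(year), cfg, rng,
                                     year=year)
        births += ndraw // 2
        deaths += died
    assert births == deaths  # exact under a constant census


def test_halving_census_loses_at_least_as_much_ho():
    freqs = {f"L{j}": {10: 0.5, 11: 0.5} for j in range(6)}
    big = SimConfig(census=_const_census(200, years=80), initial_freqs=freqs,
                    mutation_rate=0.0, n_iterations=40, seed=21)
    small = SimConfig(census=_const_census(100, years=80), initial_freqs=freqs,
                      mutation_rate=0.0, n_iterations=40, seed=21)
    ho_big = run_replicates(big).summary.mean_Ho.iloc[-1]
    ho_small = run_replicates(small).summary.mean_Ho.iloc[-1]
    assert ho_small <= ho_big


def test_wf_expected_het():
    assert wf_expected_het(0.5, 50, 20) == pytest.approx(
        0.5 * (1 - 1 / 100) ** 20, abs=1e-12)
    assert wf_expected_het(0.5, 50, 20) == pytest.approx(0.40894, abs=1e-4)
    assert wf_expected_het(0.37, 1000, 0) == 0.37
    assert wf_expected_het(0.37, np.inf, 500) == 0.37


def test_stylized_census_properties():
    c = stylized_census()
    assert c.years[0] == 1960 and c.years[-1] == 2005
    assert c.count(1960) == 564
    assert c.counts.min() >= 400 and c.counts.max() <= 2600
    # no decline run longer than the male breeding window
    diffs = np.diff(c.counts)
    run = longest = 0
    for d in diffs:
        run = run + 1 if d <= 0 else 0
        longest = max(longest, run)
    assert longest <= 6
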