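"""Exact tests for Hardy–Weinberg equilibrium and linkage disequilibrium.

The HWE probability test conditions on the observed allele counts: the
probability of a genotype table with heterozygote count h and genotype
counts {n_g} given allele counts {c_a} is

    P(table) = n! * prod_a c_a! * 2^h / ((2n)! * prod_g n_g!)

and the p-value sums P over all tables no more probable than the
observed one.  Small problems are solved by complete enumeration; larger
ones by a Markov chain over genotype tables with fixed allele margins
(random transposition of allele copies between individuals, whose
stationary distribution is exactly the conditional null), organised into
batches so a Monte-Carlo standard error can be reported.

LD between two loci is tested on the two-locus genotypic contingency
table with a log-likelihood-ratio G statistic and a permutation null.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .datasets import MISSING, GenotypeDataset

__all__ = [
    "HWEResult",
    "LDResult",
    "genotype_counts",
    "hwe_exact_enumeration",
    "hwe_mcmc",
    "hwe_test",
    "ld_gtest_mc",
    "bonferroni_alpha",
    "EnumerationBoundExceeded",
]

_REL_TOL = 1e-9  # tie tolerance when comparing table probabilities


class EnumerationBoundExceeded(ValueError):
    """The locus is too large for complete enumeration; use the MCMC test."""


@dataclass
class HWEResult:
    locus: Optional[str]
    period: Optional[str]
    p_value: float
    p_se: float
    method: str  # "enumeration" or "mcmc"
    chain_params: dict = field(default_factory=dict)
    seed: Optional[int] = None
    monomorphic: bool = False


@dataclass
class LDResult:
    locus_pair: tuple
    period: Optional[str]
    g_stat: float
    p_value: float
    permutations: int
    seed: Optional[int] = None
    testable: bool = True


def genotype_counts(ds: GenotypeDataset, locus: str,
                    period: Optional[str] = None) -> dict:
    """Map ``(a, b) -> count`` (a <= b) of non-missing genotypes at a locus."""
    j = ds.locus_index(locus)
    counts: Counter = Counter()
    for ind in ds.individuals:
        if period is not None and ind.period != period:
            continue
        g = ind.genotype[j]
        if g is not MISSING:
            counts[g] += 1
    return dict(counts)


def _allele_counts(gcounts: dict) -> dict:
    out: Counter = Counter()
    for (a, b), c in gcounts.items():
        out[a] += c
        out[b] += c
    return dict(out)


def _log_table_prob_const(allele_counts: dict, n: int) -> float:
    """Constant part of log P(table): log(n! prod c_a!) - log((2n)!)."""
    return (gammaln(n + 1)
            + sum(gammaln(c + 1) for c in allele_counts.values())
            - gammaln(2 * n + 1))


def _log_table_prob_var(table: dict) -> float:
    """Variable part: h*log2 - sum log n_g!."""
    h = sum(c for (a, b), c in table.items() if a != b)
    return h * math.log(2.0) - sum(gammaln(c + 1) for c in table.values())


def _enumerate_tables(alleles, counts, max_tables):
    """All genotype tables (dicts) consistent with the allele-count margin.

    Tables are built allele by allele: for allele i, heterozygote cells
    (i, j) with j > i are chosen freely within the remaining copy budgets,
    and the leftover copies of allele i (which must be even) are forced
    into the homozygote cell (i, i).
    """
    k = len(alleles)
    tables = []

    def fill_allele(i, remaining, table):
        if len(tables) > max_tables:
            raise EnumerationBoundExceeded(
                f"more than {max_tables} genotype tables; use hwe_mcmc"
            )
        if i == k:
            tables.append(dict(table))
            return

        def het(j, left, rem, tbl):
            if j == k:
                if left % 2 == 0:
                    if left:
                        tbl = dict(tbl)
                        tbl[(alleles[i], alleles[i])] = left // 2
                    fill_allele(i + 1, rem, tbl)
                return
            top = min(left, rem[j])
            for c in range(top + 1):
                t2 = dict(tbl)
                if c:
                    t2[(alleles[i], alleles[j])] = c
                r2 = list(rem)
                r2[j] -= c
                het(j + 1, left - c, r2, t2)

        het(i + 1, remaining[i], list(remaining), table)

    fill_allele(0, list(counts), {})
    return tables


def hwe_exact_enumeration(gcounts: dict, max_tables: int = 2_000_000,
                          locus: Optional[str] = None,
                          period: Optional[str] = None) -> HWEResult:
    """Complete-enumeration HWE probability test.

    ``gcounts`` maps genotype (a, b) with a <= b to its count.  Monomorphic
    input returns p = 1 flagged monomorphic.
    """
    gcounts = {tuple(sorted(k)): v for k, v in gcounts.items() if v > 0}
    ac = _allele_counts(gcounts)
    if len(ac) < 2:
        return HWEResult(locus, period, 1.0, 0.0, "enumeration", monomorphic=True)
    n = sum(gcounts.values())
    alleles = sorted(ac)
    counts = [ac[a] for a in alleles]

    tables = _enumerate_tables(alleles, counts, max_tables)
    const = _log_table_prob_const(ac, n)
    obs_lp = const + _log_table_prob_var(gcounts)
    total = 0.0
    p = 0.0
    for t in tables:
        lp = const + _log_table_prob_var(t)
        pr = math.exp(lp)
        total += pr
        if lp <= obs_lp + _REL_TOL:
            p += pr
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"enumeration probabilities sum to {total}, not 1")
    return HWEResult(locus, period, min(p, 1.0), 0.0, "enumeration")


def hwe_mcmc(gcounts: dict, dememorizations: int = 1000, batches: int = 100,
             iterations_per_batch: int = 1000, seed: Optional[int] = None,
             locus: Optional[str] = None, period: Optional[str] = None) -> HWEResult:
    """Markov-chain HWE probability test with batch standard errors.

    The chain state is the assignment of the 2n observed allele copies to
    n individuals; each step proposes swapping two uniformly chosen copies
    (always accepted — the uniform pairing distribution is exactly the
    conditional null given allele counts).  Each batch estimates the
    p-value as the fraction of visited tables no more probable than the
    observed table; the reported p averages the batches and p_se is the
    between-batch standard error.  Defaults follow common practice for
    this test (1,000 dememorisations, 100 batches of 1,000).
    """
    chain_params = dict(dememorizations=dememorizations, batches=batches,
                        iterations_per_batch=iterations_per_batch)
    gcounts = {tuple(sorted(k)): v for k, v in gcounts.items() if v > 0}
    ac = _allele_counts(gcounts)
    if len(ac) < 2:
        return HWEResult(locus, period, 1.0, 0.0, "mcmc", chain_params, seed,
                         monomorphic=True)
    rng = np.random.default_rng(seed)

    # allele-copy vector; positions (2t, 2t+1) form individual t
    alleles = sorted(ac)
    aidx = {a: i for i, a in enumerate(alleles)}
    copies = []
    for (a, b), c in sorted(gcounts.items()):
        for _ in range(c):
            copies.append(aidx[a])
            copies.append(aidx[b])
    v = np.array(copies, dtype=np.int64)
    m = len(v)
    n = m // 2
    k = len(alleles)

    table = np.zeros((k, k), dtype=np.int64)  # upper-triangular counts
    lg = gammaln(np.arange(n + 2) + 1.0)  # lg[c] = log(c!)
    log2 = math.log(2.0)

    def cell(i, j):
        return (i, j) if i <= j else (j, i)

    var_lp = 0.0
    for t in range(n):
        i, j = cell(v[2 * t], v[2 * t + 1])
        table[i, j] += 1
    for i in range(k):
        for j in range(i, k):
            var_lp -= lg[table[i, j]]
            if i != j:
                var_lp += table[i, j] * log2

    obs_lp = var_lp  # chain starts at the observed table
    tol = _REL_TOL

    def step(p1, p2):
        nonlocal var_lp
        t1, t2 = p1 // 2, p2 // 2
        if t1 == t2 or v[p1] == v[p2]:
            return
        g1_old = cell(v[2 * t1], v[2 * t1 + 1])
        g2_old = cell(v[2 * t2], v[2 * t2 + 1])
        v[p1], v[p2] = v[p2], v[p1]
        g1_new = cell(v[2 * t1], v[2 * t1 + 1])
        g2_new = cell(v[2 * t2], v[2 * t2 + 1])
        # update the four affected cells and the running log-probability
        for (i, j) in (g1_old, g2_old):
            c = table[i, j]
            var_lp += lg[c]
            if i != j:
                var_lp -= log2
            table[i, j] = c - 1
            var_lp -= lg[c - 1]
        for (i, j) in (g1_new, g2_new):
            c = table[i, j]
            var_lp += lg[c]
            table[i, j] = c + 1
            var_lp -= lg[c + 1]
            if i != j:
                var_lp += log2

    block = 65536
    total_steps = dememorizations + batches * iterations_per_batch
    pos = rng.integers(0, m, size=(min(block, total_steps), 2))
    bi = 0

    def next_pair():
        nonlocal pos, bi
        if bi >= len(pos):
            pos = rng.integers(0, m, size=(block, 2))
            bi = 0
        p = pos[bi]
        bi += 1
        return int(p[0]), int(p[1])

    for _ in range(dememorizations):
        step(*next_pair())

    batch_ps = np.empty(batches)
    for b in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            step(*next_pair())
            if var_lp <= obs_lp + tol:
                hits += 1
        batch_ps[b] = hits / iterations_per_batch
    p = float(batch_ps.mean())
    p_se = float(batch_ps.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return HWEResult(locus, period, p, p_se, "mcmc", chain_params, seed)


def hwe_test(ds: GenotypeDataset, locus: str, period: Optional[str] = None,
             method: str = "auto", seed: Optional[int] = None,
             **chain_kwargs) -> HWEResult:
    """Convenience wrapper choosing enumeration for small loci, MCMC otherwise."""
    gc = genotype_counts(ds, locus, period)
    ac = _allele_counts(gc)
    small = sum(ac.values()) <= 20 or len(ac) <= 3
    if method == "enumeration" or (method == "auto" and small):
        try:
            res = hwe_exact_enumeration(gc, locus=locus, period=period)
            return res
        except EnumerationBoundExceeded:
            if method == "enumeration":
                raise
    res = hwe_mcmc(gc, seed=seed, locus=locus, period=period, **chain_kwargs)
    return res


def _g_stat(codes_a, codes_b):
    """G statistic of the contingency table of two integer code vectors."""
    na = codes_a.max() + 1
    nb = codes_b.max() + 1
    obs = np.bincount(codes_a * nb + codes_b, minlength=na * nb).reshape(na, nb)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = row * col / n
        ratio = np.where(obs > 0, obs / exp, 1.0)
        g = 2.0 * float(np.sum(obs * np.log(ratio)))
    return max(g, 0.0)


def ld_gtest_mc(ds: GenotypeDataset, locus_a: str, locus_b: str,
                period: Optional[str] = None, permutations: int = 999,
                seed: Optional[int] = None) -> LDResult:
    """Genotypic linkage-disequilibrium G-test with a permutation null.

    Individuals missing either locus are excluded pairwise.  The null
    distribution is generated by permuting one locus's genotypes among
    individuals; p uses the add-one estimator ``(1 + #{G* >= G}) / (B + 1)``.
    A pair with a monomorphic member is flagged not testable with p = 1.
    """
    ja, jb = ds.locus_index(locus_a), ds.locus_index(locus_b)
    ga, gb = [], []
    for ind in ds.individuals:
        if period is not None and ind.period != period:
            continue
        a, b = ind.genotype[ja], ind.genotype[jb]
        if a is not MISSING and b is not MISSING:
            ga.append(a)
            gb.append(b)
    pair = (locus_a, locus_b)
    if len(set(ga)) < 2 or len(set(gb)) < 2:
        return LDResult(pair, period, 0.0, 1.0, permutations, seed, testable=False)

    def encode(gs):
        cats = {g: i for i, g in enumerate(sorted(set(gs)))}
        return np.array([cats[g] for g in gs], dtype=np.int64)

    ca, cb = encode(ga), encode(gb)
    g_obs = _g_stat(ca, cb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if _g_stat(ca, rng.permutation(cb)) >= g_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return LDResult(pair, period, g_obs, p, permutations, seed)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance level ``alpha / m`` for m simultaneous tests."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return alpha / m
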