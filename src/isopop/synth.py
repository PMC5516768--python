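"""Synthetic genotype, census and mtDNA generators with known truth.

These generators emulate the statistical structure of a temporal
microsatellite survey of an isolated population — 9 loci with a handful
of alleles each, ~50 diploid samples in each of 5 sampling periods —
with three planted, recoverable parameters:

* ``F``: the within-period inbreeding coefficient, planted with the
  identity-by-descent mixture (with probability F an individual's two
  allele copies at a locus are one draw duplicated, else two
  independent draws), so E[Ho] = (1 - F) * He exactly;
* ``drift_ne``: allele frequencies evolve between consecutive periods
  by binomial Wright–Fisher resampling of 2*Ne copies, so the variance
  of the per-step frequency change is p(1-p)/(2*Ne);
* mtDNA haplotype frequencies: equal-length control-region sequences
  with one diagnostic site per haplotype, multinomial counts.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datasets import (
    CensusSeries,
    GenotypeDataset,
    Individual,
    SequenceRecord,
    SequenceSet,
)

__all__ = [
    "SynthSpec",
    "gen_allele_freqs",
    "gen_genotypes",
    "gen_temporal_dataset",
    "gen_mtdna",
    "gen_divergent_freqs",
    "freqs_matching_diversity",
]


@dataclass
class SynthSpec:
    """Parameters of the synthetic study design (defaults mirror a
    9-locus, 5-period, ~50-samples-per-period microsatellite survey)."""

    n_loci: int = 9
    alleles_min: int = 2
    alleles_max: int = 7
    samples_per_period: int = 50
    periods: int = 5
    inbreeding: Sequence[float] = (0.0,)  # F per period (singleton broadcasts)
    drift_ne: float = np.inf
    generations_per_period: int = 1
    mtdna_freqs: Sequence[float] = (1.0,)
    mtdna_samples: int = 134
    mtdna_length: int = 330
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.inbreeding) != self.periods:
            if len(self.inbreeding) == 1:
                self.inbreeding = tuple(self.inbreeding) * self.periods
            else:
                raise ValueError("need one inbreeding F per period")
        for f in self.inbreeding:
            if not (0 <= f < 1):
                raise ValueError("F must be in [0, 1)")
        if not (self.drift_ne >= 1):
            raise ValueError("drift_ne must be >= 1 (or inf)")
        if abs(sum(self.mtdna_freqs) - 1.0) > 1e-9:
            raise ValueError("mtdna haplotype frequencies must sum to 1")

    @property
    def period_labels(self):
        return [f"P{i + 1}" for i in range(self.periods)]


def gen_allele_freqs(spec: SynthSpec, rng: np.random.Generator) -> dict:
    """Random per-locus allele frequencies.

    Allele count uniform in [alleles_min, alleles_max]; frequencies are
    a flat Dirichlet draw; labels are consecutive integers from ~100 so
    they look like fragment sizes.
    """
    freqs = {}
    for j in range(spec.n_loci):
        k = int(rng.integers(spec.alleles_min, spec.alleles_max + 1))
        p = rng.dirichlet(np.ones(k))
        base = 100 + 2 * j
        freqs[f"L{j + 1:02d}"] = {base + 2 * i: float(p[i]) for i in range(k)}
    return freqs


def gen_divergent_freqs(freqs: dict, fst: float, rng: np.random.Generator) -> dict:
    """Frequencies of a population at divergence ``fst`` from ``freqs``.

    Standard island-model draw: p' ~ Dirichlet(p * (1-fst)/fst), which has
    mean p and Var = p(1-p) * fst.
    """
    if not (0 < fst < 1):
        raise ValueError("fst must be in (0, 1)")
    c = (1 - fst) / fst
    out = {}
    for locus, table in freqs.items():
        alleles = sorted(table)
        p = np.array([table[a] for a in alleles])
        q = rng.dirichlet(np.maximum(p, 1e-12) * c)
        out[locus] = {a: float(q[i]) for i, a in enumerate(alleles)}
    return out


def gen_genotypes(freqs: dict, n: int, F: float, rng: np.random.Generator,
                  period: str = "P1", id_prefix: str = "") -> GenotypeDataset:
    """One period of diploid genotypes with planted inbreeding F.

    Identity-by-descent mixture: at each locus, with probability F one
    allele is drawn and duplicated, otherwise both copies are drawn
    independently; hence E[Ho] = (1-F) * (1 - sum p^2) per locus.
    """
    if not (0 <= F < 1):
        raise ValueError("F must be in [0, 1)")
    loci = list(freqs)
    n_loci = len(loci)
    geno = np.empty((n, n_loci, 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        alleles = np.array(sorted(freqs[locus]))
        p = np.array([freqs[locus][a] for a in alleles], dtype=float)
        p = p / p.sum()
        draws = alleles[rng.choice(len(alleles), size=(n, 2), p=p)]
        ibd = rng.random(n) < F
        draws[ibd, 1] = draws[ibd, 0]
        geno[:, j, :] = draws
    individuals = [
        Individual(
            id=f"{id_prefix}{period}_{i + 1:04d}", period=period,
            genotype=[tuple(geno[i, j]) for j in range(n_loci)],
        )
        for i in range(n)
    ]
    return GenotypeDataset(loci=loci, individuals=individuals,
                           period_order=[period])


def freqs_matching_diversity(summary, period: str, base_label: int = 101) -> dict:
    """Allele frequencies reproducing a published per-locus Na/He profile.

    For each locus row of ``summary`` (columns period, locus, Na, He) a
    one-dominant-allele spectrum is solved: allele 1 has frequency p and
    the remaining Na-1 alleles share (1-p) equally, with p chosen so the
    gene diversity 1 - sum(q^2) equals the printed He (clamped to the
    attainable range).  Useful for seeding the simulator when only a
    printed diversity table, not raw genotypes, is available.
    """
    sub = summary[(summary["period"] == period) & (summary["locus"] != "Average")]
    if sub.empty:
        raise ValueError(f"no per-locus rows for period {period!r}")
    out = {}
    for _, row in sub.iterrows():
        k = int(row["Na"])
        he = float(row["He"])
        if k == 1 or he <= 0:
            out[row["locus"]] = {base_label: 1.0}
            continue
        he = min(he, 1.0 - 1.0 / k - 1e-9)
        # solve 1 - p^2 - (1-p)^2/(k-1) = he for the dominant frequency p
        a = k / (k - 1)
        b = -2.0 / (k - 1)
        c = 1.0 / (k - 1) - (1.0 - he)
        p = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        rest = (1.0 - p) / (k - 1)
        table = {base_label: float(p)}
        for i in range(1, k):
            table[base_label + 2 * i] = float(rest)
        out[row["locus"]] = table
    return out


def _wf_step(freqs: dict, ne: float, rng: np.random.Generator) -> dict:
    """One Wright–Fisher generation: multinomial resampling of 2*Ne copies."""
    if ne == np.inf:
        return {locus: dict(t) for locus, t in freqs.items()}
    copies = int(round(2 * ne))
    out = {}
    for locus, table in freqs.items():
        alleles = sorted(table)
        p = np.array([table[a] for a in alleles], dtype=float)
        p = p / p.sum()
        counts = rng.multinomial(copies, p)
        out[locus] = {a: counts[i] / copies for i, a in enumerate(alleles)
                      if counts[i] > 0}
        if not out[locus]:  # numerical corner: keep the modal allele
            out[locus] = {alleles[int(np.argmax(p))]: 1.0}
    return out


def gen_temporal_dataset(spec: SynthSpec) -> GenotypeDataset:
    """Multi-period dataset: drift between periods, planted F within periods."""
    rng = np.random.default_rng(spec.seed)
    freqs = gen_allele_freqs(spec, rng)
    labels = spec.period_labels
    all_inds = []
    loci = list(freqs)
    for t, label in enumerate(labels):
        if t > 0:
            for _ in range(spec.generations_per_period):
                freqs = _wf_step(freqs, spec.drift_ne, rng)
        ds = gen_genotypes(freqs, spec.samples_per_period, spec.inbreeding[t],
                           rng, period=label)
        all_inds.extend(ds.individuals)
    return GenotypeDataset(loci=loci, individuals=all_inds, period_order=labels)


_BASES = np.array(list("ACGT"))


def gen_mtdna(spec: SynthSpec, rng: Optional[np.random.Generator] = None) -> SequenceSet:
    """Equal-length control-region sequences from given haplotype frequencies.

    Haplotype h differs from the common backbone at diagnostic site h
    (one substitution per haplotype); counts are multinomial at the
    configured frequencies, and records are spread round-robin across
    period labels.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L = spec.mtdna_length
    k = len(spec.mtdna_freqs)
    if L < 2 * k + 2:
        raise ValueError("sequence too short for the requested haplotype count")
    backbone = _BASES[rng.integers(0, 4, size=L)]
    hap_seqs = []
    for h in range(k):
        s = backbone.copy()
        if h > 0:
            site = 2 * h  # fixed diagnostic position per haplotype
            s[site] = _BASES[(np.nonzero(_BASES == s[site])[0][0] + h) % 4]
        hap_seqs.append("".join(s))
    counts = rng.multinomial(spec.mtdna_samples, np.asarray(spec.mtdna_freqs))
    labels = spec.period_labels
    records = []
    i = 0
    for h, c in enumerate(counts):
        for _ in range(c):
            records.append(SequenceRecord(
                id=f"mt{i + 1:04d}", period=labels[i % len(labels)],
                sequence=hap_seqs[h]))
            i += 1
    return SequenceSet(records=records)
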