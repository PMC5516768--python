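"""Shared fixtures: tiny hand-built datasets and seeded synthetic bundles."""

import numpy as np
import pytest

from isopop.datasets import GenotypeDataset, Individual
from isopop.synth import SynthSpec, gen_allele_freqs, gen_genotypes


@pytest.fixture
def hand_dataset():
    """Four individuals, one locus: genotypes AA, AB, AB, BC (A=101, B=103, C=105).

    Hand-counted truths: 8 allele copies, p = (0.5, 0.375, 0.125);
    Na = 3; Ho = 0.75; He = 1 - (0.5^2 + 0.375^2 + 0.125^2) = 0.59375.
    """
    inds = [
        Individual(id="i1", period="P1", genotype=[(101, 101)]),
        Individual(id="i2", period="P1", genotype=[(101, 103)]),
        Individual(id="i3", period="P1", genotype=[(101, 103)]),
        Individual(id="i4", period="P1", genotype=[(103, 105)]),
    ]
    return GenotypeDataset(loci=["LocA"], individuals=inds, period_order=["P1"])


@pytest.fixture
def two_period_dataset():
    """Two periods x two loci, with one missing genotype."""
    inds = [
        Individual(id="a1", period="1960-65", genotype=[(101, 103), (200, 200)]),
        Individual(id="a2", period="1960-65", genotype=[(101, 101), None]),
        Individual(id="a3", period="1960-65", genotype=[(103, 103), (200, 202)]),
        Individual(id="b1", period="1970-75", genotype=[(101, 103), (202, 202)]),
        Individual(id="b2", period="1970-75", genotype=[(103, 103), (200, 202)]),
    ]
    return GenotypeDataset(loci=["LocA", "LocB"], individuals=inds,
                           period_order=["1960-65", "1970-75"])


@pytest.fixture
def synthetic_period(rng):
    """One synthetic period: 9 loci, 50 individuals, no inbreeding."""
    spec = SynthSpec(seed=None)
    freqs = gen_allele_freqs(spec, rng)
    return gen_genotypes(freqs, 50, 0.0, rng), freqs


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
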