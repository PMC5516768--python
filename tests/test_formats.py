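"""GenePop/FASTA/census I/O: round trips, sentinel handling, error paths."""

import numpy as np
import pytest

from isopop.datasets import MISSING, ValidationError
from isopop.formats import (ParseError, partition_periods, read_census,
                            read_fasta, read_genepop, write_census,
                            write_fasta, write_genepop)
from isopop.synth import SynthSpec, gen_temporal_dataset


GENEPOP_2POP = """two periods, nine loci; periods: 1960-65,1970-75
L1
L2
L3
L4
L5
L6
L7
L8
L9
POP
m1 ,  102104 000000 101101 105105 103105 101103 102102 104106 101105
m2 ,  102102 101103 101103 105107 103103 101101 102104 104104 101101
m3 ,  104104 103103 101101 105105 103105 103103 102102 106106 105105
m4 ,  102104 101101 103103 107107 105105 101103 104104 104106 101105
m5 ,  104104 103103 101103 105107 103103 101101 102102 104104 105105
POP
n1 ,  102102 101103 101101 105105 103103 101101 102102 104104 101101
n2 ,  104104 103103 103103 107107 105105 103103 104404 106106 105105
n3 ,  102104 101103 101103 105107 103105 101103 102104 104106 101105
n4 ,  102102 101101 101101 105105 103103 101101 102102 104104 101101
n5 ,  104104 103103 103103 107107 105105 103103 104104 106106 105105
"""


def test_read_genepop_structure(tmp_path):
    p = tmp_path / "f.gen"
    p.write_text(GENEPOP_2POP.replace("104404", "104104"))
    ds = read_genepop(p)
    assert ds.periods == ["1960-65", "1970-75"]
    assert len(ds.loci) == 9
    assert len(ds.individuals) == 10
    # sentinel: m1 locus L2 is 000000
    m1 = ds.individuals[0]
    assert m1.genotype[1] is MISSING
    assert m1.genotype[0] == (102, 104)


def test_missing_never_coerced_to_allele(tmp_path):
    p = tmp_path / "f.gen"
    p.write_text(GENEPOP_2POP.replace("104404", "104104"))
    ds = read_genepop(p)
    n_alleles = sum(
        2 for ind in ds.individuals for g in ind.genotype if g is not MISSING)
    n_missing_slots = sum(
        2 for ind in ds.individuals for g in ind.genotype if g is MISSING)
    assert n_alleles + n_missing_slots == 2 * len(ds.individuals) * len(ds.loci)
    for ind in ds.individuals:
        for g in ind.genotype:
            if g is not MISSING:
                assert 0 not in g


@pytest.mark.parametrize("seed", [1, 7])
def test_genepop_round_trip_and_determinism(tmp_path, seed):
    ds = gen_temporal_dataset(SynthSpec(seed=seed, samples_per_period=15,
                                        periods=3))
    p1, p2 = tmp_path / "a.gen", tmp_path / "b.gen"
    write_genepop(ds, p1)
    back = read_genepop(p1)
    assert back.loci == ds.loci
    assert back.periods == ds.periods
    assert [i.id for i in back.individuals] == [i.id for i in ds.individuals]
    assert [i.genotype for i in back.individuals] == \
        [i.genotype for i in ds.individuals]
    write_genepop(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


from hypothesis import given, settings
from hypothesis import strategies as st

_genotype = st.one_of(
    st.none(),
    st.tuples(st.integers(min_value=1, max_value=999),
              st.integers(min_value=1, max_value=999)))


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.lists(_genotype, min_size=3, max_size=3),
                min_size=1, max_size=8))
def test_genepop_round_trip_property(tmp_path_factory, genotypes):
    """read_genepop(write_genepop(ds)) is the identity on the domain model."""
    from isopop.datasets import GenotypeDataset, Individual
    inds = [Individual(id=f"i{k}", period="P1", genotype=list(g))
            for k, g in enumerate(genotypes)]
    ds = GenotypeDataset(loci=["La", "Lb", "Lc"], individuals=inds)
    path = tmp_path_factory.mktemp("rt") / "x.gen"
    write_genepop(ds, path)
    back = read_genepop(path)
    assert back.loci == ds.loci
    assert [i.genotype for i in back.individuals] == \
        [i.genotype for i in ds.individuals]


def test_write_genepop_missing_and_empty_period(tmp_path):
    from isopop.datasets import GenotypeDataset, Individual
    ds = GenotypeDataset(
        loci=["L1"],
        individuals=[Individual(id="x", period="A", genotype=[None])],
        period_order=["A", "B"])
    p = tmp_path / "m.gen"
    write_genepop(ds, p)
    text = p.read_text()
    assert "000000" in text
    assert text.count("POP") == 2
    back = read_genepop(p)
    assert back.individuals[0].genotype[0] is MISSING


def test_write_genepop_code_width_overflow(tmp_path):
    from isopop.datasets import GenotypeDataset, Individual
    ds = GenotypeDataset(
        loci=["L1"],
        individuals=[Individual(id="x", period="A", genotype=[(1000, 1000)])])
    with pytest.raises(ValidationError):
        write_genepop(ds, tmp_path / "o.gen")


@pytest.mark.parametrize("mangle,exc", [
    (lambda t: t.replace("m2 ,", "m1 ,"), ValidationError),   # duplicate id
    (lambda t: t.replace("102104 000000", "102104 00000"), ParseError),  # bad width
    (lambda t: t.replace("m1 ,  ", "m1   "), ParseError),     # missing comma
])
def test_genepop_malformed(tmp_path, mangle, exc):
    p = tmp_path / "bad.gen"
    p.write_text(mangle(GENEPOP_2POP.replace("104404", "104104")))
    with pytest.raises(exc):
        read_genepop(p)


def test_fasta_round_trip(tmp_path):
    p = tmp_path / "s.fasta"
    p.write_text(">s1|1960-65\nACGTACGT\n>s2|1960-65\nACGTACGA\n>s3|1970-75\nACGTACGT\n")
    ss = read_fasta(p)
    assert len(ss) == 3
    assert ss.records[2].period == "1970-75"
    q = tmp_path / "t.fasta"
    write_fasta(ss, q)
    assert read_fasta(q).records[0].sequence == "ACGTACGT"


def test_fasta_header_without_period_is_an_error(tmp_path):
    p = tmp_path / "s.fasta"
    p.write_text(">sample1\nACGT\n")
    with pytest.raises(ParseError):
        read_fasta(p)


def test_census_round_trip_and_validation(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("1960,564\n1961,570\n1962,590\n1963,600\n1964,610\n1965,620\n")
    c = read_census(p)
    assert len(c) == 6
    assert c.count(1960) == 564
    q = tmp_path / "c2.csv"
    write_census(c, q)
    assert np.array_equal(read_census(q).counts, c.counts)
    bad = tmp_path / "bad.csv"
    bad.write_text("1960,564\n1962,600\n")
    with pytest.raises(ValidationError):
        read_census(bad)


class TestPartitionPeriods:
    INTERVALS = {
        "1960-65": (1960, 1965), "1970-75": (1970, 1975),
        "1980-85": (1980, 1985), "1990-95": (1990, 1995),
        "2000-05": (2000, 2005),
    }

    def _ds(self, years):
        from isopop.datasets import GenotypeDataset, Individual
        inds = [Individual(id=f"i{k}", period="?", genotype=[(101, 101)],
                           birth_year=y) for k, y in enumerate(years)]
        return GenotypeDataset(loci=["L1"], individuals=inds)

    def test_assignment_and_gap_years(self):
        ds, report = partition_periods(self._ds([1972, 1968, 2003]),
                                       self.INTERVALS)
        assert [i.period for i in ds.individuals] == ["1970-75", "2000-05"]
        assert report["dropped_count"] == 1
        assert report["dropped"] == ["i1"]

    def test_single_interval(self):
        ds, report = partition_periods(self._ds([1960, 1963, 1965]),
                                       {"1960-65": (1960, 1965)})
        assert ds.periods == ["1960-65"]
        assert report["dropped_count"] == 0

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValidationError):
            partition_periods(self._ds([1960]),
                              {"A": (1960, 1970), "B": (1965, 1975)})
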