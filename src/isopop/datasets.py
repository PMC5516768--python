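"""Core in-memory containers for multilocus genotype, census and sequence data.

The central object is :class:`GenotypeDataset`: diploid multilocus
genotypes annotated with a sampling-period label per individual.  Allele
labels are positive integers on whatever scale the genotyping produced
(fragment sizes or repeat counts); a missing genotype at a locus is an
explicit ``None``, never an allele code of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Individual",
    "GenotypeDataset",
    "CensusSeries",
    "SequenceSet",
    "SequenceRecord",
    "ValidationError",
]

#: Sentinel for a missing genotype at a locus.  Kept as ``None`` so that an
#: allele label of 0 can never be confused with "no data".
MISSING = None

SEQ_ALPHABET = set("ACGTN-")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _normalize_genotype(pair):
    if pair is MISSING:
        return MISSING
    a, b = pair
    a, b = int(a), int(b)
    if a <= 0 or b <= 0:
        raise ValidationError(f"allele labels must be positive integers, got {pair}")
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    """One diploid sample: id, period label, optional sex/birth year, genotypes.

    ``genotype`` holds one entry per locus of the parent dataset, each an
    unordered allele pair stored sorted ascending, or ``None`` for missing.
    """

    id: str
    period: str
    genotype: list
    sex: Optional[str] = None
    birth_year: Optional[int] = None

    def __post_init__(self):
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F', 'M' or None, got {self.sex!r}")
        self.genotype = [_normalize_genotype(g) for g in self.genotype]


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes partitioned into named sampling periods."""

    loci: list
    individuals: list = field(default_factory=list)
    period_order: Optional[list] = None

    def __post_init__(self):
        self.loci = list(self.loci)
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus names")
        seen = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise ValidationError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
            if len(ind.genotype) != len(self.loci):
                raise ValidationError(
                    f"individual {ind.id!r} has {len(ind.genotype)} genotypes "
                    f"for {len(self.loci)} loci"
                )
        if self.period_order is not None:
            self.period_order = list(self.period_order)

    # -- views ---------------------------------------------------------

    @property
    def periods(self):
        """Period labels in dataset order (declared order, else first appearance)."""
        if self.period_order is not None:
            return list(self.period_order)
        out = []
        for ind in self.individuals:
            if ind.period not in out:
                out.append(ind.period)
        return out

    def subset(self, period: str) -> "GenotypeDataset":
        inds = [i for i in self.individuals if i.period == period]
        return GenotypeDataset(self.loci, inds, period_order=[period])

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def __len__(self):
        return len(self.individuals)

    def allele_array(self) -> np.ndarray:
        """Genotypes as an ``(n, L, 2)`` int array with -1 marking missing."""
        n, L = len(self.individuals), len(self.loci)
        arr = np.full((n, L, 2), -1, dtype=np.int64)
        for i, ind in enumerate(self.individuals):
            for j, g in enumerate(ind.genotype):
                if g is not MISSING:
                    arr[i, j, 0], arr[i, j, 1] = g
        return arr


@dataclass
class CensusSeries:
    """Yearly population census: strictly increasing, contiguous years."""

    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.years.ndim != 1 or self.years.shape != self.counts.shape:
            raise ValidationError("years and counts must be 1-d and equal length")
        if len(self.years) == 0:
            raise ValidationError("empty census series")
        if not np.all(np.diff(self.years) == 1):
            raise ValidationError("census years must be strictly increasing and contiguous")
        if np.any(self.counts < 1):
            raise ValidationError("census counts must be >= 1")

    def __len__(self):
        return len(self.years)

    def count(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise KeyError(f"year {year} outside census range")
        return int(self.counts[idx])

    def items(self):
        return zip(self.years.tolist(), self.counts.tolist())


@dataclass
class SequenceRecord:
    id: str
    period: str
    sequence: str

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains characters outside ACGTN-: {sorted(bad)}"
            )


@dataclass
class SequenceSet:
    """Aligned (or to-be-trimmed) control-region sequences with period labels."""

    records: list = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def lengths(self):
        return [len(r.sequence) for r in self.records]

    def require_equal_lengths(self):
        ls = set(self.lengths())
        if len(ls) > 1:
            raise ValidationError(
                f"sequences have unequal lengths {sorted(ls)}; align or truncate "
                "to a common length first"
            )


def ordered_periods(labels: Iterable[str]) -> list:
    """Unique labels in order of first appearance."""
    out = []
    for lab in labels:
        if lab not in out:
            out.append(lab)
    return out
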