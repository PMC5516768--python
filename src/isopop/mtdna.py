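"""mtDNA control-region haplotype analysis and immigrant-detection arithmetic.

Haplotypes are defined by exact identity of the trimmed, aligned
sequences: any substitution or indel character difference separates two
haplotypes.  The module also computes the two detection quantities used
when screening an island population for female-line immigration:

* the minimum haplotype frequency detectable with n sequenced samples
  (the frequency at which the expected number sampled is one, 1/n), and
* the probability that a random immigrant from a mainland source carries
  a haplotype other than the island's (1 minus the source frequency of
  the focal haplotype).

A reference table of Central North American moose control-region
haplotype frequencies ships with the package
(``data/central_na_haplotypes.csv``).
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .datasets import SequenceRecord, SequenceSet, ValidationError

__all__ = [
    "trim_ends",
    "truncate_to_common",
    "collapse_haplotypes",
    "min_detectable_frequency",
    "nonfocal_probability",
    "load_reference_frequencies",
]


def trim_ends(seqs: SequenceSet, n: int = 30):
    """Remove ``n`` bases from both ends of every sequence (default 30).

    Trimming the alignment ends guards against false mutation calls in
    the low-quality terminal stretches of Sanger reads.  Sequences of
    length <= 2n cannot be trimmed and are dropped; their ids are
    returned alongside the trimmed set.

    Returns ``(trimmed SequenceSet, dropped ids)``.
    """
    if n < 0:
        raise ValueError("trim length must be >= 0")
    kept, dropped = [], []
    for r in seqs.records:
        if len(r.sequence) <= 2 * n:
            dropped.append(r.id)
            continue
        seq = r.sequence[n:len(r.sequence) - n] if n else r.sequence
        kept.append(SequenceRecord(id=r.id, period=r.period, sequence=seq))
    return SequenceSet(records=kept), dropped


def truncate_to_common(seqs: SequenceSet) -> SequenceSet:
    """Head-aligned truncation of all sequences to the shortest length.

    Opt-in convenience for sets of unequal length; whether variable-length
    reads of the same region should be compared this way is a judgement
    call, so :func:`collapse_haplotypes` never does it silently.
    """
    if not seqs.records:
        return SequenceSet(records=[])
    m = min(seqs.lengths())
    return SequenceSet(records=[
        SequenceRecord(id=r.id, period=r.period, sequence=r.sequence[:m])
        for r in seqs.records
    ])


def collapse_haplotypes(seqs: SequenceSet) -> pd.DataFrame:
    """Group identical sequences into haplotypes H1..Hk by descending count.

    Requires equal-length (aligned) sequences; an ``N`` is treated as a
    real character, so it separates haplotypes.  Returns a DataFrame with
    columns ``haplotype, sequence, count, frequency, members``.  Ties in
    count are broken lexicographically by sequence so labels are stable
    under permutation of the input.
    """
    if not seqs.records:
        return pd.DataFrame(columns=["haplotype", "sequence", "count",
                                     "frequency", "members"])
    seqs.require_equal_lengths()
    groups: dict = {}
    for r in seqs.records:
        groups.setdefault(r.sequence, []).append(r.id)
    total = len(seqs.records)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    for i, (seq, members) in enumerate(ordered, start=1):
        rows.append(dict(haplotype=f"H{i}", sequence=seq, count=len(members),
                         frequency=len(members) / total, members=members))
    return pd.DataFrame(rows)


def min_detectable_frequency(n_samples: int) -> float:
    """Smallest haplotype frequency detectable with ``n_samples`` sequences.

    Defined as 1/n: the frequency at which the expected number of copies
    in the sample is one.  With 134 samples this is 0.00746, i.e. about
    0.7%.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return 1.0 / n_samples


def nonfocal_probability(freq_table: pd.DataFrame, focal: str) -> float:
    """Probability a random source-population individual does NOT carry ``focal``.

    ``freq_table`` needs columns ``haplotype`` and ``frequency``;
    frequencies are renormalised if they sum within 1% of 1, otherwise
    rejected.
    """
    t = freq_table.copy()
    if "haplotype" not in t or "frequency" not in t:
        raise ValueError("frequency table needs 'haplotype' and 'frequency' columns")
    total = float(t["frequency"].sum())
    if abs(total - 1.0) > 0.01:
        raise ValidationError(f"haplotype frequencies sum to {total}, not ~1")
    t["frequency"] = t["frequency"] / total
    match = t.loc[t["haplotype"] == focal, "frequency"]
    if match.empty:
        raise KeyError(f"focal haplotype {focal!r} not in table")
    return 1.0 - float(match.iloc[0])


def load_reference_frequencies(path: Optional[str] = None) -> pd.DataFrame:
    """Load a haplotype,frequency CSV (default: the packaged Central North
    American moose table)."""
    if path is not None:
        return pd.read_csv(path)
    with resources.files("isopop").joinpath(
            "data/central_na_haplotypes.csv").open() as fh:
        return pd.read_csv(fh)
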