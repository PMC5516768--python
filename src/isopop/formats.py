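"""Readers and writers for the text formats the pipeline touches.

GenePop is the lingua franca for microsatellite genotypes: a title line,
one locus name per line (or one comma-separated line), then one ``POP``
block per sample, each line ``id ,  aabbcc ddeeff ...`` with fixed-width
2- or 3-digit allele codes and ``00``/``000`` marking missing data.
Period labels for POP blocks may be declared in the title line as
``periods: A,B,C``; otherwise blocks are auto-named P1..Pk.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datasets import (
    MISSING,
    CensusSeries,
    GenotypeDataset,
    Individual,
    SequenceRecord,
    SequenceSet,
    ValidationError,
)

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_fasta",
    "write_fasta",
    "read_census",
    "write_census",
    "partition_periods",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _parse_title_periods(title: str):
    m = re.search(r"periods\s*:\s*(.+)$", title, re.IGNORECASE)
    if not m:
        return None
    labels = [p.strip() for p in m.group(1).split(",") if p.strip()]
    return labels or None


def read_genepop(path, missing_code: str = "000") -> GenotypeDataset:
    """Read a GenePop file into a :class:`GenotypeDataset`.

    Allele codes may be 2 or 3 digits wide; the width is inferred from the
    first genotype field and must be consistent within the file.
    ``missing_code`` ("000" by default, "00" accepted for 2-digit files)
    marks a missing single-locus genotype.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")

    title = lines[0]
    period_labels = _parse_title_periods(title)

    loci: list = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend([x.strip() for x in chunk.split(",") if x.strip()])
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP")

    individuals = []
    pop_idx = 0
    cur_period = None
    seen_ids = set()
    width = None

    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            pop_idx += 1
            if period_labels is not None:
                if pop_idx > len(period_labels):
                    raise ParseError(
                        f"{path}:{lineno + 1}: more POP blocks than declared periods"
                    )
                cur_period = period_labels[pop_idx - 1]
            else:
                cur_period = f"P{pop_idx}"
            continue
        if pop_idx == 0:
            raise ParseError(f"{path}:{lineno + 1}: genotype line before first POP")
        if "," not in line:
            raise ParseError(f"{path}:{lineno + 1}: missing ',' between id and genotypes")
        ident, _, rest = line.partition(",")
        ident = ident.strip()
        if not ident:
            raise ParseError(f"{path}:{lineno + 1}: empty individual id")
        if ident in seen_ids:
            raise ValidationError(f"{path}:{lineno + 1}: duplicate individual id {ident!r}")
        seen_ids.add(ident)
        fields = rest.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}:{lineno + 1}: expected {len(loci)} genotype fields, "
                f"got {len(fields)}"
            )
        genotype = []
        for f in fields:
            if not f.isdigit() or len(f) % 2 != 0 or len(f) not in (4, 6):
                raise ParseError(
                    f"{path}:{lineno + 1}: genotype field {f!r} is not a 4- or "
                    "6-digit allele-code pair"
                )
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"{path}:{lineno + 1}: inconsistent allele-code width "
                    f"({w} vs {width})"
                )
            a_code, b_code = f[:w], f[w:]
            miss = missing_code[-w:] if len(missing_code) >= w else missing_code.zfill(w)
            a = MISSING if a_code == miss else int(a_code)
            b = MISSING if b_code == miss else int(b_code)
            if (a is MISSING) != (b is MISSING):
                # a half-missing genotype carries no usable pair
                genotype.append(MISSING)
            elif a is MISSING:
                genotype.append(MISSING)
            else:
                if a == 0 or b == 0:
                    raise ParseError(
                        f"{path}:{lineno + 1}: allele code 0 is reserved for missing"
                    )
                genotype.append((a, b))
        individuals.append(Individual(id=ident, period=cur_period, genotype=genotype))

    order = period_labels if period_labels is not None else None
    if order is None:
        order = [f"P{k}" for k in range(1, pop_idx + 1)]
    return GenotypeDataset(loci=loci, individuals=individuals, period_order=order)


def write_genepop(ds: GenotypeDataset, path, code_width: int = 3,
                  title: Optional[str] = None) -> None:
    """Write a dataset as GenePop text, one POP block per period.

    Raises if any allele label does not fit in ``code_width`` digits.
    Output ordering is deterministic: periods in dataset order, individuals
    in dataset order within each period.
    """
    path = Path(path)
    limit = 10 ** code_width - 1
    miss = "0" * code_width
    periods = ds.periods
    if title is None:
        title = "isopop genotypes; periods: " + ",".join(periods)
    out = [title]
    out.extend(ds.loci)
    for period in periods:
        out.append("POP")
        for ind in ds.individuals:
            if ind.period != period:
                continue
            fields = []
            for g in ind.genotype:
                if g is MISSING:
                    fields.append(miss + miss)
                else:
                    a, b = g
                    if a > limit or b > limit:
                        raise ValidationError(
                            f"allele label {max(a, b)} does not fit in "
                            f"{code_width}-digit codes"
                        )
                    fields.append(f"{a:0{code_width}d}{b:0{code_width}d}")
            out.append(f"{ind.id} ,  " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file whose headers are ``id|period`` into a SequenceSet."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" not in header:
            raise ParseError(
                f"{path}: FASTA header {header!r} lacks the '|period' suffix"
            )
        ident, _, period = header.partition("|")
        if not period:
            raise ParseError(f"{path}: FASTA header {header!r} has an empty period")
        records.append(SequenceRecord(id=ident, period=period, sequence=str(rec.seq)))
    return SequenceSet(records=records)


def write_fasta(seqs: SequenceSet, path) -> None:
    with open(path, "w") as fh:
        for r in seqs.records:
            fh.write(f">{r.id}|{r.period}\n{r.sequence}\n")


def read_census(path) -> CensusSeries:
    """Read a two-column ``year,count`` CSV (header optional)."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: census file needs two columns (year,count)")
    # tolerate a header row
    if not str(df.iloc[0, 0]).strip().lstrip("-").isdigit():
        df = df.iloc[1:]
    years = df.iloc[:, 0].astype(int).to_numpy()
    counts = df.iloc[:, 1].astype(int).to_numpy()
    return CensusSeries(years=years, counts=counts)


def write_census(census: CensusSeries, path) -> None:
    pd.DataFrame({"year": census.years, "count": census.counts}).to_csv(
        path, index=False, header=False
    )


def partition_periods(ds: GenotypeDataset, intervals: dict) -> tuple:
    """Re-label individuals into periods by birth-year intervals.

    ``intervals`` maps period label -> (first_year, last_year), inclusive.
    Individuals whose birth year falls outside every interval (or is
    unknown) are dropped; the second return value reports them.

    Returns ``(dataset, report)`` where ``report`` is a dict with keys
    ``kept``, ``dropped`` (list of ids) and ``dropped_count``.
    """
    spans = sorted(intervals.items(), key=lambda kv: kv[1][0])
    for (la, (a0, a1)), (lb, (b0, b1)) in zip(spans, spans[1:]):
        if a1 >= b0:
            raise ValidationError(
                f"overlapping period intervals {la!r} ({a0}-{a1}) and {lb!r} ({b0}-{b1})"
            )
    kept, dropped = [], []
    for ind in ds.individuals:
        label = None
        if ind.birth_year is not None:
            for lab, (y0, y1) in spans:
                if y0 <= ind.birth_year <= y1:
                    label = lab
                    break
        if label is None:
            dropped.append(ind.id)
        else:
            kept.append(
                Individual(
                    id=ind.id,
                    period=label,
                    genotype=list(ind.genotype),
                    sex=ind.sex,
                    birth_year=ind.birth_year,
                )
            )
    order = [lab for lab, _ in spans]
    new_ds = GenotypeDataset(loci=ds.loci, individuals=kept, period_order=order)
    report = {"kept": len(kept), "dropped": dropped, "dropped_count": len(dropped)}
    return new_ds, report
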