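"""Per-locus and per-period diversity statistics: Na, Ho, He and F_IS.

Conventions
-----------
* An individual missing its genotype at a locus is excluded from that
  locus's statistics only (per-locus n, not listwise deletion).
* He defaults to Nei's gene diversity ``1 - sum(p^2)`` computed from
  sample allele frequencies; the small-sample unbiased variant
  multiplies by ``2n/(2n-1)``.
* F_IS is reported under two estimators: ``nei`` (``1 - Ho/He``) and
  ``wc`` (Weir & Cockerham's small-sample f from variance components).
  A multilocus/period-average wc value sums the variance components over
  loci rather than averaging per-locus ratios, which is why a period's
  F_IS summary need not equal the column mean of per-locus values.
* Monomorphic loci have Ho = He = 0 and an undefined F_IS (NaN).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset

__all__ = [
    "allele_frequencies",
    "num_alleles",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "fis",
    "wc_components",
    "diversity_table",
    "round_half_away",
]


def _genotypes(ds: GenotypeDataset, locus: str, period: Optional[str] = None):
    """Non-missing genotype pairs at a locus (optionally one period)."""
    j = ds.locus_index(locus)
    return [
        ind.genotype[j]
        for ind in ds.individuals
        if (period is None or ind.period == period) and ind.genotype[j] is not MISSING
    ]


def allele_frequencies(ds: GenotypeDataset, period: Optional[str] = None) -> dict:
    """Sample allele frequencies per locus.

    Returns ``{locus: {"freqs": {allele: fraction}, "n": genotyped individuals}}``.
    Each allele copy counts once; the denominator is ``2 * n`` non-missing
    copies at that locus.  Loci with no genotyped individuals are omitted
    with a warning.
    """
    out = {}
    for locus in ds.loci:
        pairs = _genotypes(ds, locus, period)
        if not pairs:
            warnings.warn(f"locus {locus!r} has no genotyped individuals; omitted")
            continue
        counts = Counter()
        for a, b in pairs:
            counts[a] += 1
            counts[b] += 1
        total = 2 * len(pairs)
        out[locus] = {
            "freqs": {al: c / total for al, c in sorted(counts.items())},
            "n": len(pairs),
        }
    return out


def num_alleles(ds: GenotypeDataset, locus: str, period: Optional[str] = None):
    """Count of distinct alleles observed at a locus (NaN if no data)."""
    pairs = _genotypes(ds, locus, period)
    if not pairs:
        return float("nan")
    return len({al for g in pairs for al in g})


def observed_heterozygosity(ds: GenotypeDataset, locus: str,
                            period: Optional[str] = None):
    """Fraction of genotyped individuals whose two alleles differ."""
    pairs = _genotypes(ds, locus, period)
    if not pairs:
        return float("nan")
    het = sum(1 for a, b in pairs if a != b)
    return het / len(pairs)


def expected_heterozygosity(freqs: dict, locus: str, unbiased: bool = False):
    """Gene diversity ``1 - sum(p^2)`` at a locus of an allele-frequency table.

    With ``unbiased=True`` applies the ``2n/(2n-1)`` small-sample correction.
    """
    entry = freqs[locus]
    p = np.array(list(entry["freqs"].values()))
    he = 1.0 - float(np.sum(p * p))
    if unbiased:
        two_n = 2 * entry["n"]
        he *= two_n / (two_n - 1)
    return he


def wc_components(ds: GenotypeDataset, locus: str, period: Optional[str] = None):
    """Weir–Cockerham within-population variance components (b, c) at a locus.

    For each allele A with sample frequency p and observed frequency h of
    heterozygotes carrying A::

        b_A = n/(n-1) * (p(1-p) - (2n-1)/(4n) * h)
        c_A = h / 2

    summed over alleles.  f = 1 - c/(b+c); summing components over loci
    gives the multilocus estimate.  Returns ``(b, c)`` or ``(nan, nan)``
    for a monomorphic or empty locus.
    """
    pairs = _genotypes(ds, locus, period)
    n = len(pairs)
    if n < 2:
        return (float("nan"), float("nan"))
    alleles = sorted({al for g in pairs for al in g})
    if len(alleles) < 2:
        return (float("nan"), float("nan"))
    b_sum = c_sum = 0.0
    for al in alleles:
        copies = sum((a == al) + (b == al) for a, b in pairs)
        p = copies / (2 * n)
        h = sum(1 for a, b in pairs if (a == al) != (b == al)) / n
        b_sum += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c_sum += h / 2
    return (b_sum, c_sum)


def fis(ds: GenotypeDataset, locus: str, period: Optional[str] = None,
        estimator: str = "nei"):
    """Single-locus inbreeding coefficient; NaN for monomorphic loci.

    ``nei``: ``1 - Ho/He`` with biased He.  ``wc``: Weir–Cockerham f.
    """
    if estimator == "nei":
        pairs = _genotypes(ds, locus, period)
        if not pairs:
            return float("nan")
        freqs = {locus: _freqs_from_pairs(pairs)}
        he = expected_heterozygosity(freqs, locus)
        if he == 0.0:
            return float("nan")
        ho = sum(1 for a, b in pairs if a != b) / len(pairs)
        return 1.0 - ho / he
    if estimator == "wc":
        b, c = wc_components(ds, locus, period)
        if math.isnan(b) or (b + c) == 0:
            return float("nan")
        return 1.0 - c / (b + c)
    raise ValueError(f"unknown Fis estimator {estimator!r}")


def _freqs_from_pairs(pairs):
    counts = Counter()
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    total = 2 * len(pairs)
    return {"freqs": {al: ct / total for al, ct in sorted(counts.items())},
            "n": len(pairs)}


def diversity_table(ds: GenotypeDataset, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-period × per-locus table of n, Na, Ho, He and both F_IS estimates.

    Each period gets an ``Average`` row: unweighted means over loci of the
    defined per-locus Na/Ho/He/Fis_nei values, and for Fis_wc the
    variance-component sum over loci (the standard multilocus estimator).
    """
    rows = []
    for period in ds.periods:
        b_tot = c_tot = 0.0
        any_wc = False
        per_locus = []
        for locus in ds.loci:
            pairs = _genotypes(ds, locus, period)
            if not pairs:
                per_locus.append((locus, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            n = len(pairs)
            na = len({al for g in pairs for al in g})
            ho = sum(1 for a, b in pairs if a != b) / n
            freqs = {locus: _freqs_from_pairs(pairs)}
            he = expected_heterozygosity(freqs, locus, unbiased=unbiased_he)
            f_nei = (1.0 - ho / he) if he > 0 else np.nan
            b, c = wc_components(ds, locus, period)
            if not math.isnan(b):
                b_tot += b
                c_tot += c
                any_wc = True
                f_wc = 1.0 - c / (b + c) if (b + c) != 0 else np.nan
            else:
                f_wc = np.nan
            per_locus.append((locus, n, na, ho, he, f_nei, f_wc))
        for locus, n, na, ho, he, f_nei, f_wc in per_locus:
            rows.append(dict(period=period, locus=locus, n=n, Na=na, Ho=ho,
                             He=he, Fis_nei=f_nei, Fis_wc=f_wc))
        sub = pd.DataFrame([r for r in per_locus], columns=[
            "locus", "n", "Na", "Ho", "He", "Fis_nei", "Fis_wc"])
        f_wc_multi = (1.0 - c_tot / (b_tot + c_tot)) if any_wc and (b_tot + c_tot) else np.nan
        rows.append(dict(
            period=period, locus="Average",
            n=float(sub["n"].mean()),
            Na=float(sub["Na"].mean()),
            Ho=float(sub["Ho"].mean()),
            He=float(sub["He"].mean()),
            Fis_nei=float(sub["Fis_nei"].mean()),
            Fis_wc=f_wc_multi,
        ))
    return pd.DataFrame(rows)


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (presentation rounding for emitted tables)."""
    if isinstance(x, (pd.Series, np.ndarray, list)):
        return np.array([round_half_away(v, decimals) for v in np.asarray(x)])
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
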