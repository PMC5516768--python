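"""isopop: temporal genetic-diversity analysis for isolated populations.

Tools for tracking microsatellite diversity (Na, Ho, He, F_IS) across
sampling periods, testing Hardy–Weinberg and linkage equilibrium,
screening for immigrants by Bayesian genotype assignment and mtDNA
haplotypes, and simulating the expected drift of diversity in an
age-structured population whose yearly size is pinned to a census.
"""

from importlib import resources as _resources

import pandas as _pd

__version__ = "0.1.0"

from .datasets import CensusSeries, GenotypeDataset, Individual, SequenceSet  # noqa: F401


def load_published_diversity() -> "_pd.DataFrame":
    """Published per-locus diversity estimates for Isle Royale moose, 1960-2005.

    Columns: period, locus, n, Na, Ho, He, Fis.  These printed estimates
    are the reference input for the trend-regression replica and for the
    initial allele-frequency scale of the demographic simulator's
    documentation examples.
    """
    with _resources.files("isopop").joinpath(
            "data/isle_royale_published_diversity.csv").open() as fh:
        return _pd.read_csv(fh)
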