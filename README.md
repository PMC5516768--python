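# isopop

Temporal genetic-diversity analysis for isolated populations: track
microsatellite diversity across sampling periods, test whether the
population is losing heterozygosity faster than drift alone predicts,
and screen for immigrants.

Closed populations lose genetic diversity by drift at a rate set by
their effective size, and accumulate inbreeding unless immigrants
arrive. Long-monitored island populations — the package's reference
design is the Isle Royale moose population, censused yearly since 1959
and genotyped at nine microsatellite loci across five 5-year sampling
periods from 1960 to 2005 — make it possible to measure that erosion
directly. `isopop` provides the full analysis chain:

* **Diversity table** (`isopop.diversity`): per-period × per-locus Na,
  Ho, He = 1 − Σp², and F_IS under two labelled estimators —
  Nei's 1 − Ho/He and Weir–Cockerham's variance-component f, with the
  multilocus value formed by summing components over loci.
* **Trend regression** (`isopop.trend`): closed-form OLS of the
  period-average metrics on period index, with p from F(1, k−2).
* **Equilibrium tests** (`isopop.equilibrium`): the exact conditional
  Hardy–Weinberg probability test, by complete enumeration for small
  loci and by a batched Markov chain over genotype tables otherwise,
  plus a permutation G-test for genotypic linkage disequilibrium and
  Bonferroni helpers.
* **Assignment scan** (`isopop.assignment`): Rannala–Mountain genotype
  likelihoods with leave-one-out scoring and a Monte-Carlo exclusion
  test that simulates whole reference-sized populations, for detecting
  first-generation immigrants.
* **mtDNA haplotypes** (`isopop.mtdna`): end-trimming, exact-identity
  haplotype collapsing, and the two immigrant-detection quantities
  (minimum detectable haplotype frequency 1/n; probability an immigrant
  carries a non-focal haplotype).
* **Forward simulator** (`isopop.simulate`): an age- and sex-structured,
  individual-based simulation whose yearly population size is pinned
  exactly to a census series, with stepwise microsatellite mutation —
  the neutral-drift baseline against which the empirical decline is
  judged.
* **Synthetic data** (`isopop.synth`): generators with planted
  inbreeding, drift and divergence parameters, so every estimator is
  testable against known truth without any external data.
* **Pipeline & CLI** (`isopop.pipeline`, `isopop` command): one-config
  orchestration with seeds and parameters logged into every output.

## Worked example

The packaged table of published per-locus diversity estimates
(`isopop.load_published_diversity()`) carries the five period averages
of observed heterozygosity: 0.53, 0.51, 0.49, 0.51, 0.47. Regressing
them on period index:

```python
from isopop import load_published_diversity
from isopop.trend import ols_trend

pub = load_published_diversity()
avg = pub[pub.locus == "Average"].sort_values("period")
r = ols_trend(avg["Ho"].tolist(), metric="Ho")
print(f"slope={r.slope:.3f} (SE {r.slope_se:.3f}), "
      f"intercept={r.intercept:.3f} (SE {r.intercept_se:.3f})")
print(f"F={r.F:.2f}, R2={r.R2:.2f}, p={r.p_value:.2f}")
```

prints

```
slope=-0.012 (SE 0.005), intercept=0.538 (SE 0.015)
F=6.75, R2=0.69, p=0.08
```

— observed heterozygosity fell by about 0.012 per 5-year period
(roughly one moose generation), a marginally significant decline that
explains ~70% of the between-period variance. The immigration side of
the argument:

```python
from isopop.mtdna import (load_reference_frequencies,
                          nonfocal_probability, min_detectable_frequency)

ref = load_reference_frequencies()          # Central North American moose
print(f"{nonfocal_probability(ref, 'L'):.2f}")      # 0.61
print(f"{min_detectable_frequency(134):.4f}")       # 0.0075
```

With 134 sequenced samples, any haplotype at ≥ 0.7% frequency should
have been seen; a random mainland immigrant would carry a haplotype
other than the island's (L) with probability 0.61 — so observing a
single haplotype is evidence against recent female-line immigration.

From the shell, the same stages run as subcommands
(`isopop diversity`, `trend`, `hwe`, `ld`, `assign`, `haplo`,
`simulate`, `synth`, `run-all`); every Monte-Carlo command requires an
explicit `--seed` and echoes it into its output.

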