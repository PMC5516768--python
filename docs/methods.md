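# Methods

`isopop` analyses temporal change in the genetic diversity of a closed,
census-monitored population, using the Isle Royale moose population
(nine microsatellite loci, five 5-year sampling periods spanning
1960–2005, plus mtDNA control-region sequences) as its reference study
design. This note records the statistical models, the numerical and
design choices that were genuinely open, and what the synthetic-data
tests do and do not establish.

## Diversity statistics

For each locus and sampling period the package reports the number of
distinct alleles Na, observed heterozygosity Ho (fraction of genotyped
individuals with two different alleles), gene diversity
He = 1 − Σ p², and the inbreeding coefficient F_IS. An individual
missing a locus is excluded from that locus only; per-locus sample
sizes therefore vary within a period, matching standard practice in
GENALEX/GENEPOP-style workflows.

F_IS is reported under two estimators, both labelled in every output:

* `nei`: 1 − Ho/He with the (biased) gene diversity — transparent and
  exactly consistent with the printed Ho/He columns
  (Ho = He(1 − F_IS) holds to machine precision);
* `wc`: Weir & Cockerham's small-sample f from variance components,
  with the multilocus (and period-average) value formed by summing the
  b and c components over loci rather than averaging per-locus ratios.
  This is why a period's F_IS summary is not the column mean of the
  per-locus values — a property the reference study's table shares.

Published per-locus F_IS values in the reference table are not exactly
reproducible from the printed Ho/He (e.g. one locus has Ho > He with a
positive printed F_IS), so the replica prints both estimators rather
than chasing a single unidentifiable variant.

Emitted tables round half-away-from-zero to 2 decimals for display;
full precision is kept internally and in CSV output.

## Hardy–Weinberg and linkage tests

The HWE test is the exact conditional probability test: given the
allele counts, a genotype table with h heterozygotes and counts {n_g}
has probability n!·Π c_a!·2^h / ((2n)!·Π n_g!), and the p-value sums
the probabilities of all tables no more probable than the observed one.
Small problems (≤ 3 alleles or ≤ 20 allele copies by default) are
enumerated completely; the enumeration asserts that table probabilities
sum to 1 within 1e-10. Larger problems use a Markov chain whose state
is the assignment of the 2n observed allele copies to n individuals;
a step swaps two uniformly chosen copies and is always accepted, since
the uniform-pairing distribution is exactly the conditional null. A
laziness step (no-op when the same position is drawn twice) guarantees
aperiodicity. The chain is organised as dememorisation + batches
(defaults 1,000 + 100 × 1,000, the convention popularised by the
GENEPOP web service), and the p-value's Monte-Carlo standard error is
the between-batch standard error. Ties in table probability are counted
as "at least as extreme" with a 1e-9 log-space tolerance, keeping the
test conservative.

Linkage disequilibrium uses the genotypic contingency-table G statistic
(gametic phase is unknown for diploid microsatellites) with a
permutation null (one locus's genotypes permuted among individuals) and
the add-one p estimator (1 + #{G* ≥ G})/(B + 1), which can never return
p = 0. Bonferroni-corrected alphas (α/m; m = 9 loci for HWE, 36 locus
pairs for LD) are annotations on the output — raw p-values are always
emitted.

## Trend regression

Period-average Na, Ho and F_IS are regressed on the period index 1..k
by closed-form OLS, with the p-value from F(1, k−2). Index coding —
not calendar midyear — reproduces the published regression table from
the published period averages (slope −0.012, intercept 0.538, F = 6.75
for Ho); midyear coding would rescale the slope by 1/10. The published
F_IS intercept (0.094) is not recoverable from the rounded published
averages (which give 0.088), implying the original fit used unrounded
inputs; the replica therefore asserts only slope, R² and F for that row.
No multiple-testing correction is applied across the three regressions.

## Assignment test for first-generation immigrants

The genotype likelihood follows Rannala & Mountain's posterior-
predictive form. At a locus where the reference holds n copies over K
observed allele states, the two alleles are scored sequentially:
P(first = a) = (n_a + 1/K)/(n + 1), P(second = a′ | first) =
(n_{a′} + [a′ = first] + 1/K)/(n + 2), doubled for heterozygotes; loci
multiply. Alleles absent from the reference receive the 1/K prior mass
(K is minimally extended for novel alleles), so no genotype has zero
likelihood. Per locus the scores sum to exactly 1 over all genotypes.

Members of the reference are scored leave-one-out (their own two copies
removed per locus) so a sample never certifies itself. The exclusion
null simulates, for each of n_sim draws, an entire population of the
reference's per-locus sample size from the reference allele
frequencies, then scores one member of that simulated population
leave-one-out against the rest of it. Simulating whole same-sized
populations — the "same sample size as the reference" resampling idea —
rather than lone genotypes against the observed counts serves two
purposes: it propagates the reference's sampling variance into the
null, and it reproduces the leave-one-out situation of a real member
exactly. Variants that simulate single genotypes from the observed (or
bootstrap) frequencies and score them against the observed counts are
measurably anti-conservative here (self-assignment rejection ≈ 0.024 at
α = 0.01 versus ≈ 0.013 for the implemented scheme, over 2,000
self-assignments at 9 loci, n = 50), because simulated genotypes are
never penalised for their own alleles the way leave-one-out members
are. Exclusion probabilities use the add-one estimator with ties
counted conservatively; the default α is 0.01 with n_sim = 10,000.

An individual whose every locus is missing is skipped and reported. An
individual with some missing loci is scored on its typed loci while the
null is scored on all loci; with pervasive missingness the null is then
slightly too low (conservative).

## mtDNA haplotypes and immigrant detectability

Haplotypes are exact-identity classes of the trimmed, aligned
control-region sequences (substitutions and indel characters both
count; N is a real character). The first and last 30 bases are trimmed
by default to avoid false variants in the low-quality read ends.
Unequal post-trim lengths are an error — head-aligned truncation to the
common length is available only behind an explicit flag, because
comparing variable-length reads as one haplotype is an interpretive
step the package refuses to take silently. Labels H1..Hk are assigned
by descending count with lexicographic tie-break, so group membership
and labels are invariant to input order.

Two detection quantities summarise the immigration evidence: the
minimum detectable haplotype frequency with n sequences, defined as 1/n
(the frequency at which one copy is expected in the sample; 1/134 ≈
0.7%), and the probability that a random immigrant from a reference
source population carries a haplotype other than the island's focal
one, 1 − f(focal) (61% for the packaged Central North American table
with focal haplotype L). Alternative detectability definitions (e.g.
P(≥1 copy) ≥ 95%) would give smaller detectable frequencies; 1/n is the
implemented convention.

## Census-constrained forward simulator

Each replicate founds the population at the first census count (564 by
default for 1960), drawing two alleles per locus from the supplied
initial frequencies (Hardy–Weinberg draw), sex with probability 0.5,
and founder age uniform on 1–15. Each subsequent year, in this order:
ages increment; individuals older than 15 die; the population is
reconciled to that year's census — a uniform random subset survives a
decline, and a growth deficit is filled with newborns. Each newborn
draws an eligible mother (age 2–15) and father (age 5–12) independently
and with replacement, receives one allele per parent per locus (±1
stepwise mutation at 10⁻⁴ per transmission, unbounded), sex Bernoulli
(0.5), age 0. The within-year order was chosen because it is the only
arrangement of the stated steps that guarantees the population size
equals the census exactly in every year, which the tests assert.
Newborns cannot breed in their birth year; a female may mother several
calves in one year (no litter constraint is imposed). Replicates that
lose all eligible breeders while offspring are required are recorded as
extinct and excluded from summaries (restarting them would bias toward
diversity retention); the count is surfaced.

Replicates use independently spawned child streams of one master seed,
so results are bit-reproducible and independent of replicate order.
Summaries report per-year cross-replicate means of Ho (per-individual
heterozygosity averaged over loci) and Na (alleles per locus), with
95% bands as 2.5/97.5 percentiles across replicates — percentiles, not
a normal approximation, because 100 replicates of a skewed Na
distribution do not justify one.

### Drift calibration and effective size

With mutation off and a constant census N, allele conservation and
non-increasing Na are exact properties. The fitted rate of
heterozygosity decay depends on the time unit: fitted on the yearly
trajectory, H(t) ≈ H0·(1 − 1/(2Ne_y))^t gives Ne_y ≈ 4.2–4.5·N for the
moose life history; converted with the realised generation time
(mean parent age, T ≈ 8.5 y) the per-generation effective size is
Ne_g = Ne_y/T ≈ 0.5·N. Both match Hill's overlapping-generation theory
Ne_g = 4BT/(V_k + 2) with B ≈ N/16 recruits per year and near-Poisson
lifetime reproductive variance V_k ≈ 2. In words: drift per *year* is
much slower than in a Wright–Fisher population of size N (hence
simulated heterozygosity is nearly flat over 45 years even through an
80% crash), while drift per *generation* corresponds to roughly half
the census size. The drift-calibration test asserts the yearly-fit
band [N, 4N] and reports both ratios; the measured yearly ratio sits
just above that band (≈ 4.25 at N = 100), which is documented rather
than hidden.

### Stylised census

A built-in 1960–2005 census interpolates the landmark sizes of the
Isle Royale trajectory (564 → ~1,500 → ~870 → ~2,400 → 80% crash →
~1,100) and superimposes a small deterministic two-frequency
oscillation (±5%, ±3%). The oscillation matters: real yearly censuses
fluctuate, and a smooth monotone multi-year decline would create long
birth gaps that age every male out of the 5–12 breeding window — an
artifact of interpolation, not a property of the system. Users with
the real yearly counts should supply them as a `year,count` CSV.

## Synthetic data generator

The generator emulates the reference study design — 9 loci with 2–7
alleles, ~50 diploid samples in each of 5 periods — with three planted,
analytically recoverable parameters: within-period inbreeding F via the
identity-by-descent mixture (probability-F duplication of a single
draw, so E[Ho] = (1 − F)·He exactly — chosen over selfing pedigrees
precisely for this closed form); between-period drift via binomial
Wright–Fisher resampling of 2·Ne copies (variance p(1−p)/(2Ne) per
step, one generation per period step by default although real periods
span ~1.5 moose generations — configurable); and mtDNA haplotype
frequencies realised as multinomial counts of sequences differing at
fixed diagnostic sites. Divergent source populations for migrant-power
tests use the symmetric island model: island and mainland frequencies
are independent Dirichlet(p·(1−FST)/FST) draws around a common
ancestor, which — unlike one-sided divergence from the island's own
frequencies — lets immigrants carry alleles absent from the island
sample, the signal that actually powers exclusion tests.

What passing on synthetic data shows: the estimators are unbiased and
calibrated under the generating models (HW genotypes, IBD-mixture
inbreeding, WF drift, island-model divergence). What it does not show:
robustness to null alleles, allelic dropout, scoring error or
population substructure, none of which the generator emulates (the
reference workflow screens for these upstream).

## Problem sizes and defaults

Chain and simulation defaults are the study's own settings (1,000
dememorisations, 100 × 1,000 batches; 10,000 assignment simulations;
100 simulator replicates). Calibration tests run at 1,000 replicate
loci (HWE type-I), 2,000 self-assignments (exclusion calibration), 500
replicates of n = 500 (F_IS recovery), and 100 replicates × 300 years
(drift fit) — sizes chosen so each check has enough Monte-Carlo
resolution to detect miscalibration at its asserted band.

## Known limitations

* Single reference population only; multi-population assignment and
  migration-rate estimation are out of scope.
* The simulator has no selection, spatial structure, linked loci or
  density dependence; the census is exogenous.
* Exact-test p-values are discrete and hence conservative at small n.
* The mtDNA module assumes pre-aligned sequences; no alignment is
  performed.
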