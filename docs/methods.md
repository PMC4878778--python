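# Methods

This note documents the models and procedures implemented in `exomecarrier`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable construction existed. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Carrier-rate model

For an autosomal-recessive disorder with causal allele frequency *p* and
wild-type frequency *q* = 1 − *p*, random mating implies genotype
frequencies *p*², 2*pq*, *q*². Population exome cohorts are depleted for
affected homozygotes (participants are broadly healthy), so the fraction of
sampled individuals carrying at least one causal allele is approximated by

    p² + 2pq · ½ = p² + pq ≈ pq ≈ p        (valid for p < 0.05),

counting each heterozygote once (the ½ factor counts one of the two alleles
of each heterozygote) and treating the homozygote term as negligible. In
this regime the implied disease prevalence *p*² is below 0.25%, which is
what justifies dropping it. The package therefore reports, per observation:

* `af` / `carrier_rate` — the allele frequency AC/AN, which **is** the
  operational carrier rate under this approximation (this matches the
  convention used throughout published carrier tables of this kind);
* `het_frequency` — the textbook heterozygote frequency 2*p*(1 − *p*),
  exposed separately so users who want the exact HWE heterozygote fraction
  can use it;
* `one_in` — the reciprocal 1/af (∞ for AC = 0), displayed to one decimal;
* `hwe_valid` — False when af ≥ 0.05; the numbers are still produced, the
  flag marks that the rare-allele shortcut is outside its stated regime.

Frequencies are stored at full precision; display rounding (3 significant
figures for af, one decimal for 1-in-N) applies only at the formatting
layer. Ranking for screening priority sorts by descending af and groups as
ties estimates that agree at display precision (3 significant figures),
using competition ranking (1, 2, 2, 4). Disease-level burden is the sum of
per-mutation allele frequencies — exact only for rare, independently
carried alleles — and is flagged as an approximation in all outputs; no
published aggregation rule exists for this quantity, and the package makes
no attempt to reproduce narrative summary percentages that cannot be
derived from printed counts by summation.

## Allele counting (AC/AN)

AN counts *called* alleles: two per fully genotyped diploid individual, one
per half-called genotype, zero per missing genotype. This is the standard
aggregation-database convention and is why denominators vary site-by-site
below 2 × cohort size. Multi-allelic VCF records are decomposed into
biallelic (ref, alt) pairs before panel matching; AN at a decomposed site
still counts every called allele, while AC counts only the matched
alternate. Counting is by construction invariant to VCF record order and
sample column order. Coordinates are VCF-style 1-based throughout;
"chr"-prefixed and bare contig names are treated as equivalent, with an
explicit alias map available for other dialects. The mutation panel is
autosomal-only; non-autosomal panel entries are rejected outright rather
than risk mis-counting hemizygous genotypes.

### Variant matching and normalization

Panel matching is locus-first. Both panel and query alleles are reduced to
a minimal spelling (shared suffix then prefix trimmed); when a reference
context is supplied, `normalize_allele_pair` additionally left-aligns
indels by the standard right-trim/left-extend algorithm, so equivalent
spellings of the same deletion or insertion in a repeat run collide on one
canonical representation. The operation is idempotent and is verified in
the tests against an independent brute-force oracle that enumerates every
equivalent spelling on a short context by haplotype identity. rsID matching
is a fallback only: a record that carries its own locus is never matched
via rsID when a locus query fails (multi-allelic decomposition produces
sibling alternates sharing one rsID; resurrecting them by rsID would
double-count). Two panel entries matching one variant is an error, never a
silent pick. A mismatch between a record's rsID and locus is tolerated at
load time (identifier merges drift over time); genome build is opaque
metadata and no liftover is attempted.

### Site QC

Published pipelines of this kind filter candidate sites on four dimensions:
total read depth, fraction of individuals with coverage, alternate-read
fraction in heterozygotes, and read position of alternate alleles — but
published cutoffs are typically unstated. The defaults here are
`min_total_depth=10`, `min_fraction_samples_called=0.8`,
`het_alt_fraction_range=(0.25, 0.75)` (applied to the mean across
heterozygotes when per-sample AD is present), and the read-position filter
disabled (site-level VCFs rarely carry the needed field; it activates on a
`READPOS` INFO key when configured). Each filter applies only when the
corresponding VCF field exists, every threshold is configurable, and QC can
be disabled wholesale. These defaults reproduce the filtering *stage*
faithfully while acknowledging the thresholds themselves are a choice.

## Concordance tests

**Two cohorts.** Equality of two binomial proportions is tested with the
pooled-variance z statistic

    Z = (p̂₁ − p̂₂) / sqrt( p̂ (1 − p̂) (1/n₁ + 1/n₂) ),
    p̂ = (x₁ + x₂) / (n₁ + n₂),

two-sided p from the standard normal. With `continuity=True` the absolute
difference is reduced by (1/n₁ + 1/n₂)/2, floored at zero, before
standardisation — the classical correction used by R's `prop.test`. Both
variants are provided because they serve different purposes: the corrected
form is the default for batch screening (it is what the "two-sample test
for equality of proportions with continuity correction" names), while the
uncorrected form satisfies the algebraic identity Z² ≡ 2×2 Pearson
chi-square, which the tests verify numerically to 1e-9 against
`scipy.stats.chi2_contingency`. When the pooled proportion is 0 or 1 the
statistic has no variance; the result is flagged degenerate with p = 1 and
is never counted as significant. Batch mode pairs observations by mutation
across ancestry-matched population pairs, lists unpaired mutations as
skipped rather than dropping them, and applies no multiple-testing
adjustment by default (a Bonferroni option exists but is off, matching
standard practice for this kind of descriptive concordance screen).

**Cohort vs literature.** An observed (AC, AN) is tested against an
externally reported allele frequency *f* with the one-sample goodness-of-fit
chi-square on expected allele counts, e = f·AN:

    χ² = (AC − e)²/e + ((AN − AC) − (AN − e))²/(AN − e),   df = 1,

with **no** continuity correction. This choice was validated, not assumed:
the uncorrected construction reproduces every verifiable published p-value
of the reference comparison table to printed precision (0.155, 0.204,
0.967, 0.321, 0.335, 0.657, 0.0001); the Yates-corrected variant does not.
One published row (expected 0.038, observed 19/194, printed p = 0.000346)
is not reproducible under the construction that matches all other rows
(it yields ≈1.3e-5); it is treated as an inconsistency in the source and
deliberately excluded from machine assertions rather than tuned to.
Reference frequencies given as a range are evaluated at both endpoints,
yielding a p-value interval. Expected frequency exactly 0 is handled
specially: agreement (AC = 0) is an exact match with p = 1; disagreement
yields an infinite statistic reported with p = 0 and a warning flag.

## Detection-power model

The probability that a mutation with per-individual carrier rate *p* is
observed at least once among *N* exomes, when each observation of a true
carrier fails independently with probability σ, is

    D(N) = 1 − (1 − p(1 − σ))^N.

*N* counts **individuals**, not haploid exomes. This is forced by the
model's own published worked value: D = 99.95% at p = 0.001, σ = 0.01
obtains at N = 7,595 (the number of individuals in the pooled cohorts);
using 15,190 haploid exomes instead would give 99.99997%. σ is a single
per-observation false-negative probability — the published description
("error rate of exome sequencing") supports no richer model, so no
distinction is made between heterozygous and homozygous carriers and false
positives are not modelled. All evaluations go through
`n·log1p(−p(1−σ))`, so non-detection probabilities at aggregation-database
scale (≈8e-27 at N = 60,706) are exact rather than underflowed, and are
reported both as fractions and percentages. `required_n` inverts the closed
form with a ceiling plus a boundary scan to guarantee the exact-inverse
property (D(n) ≥ target, D(n−1) < target). The Monte-Carlo twin draws the
per-cohort detected-carrier count as Binomial(N, p(1−σ)) — distributionally
identical to simulating N independent observations — and is required by the
tests to agree with the closed form within three binomial standard errors.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
known truth: per individual and site, alternate dosage ~ Binomial(2, af)
(HWE sampling at the individual level, so heterozygote/homozygote structure
exists for QC testing); each true alternate allele is then dropped to
reference independently with probability σ (the same error semantics as the
power model — dropout only, no false positives); whole genotypes go missing
with probability `missing_rate`. Output is a standard VCF 4.2 with GT
(optionally DP/AD drawn around the true dosage for allele-balance QC
testing), a sample manifest TSV, and a truth JSON holding the pre-error
dosage matrix. One master seed spawns per-population substreams via
`numpy.random.SeedSequence`, so a fixed seed reproduces the cohort
byte-for-byte and population subsets are independently reproducible.
`sample_allele_counts` exposes the same generative model marginally
(AC ~ thinned binomial) without materialising files; replicate-heavy
simulation tests (type-I-error calibration at 1,000 replicates, parameter
recovery at 500 sites) use it, while the full VCF → count → estimate path
is exercised at smaller scale (60 sites × 150 individuals).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium between sites,
consanguinity/inbreeding structure, population substructure within a
labelled population, site-specific coverage variation, batch effects
between sequencing centres, and false-positive calls. Recovery of a true
allele frequency within binomial error on synthetic data demonstrates the
pipeline's arithmetic, not the calibration of any real cohort.

## Simulation sizes and numerical choices

* Type-I-error calibration: 1,000 null cohort pairs at af = 0.05 with
  2,000 alleles per cohort; the uncorrected test is required to reject at
  0.05 within 3.5 binomial standard errors, the corrected at no more.
* Parameter recovery: 500 replicate sites, 300 individuals, af = 0.1,
  σ = 0; ≥99% of sites must recover truth within 3 standard errors.
* Monte-Carlo power checks: 10,000 replicates (seconds of runtime).
* Tie grouping in rankings uses 3-significant-figure display equality;
  stored values stay full precision.
* Reciprocal rates are returned as `math.inf` for AC = 0, never a division
  error; degenerate test inputs (0 vs 0) yield flagged results, not crashes.
* Chi-square and normal tail probabilities come from `scipy.stats`;
  `statsmodels` and `scipy.stats.chi2_contingency` appear in the test suite
  only, as independent cross-checks of the hand-built statistics.

## Known limitations

* The carrier-rate convention (carrier rate = allele frequency) slightly
  understates the heterozygote fraction as af grows; use `het_frequency`
  when exactness matters, and heed the `hwe_valid` flag.
* Disease-level burden by summation ignores compound heterozygosity
  structure and allele dependence.
* Panels must carry explicit loci or rsIDs; there is no HGVS
  transcript-to-genome projection.
* No confidence intervals on allele frequencies are produced, and no
  penetrance or consanguinity adjustment is made.
* The QC read-position filter requires a field that site-level VCFs rarely
  provide; when absent the filter silently does not apply (by design, as
  every filter activates only on available evidence).
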