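# Methods

## Model and procedure

The analysis asks, pathway by pathway, whether a case cohort is enriched
for carriers of rare putative loss-of-function (pLoF) variation relative
to several comparison cohorts.

**Qualifying variants.** A variant record (one ALT allele at one site;
multi-allelic sites are decomposed before anything else) qualifies when

* its consequence class is one of stop-gain, start-loss, frameshift
  insertion, frameshift deletion, canonical splice (the ±1–2 bp
  donor/acceptor dinucleotides; extended splice-region terms map to
  `other`), and
* it is rare: population allele count AC ≤ 10 at a reference denominator
  of AN = 280,000 chromosomes. The boundary is inclusive and the
  comparison is done exactly on integers (cross-multiplied), so records
  annotated against a different AN are judged on the frequency scale
  AC/AN ≤ 10/280,000. A variant absent from the reference population is
  AC = 0 and therefore rare — pLoF alleles private to a patient are the
  signal, not missing data.

The same filter is applied to every cohort; the pipeline refuses
per-cohort overrides at config parse time, since differential filtering
between case and comparison cohorts would bias the burden directly.

**Collapsing.** Carriage is dominant and binary at both levels: sample →
gene (≥ 1 qualifying variant, dose 1 or 2 alike) and sample → pathway
(≥ 1 member gene). The sampling unit in every table is the carrier
*sample*; variant-level counting is rejected because variants within a
sample are not independent draws and would break both the Fisher
conditioning and the label-permutation exchangeability. Missing
genotypes never create carriage; an optional strict mode drops samples
whose missing-call fraction across qualifying variants exceeds a
threshold (default off, threshold 10% when enabled). An optional family
manifest triggers one-sample-per-family subsampling (case/proband
preferred, else a seeded random pick), since family-structured
comparison cohorts violate independence.

**Per-comparison Fisher test.** For pathway P and comparison cohort j,
the 2×2 table (a = case carriers, b = case non-carriers, c = cohort-j
carriers, d = cohort-j non-carriers) is tested with the exact
conditional hypergeometric upper tail (alternative `greater`;
`two_sided` available). The odds ratio reported is the sample OR
(a·d)/(b·c), with `inf`/`nan` sentinels in text output when a zero cell
makes it undefined.

**Monte Carlo vs the pooled comparisons.** All comparison cohorts are
concatenated; each of B iterations draws a pseudo-case set of size
n_case without replacement and recomputes the case carrier count. With
binary carriage and fixed subset size this count is exactly
hypergeometric, so each iteration is realized as one hypergeometric
draw — the same null, at a fraction of the cost of materializing index
permutations. The empirical p is the add-one estimator
(1 + #{draws ≥ observed})/(1 + B): strictly positive, minimum 1/(1+B).
Because the permutation null coincides with the Fisher null, the two
p-values must agree within Monte Carlo error; the run summary flags any
pathway where they differ by more than 4 standard errors as an internal
consistency alarm.

**Multiplicity and consensus.** Benjamini–Hochberg step-up across
pathways, applied within each comparison cohort and, separately, to the
Monte Carlo p-values (Bonferroni and `none` available; raw p is always
emitted). A pathway reaches consensus iff its adjusted Monte Carlo p and
its adjusted Fisher p against *every* comparison cohort are below α
(default 0.05). A primary-comparison-only mode exists behind a flag.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_pop_allele_count` | 10 | rarity cutoff (alleles) |
| `reference_allele_number` | 280,000 | denominator for the cutoff (chromosomes) |
| `allowed_consequences` | 5 pLoF classes | functional filter |
| `alpha` | 0.05 | significance threshold after adjustment |
| `multiplicity` | Benjamini–Hochberg | adjustment across pathways |
| `mc.iterations` (B) | 100,000 | permutation draws per pathway (min p 10⁻⁵) |
| `mc.adaptive_alpha` | off | early stop for clearly null pathways |
| `threads` | 1 | pathway-parallel workers |

Adaptive stopping ends iteration for a pathway once the Wilson 99% lower
bound of its empirical p exceeds 2α — only clearly non-significant
pathways stop early, so the p-resolution needed for BH on significant
pathways is never sacrificed. Reported `iterations_used` records the
actual B per pathway.

## Randomness and determinism

Every pathway's permutation stream comes from a counter-based generator
(Philox) keyed by (global seed, CRC-32 of the pathway id). Results are
therefore bit-identical across runs, across pathway orderings, and
across any number of worker threads; the run manifest records the seed,
all filter settings, input checksums and library versions, and the TSV
outputs carry the same provenance in `#` header lines (no timestamps, so
reruns are byte-identical).

## Synthetic data

The generator emulates the structure the test assumes, at study scale:

* cohort sizes default to one case cohort of 39 and comparisons of 86,
  310, 1,296, 2,990 and 385 samples;
* each (sample, gene) carriage is an independent Bernoulli draw at
  baseline rate 0.002 — chosen so a ~50-gene pathway has ≈ 10% baseline
  pathway-carrier probability, the regime where Fisher on n = 39 has
  meaningful but unsaturated power;
* a planted pathway multiplies the per-gene rate by a relative risk for
  case samples only (genes in several planted sets take the maximum);
* the default pathway collection is 200 sets of 10–100 genes drawn from
  a 2,000-gene universe;
* VCF realization writes one shared heterozygous qualifying variant per
  carried gene (consequence drawn among the five pLoF classes, POP_AC
  uniform 0–10 at POP_AN = 280,000), carriers 0/1 and everyone else 0/0;
  since collapsing is dominant, one variant per gene is equivalent to
  one per carrier and keeps files small. A decoy flag interleaves
  non-qualifying records (wrong class, or qualifying class at AC > 10)
  that the filter must remove for the round trip to be exact.

What the generator does **not** model: linkage disequilibrium between
genes, relatedness between samples, ancestry stratification, annotation
error, or per-cohort sequencing-depth differences. Passing tests
therefore demonstrate correctness of the statistical machinery under
the method's own assumptions — not robustness of the method to real
exome confounders, which is exactly the caveat that applies to the 2×2
design itself.

## Numerical choices

* Fisher upper tails are computed via the hypergeometric survival
  function; a brute-force enumeration over all tables with both margins
  ≤ 30 agrees to relative error < 10⁻¹⁰ (the test grid shows ~10⁻¹⁵).
* Rarity comparisons are integer cross-multiplications — no floating
  point at the AC = 10 boundary.
* Two-sided Fisher p delegates to scipy's exact implementation,
  including its tie handling for tables whose point probability equals
  the observed one within floating-point tolerance; the default
  one-sided path never encounters ties.
* Degenerate permutation input (all samples carriers, or none) returns
  p = 1 exactly with zero iterations consumed.
* An all-zero carrier matrix (no qualifying variants) is valid: every
  table becomes (0, n₁, 0, n₂), p = 1, and the run summary states that
  no qualifying variants were found.

## Design decisions taken where the design was open

* **Carrier counting over variant counting** (see Collapsing above).
* **Statistic = case carrier count** for the permutation test; with
  margins fixed it is equivalent to a difference in proportions and
  makes the Fisher cross-check exact.
* **Pooling for the Monte Carlo test**: the validation is explicitly
  case vs the sum of all comparison cohorts; per-cohort permutation is
  available behind the library API for symmetry with the Fisher design.
* **Global rarity cutoff**: the AC ≤ 10 rule is applied against the
  global reference AN, not per sub-population.
* **No hemizygosity logic**: dose ≥ 1 means carrier on autosomes and X
  alike.

## Problem sizes used in the shipped checks

The packaged statistical checks run the generator at its study-scale
defaults: 50 replicates (10,000 pathway-replicates) for type-I
calibration, 50 seeded replicates for power/FDR with one ~50-gene
pathway at relative risk 8, 50 random tables at B = 200,000 for
permutation/Fisher agreement, and the exhaustive ≤ 30×30 margin grid
for Fisher exactness. The acceptance script uses 20 replicates per rate
estimate.

## Known limitations

* Gene identity is by symbol string; no HGNC alias resolution.
* No covariate adjustment, ancestry correction, kinship inference, or
  recessive/compound-het models — the test is the exact 2×2 design.
* Minimum reportable Monte Carlo p is 1/(1+B); extreme tails need the
  Fisher p (which the design equates to the permutation p anyway).
* GO/KEGG release differences change the pathway universe; the pathway
  collection is whatever GMT the user supplies.
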