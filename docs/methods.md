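# Methods

## Model and conventions

A-to-I editing is observed in sequencing data as A→G mismatches on the
transcribed strand. Sites are stored as 1-based point coordinates with a
strand; on the '-' strand the genomic reference is T and editing appears
as C, and all counts are strand-adjusted to logical (A, G) at the I/O
boundary so that every downstream statistic works on a→unedited,
g→edited. BED input (0-based half-open) is converted on read; VCF-style
records must be A→G or T→C. Strand adjustment is an involution: applying
the genome↔logical mapping twice returns the original bases.

The editing level at a site is φ = g/(a+g), undefined (NaN) at zero
coverage. Replicates of a population are pooled by summing counts before
dividing — the pooled level is the coverage-weighted mean of replicate
levels, which differs from the plain mean whenever replicate depths
differ, and is the quantity all between-population statistics use.
"Overall editing" per replicate is Σg/Σ(a+g) across a site set.

## Pileup

`pileup_counts` streams a SAM/BAM once (no coordinate index required)
and assigns base calls to sites via each read's aligned pairs. Reads
flagged secondary/supplementary/unmapped/duplicate or below the mapping-
quality threshold are excluded ("uniquely mapped" in the usual pileup
sense); base calls below the base-quality threshold or within
`min_end_distance` of a read end are ignored. Defaults: base quality 25,
mapping quality 20, end distance 0 (5 is recommended for de novo
discovery, where read-end misalignment artifacts matter most). These
thresholds are explicit configuration, chosen to match common editing-
pipeline practice.

## Discovery

The variant-calling cascade keeps a position when pooled depth ≥ 20, alt
reads ≥ 3, and alt fraction ∈ [0.05, 0.95]; the upper bound removes
homozygous-SNP-like positions and an explicit SNP exclusion list takes
precedence over counts. All 12 ref→alt conversion classes are retained
so the A→G + T→C share — the standard specificity readout of an editing
screen — is computed over an honest denominator. Raising any threshold
can only remove calls (monotonicity, property-tested). Sites chain into
loci by single-linkage when adjacent same-chrom/strand sites are <100
bases apart; this equals connected components of the proximity graph and
is order-invariant.

## Inclusion rule

A site enters comparative analysis iff it reaches 20× pooled coverage in
at least 7 of 10 populations (boundaries inclusive) and, within every
covered population, the replicate level spread (max−min over covered
replicates) is at most 0.2. The spread form was chosen as the simplest
testable operationalization of "reproducible between replicates"; it is
configurable. Relaxing any field of the rule never removes a kept site.

## Differential editing

For each site and each unordered population pair with both pooled totals
≥ 20, a two-sided Fisher exact test is run on [[g₁, a₁], [g₂, a₂]]
(scipy). Multiplicity correction is applied jointly across all emitted
tests: Benjamini–Hochberg by default, with Bonferroni and uncorrected
modes available (the uncorrected mode mirrors analyses that quote raw
P < 0.05). A record is significant iff corrected p < α (0.05) and
|Δφ| > 0.20. Deltas are antisymmetric and p-values orientation-invariant
by construction. Summaries count, per population, the sites with ≥1
significantly higher (or lower) pair, and bin each site by how many
other populations differ.

## Population specificity

Per site, z-scores are computed for every covered replicate of every
population against the mean and SD of all covered replicate levels at
that site (sample SD, ddof = 1; population SD available by flag — the
choice is a convention, both exposed). Sites where the SD is below 1e-12
are skipped: every replicate sits at the mean and no outlier statement
is possible (the tolerance absorbs float rounding of identical levels).
A population is called at a site when all of its replicates have
|z| > 1.65 with a common sign and its pooled level differs from the
*nearest* other population's pooled level by ≥ 0.10 — absolute
percentage points, not relative; the nearest-population form makes ties
conservative. If two populations pass in the same direction, the one
with the larger minimum |z| is reported (at most one call per site per
direction). Raising either threshold never adds a call.

Category enrichment uses one Pearson χ² (2×2, continuity correction
optional, off by default) per annotation category: specific-set
membership vs the full tested background, matching the "X% of specific
sites vs Y% of tested sites" framing. The background is all sites
passing inclusion, not the genome.

## Isoform linkage

Sites within 40 bases chain into clusters (single-linkage, size ≥ 2);
each read spanning *all* sites of a cluster contributes one isoform
string over {A, G}, with reads carrying any other base at a cluster site
discarded. Mates of a pair are merged; on a double-covered, conflicting
site the first mate's call wins. Marginal g-fractions recomputed from
the isoform table equal the per-site levels of the same reads exactly
(asserted in tests).

The independence expectation P(isoform) = Π(pᵢ if G else 1−pᵢ) is built
from the marginals of the same spanning-read set, never from externally
reported (rounded) levels — rounded marginals are generally inconsistent
with rounded isoform fractions, so mixing them would manufacture
spurious deviations. Per-replicate observed−expected differences are
tested with a paired Student's t test; focal-population isoform usage is
compared with all other populations' replicates by Welch's t with a
10-point mean-difference gate. Under full linkage the fully-unedited and
fully-edited isoforms are overrepresented and mixed isoforms
underrepresented — provable from the comonotone construction and
asserted on constructed inputs.

Ordering inference declares "site i precedes site j" when isoforms
edited at j but not i are below a noise floor (default 2% of spanning
reads) while isoforms edited at i but not j are at or above it; the
two-sided absence (full linkage) or two-sided presence (independence)
yields no order. The floor absorbs sequencing error and rare bona fide
violations.

## Synthetic data

The generator emulates the target study design: 10 populations × 3
replicates, per-site true levels drawn Beta(0.8, 2) (skewed low, as
editing-level distributions are), planted population-specific shifts
(one population per shifted site, clipped at 0.98), coverage
negative-binomial with mean 200 and dispersion 0.1 (variance m + d·m²),
and counts beta-binomial with ρ = 0.01 so replicate spread resembles
highly reproducible biological replicates; ρ is configurable up to
strong overdispersion for robustness tests. Artifacts: SNP-like
positions at alt fraction exactly 0.5 or 1.0 (caught by the
max-alt-fraction filter or exclusion list) and non-editing conversions
(ref→alt excluding A→G and T→C) at low alt fractions, at configurable
rates relative to the number of true sites. Dense "repeat loci" place
runs of novel-style sites with <100-base gaps.

Joint isoform distributions come in four modes: independent (product of
marginals), fully linked (comonotone coupling through one latent
uniform — the maximal-linkage distribution with the given marginals),
sequential (the first site in cluster order is a prerequisite;
downstream sites are conditionally independent given it, which matches
the observed support {AAA, GAA, GGA, GAG, GGG} of prerequisite-style
clusters — a strict chain model would not), and custom tables.
`LinkageSpec.from_table` derives marginals from a table for the
rounded-published-values case. Every mode's table reproduces its
declared marginals to 1e-9, validated at construction.

All draws flow from one `numpy.random.default_rng(seed)` stream per
generator call; identical seeds give byte-identical outputs, asserted in
tests. Every generated quantity is exported by `truth_report` for
parameter-recovery assertions.

What the generator does *not* emulate: position-dependent sequencing
error, mappability and alignment artifacts, expression-linked coverage
(coverage is independent of editing level), fragment-length effects, and
allele-specific expression. Passing tests therefore demonstrate that the
statistics recover known truth under the stated sampling model, not that
the pipeline is robust to alignment pathology upstream.

## Problem sizes and numerical choices

Tests run on hundreds to a thousand sites with depths 100–2000 and read
counts up to 2×10⁴ per cluster — sizes chosen so every Monte-Carlo
assertion sits ≥3 standard errors from its threshold while the full
suite stays fast. Fisher tests are exact at any count; BH is applied
over all site×pair tests jointly. Zero-coverage levels are NaN and
propagate to skips, never to zeros. Tie-breaks: specificity gap uses the
minimal gap over other populations; equal-z duplicate calls resolve by
larger minimum |z|; cluster/locus chaining splits exactly at gap ≥
window (strict inequality keeps, as "within N bases" implies).

## Known limitations

- The inclusion rule's reproducibility criterion (max−min ≤ 0.2) is one
  reasonable operationalization; analyses sensitive to it should sweep
  the threshold.
- z-scores are computed on raw level fractions, not variance-stabilized
  (arcsine/logit) transforms; with 30 replicates and levels away from
  the boundaries the difference is small, but boundary-heavy data may
  warrant the transform.
- Isoform phasing is limited to sites reachable by one read/amplicon;
  clusters beyond four sites produce 2^k tables and a warning.
- χ² enrichment treats the specific set as part of the background
  (matching the quoted-percentage framing); for small specific sets a
  disjoint background or Fisher test would be stricter.
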