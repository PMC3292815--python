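# Methods

## Scope and intent

`nahrkit` analyses breakpoint junctions of rearrangements formed by
non-allelic homologous recombination (NAHR) between two short, highly
similar paralogous elements — the motivating case being the recurrent
t(4;18) between ~92%-identical HERV-H elements. Real junction analyses of
this kind hinge on unpublished full-length substrate sequences, so the
package pairs every analysis stage with a simulator that emits ground
truth, letting each method's recovery behaviour be measured rather than
assumed.

## Sequence simulation

**Model.** One i.i.d.-uniform ACGT ancestor of length `ancestor_length`
(default 5700 bp, matching the longer of the two HERV-H substrates)
accumulates substitutions independently on each descendant at rate
`target_divergence / 2` per site, so the pairwise divergence is
approximately the target. At the relevant divergences (~8%) multiple-hit
(Jukes–Cantor) corrections shift identity by ~0.2 percentage points
(two sites both mutated collide with probability (d/2)^2 and still differ
2/3 of the time); we ignore them, and the realized identity at 8%
divergence is ~92.2%, within the ±1-point band used everywhere.

**Indels.** Per-copy indel events at rate `indel_rate / 2` per site
(default total 0.002), geometric lengths (p = 0.5), insertion or deletion
with equal probability. The true indel process separating the 4.6-kb and
5.7-kb elements is unknown; this is a declared stand-in that exists so the
marker and resolution machinery is exercised on gapped alignments.

**Flanks** are freshly sampled unrelated sequence (default 2000 bp per
side), guaranteeing that junction alignments anchor uniquely outside the
repeat.

**Tandem-repeat alleles.** A single random unit (default 61 bp) is
inserted as 2 exact copies (allele A) vs 4 copies (allele B) at the same
locus, giving the 122-bp length polymorphism. Copies are exact; the real
arrays are near-exact, and the package's detection floor (80% copy
identity) is exercised by separate tests with mutated copies.

**Probe tracks.** Probes every `probe_spacing` bp (default 100, the
published array design's mean spacing); the altered side takes mean
−1.0 = log2(1/2) for a one-copy loss or +0.585 = log2(3/2) for a one-copy
gain in a diploid (the published figure only shows guide lines at ±1, so
the gain magnitude is this package's choice), Gaussian noise sd 0.25.

**Genotypes.** Each individual draws two alleles i.i.d. Bernoulli(freq_A).

**Randomness.** Every operation derives its generator from the single
integer seed via a named stream (`default_rng([stream, seed])`); equal
seeds give byte-identical outputs, and no global state is touched.

**What the simulator does not emulate:** retroviral internal structure
(ORFs, LTRs), mutation-rate heterogeneity along the element, gene
conversion between paralogs, array-CGH wave artefacts and dye bias, and
population structure beyond independent Bernoulli alleles. Passing
recovery tests therefore demonstrate correctness of the inference under
the stated generative model, not robustness to every artefact of real
data.

## Alignment

Exact global affine-gap alignment (Needleman–Wunsch–Gotoh) replaces the
heuristic genome-scale mapping used for discovery: inputs are single-locus
few-kb sequences, exactness permits brute-force oracle tests, and the DP
engine is Biopython's `PairwiseAligner` with a custom ACGTN matrix.
Defaults: match +1, mismatch −2, gap open −5, gap extend −1 (a length-k
gap costs open + (k−1)·extend), which prefers one contiguous gap over
split gaps at these rates. `N` matches nothing, including `N`, so
ambiguity never inflates identity. Among co-optimal alignments the first
in the engine's deterministic enumeration order is returned; this is
reproducible run-to-run, though not guaranteed to follow a particular
gap-placement preference. DP tables above 1.5e8 cells are refused with
advice to window.

Percent identity is surfaced in two modes because published identity
figures rarely state how indel columns were counted: `overall` (gap
columns count against identity) and `substitution_only` (gap columns
excluded). The ~92% figure corresponds to the overall mode on indel-free
simulations, where the modes coincide.

## PSV ladder

Every mismatched column of the paralog alignment is a substitution PSV;
every maximal one-sided gap run is a single indel PSV (a junction either
carries the inserted segment or not). Substitution PSVs within
`min_gap_distance` (default 5) columns of a gap run are flagged
low-confidence and excluded from resolution by default: columns adjacent
to gaps are unstable across co-optimal alignments. Ladder density (markers
per kb) predicts the expected ambiguity-interval width as ≈ 2/density: the
crossover lands in a marker gap chosen with probability proportional to
its length (size-biased sampling), doubling the mean gap 1/density.

## Junction resolution

The junction is globally aligned to `flank_18 + paralog_18 + flank_4`
(and, only when the ladder has 4-carried indel markers, to the paralog-4
reference as well); the flanks anchor the alignment, and each informative
marker is read through the coordinate maps. Indel markers are read by the
fraction of their footprint covered by junction bases (≥ 0.7 carries,
≤ 0.3 lacks, else `neither`).

The switch is placed at the discordance-minimizing cut over all cut points
including both ends, ties to the earliest cut. Discordance 1 sets the
gene-conversion flag; ≥ 2 labels the call `complex` — never split into
multiple crossovers. All markers one state → `non_recombinant`; fewer than
two readable markers → `unresolvable` (a result, not an exception).

A flipped (reverse-complement) junction still reads a scatter of markers
through a garbage alignment, so orientation is decided by quality: if
fewer than 70% of markers are informative or the best cut leaves more than
20% discordance, the opposite strand is tried and the better read chosen,
with `orientation_ok = False` when the flipped strand wins. The model
otherwise assumes the paralogs recombine in the same orientation.

**Intervals.** The ambiguity interval is open — it excludes the defining
markers — matching the convention of highlighting only the region where
the exchange may have occurred. Stored 0-based half-open, rendered 1-based
inclusive (`chrN:start-end`). Two adjacent flanking markers give a legal
zero-width interval (crossover localized exactly between bases). Both
parental coordinate systems are always reported.

**Recurrence and segment sizes.** "~150 bp apart" is operationalized as
midpoint-to-midpoint distance: the bundled published intervals give
exactly 150.5 bp by midpoints on both chromosomes (versus 73 bp
edge-to-edge), so midpoints are the consistent reading. Distal
derivative-segment size is `chrom_length − start_1based + 1` from the
interval's proximal edge; for the published loci either edge rounds to the
same 2-decimal Mb figure (asserted in tests). hg18 lengths for chr4
(191,273,063 bp) and chr18 (76,117,153 bp) ship as constants.

## CGH segmentation

A deliberately transparent single-changepoint model: the cut minimizing
the two-segment sum of squared errors (the Gaussian maximum-likelihood
changepoint), computed by prefix sums and checked in tests against a naive
per-cut scan. At least 4 probes are required per side. Mean difference
below `min_delta` (default 0.4 log2 units) → neutral. The altered side is
classified loss below −0.5 or gain above +0.3 — midway between 0 and the
diploid single-copy expectations. Multi-segment callers are out of scope
because each simulated arm carries exactly one event.

## Tandem repeats, PCR, genotyping

**Period scan.** For each candidate period p the sequence is compared to
itself shifted by p; exact-match runs shorter than 4 are discarded (random
sequence matches a shift at ~25% per base), surviving runs are greedily
merged while the span keeps ≥ 80% agreement, and overlapping reports
collapse to the highest-scoring (then shortest) period, which selects the
primitive unit over its multiples. Copies are reported fractionally, as
period-finders conventionally do; chance period-continuation into a flank
can extend an array by a base or two.

**In-silico PCR** finds the forward primer and the reverse primer's
reverse-complement downstream, each within `max_mismatch` (default 0),
and reports every product up to 5 kb, inclusive of both primers. Allele
classification maps band sizes to labels within ±5 bp (default assay:
326 → A, 446 → B); two matching bands call a heterozygote. Note the
published band sizes differ by 120 bp while the duplication measures
122 bp by alignment; the package reports both numbers and does not force
agreement (amplicon-boundary effects are the likely cause).

**Allele frequencies.** Counts and frequencies per population and pooled;
percentages render with half-up rounding to one decimal (so 37/198 →
18.7). Homogeneity across populations is tested by the chi-square on the
populations × alleles table (df = populations − 1 for two alleles). With
any expected count below 5 — the norm for ~12-allele panels — the
asymptotic reference is unreliable, so the p-value is computed by a seeded
permutation test; permuting alleles with fixed margins is equivalent to a
multivariate-hypergeometric draw of per-population counts, which is
sampled directly and vectorized. The add-one estimator (1+#{perm ≥ obs})/
(1+N) keeps the test valid; its measured type-I error at α = 0.05 over
2000 null panels is ~4.6% (slightly conservative from discreteness).

## Problem sizes in tests

Property-based checks run at desk scale chosen to pin the statistical
behaviour without excess runtime: crossover-recovery uses 200 simulations
of 1.2-kb paralogs with 300-bp flanks at 8% divergence (marker density and
interval-width behaviour are per-kb properties, independent of element
length); identity recovery uses a single 5-kb pair; CGH recovery uses 200
tracks of 200 probes; calibration uses 2000 null genotype panels with
1000 permutations each. Simulator defaults remain at the full 5.7-kb /
2-kb scale.

## Known limitations

- The resolver assumes one crossover between two fixed paralogs; nested or
  double crossovers are surfaced only as `complex` calls.
- Marker reading trusts a single global alignment per side; in extremely
  gap-dense regions co-optimal placements could misread markers near
  indels (mitigated, not eliminated, by the low-confidence filter).
- The period scan does not align copies, so arrays whose copies diverge
  beyond ~20% or contain indels between copies are missed.
- In-silico PCR models primer sites as (mismatch-tolerant) exact
  matches — no thermodynamics, no primer-dimer or specificity modelling.
- The genotype simulator assumes Hardy–Weinberg independence within
  populations.
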