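# Methods

## Problem and data model

A chromosome end-to-end fusion joins two deprotected termini into a
dicentric chromosome. In paired-end sequencing aligned to the unfused
reference, a fragment spanning the fusion junction produces a mate pair
whose two reads map to two different chromosomes, typically with at
least one read near a chromosome end. `telofuse` quantifies this
signature from coordinate-level alignments; read trimming and alignment
are upstream of the package, which consumes SAM/BAM in any sort order.

Coordinates are 0-based half-open throughout; SAM's 1-based POS is
converted once at parse time (pysam's convention). "Telomere" is
operationalized as the assembly end of each chromosome sequence; no
telomeric-repeat detection is attempted, so reference assemblies whose
termini are not the biological telomeres (e.g. incomplete scaffolds)
will blur the annotation. All chromosomes listed in the input table are
used; users control inclusion of organellar or short sequences by
editing the table.

## Subtelomere annotation

For window width W (default 100,000 bp) and chromosome length L the
subtelomeric intervals are [0, min(W, L)) and [max(0, L−W), L), merged
when L < 2W. The total span is S = Σ min(2W, L), the genome fraction
f = S/G. S and f are non-decreasing in W and saturate at f = 1 once
2W ≥ L for every chromosome. Intervals are exportable as 3-column BED.

## Pair scanning and the uniqueness filter

No SAM flag marks "uniquely mapped"; the package uses the standard
operational proxy: a pair passes iff both primary records are paired,
mapped with mapped mates, neither secondary nor supplementary, not
duplicate-flagged, and have MAPQ ≥ `mapq_min` (default 20, exposed on
every interface because the appropriate threshold is aligner-specific).
Duplicate-flagged records are excluded before pair collation and no
internal duplicate marking is performed.

Pairs are reconstituted by query name in a pending-mate table and
flushed when both primaries have been seen — a record does not carry its
mate's MAPQ, so the pair-level decision needs both records. Memory is
proportional to the number of unflushed pairs; counts are invariant
under any permutation of the input records. More than two primary
records under one query name is treated as corrupt input and raises.

Classification uses each mate's leftmost mapped coordinate (POS); at
W = 100 kb the window dwarfs the read length, so the choice between POS,
midpoint and 5′ end is immaterial. A pair with both mates subtelomeric
counts once toward the pair-level count k and twice toward the
mate-level count m (so k ≤ m ≤ 2k). The alignment header's @SQ
dictionary must match the chromosome table exactly; discrepancies are
reported and abort the scan, since a silently mismatched genome would
corrupt the null.

## Enrichment under the uniform-recombination null

Under the null, junction endpoints are independent uniform positions at
single-bp resolution (no binning; the null depends only on f), giving
the pair-level probability q = 1 − (1−f)² of subtelomere involvement.
Two test variants are implemented because "a hypergeometric test against
a uniform null" admits more than one parameterization, and the original
choice is not recoverable:

* **pair-binomial** (default): p = P(X ≥ k), X ~ Binomial(n, q) — the
  variant that matches pair-level counting of k;
* **mate-hypergeometric**: p = P(Y ≥ m), Y ~ Hypergeometric(G, S, 2n) —
  the literal mate-level reading, drawing 2n base-pair positions without
  replacement.

At G ≥ 10⁷ and n ≤ 10⁵ the without-replacement correction is negligible
and the two agree within an order of magnitude of log₁₀ p; both are
always reported. The binomial upper tail is computed as a log-sum-exp
over the pmf via `gammaln` because `scipy.stats.binom.logsf` returns
−inf once the linear-scale tail underflows, which happens routinely at
genome-scale counts (the motivating dataset sits near 10⁻⁴³⁷). Linear
p-values below 10⁻³⁰⁰ are reported at that documented floor with an
`underflowed` flag; `log10_p` is always exact. The effect size reported
is (k/n)/q, the observed/expected ratio.

Libraries are compared by fold enrichment (k₁/n₁)/(k₂/n₂) — undefined
when k₂ = 0, in which case the comparison test is advised instead — and
by a Pearson chi-square test on the 2×2 table (k, n−k per library),
df=1, two-sided, without Yates continuity correction by default (all
expected cells are ≫ 5 in the motivating data; the correction is
available by flag). Fisher's exact test and multiple-testing correction
are deliberately out of scope: one pre-specified test per library pair.

## Mixture estimate of the telomeric fraction

If a fraction θ of interchromosomal junctions are telomeric (both
partners within the window) and the remainder uniform, then
E[k/n] = θ + (1−θ)q, inverted as θ̂ = (k/n − q)/(1 − q) with
SE(θ̂) = SE(k/n)/(1 − q) by the delta method. θ̂ outside [0, 1] is
reported as computed — a useful diagnostic of model misfit rather than
an error.

## Synthetic libraries

The generator emits alignments directly — coordinates, flags, MAPQ and
mate fields, not basecalls — because the analysis begins at the SAM
stage. (A FASTQ emitter with random bases exists purely as an
interoperability demo and is not validated against any aligner.)

A library mixes concordant background pairs (chromosome chosen with
probability proportional to length; insert ~ Normal(mean 500, sd 50) bp
truncated at twice the 100 bp read length and clamped to the chromosome;
proper-pair FR flags) with junction-spanning discordant pairs. Junctions
are telomeric with probability θ — an end chosen uniformly among all 2C
chromosome ends, the partner among the other chromosomes' ends, each
position offset uniformly within the fusion zone D of its terminus,
echoing telomere erosion before fusion — and otherwise uniform over the
genome with distinct chromosomes enforced by redraw. D defaults to the
100 kb analysis window so truth and annotation align, but is an
independent knob for mismatch-sensitivity experiments. θ near 0.8
emulates a fusion-rich mutant (most anaphase bridges in such material
carry subtelomeric signals); θ = 0 is the uniform background used for
calibration.

When the simulator draws its own junctions, each discordant pair spans
its own junction (one junction, one pair), so subtelomere status is
independent across pairs and k is exactly binomial — the regime the
recovery and calibration checks assume. Supplying an explicit junction
list instead assigns junctions to pairs uniformly at random, which
models repeated sequencing of a few fusion events and inflates the
variance of k/n accordingly. Discordant mates are placed at the junction
coordinate minus a uniform offset within the insert, clipped to the
chromosome; at D ≫ insert the resulting edge bias in subtelomere
membership is of order insert/D (≈0.4% at defaults) and is far inside
the statistical tolerance of the recovery checks.

Every pair is recorded in a truth TSV (class, junction id and type,
junction coordinates, and the realized mate positions) whose header
records the seed; identical configuration yields byte-identical SAM and
truth output. One seeded `numpy` generator drives each library.

What the simulator does *not* model — sequencing error, basecall
quality, coverage non-uniformity, multi-mapping ambiguity, breakage–
fusion–bridge dynamics across cell generations, or rearrangements that
destroy alignability near real junctions — bounds what passing tests
show: they validate the counting and inference machinery, not the
upstream mapping process. On real data the scan is as good as the
aligner's MAPQ calibration, and counts of fusion pairs are best read as
lower bounds.

## Validation problem sizes and numerical choices

The test suite validates the chain at sizes chosen to make sampling
noise negligible relative to the tolerances while keeping the default
run fast: scanner-vs-truth exactness on 10 seeds of 10,000-pair
libraries (an exact, not statistical, check); θ recovery within 3
binomial SE for θ ∈ {0, 0.2, 0.8} across 20 seeds with 500 discordant
pairs each on a 4 × 1 Mb toy genome (f = 0.2, q = 0.36, chosen so the
null and the signal are both well away from 0); type-I error calibration
with 1,000 replicates of 1,000 null junctions, where the discrete
upper-tail test's exact size at α = 0.05 is ≈ 0.047, inside the 3–8%
acceptance band; chi-square against the closed-form 2×2 expression at
10⁻¹⁰ relative tolerance on 1,000 random tables; and the binomial tail
against exact rational enumeration for all n ≤ 20. Monte-Carlo
cross-checks of q use 10⁶ uniform position pairs and 3–4 SE bands.

## Design choices where the design was open

* Counts JSON, per-pair TSV and report JSON are schema-versioned; the
  report is a pure formatter over saved counts plus parameters, so
  regeneration is byte-identical and every printed number traces to a
  `ScanCounts` or `TestResult` field.
* Config precedence is CLI flag > YAML config file > built-in default,
  with effective parameters echoed into every output.
* The statistical core is also exposed statsmodels-style —
  `FusionEnrichment(counts, chromosomes).fit()` returns a results object
  with estimates, standard errors and a `summary()` — alongside the
  pipeline functions and CLI, since the enrichment analysis is at heart
  a small model fitted to count data.

## Known limitations

Breakpoint base-pair resolution, split-read analysis and junction
microhomology are out of scope; the package counts pair-level evidence
only. Terminal-window annotation assumes chromosome-scale assemblies.
The hypergeometric variant treats 2n mate positions as independent
draws, ignoring the correlation between mates of the same pair; that is
why the pair-binomial variant is the default and both are reported.
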