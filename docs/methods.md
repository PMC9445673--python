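# Methods

## The unit of evidence

A profile is one contrast (mutant or treatment vs its control) reduced to a
set of direction-binarized DEG calls: gene, sign, optional fold-change. The
deliberate information loss — discarding magnitudes — is what makes profiles
from different platforms, labs and DEG pipelines commensurable; the cost is
that the consensus cannot rank genes by effect size, only by reproducibility.
Gene identifiers are normalized to the AGI locus (uppercase, transcript
suffix stripped) because the locus is the unit that survives probe-set and
annotation differences across arrays. Nonstandard IDs are kept and warned
about rather than dropped, since external collections sometimes carry them.

Within one profile a gene may arrive with conflicting signs (merged
probe-level rows). One signed state per gene per profile is required, so the
larger |fold-change| wins; with no magnitudes or a tie, the gene is dropped
from that profile with a warning — ambiguous evidence should not vote.

## Timing classes

Treatment durations are binned as short (0, 3] h, medium (3, 24) h, long
[24, ∞) h. The boundaries are configurable (`TimingBounds`); the defaults
put 3 h in *short* and 24 h in *long*, reconciling the conventional
0.5–3 h / 3–23 h / ≥24 h description of the three regimes. Class counts are
always derived from the manifest, never asserted: the short/long profile
counts of any particular dataset are a property of its metadata.

## Consensus footprints

For a timing class, membership requires support ≥ `min_profiles` (defaults:
5 early, 4 late) **and** distinct-study support ≥ `min_studies` (default 4).
Study support counts distinct studies among the *supporting profiles of that
class only* — a gene's appearances at other timings do not count. Thresholds
are absolute counts; a fractional convenience (`ConsensusConfig.from_fraction`)
rounds up.

Direction policy defaults to `any`: presence counts regardless of sign,
because the presence/absence encoding of the underlying evidence matrices is
unsigned and requiring sign agreement is a stronger assumption than the
method itself makes. Per-gene direction consistency (max(n_up, n_down)/support)
is always computed and reported, and `majority-consistent` /
`strict-consistent` policies are available for sensitivity analysis.

Membership is a per-gene predicate on counts, so the footprint is
deterministic and invariant to gene/profile permutations, and monotone:
tightening any threshold can only shrink it. These invariants are property-
tested, and membership is cross-checked against an exhaustive brute-force
scan on random matrices.

## Set comparisons

Venn partitions are exact membership-signature partitions for 2–6 sets (2^k−1
regions; beyond 6 sets only pairwise overlap summaries are produced, to avoid
the 2^k report explosion). Overlap percentages are rounded half-even to one
decimal **with the raw fraction always alongside**: published percentages in
this literature are ambiguous about rounding and denominators (e.g. a printed
82.1% where the counts give 82.18%), and the raw fraction removes the
ambiguity.

## Over-representation

One-sided upper-tail hypergeometric p-values per category (scipy's
log-space survival function; the degenerate whole-support case returns 1
exactly), Benjamini–Yekutieli adjustment across categories (statsmodels
step-up; cross-checked in tests against a hand-applied definition and the
BH lower bound). BY rather than BH because annotation categories overlap
heavily, violating BH's independence/PRDS assumptions; the harmonic-factor
penalty is the price of validity under arbitrary dependence.

The background universe is explicit. It defaults to the union of the
collection's categories; a whole-genome list can be supplied instead, and
query and categories are restricted to it before any counting, because
mixing universes silently is the classic way enrichment analyses go wrong.
Normed frequency is (k/n)/(K/N) — query frequency over background frequency,
1 meaning no enrichment. Bootstrap standard deviations some web tools attach
to this score are not computed.

## qPCR quantities

Standard-curve efficiency uses E = (10^(1/|a|) − 1)·100 with `a` the slope of
Ct vs log10 template. The magnitude is used so either sign convention for the
(conventionally negative) slope yields the positive efficiency; a = −3.32
gives 100%. The Pfaffl ratio uses base (1 + E/100) per gene and
ΔCt = Ct(calibrator) − Ct(sample), so higher expression than the calibrator
gives Er > 1, and the calibrator evaluates to exactly 1 under any efficiency
pair. With both efficiencies at 100% the ratio reduces exactly to 2^−ΔΔCt.

`relative_expression_table` computes per-replicate ratios against the
replicate-mean calibrator Ct by default (replicate-paired calibration is
available behind a flag; pairing is only meaningful when replicates are
physically paired across conditions, which the mean mode does not assume).
SEM is reported with n−1 degrees of freedom and is *absent* (NaN), not zero,
for a single replicate. Reference-gene choice is an input; reference-gene
selection algorithms are out of scope, as are significance tests on Er.

## Synthetic data

The generator's default fixture mirrors the shape of the motivating
meta-analysis: 21 profiles from 7 studies, timing split 9 short / 1 medium /
11 long, per-profile DEG counts log-uniform in [4, 6266] over a 25,000-gene
genome (the scale of the Arabidopsis protein-coding annotation), a planted
early footprint of 100 genes (support uniform in [5, 9] short profiles from
≥4 studies), a planted late footprint of 85 genes (support in [4, 11]), 6
genes shared between them, and 90% per-placement direction consistency.
Planted genes are placed into exactly their planned profiles; background
DEGs are sampled uniformly without replacement from the non-planted genes —
the simplest null consistent with vote counting. A hot-gene propensity
option reweights background sampling to stress-test false-positive
footprints. When a near-saturated profile exhausts the non-planted pool,
sampling spills into genes planted elsewhere; this only adds support to
already-planted genes and is recorded nowhere else.

Annotation planting follows overlap = min(n, K, round(fold · nK/N)) — `fold`
times the null expectation, capped at feasibility; the defaults plant a
GO-scale category (K = 2000 at 5×) and a sharper one (K = 500 at 8×) over 30
null fillers of 200 genes. Ct tables are generated as
Ct = baseline − log_b(expression) + N(0, sd) with sd = 0.2 cycles and 3
replicates by default — a tight but realistic technical-replicate spread.

Determinism: one integer-indexed RNG stream per profile plus separate
planning streams, all derived from (seed, stream index), so results are
reproducible across platforms and adding profiles does not perturb existing
draws.

What the simulation does *not* emulate: expression magnitudes, gene-gene
correlation within profiles, platform-specific coverage (every profile can
in principle call any gene), or annotation hierarchies. Passing tests on
synthetic data therefore demonstrate correctness of the counting, set and
statistical machinery under a known model — not robustness to correlated
DEG calls or biased gene coverage in real compendia.

## Numerical and design notes

- Hypergeometric tails: exact agreement with rational enumeration is tested
  for all universes N ≤ 12; whole-support calls short-circuit to 1.0.
- Enrichment results sort by adjusted p with stable name tie-breaks, so
  output order is deterministic.
- Problem sizes in the test and acceptance runs (20-seed recovery sweeps,
  500-replicate null calibration at 2,000-gene background, 1,000 random
  oracle matrices) were chosen to keep the full suite around ten seconds
  while leaving Monte-Carlo error well below the tested tolerances.
- The pipeline runner never hard-codes expected counts; reproducing a
  published analysis is a matter of configuration (thresholds 5/4 and 4/4
  ship as defaults for the early/late classes).

## Known limitations

- Vote counting has no notion of study quality or profile size; a tiny
  profile votes like a 6,000-DEG profile. The per-gene support table is the
  transparency mechanism, not a weighting scheme.
- Ortholog handling is a join against a user-supplied two-column table;
  no ortholog inference is performed.
- Depletion testing exists behind a flag but multi-tail reporting, GSEA-style
  ranked enrichment and topology-aware GO methods are out of scope.
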