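# Methods

## The array model

A satellite locus is represented as a linear sequence of non-overlapping
annotated units on a single contig: repeat monomers (left, right, variant,
truncated), TE islands, a proximal simple-satellite flank and a distal TE
block. Coordinates are 0-based half-open throughout; BED is read natively
and RepeatMasker `.out` (1-based inclusive, `C` for reverse strand) is
converted on input. Overlapping annotations are rejected rather than
merged: every downstream quantity (copy totals, deletion arithmetic,
simulation) assumes a linear unit order, and silently resolving overlaps
would corrupt counts without any record of the decision.

### Repeat classification

Alignment hits of a monomer consensus against the locus are classified by
three thresholds applied in a fixed precedence:

1. alignment length < 90 bp → **truncated** (structural; a short perfect
   match is still a truncated unit);
2. percent identity < 90% or bitscore ratio < 0.7 → **variant**;
3. otherwise **left** or **right** by query label.

The bitscore ratio divides the hit's bitscore by that of a perfect
self-alignment of the consensus. When no empirical self-alignment score is
supplied, it is approximated with the ungapped Karlin–Altschul formula
`(λL − ln K)/ln 2` under default blastn scoring (λ = 1.28, K = 0.46,
match reward +1); for a 120-bp monomer this gives ≈ 155 bits. A raw-score
threshold of 0.7 would be meaningless, and the ratio form matches common
repeat-curation practice; both the denominator and all three thresholds
are keyword parameters. Sub-threshold hits become variants rather than
being dropped, because array copy totals in this field count variant and
truncated units as repeats.

### Copy-number statistics

`percent_change(parent, subline) = 100·(subline − parent)/parent`; the
sign convention (negative = deletion) follows directly. qPCR relative
abundance uses ΔΔCt with an assumed amplification efficiency of 2.0 per
cycle and the parent strain as calibrator; efficiency is a parameter since
real primer pairs rarely amplify at exactly 2×.

## Guide-site search

The search is exhaustive: every placement on both strands is scored, with
mismatches counted only in the protospacer and the PAM required to match
exactly under IUPAC degeneracy. An `N` in the subject sequence matches
nothing (an undetermined base is never evidence of a target site). The cut
is blunt, 3 bp 5′ of the PAM — standard SpCas9 geometry — and minus-strand
sites are projected onto plus-strand coordinates so that cut positions
from both strands live on one axis, which the simulator requires. The scan
is vectorized (per-position boolean tables accumulated across the
protospacer), so a 50-kb locus scans in milliseconds; an independent
character-by-character oracle in the test suite checks exact equality of
results at mismatch tolerances 0–3.

Site clustering is single-linkage on cut positions with a user-set gap
threshold: clusters are maximal runs whose consecutive cuts are within the
gap. Nothing more elaborate is warranted — the quantity that matters
downstream is the span between a cluster's extreme cuts.

## The editing simulator

The simulator is a hypothesis-exploration tool for multi-cut repair, not
an estimator of cleavage efficiencies. Per replicate: each target site is
cleaved independently with probability *p* (scalar or per-site); fewer
than two cuts leaves the array untouched; otherwise one of three explicit
repair rules decides the deleted span(s):

- **adjacent-join** (default): each segment between consecutive cuts is
  lost independently with probability ½, then ends religate. With
  clustered sites this reproduces discrete allele-size classes.
- **outermost-join**: everything between the first and last cut is lost —
  the maximal deletion the site layout allows.
- **random-pair-join**: one pair of distinct cut positions, uniform over
  pairs, bounds the loss.

Repair is perfect at the junction: no indels are modeled, so a
cleaved-then-religated site is restored. Consequently target-site survival
is geometric — a site survives iff its protospacer+PAM footprint avoids
every deleted interval — and a junction formed by two cuts at the same
in-protospacer offset reconstitutes one hybrid site, which is visible in
the worked example (1 of 29 sites "survives" a complete inter-cluster
deletion). Units spanning a cut are clipped; clipped repeat units shorter
than 90 bp are reclassified as truncated (still counted as repeats,
mirroring the classification rules). An optional recombination pathway
replaces the chosen inter-cut span with the homolog's span between its own
outermost cuts, modeling a single crossover at the locus; this is
unit-level only (the outcome's base-level sequence is not reconstructed).
An optional logistic lethality in the number of cuts (off by default)
models the failure to recover progeny under cleavage overload.

For ≤ 10 sites the exact outcome distribution is obtained in the tests by
enumerating all 2^n cleaved subsets; simulation frequencies at 10,000
replicates are required to sit within three binomial standard errors of
every enumerated probability.

## Breakpoint inference

Filtering keeps records with QUAL strictly above 30 and total depth inside
the inclusive 25–75% quantile band of the input set, with quantiles by
linear interpolation (numpy type 7). Both the band and the quantile
definition are parameters — the band is data-dependent, so refiltering
survivors shifts it unless the caller freezes the bounds, and the tests
document that behavior.

Per-site state is a total function of the AD ratio `alt/(ref+alt)`:
alternate ≥ 0.9, reference ≤ 0.1, heterozygous in [0.3, 0.7], uncertain in
the open gaps or when ref+alt = 0. Sites are tallied in non-overlapping
50-kb windows tiling the contig from zero.

Window labeling uses the dominant state fraction among classified sites
(threshold 0.9), not the alternate frequency alone: heterozygous and
reference windows both have alternate frequency near zero and are only
separable by their heterozygous-site content. Windows below the purity
threshold — including tract-transition windows, which are mixtures — are
ambiguous and act as gaps. Maximal runs of ≥ 2 identically labeled windows
are found; a breakpoint is emitted between consecutive runs of differing
state. The interval is then refined at site resolution: over the
classified sites between the facing run windows, the switch point is
placed where (left-state sites before) + (right-state sites after) is
maximal, with ties widening the interval. This refinement is what keeps
the call within one window of the true boundary when an ambiguous window
abuts the transition; run-boundary midpoints alone do not.

Multiallelic VCF records contribute only their first alternate allele
(counted and warned). A summed-depth window frequency (Σalt/Σ(ref+alt)) is
available through the window summaries' tallies but the site-count form is
the default.

## Drive statistics

`k_raw = n_SD/(n_SD + n_+)` from the male cross. The reciprocal female
cross transmits Mendelianly, so its SD:+ ratio *v* estimates the relative
viability of SD-bearing offspring; the correction rescales the male SD
count by 1/v: `k_corr = (n_SD/v)/(n_SD/v + n_+)`. The alternative
parameterization (rescaling n_+ by v) is algebraically identical here. At
v = 1 the correction is the identity; k is always in [0, 1], monotone in
n_SD and in 1/v. Confidence intervals are Clopper–Pearson on the raw
counts — exact, conservative, and reported uncorrected because the
correction is a point rescaling without a propagated error model.

Fisher's exact test is computed by direct summation of hypergeometric
probabilities ≤ the observed table's (probability-mass two-sidedness, with
a 1e-10 relative guard for floating ties). The rule is stated because the
doubling alternative gives different p-values; the implementation is
checked against exact rational-arithmetic enumeration to 1e-12 and against
an independent library implementation.

## Synthetic data

The generators define the study conditions for every test:

- **Arrays**: left/right consensus monomers of 120 bp (generated from the
  seed — no public consensus sequence is bundled), tandem dimers with
  per-base substitution at 2% (15% for a 10% "variant" subset), 3%
  truncation to 20–89 bp, two TE islands, a 500-bp AAGAG proximal flank
  and a 1-kb random distal block. Truth classes are assigned by the same
  length/identity rules the classifier applies, so generator truth and
  rule application are mutually consistent by construction — the tests
  verify this by recomputing identities from the emitted sequence.
  Guide sites can be planted at recorded positions; accidental extra
  matches of a 20-mer in random sequence are vanishingly improbable, and
  the tests assert exact recovery.
- **Variant tables**: Poisson site placement (2 sites/kb default), total
  depth negative-binomial (mean 40, dispersion 10) so the quantile filter
  removes a realistic tail, alt depth binomial with success probability
  2% / 50% / 98% for reference / heterozygous / alternate tracts, QUAL
  normal (45 ± 6) so a small fraction fails the quality filter, and
  optional per-site state misassignment (noise). Truth breakpoints are the
  tract boundaries.
- **Cross counts**: male-cross SD offspring are binomial with
  `p = kv/(kv + (1−k))` — transmission at rate k thinned by viability v —
  and the reciprocal cross is binomial with `p = v/(1+v)`. Parameter
  recovery (1,000 crosses of 200 offspring at k = 0.8, v = 0.9) is part of
  the acceptance suite.

What the generators do not emulate: read-level errors and mapping bias
(depths and AD ratios are drawn directly, not from reads), TE sequence
realism, indel variation, linked-site correlation along reads, and
segmental structure beyond single-crossover recombination. Passing tests
therefore demonstrate correctness of the inference procedures under their
stated statistical assumptions, not robustness to alignment artifacts in
real long-read data.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes — 2–3-Mb synthetic
contigs, 50-kb windows, 10,000 simulator replicates, 1,000 crosses, 100 ×
50-kb guide-search sequences — chosen so the full suite completes in well
under a minute per property while keeping every statistical check at ≥ 20
seeds or ≥ 3-standard-error resolution. All randomness flows through
`numpy.random.default_rng` seeded per generator call; no global state is
touched, and identical seeds reproduce byte-identical outputs.

## Known limitations

- The bitscore-ratio denominator is analytic unless a measured
  self-alignment score is given; for non-default aligner scoring the
  default λ and K are wrong and should be overridden.
- Breakpoint calls assume one sample and biallelic sites; phasing,
  multi-sample joint calling and indel realignment are out of scope.
- The simulator's independence assumptions (per-site cleavage, per-segment
  repair choice) are the simplest model that produces the observed
  discrete outcome classes; real repair-pair choice is unknown.
- The viability correction treats v as estimated without error; with small
  reciprocal crosses the corrected k inherits that noise unquantified.
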