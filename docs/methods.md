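# Methods

## The problem

Endogenous viral elements (EVEs) are fragments of viral genomes integrated
into a host germline and inherited vertically. In *Aedes* mosquitoes,
flavivirus-derived EVEs appear as clusters of short alignment fragments
scattered over a few genomic regions. The central inferential question is
how many *historical insertion events* produced the observed fragments: a
long viral sequence that integrates once and is subsequently eroded by
internal deletions and shuffled by segmental duplication leaves a
characteristic signature, and `evechain` turns that signature into an
explicit grouping algorithm.

## Gap-consistency chaining

For two fragments `a`, `b` on one host contig, the gap pair is

    g_v = max(a.v_start, b.v_start) − min(a.v_end, b.v_end)
    g_h = max(a.h_lo,   b.h_lo)   − min(a.h_hi,   b.h_hi)

i.e. the distance between the nearest interval ends on the viral and the
host coordinate system (negative values encode overlap). If both fragments
descend from one insertion and the intervening sequence merely decayed
beyond recognition, the two distances should be nearly equal; if the
intervening host sequence was instead inserted later (e.g. a transposon),
`g_h` inflates while `g_v` does not.

Host-adjacent fragments are linked when

1. they share an orientation under which viral order matches host order,
2. `0 < g_v ≤ 5000` and `0 ≤ g_h ≤ 5000`, and
3. `|g_v − g_h| ≤ max(300, 0.5 · max(g_v, g_h))`.

The absolute tolerance (300 bp) and relative tolerance (0.5) were
calibrated on the curated AaegL5 worked example: the largest discrepancy
among chained pairs there is 243 bp, while pairs that must not link
(cross-region, cross-chromosome, or order-discordant) fail by orders of
magnitude. The 5 kbp cap keeps a chain from jumping across unrelated loci.

## Clustering and duplicates

Chains and leftover singletons are merged by union–find (index-ordered
union, so the result is independent of input order): two units join when
some member pair overlaps by more than 50 bp on the *viral* genome and —
when sequence identity is available — shares more than 94% identity over
the overlap. When no sequences are given (the coordinates-only mode used
for the worked example), same-region viral overlap alone stands in for the
identity test; this proxy is justified by the empirical bimodality of
pairwise identities (fragments within a region align at >94%, everything
else below 85%), and clustering never crosses region boundaries in this
step. Pairs at ≥99% identity with full mutual coverage are additionally
flagged as candidate segmental duplicates; the flag is reported, not acted
on, because duplication versus independent re-insertion of a similar virus
is an interpretive call.

Events whose viral spans abut within 50 bp (no overlap) and share a virus
can finally be merged, but only when small-RNA orientation evidence marks
the pair consistent — both blocks showing the piRNA bias expected
*antisense* to their respective element strands — or when the caller
explicitly allows unevidenced merges. Pairwise identity itself is computed
with Biopython's local aligner under megablast-like scores
(+2/−3, gap open −5, extend −2), identity = matches / alignment columns.

## Hit filtering and regions

Upstream of chaining, a raw hit table is reduced by a two-stage cascade:
an e-value cut-off (default 0.001) and a corroboration stage that keeps a
hit only if its host footprint overlaps hits from at least 2 distinct
viral accessions — independent viruses aligning over the same locus being
the signature of a genuine EVE rather than a spurious local match. Each
stage's discard count is reported. Retained footprints are merged
single-linkage into regions at 100 kbp (bridges the 56 kbp separation
inside one curated region while keeping loci ~8 Mbp apart distinct), and
each region's representative accession is the one covering the most
non-redundant host bases (ties break lexicographically).

## Cohort profiling

* **QC**: a sample passes when ≥90% of the organellar genome is covered at
  ≥1×. The threshold separates failed libraries (~35% in the motivating
  data) from good ones (>96%) with margin on both sides.
* **Presence**: cell (e, s) of the presence matrix is the fraction of
  element e's bases covered at ≥5× in sample s; an element is called
  present at breadth ≥0.99 (the 1% slack tolerates edge effects). Raising
  the depth threshold can only lower cells (monotonicity is tested).
* **Conservation summary**: exact counts of samples carrying the full
  element complement and per-element missing counts; heterogeneity is the
  mean pairwise Jaccard distance between sample presence vectors (0 =
  identical carriage, →1 = disjoint).
* **Embedding**: t-SNE (perplexity 5, 1000 iterations, fixed seed) of
  coverage profiles, reported together with the silhouette score of
  integration-event labels — a number for the qualitative claim that
  fragments cluster by event.

## Variant density

Per (region, sample): variants are counted *unfiltered* — deliberately, to
match the upstream calling convention; users expecting a quality filter
should apply one before input. A combination is masked when <85% of the
region is covered at ≥1× (uncovered bases cannot yield variants and would
bias density downward). Density is count/length × 1000. The source
material states the mask two ways (<25% uncovered versus <85% covered,
i.e. <15% uncovered); the 85% figure is the default and both are
config-exposed. Ratios to a baseline locus (e.g. mitochondrial *cox1*)
pool unmasked counts and lengths across samples before dividing.

## piRNA strand bias

Reads of 25–29 nt are binned by 5′ coordinate into 500 bp windows;
each window reports n_forward / n_total. The windowing and the 0.8
dominance threshold for calling a block sense-/antisense-dominant are not
dictated by any published value; they were chosen for stability at the
read densities the simulator produces and are config-exposed.

## The simulator

`simulate` generates every input with known truth: i.i.d. host (GC 0.38)
and viral (GC 0.49, 11 kbp) sequences; per event a contiguous viral slice
(default 8 kbp) inserted at sites ≥150 kbp apart, fragmented by internal
deletions (200–1500 bp) whose host-side spacer length is the viral gap
plus N(0, 50) jitter — reproducing the near-equal gap pairs; optional
duplication of one fragment to a nearby locus (5–40 kbp) with 1% extra
divergence; substitution-only decay at 30% divergence. Substitution-only
decay keeps coordinate truth exact; indel decay is a possible extension.
The hit emitter produces one hit per surviving fragment per supporting
accession (default 3, emulating related viruses covering the same locus)
plus isolated single-accession decoys that the support filter should
remove.

The cohort layer draws one negative-binomial depth (mean 20, dispersion
10) per present fragment and sample, applied across the fragment with
5–10× inflated flanks (transposon-dense borders); dropped fragments get
depth 0. Depth is deliberately constant within a fragment: real coverage
varies between libraries and loci far more than base-to-base, and per-base
noise would only blur the presence truth the recovery tests score against.
Dropout acts at two levels — whole event per sample and individual
fragment — with presets for a conserved cohort (2% fragment, 1% event) and
a patchy cohort (40% fragment, 15% event). Variants arrive Poisson at a
per-kbp rate; small-RNA reads cover each event's span with an 85%
antisense bias at lengths 25–29 nt.

What the simulator does **not** emulate: read-level sequencing (no FASTQ,
no mapping ambiguity between duplicated fragments — so it cannot probe the
real concern that SNPs in duplicates may be mis-mapping artefacts),
transposon sequence content (only flank-depth inflation), indel decay
inside fragments, and GC-driven coverage bias. Passing recovery tests
therefore demonstrate the *algorithms* are correct under the stated decay
model, not that the thresholds are optimal for any particular real
dataset.

## Numerical choices and problem sizes

Ties in event numbering resolve by (chromosome, leftmost host coordinate);
union–find unions by smaller index, making partitions order-independent
(tested by permutation). Degenerate inputs: empty hit files parse to empty
lists; a zero-length region is an error; a single sample cannot have a
heterogeneity score; perplexity must be below the row count.

Stochastic validation runs at deliberately modest sizes — 1.5 Mbp hosts
for the 100-seed event-count recovery, a shared 0.5 Mbp three-event truth
for the cohort, variant-rate (200 seeds) and strand-bias checks — sizes at
which every probabilistic assertion has comfortable margins while the full
suite stays fast.

## Known limitations

Chaining assumes fragments of one event retain a single shared orientation
per region; inversions within an insertion would break a chain (they would
still usually cluster via viral overlap). The coordinates-only identity
proxy cannot distinguish a genuine duplicate from an independent insertion
of a near-identical virus inside the same region. Region-level statistics
inherit the difference (not inclusive-span) length convention of the
curated tables, which undercounts each interval by one base.
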