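# Methods

This note records the models, parameter choices and numerical conventions
behind `fourc`, and what the simulation-based tests do and do not
demonstrate about real 4C-seq data.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention); 1-based
inclusive coordinates appear only at I/O boundaries and are converted there
(`fourc.intervals.from_one_based`). Fragment membership in any region —
domains, masks, asymmetry sides, region summaries — is decided by the
fragment midpoint, one rule used consistently across modules.

## Restriction fragments

The primary digest (NlaIII, `CATG`) defines the fragment coordinate system.
Cuts are placed after the last motif base on the forward strand (`CATG^`);
both motifs are palindromic so forward-strand scanning is complete, and any
fixed cut convention is equivalent for fragment-level counting. Fragments
without a fully contained secondary-enzyme site (DpnII, `GATC`) are flagged
blind but not removed; a motif straddling a fragment boundary counts for
neither fragment. `N` runs never match, which produces long fragments in
assembly gaps — the low-mappability exclusion mask is the intended remedy.
Reads are assigned to the fragment containing their 5′-most aligned
coordinate, regardless of strand; per-fragment-end counting would be a
refinement, not implemented.

## Profile pipeline

Order of operations: count → RPM-normalize → mask → smooth. RPM
normalization divides by the viewpoint-chromosome total (including
viewpoint-proximal reads; the 10-kb exclusion is applied afterwards, so it
affects masks and summary statistics, not the denominator) and multiplies by
10⁶. The viewpoint mask removes fragments whose midpoint lies within a
10 kb radius of the viewpoint fragment's midpoint — self-ligation and
undigested-template artifacts concentrate there. Smoothing is a running
mean over 11 adjacent fragments, centered, truncated at chromosome ends (no
padding), with masked fragments excluded from both numerator and
denominator so that artifactual zeros (low mappability) do not drag the
local mean down. Demultiplexing requires an exact, mutually prefix-free 5′
tag match with no mismatch tolerance, which keeps assignment deterministic.

## Segmentation and domain calling

Segmentation operates on log2(smoothed + 1): 4C signal spans orders of
magnitude and least-squares segmentation assumes roughly homogeneous
variance. Masked fragments are dropped, not interpolated — interpolation
would fabricate signal inside mappability gaps — and domain intervals are
reported in the genomic coordinates of the retained fragments.

`fit_piecewise_constant` is an exact O(k·n²) dynamic program over a
prefix-sum cost matrix; it returns the globally SSE-optimal k-partition,
with ties resolved toward the leftmost changepoints (first-minimum argmin at
every stage). The number of segments minimizes
`n·log((SSE(k)+ε)/n) + λ·k·log n` with ε = 1e-12 guarding noiseless
signals, λ = 2 and k_max = 12 by default; ties go to the smaller k.

The primary interaction domain is the maximal run of contiguous segments
containing the viewpoint whose mean smoothed signal (linear scale) exceeds
`threshold_factor` (default 3) times the background, defined as the median
smoothed signal over unmasked fragments farther than 1 Mb from the
viewpoint. On chromosomes too short for that window (fewer than 20 distal
fragments — including the 1 Mb simulated locus), the farthest quartile of
unmasked fragments stands in. If no segment at the viewpoint clears the
threshold, the viewpoint's own segment is returned flagged low-confidence.
Since the viewpoint fragment is itself always masked, the domain anchors at
the nearest retained fragment.

**Edge localization.** A running mean spreads the step at a true domain
boundary into a ramp of window width; segments straddling the ramp, and
near-boundary cross-domain signal sitting just above 3× background, can
drag the qualifying run several fragments outward. Both artifacts are
positional, not structural: the unsmoothed profile still carries the sharp
step, whose height at matched distance is log2(β/γ) ≈ 4.6 — larger than any
other local feature, including enhancer peaks. Each domain edge is
therefore re-localized where the difference between the mean log signal of
the 4 fragments inside and the 4 outside a candidate boundary is maximal,
searching from the viewpoint anchor to 14 fragments beyond the provisional
edge. This two-stage scheme (smoothed segmentation for detection, raw
signal for localization) recovers planted boundaries exactly in the
low-noise limit, which pure segment-edge reporting cannot do. It can be
disabled (`refine=False`) to obtain the raw segment-run edges.

## Topology statistics

The transition zone between two domains is their intersection when they
overlap with Jaccard below 0.5, the inter-domain gap when disjoint, and
"merged" at Jaccard ≥ 0.5 — the cutoff separates the narrow physiological
overlap (tens of kb against domains of hundreds of kb, Jaccard ≈ 0.03) from
wholesale fusion after TZ deletion (Jaccard near 1); any value well between
those regimes behaves identically. Cumulative asymmetry sums normalized
signal in (radius, d] on each side of the viewpoint; ratios are reported as
log2((right+ε)/(left+ε)) with ε = 1 RPM to guard one-sided profiles.
Region summaries report percentages of normalized unmasked signal over a
named partition (default: a focus segment plus 400-kb flanks) and are
invariant under uniform rescaling.

## The generative model

The simulator's mandate is to reproduce the qualitative features of a
two-domain locus — elevated in-domain contacts that stop almost abruptly at
the TZ, a TZ contacting both flanks (an interaction sink), tissue-specific
enhancer peaks, power-law decay, overdispersed counts — not polymer
physics. Expected intensity is `(1+d)⁻α·D·E` (d in kb): α = 1 is the
canonical contact-decay exponent at sub-Mb scales; β = 5 vs γ = 0.2 gives a
25-fold in/out contrast, matching the visual sharpness of real profiles;
τ = 2 makes the TZ contact both sides at roughly in-domain strength;
enhancer peaks are Gaussian (σ = 5 kb, amplitude 3) and active only in
their tissue. Counts are one multinomial draw of the library (10⁶ reads)
over fragments with weights μ·Gamma(1/φ, φ), φ = 0.1 — so the total equals
the library size exactly while per-fragment counts are overdispersed
(a fixed-depth analogue of independent negative binomials).

The default geometry places a 20-kb TZ at 480–500 kb of a 1 Mb chromosome,
domains bounded at 140 kb and 840 kb (the "adjacent TADs"), viewpoints at
320 kb and 620 kb (300 kb apart, straddling the TZ, mirroring two gene
promoters), a heart enhancer at 530 kb between the TZ and the second
viewpoint, and ~3 kb mean fragments (exponential lengths, 50 bp minimum;
5% blind). Engineered alleles lift the structural elements and re-derive
domain membership from the lifted TZ — deleting the TZ yields one merged
domain spanning both outer limits; domains are consequences of TZ position,
not liftable objects themselves. The optional sequence realization uses an
{A, C} filler alphabet (which cannot form either motif) with `CATG` planted
at boundaries and `GATC` inside non-blind fragments, so digestion
round-trips bit-exactly.

**What passing tests do not show.** The simulator has no trans
chromosomes, no PCR duplicates, no mappability structure beyond an optional
mask, no fragment-end bias, and a single global decay exponent; boundary
recovery within ±3 fragments on these data therefore demonstrates
correctness of the pipeline and identifiability under the stated model, not
expected accuracy on real libraries, where segmentation settings interact
with unmodeled noise.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed or generator; fixed seeds
reproduce results bit-exactly. The standard verification runs use: 200
random vectors (n ≤ 30, k ≤ 4) for the exhaustive segmentation oracle; 100
replicates of the default locus for boundary recovery; 10⁴ positions per
allele type for liftover round trips; and full 10⁶-read libraries for the
read-level round trip. The complete suite plus the acceptance script run in
about a minute on one CPU.

## Known limitations

Single-event alleles only (no nested or overlapping events, no
translocations); per-fragment rather than per-fragment-end counting; no
statistical testing of differential contacts between conditions; domain
boundary uncertainty is not quantified. The segmentation settings of
published analyses are rarely reported, so coordinates called here on real
data should be treated as reproducible under *these* documented settings
rather than as re-derivations of any published table.
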