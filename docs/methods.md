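# Methods

This note documents the models, conventions and parameter choices behind
`nickedit`, and what the synthetic-data validation does and does not show.

## Coordinates and guide geometry

All coordinates are 0-based, half-open; cut and nick sites are
*between-base* integers, which removes every ±1 ambiguity in deletion
spans: the clean inter-nick excision removes exactly `seq[n1:n2]`.

A guide is (protospacer, PAM, strand, start). The D10A nick is placed
`nick_offset` nucleotides 5′ of the PAM-proximal protospacer end on the
protospacer strand (plus strand: `start + L − offset`; minus strand:
`start + offset`). The default offset is 3, the canonical Cas9 scissile
position; it is configurable because for SaCas9 the exact offset is a
convention rather than a measured constant. Orientation is derived, never
user-asserted: opposite strands with the minus-strand guide leftmost is
PAM-out; the reverse is PAM-in; equal strands are tandem. For D10A pairs,
PAM-out yields 5′ overhangs of length equal to the nick-to-nick distance,
PAM-in yields 3′ overhangs, tandem pairs nick one strand only (no DSB,
warned). The inter-guide distance is defined nick-to-nick; the protospacer
inner-edge gap is reported alongside because design tools sometimes quote
that measure instead.

## Read classification

Classification follows a two-pass rule: amplicon first, vector on the
remainder. Pass 1 is a local affine alignment of the read to the amplicon
(same scoring as below). Pass 2 scans the unanchored portions — soft clips
and internal insertions of the anchor alignment, padded by 6 bp and merged
when separated by ≤ 8 aligned columns (a local aligner can split one
vector insert into nearby gaps or absorb junction bases as mismatches) —
against an exact k-mer index (k = 12) of the vector, grouping seeds by
diagonal and rescoring each group ungapped.

Thresholds (all configurable): amplicon anchor ≥ 25 nt at ≥ 0.85 identity;
vector hit ≥ 15 nt at ≥ 0.90 identity; a read is `amplicon_only` when the
anchor covers ≥ 50% of it with no qualifying vector hit. With a kb-scale
vector, the chance probability of a spurious 15 nt/90% hit per read is far
below one, and at amplicon scale the anchor requirement plays the role
that genome-wide pre-filtering plays in a full mapping pipeline (the
equivalence is pragmatic, not exact, and only matters off-amplicon).
Palindromic ITRs make some vector placements score-equivalent (a 5′ ITR
prefix equals the reverse complement of the 3′ ITR suffix); ties are kept
as `ambiguous` events whose co-optimal placements share unit weight in
coverage and breakpoint summaries.

## Alignment and variant calling

Amplicon-only reads are aligned glocally — read global, reference local —
because reads are subfragments of the amplicon. Scoring is match +5,
mismatch −4, gap cost(L) = 25 + L·1; since gap conventions differ between
tools, we state ours explicitly: the first gap base costs open+extend.
The production aligner is Biopython's `PairwiseAligner` (C implementation)
configured with open = −26, extend = −1 and free reference end gaps; the
test suite checks its scores cell-for-cell against an independent
brute-force Gotoh DP on random instances.

Indels are normalised by left-alignment to the minimal reference start
among sequence-equivalent placements (idempotent; deletion-before-insertion
at shared points). Variant signatures are built from the normalised ops. A
read is *edited* iff ≥ 1 indel overlaps the quantification window, default
`[min(nick) − 5, max(nick) + 5)` — wide enough for both nicks plus NHEJ
jitter, and reported in the output metadata since the window width is an
analysis choice, not a biological constant. Substitutions never count as
edits; reads whose only indels fall outside the window are counted
unedited but flagged. No minimum per-variant support is imposed: paired
nickase outcomes are heterogeneous with low per-variant frequency, and a
support floor would silently discard most of the signal.

Chimeric reads are appended to the variant table as vector-insertion
records and counted as edited, giving the two integration denominators
(of all reads; of edited reads) a consistent read universe:
`integration_of_indels = integration_of_reads / indel_frequency` holds by
construction. The deletion coverage profile reports, per reference
position, the fraction of covering reads (span includes deleted bases)
that delete that position; uncovered positions are missing, not zero.

## Integration junctions

A chimeric read is split into amplicon prefix / vector middle / amplicon
suffix. Junctions are canonicalised by **maximal vector extension**: a base
compatible with both flank and vector is attributed to the vector. The
simulator applies the same rule (in independent code) when recording
truth, which makes "resolved interval equals truth interval" well defined
on error-free data despite the inherent sequence-level ambiguity of
junction bases. Flank breakpoints are taken from glocal flank alignments,
anchored on the innermost match run of ≥ 5 bp so that an undetected vector
stump (seeds broken by a sequencing error at the junction) cannot drag the
breakpoint into the insert. Flanks shorter than 10 bp yield single-sided
events (short reads truncate long inserts; requiring both junctions would
bias against exactly the events of interest). Events with crossing flanks
are rejected and the read reclassified amplicon-only under a warning
counter. One chimeric read is one event; events, not base pairs, are the
unit of integration frequency.

Arm-boundary statistics use the junction between the ITR A–A′ stem and the
B–B′ palindrome, with tolerance ±3 bp: junction microtrimming blurs exact
positions, and the biological signal is a regional preference, not a
base-exact site.

## Microhomology

`mh_length` of a deletion `[s, e)` is the placement ambiguity
`max { m : ref[s:s+m] == ref[e:e+m] }`, computed on the reference after
left-normalisation — a property of the deletion, robust to read errors.
The MMEJ-compatible class uses MH strictly greater than 2 bp
(configurable). Insertions are excluded from MH scoring; locus-templated
insertions are instead attributed by matching the inserted sequence (or
its reverse complement) against the inter-nick segment — exact match for
< 10 bp, ≥ 90% identity otherwise, with locus taking precedence over
vector on ties — because short random matches are otherwise too likely.

## Off-target identity

Candidate sites are scored as matching positions / total over
protospacer + PAM, all positions weighted equally. Degenerate PAM positions
match by IUPAC class containment (site base class ⊆ pattern class), so `N`
in a pattern can never mismatch, while an `N` in the site matches only a
pattern `N`. Off-target *discovery* is out of scope; the scorer serves
re-analysis of externally provided candidate lists.

## Synthetic data: what it emulates, what it does not

The generator reproduces the read classes of a paired-nickase/AAV
experiment on a 646 bp amplicon with guides 64 bp apart in PAM-out
orientation (the study-scale design): wildtype; small NHEJ indels at the
nicks; the perfect inter-nick deletion; MMEJ deletions drawn only from
reference positions with a genuine flanking microhomology of the requested
length (the engineered locus contains a 23 bp deletion site with 4 bp MH
and a 10 bp site with 5 bp MH, the canonical recurrent signatures);
insertions templated from the inter-nick segment (5–25 bp, either
orientation); truncated-ITR vector insertions; and complex
deletion+insertion alleles. The synthetic vector carries two palindromic
ITRs (arms A/A′, B/B′, C/C′, D; layout A C C′ B B′ A′ D; 3′ ITR = reverse
complement of the 5′) flanking a 500 bp stuffer. Vector fragments run from
an ITR terminus to a breakpoint at the arm boundary with probability
`itr_breakpoint_bias` (default 0.8), otherwise uniform over the ITR
excluding the ±3 bp boundary zone, so the configured bias is the exact
expectation of the measured fraction. The minimum simulated fragment is
25 bp — fragments near the 15 bp detection threshold are not reliably
recoverable by any junction method once canonicalisation shares bases with
the flanks.

Defaults: 250 nt single-end reads placed uniformly subject to covering the
quantification window with ≥ 30 nt flanks; substitution-only errors at
1e-3 per base (amplicon platforms are substitution-dominated and indel
errors would make truth records ambiguous; an indel error model is
deliberately absent); constant base quality Q35 (quality trimming is
exercised by dedicated low-quality fixtures instead). Truth records use
the same left-alignment and junction conventions as the pipeline, so
signatures are directly comparable. Everything derives from one seeded
PCG64 stream; regeneration is byte-identical.

Passing the simulation-based tests therefore demonstrates correctness of
the algorithms under substitution noise and the stated outcome spectrum —
not robustness to PCR chimeras/jackpots, platform-specific error profiles,
indel sequencing errors, concatemeric or rearranged vector inserts, or
off-amplicon integration, none of which the generator emulates.

## Numerical and degenerate-input choices

Deterministic tie-breaks throughout: leftmost indel placement after
normalisation; vector-hit ties resolved to the lexicographically smallest
(start, strand) with all co-optimal placements retained; deletion emitted
before insertion at a shared point. Zero classified reads yield frequency
0 with a warning rather than an error; zero deletions or zero events yield
missing (None/NaN) summaries, never fabricated zeros. Quality trimming
cuts at the start of the first sliding window (length 4) whose mean
quality drops below 20. Unmergeable read pairs are dropped and counted.
Summary JSON is written with sorted keys and no timestamps, so identical
inputs give byte-identical output.

## Problem sizes used in validation

The bundled validation uses 300–2,000-read fixtures for behavioural tests
and one 10,000-read bundle for parameter recovery; 200 random instances
for the alignment score oracle and 1,000 for the microhomology oracle.
These sizes give 3-standard-deviation binomial tolerances of ±1–4% on the
recovered fractions, tight enough to detect any systematic
misclassification while keeping the full suite fast.

## Known limitations

- Junction resolution reports one contiguous vector interval per read;
  concatemer structure and full-length insert reconstruction are beyond
  short-read resolution and out of scope.
- Integration frequencies count events (reads), so long inserts that
  suppress amplification are under-represented in exactly the way any
  amplicon assay under-represents them.
- The vector-hit scan is seeded with exact 12-mers; inserts shorter than
  ~20 bp carrying an error near their centre can escape detection.
- Whether per-position vector coverage should count reads or fragments is
  ambiguous in general; we define read-weighted coverage (each event's
  placements share unit weight) and report it as such.
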