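# Methods

This note documents the models, parameter choices and numerical decisions
behind `pseudoscan`, and what the synthetic benchmarks do and do not show.

## Scan model

The homology search is a word-seeded local alignment. Exact reference
k-mers (default word size 11) anchor candidate genomic windows (hit span
padded by 30 nt, overlapping windows merged); each window is aligned with
an affine-gap Smith–Waterman (match +1, mismatch −2, gap open −5, gap
extend −2). Minus-strand hits come from scanning the reverse complement of
the genome and mapping coordinates back, which makes strand symmetry exact
by construction rather than a property to be approximated.

Local alignment clips a terminal segment whenever its partial score is
non-positive — the familiar artifact in which a full-length copy with one
or two mismatches in its first or last 10–15 nt is reported with a clipped
reference span. Refinement therefore re-aligns the full reference against
the hit window padded by the unaligned reference overhang plus 20 nt, and
then extends both alignment ends ungapped to the farthest position whose
cumulative score is maximal (ties resolved to the farthest position, so a
mismatch bracketed by recovering matches is absorbed while a strictly
terminal mismatch is not). We chose this over a global alignment with free
end gaps: with near-free end gaps a global optimizer admits degenerate
all-end-gap solutions when the reference overhangs the window, and a forced
full-span alignment would mis-score genuinely 3′-truncated copies by
dragging the reference tail through unrelated downstream sequence. The
refined span never shrinks below the seed span.

Identity is computed as matches / (matches + mismatches + gap columns)
over the aligned reference span — the conservative, BLAST-style alignment
-length denominator. Defaults: identity ≥ 0.975, length ≥ 26 nt, e-value
≤ 10 (ungapped Karlin–Altschul approximation with fixed λ = 1.28,
K = 0.46; the e-value is deliberately loose since identity and length are
the operative filters). 97.5% is the appropriate threshold for high-copy
RNAs such as U2/U6; 90% is the customary base threshold otherwise, and the
planted-recovery benchmark runs at 0.90 because at 1% simulated divergence
a non-negligible fraction of copies (≈ 9% full-length, ≈ 12% of 60-nt
truncated copies) carries enough substitutions to fall below 0.975 —
a property of the binomial mutation count, not of the scanner.

Segmental-duplication removal aligns concatenated 100-nt flanks of every
locus pair globally; pairs at ≥ 0.9 identity (matches over the longer
flank length) are clustered by single linkage and only the highest-identity
copy per cluster is kept, ties broken by lowest coordinate. Random flank
pairs score far below the threshold, so false merges are not a practical
concern at desk scale (the step is quadratic in loci).

## TSD search

Region A is the upstream flank plus the first 10 nt of the copy; region B
is the last 10 nt of the copy plus the downstream flank (100 nt). Stage 1
finds the longest exact common substring of length ≥ 10; stage 2 extends
region B to 6 kb; stage 3 allows one internal mismatch (no indels) at a
raised minimum length of 12. Ties are broken by segment length, then by
combined distance of the occurrence pair to the copy boundaries, then by
leftmost position — consistent with defining the TSD as the longest
identical segment at each extremity.

Two constraints keep the distant stages from drowning in chance matches,
whose expected counts are otherwise large (≈ 0.6 chance exact ≥ 10-mers
between a 110-nt region and 6 kb, ≈ 1.4 for the 1-mismatch ≥ 12-mer
search):

* the **upstream anchor**: the upstream TSD occurrence must end within
  10 nt of the copy 5′ boundary. Biologically nothing can lie between the
  upstream TSD and the copy — only the downstream junction can carry an
  inter-region — so the anchor discards only implausible geometry;
* the **plausibility rule** (pipeline level): a TSD from the extended or
  mismatch stages whose inter-region exceeds 20 nt yet contains neither a
  repeat partner nor a poly(A) tract is discarded as noise and the locus is
  re-annotated through the TSD-less path. Distant TSDs exist to explain
  chimeric inserts; an unexplained distant match is overwhelmingly likely
  to be a coincidence. This mirrors the manual curation step that unusual
  loci received in practice.

N is treated as an ordinary character by the substring search; loci whose
boundaries contain N-runs are routed to the Gaps group before any other
label, so this has no classification consequence.

## Classification cascade

Evidence is computed in the pipeline order TSD → rebuild → repeat →
poly(A) → truncation → gaps. Exactly one label per locus: `Gaps` (≥ 5
consecutive N inside the insertion boundaries; the run threshold is our
choice, the boundary definition follows the rebuild); otherwise with a TSD:
`Repeat` (inter-region aligns to a library entry at ≥ 0.8 identity over
≥ 30 nt — our stand-in for default-parameter library searches) >
`PolyA` (> 6 A in a 10-nt window starting within 30 nt of the copy 3′ end;
a tail must abut the copy, hence the 30-nt cap) > `ThreePrimeTrunc`
(reference end missing by more than the 5-nt tolerance) > `ToCheck` with
sub-flag `full_length_tsd` (a case the group scheme does not name; routing
it to the curation bucket keeps the four comparison groups clean);
without a TSD: `Alone` only for full-length copies with no repeat/poly(A)
evidence in the downstream flank, everything else `ToCheck`. Any
5′-truncated copy without a repeat explanation is forced to `ToCheck`
regardless of other evidence. The twin-priming signature (antisense repeat
partner + 3′-truncated copy inside one TSD pair) is a flag on Repeat
copies, not a separate group.

Truncation tolerance is 5 nt at each reference end — within the boundary
imprecision already tolerated by the 10-nt TSD slack, and necessary
because junction microhomology makes the copy/TSD boundary genuinely
ambiguous by up to a few bases.

## Junction microhomology

For a 3′-truncated copy with a TSD, the statistic is two-sided:
*b* counts identities between the reference continuation past the
truncation point and the genomic sequence at the downstream TSD start, *a*
counts identities between the copy end and the bases 5′ of the upstream
TSD occurrence, and *n* = *a* + *b*. This is the unique operationalization
whose null is the stated P(*n*) = (*n*+1)·p^*n*·(1−p)² — the distribution
of a sum of two independent geometric variables with per-base match
probability p (0.25 for unbiased composition).

Boundary ambiguity interacts with the measurement: a greedy aligner
absorbs downstream homology into the copy span, and the longest-segment
TSD definition absorbs upstream homology into the TSD. The truncation
point used for the measurement is therefore backed off by the overlap
between the aligned copy and the called downstream TSD occurrence. With
this correction the total *n* is exact on engineered fixtures at zero
divergence; the (*a*, *b*) split itself is only identifiable when the
upstream component is absent (the simulator's componentwise check uses
a = 0 fixtures, and the sum elsewhere).

## Cleavage-site consensus

The window takes the u genomic bases immediately 5′ of the upstream TSD
occurrence plus the first d bases of the TSD (copy orientation) and
reports the reverse complement, so the nick falls between positions d and
d+1 and an endonuclease-preference site reads TTTT/A on the reported
(bottom) strand. The upstream occurrence is used because it is the only
junction retaining intact pre-insertion flank on its 5′ side. Defaults
u = d = 5; the consensus-recovery benchmark reports u = 5, d = 4 windows so
the four thymines of the canonical site sit flush at the window start.
PFM columns drop windows carrying N at that position and track the drops
separately; the majority consensus breaks ties in A<C<G<T order.

## Fisher's exact test

r×2 tables are tested two-sided under the fixed-margin multivariate
hypergeometric: the p-value sums the probabilities of all margin-
compatible tables at most as probable as the observed one, with a 1e-12
relative tolerance on probability ties (the standard convention; sidedness
is our choice as none is stated for the original analysis). Full
enumeration is used while the candidate-table count (computed by dynamic
programming) is ≤ 10⁷; beyond that, Monte Carlo draws column-1 vectors
from the multivariate hypergeometric (10⁵ replicates, fixed seed, standard
error reported). Genome comparisons use the four comparable groups only
(ToCheck and Gaps are curation buckets, not biology) and report raw
p-values — no multiple-testing correction, matching how such matrices are
customarily read, with pairs at p > 0.01 flagged "not statistically
different".

## Synthetic data: what it does and does not emulate

The generator plants `[TSD][mutated copy (+ poly(A) / N-run / oriented
repeat fragment)][TSD]` cassettes at sites ≥ 250 nt apart in an i.i.d.
background of configurable GC (default 0.5), with the TSD copied from the
target site — true duplication semantics, so TSD detection is tested
against realistic flank composition, not planted random strings. Optional
edits write a cleavage context (given as `"TT/AAAA"`-style strings around
the nick) and exact junction microhomology into the target before
duplication; both are strand-aware. Defaults follow the study conditions
of the benchmarks: substitution divergence 0.01 (indels off by default),
TSD lengths uniform in 10–16, 20-nt pure-A tails (contamination
configurable), 300-nt 3′ repeat fragments — 5′-truncated partners, as
template switching and twin priming produce — alternating sense and
antisense. The repeat "library" is three random sequences under familiar
family names: sufficient for alignment-based family assignment and
orientation, but carrying no real repeat structure.

What passing these benchmarks does **not** show about real genomes: no
nested/fragmented repeats or low-complexity sequence (poly(A)-rich
background would stress the poly(A) rule), no real assembly artifacts
beyond planted N-runs and whole-locus duplications, no indel divergence by
default, no CpG-biased substitution, and uniform base composition in the
junction null where real target sites are AT-rich. Group-recovery rates
measured here are accordingly upper bounds on field performance.

## Determinism and sizes

All randomness flows through explicitly seeded `numpy` generators; a
config + seed reproduces genomes, truth tables and reports byte for byte.
The standard benchmark sizes — 500 TSD fixtures, a 200-kb genome with 40
insertions, 10⁴ junction simulations, 10⁵ Monte-Carlo Fisher replicates,
50 cleavage-site insertions — were chosen to give comfortable statistical
resolution on a single CPU in seconds; they are package defaults, and all
scale up through the same interfaces.
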