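# Methods

This note documents the models behind `intragene`, the parameters that matter,
the conventions adopted where several were defensible, and what the synthetic
data does and does not establish about real data.

## Border model

T-DNA borders are treated as exact matches to the degenerate 24-bp consensus
`GRCAGGATATATNNNNNKGTMAWS` (IUPAC codes; degeneracy 2^5 x 4^5 = 32,768). The
scanner reports every compatible window, overlapping hits included, on both
strands by default; minus-strand hits carry forward-strand coordinates with the
matched sequence given in motif orientation. A subject `N` (masked base)
satisfies only a pattern `N` — informative codes never match masked sequence,
which avoids spurious hits in masked regions.

Border assembly enumerates every (prefix window in sequence A, complementary
suffix window in sequence B, cut point 1..23) triple whose concatenation
matches the full consensus, on the forward strand of both sources. Because the
five-nucleotide spacer is unconstrained, sequences engineered to donate one
border's halves can also cross-pair with another border's donors at nearby cut
points; this is a property of the degenerate consensus itself, and callers
should select candidates by the assembled sequence, not assume uniqueness per
sequence pair.

## Construct model

A `ConstructMap` is a (usually circular) sequence with flat features and an
ordered provenance tiling: every base of the construct is attributed to exactly
one `SourceFragment` with 1-based coordinates on its host chromosome or on a
synthetic source (backbone, ligation linkers).

* **Restriction-ligation** uses SalI (`GTCGAC`, cut after position 1). The
  insert must carry exactly two sites, the backbone exactly one (opened as a
  circle). Both ligation junctions regenerate the site. The flipped insert
  orientation keeps the sticky ends in place and reverse-complements only the
  interior between the half-sites — the string form of physically inverting a
  cohesive-end fragment.
* **In-silico PCR** is exact-match by design (degenerate primers rejected):
  the assays it models report single clean products, and mismatch tolerance
  would add parameters without adding information. Product length includes
  both primers. Circular templates are scanned across the origin by internal
  doubling with products deduplicated modulo length, which makes the product
  multiset invariant under rotation of the template.
* **The translocation table** clips each provenance fragment to the
  transferred interval; the clipped lengths always sum to the interval span
  (conservation is asserted in tests against a per-base counting oracle).

## Read mapping

Desk-scale references make a full aligner unnecessary. `map_to_reference`
seeds with exact 21-mers (sampled every 10 bp plus the final position),
merges seed diagonals within 6 bp, and aligns each candidate placement with
edlib in infix mode. From the alignment CIGAR it keeps the maximum-scoring
contiguous stretch of runs (match +1, mismatch/indel -3) and then trims both
ends back to a run of at least 4 consecutive matches.

The penalty and end-anchoring matter at integration junctions: a read that
crosses a junction has a tail that belongs to the other reference, and greedy
+1/-1 extension will drift across unrelated bases whenever they exceed 50%
chance identity. Break-even at -3 is 75%, and isolated 1-3 base chance matches
at the segment edge are removed by the anchoring rule. Both trims only shorten
a segment, which biases cluster edges conservatively (outward), never across a
breakpoint. Acceptance thresholds: identity >= 0.9 over >= 50% of the read —
tolerant of the simulated 1% substitution error on 150-mers, strict enough to
reject random placements. Ties break deterministically (lowest reference id,
leftmost, plus strand); the count of distinct best placements is reported so
callers can drop ambiguous reads.

## Insertion calling

The caller follows the two-step discordant-pair strategy: (1) keep pairs with
exactly one vector-mapped mate, classifying the anchor by the midpoint of its
vector interval as T-DNA or backbone; (2) map the informative mates to the
genome, drop ambiguous placements, and single-linkage cluster start positions
with gap <= `cluster_gap` (default 700 bp, about twice the 350 bp library
insert: mates of pairs straddling the same junction cannot be farther apart).
Clusters need `min_support` >= 3 informative mates — small enough to find a
single-copy event at modest coverage, large enough that three independent
chance placements at one locus are vanishingly unlikely. When both
orientations support a call, the reported interval narrows to the breakpoint
window between the forward cluster's right edge and the reverse cluster's left
edge; otherwise it is the cluster span.

**Host-derived vectors need a mask.** Every fragment of an intragenic vector
is host sequence, so wild-type reads genuinely anchor to the vector wherever
they overlap a donor locus, and their mates cluster at those loci. These calls
are real alignments but not integrations. `provenance_mask` derives exclusion
intervals from the construct's provenance (donor loci padded by 500 bp, about
one insert plus read length), and `call_insertions` suppresses calls
overlapping them — the computational equivalent of reading the transformed
sample against its wild-type controls. With the mask, wild-type read sets
yield zero calls and the integration locus, which is never a donor locus,
is unaffected. The unmasked behaviour is itself asserted in tests: wild-type
anchors exist and sit exactly at donor loci.

The backbone screen counts backbone-anchored pairs; zero at the sampled
coverage certifies a backbone-free event, and simulated backbone
read-through produces a positive count.

## Junction calling

A junction amplicon is modelled as one genome/vector switch. For every split
position the caller scores the best gapless match count of the 5' part over
all windows of one reference plus the same for the 3' part over the other
(window ties: leftmost). Scoring is vectorised as cumulative sums along
full-junction-length diagonals with the reference zero-padded so windows exist
at every offset; an exhaustive loop-based scorer in the test suite reproduces
it exactly. Which reference is 5' is auto-detected by trying both layouts.

* **No junction**: if the best split improves on the best single-reference
  explanation by fewer than `min_gain` = 8 matches, the sequence is declared
  all-genomic/all-vector (a real switch with >= 20 nt on each side gains ~15).
  This is distinguished from **ambiguity** (best split explains < 90% of the
  junction — sequence matching neither reference).
* **Microhomology** makes a run of splits score equally; the breakpoint is
  placed so shared bases belong to the genome side (a stated convention;
  junction sequence alone cannot resolve ownership). The homology length is
  reported by bidirectional extension at the chosen split.
* **Filler** (non-templated bases) appears as mismatches flanking the switch
  and is trimmed and reported; filler and microhomology are mutually
  exclusive by construction. A filler base that by chance matches one
  reference's continuation is absorbed by that side — only the conservation
  of (genome extension + reported filler + vector extension) is identifiable.

`summarize_integration` computes border quantities as interval overlaps
between the integrated construct interval and the annotated border features,
which makes the summary invariant under junction relabelling and global
reverse complement. `lb_truncation` counts interior bp missing short of the
left border; a separate `lb_border_retained` field (0-24) covers partial or
complete border retention, since one number cannot encode both a lost border
plus truncation and a fully retained border.

**Canonical geometry.** When integrated bases adjacent to a junction happen to
equal the reference bases they replaced, the breakpoint is intrinsically
ambiguous and all evidence (read ends, split scores) lands on the genome-side
representative — the same situation as indel left-alignment. The simulator
therefore exposes `SyntheticTruth.canonical_summary()` and
`canonical_insertion_site`, the truth after those shifts, and recovery is
asserted exactly against them (they equal the nominal parameters whenever no
chance homology exists).

## Segregation testing

Pearson chi-square goodness of fit on 1 df without Yates continuity
correction; the uncorrected statistic is what segregation tables of this kind
report (with correction the first example row would give 0.24, not 0.39).
Expected counts below 1 are rejected. Significance default alpha = 0.05.
Such tables conventionally print statistics truncated (not rounded)
to two decimals — e.g. a computed 1.849 printed as 1.84 — so the display
helper `truncate2` floors at two decimals; the statistic itself is exact.
Calibration is verified by simulation: under true 3:1 segregation with 100
progeny, the test rejects at alpha = 0.05 in ~4.9% of 1,000 replicates
(exact binomial computation gives 4.87%).

## Synthetic data: what it emulates

The default study (all defaults are the study conditions, not tuning knobs):

* **Genome**: five chromosomes ("chr2", "chr4", "chr5", "chr19", "scaffold";
  6-8 kb donors plus a 100 kb integration chromosome; GC 0.40, typical of
  solanaceous genomes). Donor chromosomes are miniatures: only the donor loci
  and their flanks matter to any stage.
* **Vector** (11,591 bp): a synthetic 7,998 bp bacterial backbone ligated via
  SalI to a host-derived insert tiled from five donor fragments — two
  left-border donors (32 + 84 bp), a 3,386 bp AHAS-like cassette (1 kb
  promoter, gene, 300 bp terminator), and two right-border donors (56 + 29
  bp). Concrete border instances match the consensus; the two borders differ
  so left/right donors cannot cross-assemble. Donor loci in the genome are
  patched to contain exactly the fragment sequences (the vector is genuinely
  host-derived), and SalI sites inside donors are scrubbed. Diagnostic primer
  pairs are designed across the left-border-donor/promoter junction (422 bp
  product) and within the backbone (210 bp); these are synthetic stand-ins
  for a real vector's assay, with those conventional product sizes as the
  design truth — in-silico PCR then measures them rather than assuming them.
* **Integration** on chr5: 3 right-border bases transferred (the T-strand
  nick sits between border bases 3 and 4, so ~3 bases normally transfer),
  left border lost plus 7 bp of adjacent T-DNA, 20 bp target-site deletion
  (median-scale for T-DNA integration), right-border end leading. The
  transferred 3,495 bp decompose as 65 bp (chr4 donor) + 3,386 bp (cassette)
  + 44 bp (chr19 donor, including the 3 border bases).
* **Reads**: 150 bp pairs, insert ~N(350, 35) truncated at 250 bp, 20x
  coverage, 1% substitution error, constant quality. Pair count =
  round(coverage x genome / (2 x read length)).
* **Progeny**: resistant counts ~ Binomial(n, 3/4) for a selfed hemizygote,
  Binomial(n, 1/2) for a backcross, 0 for wild-type controls.

Problem sizes used by the test suite and acceptance script: 20 simulated
events (126 kb genome, 20x) with matched wild-type controls for recovery and
specificity; 50 randomized error-free truths on a 46 kb genome for junction
recovery; 50 kb sequences for scanner-oracle equivalence; 100 random
junctions for breakpoint-oracle equivalence.

**What passing does not show.** The generator draws uniform random genomes:
no repeats, paralogy, or heterozygosity, so mapping ambiguity is far rarer
than in a real plant genome; substitution-only errors (no indels) keep the
mapper and callers separable but understate real error structure; a single
intact integration is assumed throughout — tandem or multi-copy arrays,
chromosomal rearrangements beyond the target-site deletion, and
quality-score-dependent errors are out of scope. Real-data use would keep
the algorithms but demands a repeat-aware mapper and multi-locus handling.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; human-facing reports (TSV, GFF3,
1-based fields in records) are 1-based closed. All generators are pure
functions of (parameters, seed) via `numpy.random.default_rng`; compound
simulations derive stage sub-seeds from one master seed with
`SeedSequence`. Empty inputs return empty results (scan of an empty
sequence, clustering of no anchors); invalid inputs raise `ValueError` with
the offending quantity (bad IUPAC code position, site counts, out-of-bounds
intervals, zero-progeny ratios). GFF3 output is flat one-line-per-feature
with percent-encoded attributes and round-trips losslessly.

## Known limitations

Single-switch junctions only (chimeric multi-switch reads are reported as
ambiguous, not resolved); exact-match primer dialect; insertion calls locate
but do not base-resolve breakpoints (that is the junction caller's job, from
amplicon sequence); the circular construct is mapped in its linear
representation (reads spanning the backbone origin do not arise from
transformed-genome sequencing); the backbone screen certifies absence only at
the sampled coverage.
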