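# Methods

This note documents the models, conventions, parameter defaults, and
design choices behind `spliceward`, and what the synthetic study designs
do and do not demonstrate.

## Coordinates and junction identity

All internal coordinates are 0-based half-open; GTF IO converts to/from
1-based inclusive at the boundary (the conversion is its own inverse and
is round-trip tested).  A junction is keyed by
`(chrom, intron_start, intron_end, strand)`.  Donor/acceptor dinucleotides
are reported strand-oriented, so a canonical intron reads GT–AG on either
genomic strand.  The minimum intron length is 42 bp by default (a common
spliced-aligner setting for compact invertebrate genomes); shorter
alignment gaps are treated as indels, not junctions.  Strand of an
unannotated junction is inferred from the interior motif, checking GT-AG,
GC-AG, AT-AC in plus orientation and then their reverse complements; an
annotated junction takes the annotation strand.

## Error model

Estimated from permissive *ungapped* alignments (SAM/BAM with MD tags, or
bowtie map text).  Reverse-strand records are reflected into
sequencing-cycle coordinates (position `L−1−p`, complemented bases,
reversed qualities) before tallying.  The model holds:

* per-position mismatch frequency (fraction of reads mismatching at each
  cycle);
* per-position 4×4 substitution weights conditioned on the reference
  base — the finest granularity consistent with "by position and by
  substitution type"; rows with fewer than 10 observations fall back to
  the position-marginal matrix;
* the empirical per-read mismatch-count distribution, tabulated without
  smoothing (never-observed counts are never sampled);
* consensus quality strings for matched and mismatched positions, taken
  as the per-position modal quality character with ties broken toward the
  higher quality (a "consensus" must be a single character; the mode is
  robust and reproducible).

Sampling draws the count, then that many distinct positions weighted by
the rate vector, then a substitution per position.  When the caller
supplies the read's true sequence the substitution row for the actual
reference base is used (uniform over the three alternatives if that base
was never observed mismatching); otherwise the joint empirical (ref, alt)
distribution at the position is sampled.  Multi-mapped reads are not
excluded from tallies; model building counts every record in the stream.

Two built-in models are provided: `uniform` (flat rate 0.01/position,
uniform substitutions, truncated-Poisson count distribution) and `ramp`
(rate rising quadratically toward the 3′ end from 0.004 to ≈ 0.02, plus an
exponential bump over the first five cycles), mimicking typical Illumina
profiles.

## Simulator

* Pair counts: coverage mode `round(X·L/(2r))` — coverage means expected
  X-fold base coverage of the spliced template counting both mates — and
  RPK mode `round(RPK·L/1000)`; rounding is numpy's half-even.
* Fragments: normal(200, 20) bp rounded to integers, redrawn up to 100
  times if a draw exceeds the template (then the pair is skipped with a
  warning); start uniform over valid positions; mate 2 is the reverse
  complement of the fragment 3′ end.  Both mates share the same error and
  quality model.
* Intron retention: each pair is drawn from the unspliced pre-mRNA
  template with probability 0.20 by default.  Retained-template reads are
  attributed to the parent transcript's truth, not to any junction; they
  exist to produce intron read-through and to stress filters.
* Truth: read IDs encode `transcript|kind|chrom|blocks|mate|serial` and
  decode exactly; the truth SAM uses mapping quality 255 and exact M/N
  CIGARs.  Per-junction truth coverage is recomputable from read origins
  alone (a read supports a junction iff one block gap equals the intron
  and both flanking blocks meet the overhang).
* Determinism: one seeded generator per run; transcripts are processed in
  sorted order with a documented draw order (per-transcript retention
  flags and mismatch counts in bulk, then per pair: fragment, start,
  mate-1 errors, mate-2 errors).

## Junction quantification and filters

The default anchor overhang is 8 bp (the parameter is tunable; no
canonical default exists, so the choice is documented here), applied
identically to junction calling and intron read-through.  The offset of a
supporting read is its left-anchor length; any bijection of alignment
start positions gives the same entropy.  MMES aggregates to the junction
as the maximum over reads of the per-read minimum anchor.  Each gap of a
multi-gap read is an independent observation with the immediately
flanking matched blocks as anchors; duplicate alignments are counted as
separate observations (deduplication is the aligner's job).

Repeat identity compares the 10 bp upstream of the donor with the 10 bp
upstream of the acceptor, and the 10 bp downstream of each, as percent
identity `100·(w−d)/w` with `d` the Levenshtein edit distance; windows are
truncated symmetrically at contig edges and zero-length windows score 0.
Gene assignment resolves each junction end to the gene whose span overlaps
it on a compatible strand, breaking ties by exonic overlap within ±8 bp of
the site; the two ends must agree, else the junction is flagged
ambiguous/unassigned.  Intron read-through counts only fully ungapped
alignments covering `[boundary−o, boundary+o)`.

Filters are non-destructive flags; qualitative (unannotated minor motif,
gene-model inconsistency, shoulder identity > 80%) and quantitative
(entropy < 2 bits) verdicts are independently selectable.  False-positive
classification against truth checks, in order: incorrect strand (interval
matches truth, strand opposite), minor form, paralog joining, repeat
induced, shifted (same strand within a 50 bp window — configurable; no
canonical window exists), else unidentified.  The more specific diagnoses
are checked before "shifted" so that a paralog join whose donor coincides
with a true donor is not absorbed by the shift window.  False negatives
split into alignment failures (a truth spanning read existed) and sampling
misses.

## Events and PSI

Events are maximal pairwise bubbles between transcript paths in the
per-gene splice graph, deduplicated by (gene, flanks, structure code);
enumeration is invariant to transcript input order.  Alternative-promoter
and alternative-last-exon bubbles are kept and flagged not internal;
overlapping first exons that differ only in their 5′ ends are excluded
(they are transcription-start, not splicing, variation).  The structure
code ranks the interior sites of both paths in genomic order and writes
`rank^` for donors and `rank-` for acceptors (`0` for an empty path), so a
cassette exon is `0,1-2^`; code equality is pattern isomorphism on the toy
designs used here.

Inclusion orientation is deterministic: a junction-free path is the
exclusion path; otherwise more junctions, then more interior exonic bases,
then the smaller first interior coordinate win.  PSI uses reads *per
junction* in each path.  For retained introns the exclusion path has no
junction; its per-junction term is the mean of the left and right intron
read-through counts at the spliced junction, which keeps the
normalization symmetric.  Events where a non-retintron path has no
interrogating junction are flagged unquantifiable rather than guessed.
Junction coverage from neighbors — joins from interior exons to exons
outside the event's flanks — is reported per event as potential
confounding, not subtracted.

An external pairwise event file can be supplied instead of native
enumeration.  The supported dialect is GTF-style `as_event` lines with
`structure`, `splice_chain`, and `flanks` attributes; sites are 1-based
with `p^` marking a donor after exonic base `p` and `a-` an acceptor at
exonic base `a`; terminal flanks are `null`.  Parsing is validated against
native enumeration on toy annotations.

## Differential comparison

Fisher's exact test (two-sided — standard for a null of equal proportions)
on `[[inc_a, exc_a], [inc_b, exc_b]]`; degenerate tables score p = 1 so
the BH input length is stable.  Only events with inclusion coverage in
either sample and exclusion coverage in either sample are tested.  Call
gates (all reported separately, all configurable): BH-adjusted p < 0.01;
strictly more than 10 reads in each path in both samples (applied to path
totals, not per-junction means); |ΔPSI| > 0.20; and, when replicates are
supplied, raw between-sample p below the minimum raw p across replicate
pairs (the most conservative replicate reference).  ΔPSI is sample b −
sample a.  Events are tested independently; a gene may contribute several.

## Synthetic study designs

The fixture generator lays out genes on one synthetic chromosome with
planted GT-AG (or, on the minus strand, CT..AC) dinucleotides at every
splice site, one planted pairwise event per multi-isoform gene (cassette,
double skip, alternative donor/acceptor, retained intron, mutually
exclusive exons, alternative first/last exons — realized strand-aware),
and optional error-class material: a duplicated proximal paralog gene,
identical 10-bp exon/intron shoulder windows, reverse-complement motif
tracts inside forward-strand genes, and shifted or minor-motif (AT-AC)
site pairs near true junctions.  A post-layout scrub guarantees no *true*
junction accidentally exceeds the 80% shoulder-identity threshold, so
filter-completeness checks are exact.  The generator is deterministic per
seed and emits a truth manifest of everything planted.

Problem sizes used by the reproduction script and acceptance tests, chosen
as the smallest designs that exercise the statistics cleanly: 55
three-exon cassette genes (exons 250–350 bp so both isoform templates
comfortably exceed the 200 bp fragment) at total 4000 RPK for the designed
ΔPSI = −0.50 pools, sized so the weakest path clears 100 junction reads at
PSI 0.25 under 20% retention; 220 mixed-event genes at the 300 RPK
equal-abundance null; four single-exon 5 kb genes at 800× coverage
(≥ 10⁵ pairs) for the fragment-length and retention checks — the long
template keeps the fragment distribution untruncated so the mean is
unbiased.

What these designs do not show: real genomes have overlapping genes,
shared junctions between events, non-uniform coverage, indel errors and
fragment-length biases none of which the generator models, and the
simulated "alignments" here are the truth SAM (perfect alignment), so
aligner-induced errors appear only where explicitly planted or doctored.
Passing these checks demonstrates correctness of the accounting,
filtering, and inference machinery under its stated assumptions, not
end-to-end accuracy on real libraries.

## Known limitations

* Substitution errors only; no indels, PCR duplicates, GC bias, or
  strand-specific protocols.
* Trans-spliced or antisense-overlapping gene models are outside the
  event builder's contract; behavior on such input is undefined and such
  annotations should be pre-filtered.
* Higher-order (more than pairwise) event grouping is out of scope;
  enumeration is dimension-2 by design.
* The entropy filter is coverage-dependent and intentionally conservative
  for rare transcripts; qualitative filtering is the abundance-independent
  alternative.
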