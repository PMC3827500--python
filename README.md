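# spliceward

Splice-junction centric analysis of RNA-seq data: an error-model-driven
paired-end read simulator with complete truth reporting, a junction
quantifier with alignment diagnostics and *post hoc* filters against known
aligner error classes, pairwise splicing-event definition with
percent-spliced-in (PSI) quantification, and exact-test differential
splicing calls.

## Who this is for

Reads that span a splice junction — gapped alignments whose gap equals an
intron — are direct, unambiguous evidence of a splicing event, unlike exon
read counts, which are confounded by overlapping exon boundaries, coverage
heterogeneity, and unprocessed transcripts.  But junction alignment is
error-prone: aligners introduce spurious gaps at minor splice motifs
(GC-AG, AT-AC), on the wrong strand, shifted from the true site, between
proximal paralogs, and across low-complexity repeats.  `spliceward` is for
anyone building or evaluating a junction-based splicing pipeline: it
simulates reads with empirically modeled sequencing errors and known truth,
diagnoses and filters the resulting junction-call errors, and tests for
differential splicing on filtered junction counts.

## The model in brief

**Error model.**  From a permissive ungapped alignment, the per-position
mismatch frequency, per-position base-substitution weights, the empirical
per-read mismatch-count distribution, and two consensus quality strings
(matched/mismatched positions) are tallied.  The simulator draws the
mismatch count, positions (weighted without replacement), and
substitutions from these matrices.

**Simulator.**  Pairs per transcript follow `round(X·L/(2·r))` at coverage
`X` (read length `r`) or `round(RPK·L/1000)`; fragment lengths are
`N(200, 20²)` bp; a configurable fraction of pairs (default 0.20) is drawn
from the unspliced pre-mRNA template to model intron retention.  Every read
identifier encodes its genomic blocks of origin, and a truth SAM gives a
perfect alignment of every read.

**Junction diagnostics and filters.**  For each junction (keyed by its
intron interval) the quantifier reports coverage, the Shannon entropy of
alignment offsets `H = −Σ pᵢ log₂ pᵢ` (quantitative filter: `H ≥ 2`, which
needs at least four distinct offsets), MMES (max over reads of the shorter
anchor), exon/intron shoulder percent identity over 10-bp windows
(repeat filter: > 80% identical), motif-inferred strand, and a
donor/acceptor gene assignment that must agree (filters wrong-strand calls
and paralog joins), plus intron read-through counts at both boundaries.

**Events and PSI.**  Per gene, transcripts are decomposed into splice
sites; pairwise events are splice-graph bubbles (shared flanking nodes, no
shared interior node), each mapped to disjoint inclusion/exclusion
junction sets.  With `nᵢ` junctions and `Rᵢ` total reads per path,

    PSI = (R_inc/n_inc) / (R_inc/n_inc + R_exc/n_exc)

Retained-intron events use mean intron read-through as the junction-free
path's "reads per junction".

**Differential calls.**  Per event, a two-sided Fisher's exact test on the
2×2 table of inclusion/exclusion totals in two samples, BH FDR across
events, and conservative gates: adjusted p < 0.01, more than 10 reads in
every path in both samples, |ΔPSI| > 0.20, and (with replicates) a
between-sample raw p below the between-replicate raw p.

## Worked example

```python
import numpy as np
import spliceward as sw

fx = sw.make_toy_fixture(
    sw.FixtureConfig(n_genes=8, event_fractions={"exonskip": 0.5, "retintron": 0.25}),
    seed=4,
)
pool1, pool2 = sw.simulate_delta_psi(
    fx.manifest["events"], fx.annotation, fx.genome,
    psi_a=0.25, psi_b=0.75, total_rpk=2000, seed=1,
)

def quantify(pool):
    table = sw.quantify_junctions(pool.alignments, fx.genome, fx.annotation)
    flagged = sw.apply_filters(table, mode="qualitative")
    events = sw.enumerate_events(fx.annotation)
    return sw.quantify_events(
        events, sw.coverage_map(flagged, passing_only=True), sw.readthrough_map(flagged)
    )

calls = sw.compare_events(quantify(pool1), quantify(pool2))
print(calls[["event_type", "psi_a", "psi_b", "delta_psi", "p_adj", "call"]].round(3))
```

prints

```
                      event_type  psi_a  psi_b  delta_psi  p_adj  call
event_id
G001:2280-2667:0,1^2-  retintron  0.205  0.615      0.410    0.0  True
G003:4505-4872:0,1-2^   exonskip  0.356  0.827      0.471    0.0  True
G004:6128-6537:0,1^2-  retintron  0.166  0.621      0.455    0.0  True
G005:7021-7377:0,1-2^   exonskip  0.360  0.829      0.469    0.0  True
G007:9067-9436:0,1-2^   exonskip  0.306  0.805      0.499    0.0  True
```

Five toy genes carry a planted event simulated at PSI 0.25 in pool 1 and
0.75 in pool 2 (ΔPSI here is pool 2 − pool 1); all five are recovered with
PSI estimates near the designed values, pass every call gate, and are
significant after BH adjustment.  The `structure_code` in each event id
(`0,1-2^` = cassette exon; `0,1^2-` = retained intron) encodes the bubble
pattern.

The same pipeline is available from the shell:

```sh
spliceward fixtures --genes 8 --seed 4 --out fix/
spliceward sim --gtf fix/annotation.gtf --fasta fix/genome.fa --rpk 300 --seed 1 --out sim/
spliceward juncs --bam sim/truth.sam --gtf fix/annotation.gtf --fasta fix/genome.fa --out juncs/
spliceward events --gtf fix/annotation.gtf --juncs juncs/junctions_all.tsv --out events.tsv
spliceward compare --a eventsA.tsv --b eventsB.tsv --out calls.tsv
```

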