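"""Splice-junction quantification, diagnostics, and *post hoc* filters.

The quantifier streams gapped alignments (SAM/BAM or in-memory records),
tallies per-junction spanning-read coverage together with alignment
diagnostics — offset (left-anchor) multiset, Shannon entropy of offsets,
minimum match on either side (MMES), exon/intron shoulder repeat identity,
motif-inferred strand, gene assignment and intron read-through — and applies
two independently selectable filtering strategies:

* *quantitative*: offset entropy >= 2 bits (at least four distinct,
  equally weighted offsets reach this threshold);
* *qualitative*: drop unannotated minor-motif junctions, junctions whose
  two ends disagree on (or lack) a gene assignment, and junctions whose
  shoulder windows exceed 80% identity (repeat-induced gaps).

Filtering is non-destructive: flags are added, coverages never change.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    MIN_INTRON,
    Annotation,
    GenomeRef,
    Junction,
    forward_motifs,
    percent_identity,
)

logger = logging.getLogger(__name__)

DEFAULT_OVERHANG = 8
REPEAT_IDENTITY_MAX = 80.0
ENTROPY_MIN = 2.0

#: forward-genomic (donor, acceptor) dinucleotides -> (strand, motif class)
_MOTIF_TABLE = [
    (("GT", "AG"), ("+", "GT-AG")),
    (("GC", "AG"), ("+", "GC-AG")),
    (("AT", "AC"), ("+", "AT-AC")),
    (("CT", "AC"), ("-", "GT-AG")),
    (("CT", "GC"), ("-", "GC-AG")),
    (("GT", "AT"), ("-", "AT-AC")),
]

QUALITATIVE_FLAGS = ("minor_unannotated", "ambiguous_gene", "repeat_like")


# ---------------------------------------------------------------------------
# Alignment streaming
# ---------------------------------------------------------------------------


def _iter_blocks(source) -> Iterator[tuple[str, tuple[tuple[int, int], ...]]]:
    """Normalize an alignment source to (chrom, blocks) tuples.

    Accepts a SAM/BAM path, an open pysam.AlignmentFile, or an iterable of
    objects exposing either pysam's AlignedSegment interface or
    ``.chrom``/``.blocks`` attributes (e.g. simulator truth records).
    """
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), check_sq=False) as aln:
            yield from _iter_blocks(aln)
        return
    for rec in source:
        if isinstance(rec, pysam.AlignedSegment):
            if rec.is_unmapped or not rec.cigartuples:
                continue
            yield rec.reference_name, tuple(rec.get_blocks())
        elif hasattr(rec, "blocks"):
            yield rec.chrom, tuple(rec.blocks)
        else:
            raise TypeError(f"cannot interpret alignment record {rec!r}")


def extract_spliced_alignments(
    source,
    min_overhang: int = DEFAULT_OVERHANG,
    min_intron: int = MIN_INTRON,
) -> tuple[dict, dict]:
    """Stream alignments into junction observations and ungapped spans.

    Returns ``(observations, ungapped)`` where ``observations`` maps
    ``(chrom, intron_start, intron_end)`` to a list of per-read
    ``(left_anchor, right_anchor)`` pairs (anchors are the matched blocks
    immediately flanking the gap; observations with either anchor below
    ``min_overhang`` are discarded), and ``ungapped`` maps chromosome to a
    list of (start, end) spans of fully ungapped alignments, used for
    intron read-through counting.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    obs: dict[tuple[str, int, int], list[tuple[int, int]]] = defaultdict(list)
    ungapped: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, blocks in _iter_blocks(source):
        if len(blocks) == 1:
            ungapped[chrom].append(blocks[0])
            continue
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            gap = s2 - e1
            if gap < min_intron:
                continue
            left, right = e1 - s1, e2 - s2
            if left < min_overhang or right < min_overhang:
                continue
            obs[(chrom, e1, s2)].append((left, right))
    return dict(obs), dict(ungapped)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def offset_entropy(offsets: Mapping[int, int] | Sequence[int]) -> float:
    """Shannon entropy (bits) of the alignment-offset distribution."""
    if not isinstance(offsets, Mapping):
        offsets = Counter(offsets)
    counts = np.array([c for c in offsets.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("offset multiset is empty")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mmes(anchors: Sequence[tuple[int, int]]) -> int:
    """Junction MMES: max over supporting reads of min(left, right anchor)."""
    if not anchors:
        raise ValueError("no supporting reads")
    return max(min(l, r) for l, r in anchors)


def repeat_identity(
    genome: GenomeRef,
    junction: Junction | tuple[str, int, int],
    window: int = 10,
) -> tuple[float, float]:
    """Percent identity of the exon/intron shoulder windows of a junction.

    Donor side compares the ``window`` bp upstream of the donor (exon) with
    the ``window`` bp upstream of the acceptor (intron 3' end); acceptor
    side compares the windows immediately downstream of the donor (intron
    5' end) and of the acceptor (exon).  Windows are truncated symmetrically
    at contig edges; zero-length windows score 0.
    """
    if isinstance(junction, Junction):
        chrom, s, e = junction.chrom, junction.intron_start, junction.intron_end
    else:
        chrom, s, e = junction
    clen = genome.length(chrom)
    w_up = min(window, s)
    w_dn = min(window, clen - e)
    donor_side = (
        percent_identity(genome.fetch(chrom, s - w_up, s), genome.fetch(chrom, e - w_up, e))
        if w_up > 0
        else 0.0
    )
    acceptor_side = (
        percent_identity(genome.fetch(chrom, s, s + w_dn), genome.fetch(chrom, e, e + w_dn))
        if w_dn > 0
        else 0.0
    )
    return donor_side, acceptor_side


def infer_strand(donor_fwd: str, acceptor_fwd: str) -> tuple[str, str]:
    """Infer strand and motif class from forward-genomic intron dinucleotides.

    Canonical and minor motifs are checked in plus orientation first
    (GT-AG, GC-AG, AT-AC), then as their reverse complements in minus
    orientation (CT-AC, CT-GC, GT-AT); the first match wins.
    """
    pair = (donor_fwd.upper(), acceptor_fwd.upper())
    for motif, result in _MOTIF_TABLE:
        if pair == motif:
            return result
    return "unknown", "other"


def assign_gene(
    junction: Junction | tuple[str, int, int, str],
    annotation: Annotation,
    min_overhang: int = DEFAULT_OVERHANG,
) -> str:
    """Assign a junction to a gene, requiring donor/acceptor agreement.

    Each end is assigned to the gene whose span overlaps it on a compatible
    strand; ties go to the gene with the greatest exonic overlap within
    ``min_overhang`` of the site, remaining ties are ambiguous.  Returns the
    agreed gene id, ``"ambiguous"`` when the two ends disagree or a site
    matches several genes, or ``"unassigned"`` when either end overlaps no
    gene.
    """
    if isinstance(junction, Junction):
        chrom, s, e, strand = junction.key
    else:
        chrom, s, e, strand = junction

    TIE = "__tie__"

    def _site_gene(pos: int) -> str | None:
        hits = [
            g
            for g in annotation.genes.values()
            if g.chrom == chrom
            and g.start <= pos < g.end
            and (strand == "unknown" or g.strand == strand)
        ]
        if not hits:
            return None
        if len(hits) == 1:
            return hits[0].gene_id
        lo, hi = pos - min_overhang, pos + min_overhang
        best, best_ov, tie = None, -1, False
        for g in hits:
            ov = sum(
                max(0, min(hi, ge) - max(lo, gs)) for gs, ge in g.exons
            )
            if ov > best_ov:
                best, best_ov, tie = g.gene_id, ov, False
            elif ov == best_ov:
                tie = True
        return TIE if tie else best

    donor_gene = _site_gene(s)
    acceptor_gene = _site_gene(e - 1)
    if donor_gene is None or acceptor_gene is None:
        return "unassigned"
    if TIE in (donor_gene, acceptor_gene) or donor_gene != acceptor_gene:
        return "ambiguous"
    return donor_gene


def intron_readthrough(
    ungapped: Mapping[str, Sequence[tuple[int, int]]],
    junctions: Iterable[tuple[str, int, int]],
    min_overhang: int = DEFAULT_OVERHANG,
) -> dict[tuple[str, int, int], tuple[int, int]]:
    """Count ungapped alignments spanning each exon/intron boundary.

    The left count covers ``[intron_start - o, intron_start + o)`` and the
    right count ``[intron_end - o, intron_end + o)`` with ``o`` the same
    overhang used for junction calling.
    """
    spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in ungapped.items():
        arr = np.asarray(ivals, dtype=np.int64)
        spans[chrom] = (arr[:, 0], arr[:, 1]) if arr.size else (
            np.empty(0, np.int64),
            np.empty(0, np.int64),
        )
    out = {}
    o = min_overhang
    for chrom, s, e in junctions:
        starts, ends = spans.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        left = int(np.count_nonzero((starts <= s - o) & (ends >= s + o)))
        right = int(np.count_nonzero((starts <= e - o) & (ends >= e + o)))
        out[(chrom, s, e)] = (left, right)
    return out


# ---------------------------------------------------------------------------
# Table assembly and filters
# ---------------------------------------------------------------------------


def quantify_junctions(
    source,
    genome: GenomeRef,
    annotation: Annotation | None = None,
    min_overhang: int = DEFAULT_OVERHANG,
    min_intron: int = MIN_INTRON,
    window: int = 10,
) -> pd.DataFrame:
    """One-pass junction quantification with full diagnostics.

    Returns a DataFrame with one row per detected junction: coordinates,
    coverage, offset diversity/entropy, MMES, shoulder repeat identities,
    motif class, inferred/final strand, annotation status, gene assignment
    and read-through counts.  Annotated junctions take the annotation
    strand; unannotated junctions use the motif-inferred strand.
    """
    obs, ungapped = extract_spliced_alignments(source, min_overhang, min_intron)
    known_strand = {}
    if annotation is not None:
        for c, s, e, st in annotation.known_junction_keys:
            known_strand[(c, s, e)] = st

    rt = intron_readthrough(ungapped, obs.keys(), min_overhang)
    rows = []
    for (chrom, s, e), anchors in sorted(obs.items()):
        offsets = Counter(l for l, _ in anchors)
        donor_fwd, acceptor_fwd = forward_motifs(genome, chrom, s, e)
        inferred, motif_class = infer_strand(donor_fwd, acceptor_fwd)
        annotated = (chrom, s, e) in known_strand
        strand = known_strand.get((chrom, s, e), inferred)
        don_id, acc_id = repeat_identity(genome, (chrom, s, e), window)
        gene = (
            assign_gene((chrom, s, e, inferred), annotation, min_overhang)
            if annotation is not None
            else "unassigned"
        )
        left_rt, right_rt = rt[(chrom, s, e)]
        rows.append(
            {
                "chrom": chrom,
                "intron_start": s,
                "intron_end": e,
                "coverage": len(anchors),
                "n_offsets": len(offsets),
                "entropy": offset_entropy(offsets),
                "mmes": mmes(anchors),
                "donor_fwd": donor_fwd,
                "acceptor_fwd": acceptor_fwd,
                "motif_class": motif_class,
                "inferred_strand": inferred,
                "strand": strand,
                "annotated": annotated,
                "repeat_id_donor_side": don_id,
                "repeat_id_acceptor_side": acc_id,
                "gene_assignment": gene,
                "readthrough_left": left_rt,
                "readthrough_right": right_rt,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "intron_start",
            "intron_end",
            "coverage",
            "n_offsets",
            "entropy",
            "mmes",
            "donor_fwd",
            "acceptor_fwd",
            "motif_class",
            "inferred_strand",
            "strand",
            "annotated",
            "repeat_id_donor_side",
            "repeat_id_acceptor_side",
            "gene_assignment",
            "readthrough_left",
            "readthrough_right",
        ],
    )


def apply_filters(
    table: pd.DataFrame,
    mode: str = "qualitative",
    entropy_min: float = ENTROPY_MIN,
    repeat_max: float = REPEAT_IDENTITY_MAX,
) -> pd.DataFrame:
    """Add filter flags and pass/fail verdicts to a junction table.

    Flags: ``minor_unannotated`` (non-GT-AG motif class and not annotated),
    ``ambiguous_gene`` (ends disagree on, or lack, a gene assignment),
    ``repeat_like`` (either shoulder identity above ``repeat_max``),
    ``low_entropy`` (offset entropy below ``entropy_min``).  ``mode``
    selects which verdict fills the ``passes`` column: ``qualitative``,
    ``quantitative``, ``both`` or ``none``.  Coverage values are untouched.
    """
    if mode not in ("qualitative", "quantitative", "both", "none"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = table.copy()
    out["minor_unannotated"] = (
        out["motif_class"].isin(["GC-AG", "AT-AC", "other"]) & ~out["annotated"]
    )
    out["ambiguous_gene"] = out["gene_assignment"].isin(["ambiguous", "unassigned"])
    out["repeat_like"] = (
        out[["repeat_id_donor_side", "repeat_id_acceptor_side"]].max(axis=1)
        > repeat_max
    )
    out["low_entropy"] = out["entropy"] < entropy_min
    out["pass_qualitative"] = ~(
        out["minor_unannotated"] | out["ambiguous_gene"] | out["repeat_like"]
    )
    out["pass_quantitative"] = ~out["low_entropy"]
    if mode == "qualitative":
        out["passes"] = out["pass_qualitative"]
    elif mode == "quantitative":
        out["passes"] = out["pass_quantitative"]
    elif mode == "both":
        out["passes"] = out["pass_qualitative"] & out["pass_quantitative"]
    else:
        out["passes"] = True
    return out


def coverage_map(table: pd.DataFrame, passing_only: bool = False) -> dict:
    """Junction key -> coverage mapping from a (filtered) table."""
    sub = table[table["passes"]] if passing_only and "passes" in table else table
    return {
        (r.chrom, r.intron_start, r.intron_end): int(r.coverage)
        for r in sub.itertuples()
    }


def readthrough_map(table: pd.DataFrame) -> dict:
    return {
        (r.chrom, r.intron_start, r.intron_end): (
            int(r.readthrough_left),
            int(r.readthrough_right),
        )
        for r in table.itertuples()
    }


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

FP_CLASSES = (
    "incorrect_strand",
    "minor_form",
    "paralog_joining",
    "repeat_induced",
    "shifted",
    "unidentified",
)


def evaluate_vs_truth(
    detected: pd.DataFrame,
    truth_counts: Mapping[tuple[str, int, int], int],
    annotation: Annotation,
    shift_window: int = 50,
) -> dict:
    """Classify false positive detections and split false negatives.

    ``detected`` is a (flagged) quantification table; ``truth_counts`` are
    the simulator's per-junction spanning-read truth counts.  Detections
    absent from the truth are classified, in priority order: incorrect
    strand (interval matches a truth junction, inferred strand opposite),
    minor form (unannotated minor motif within ``shift_window`` of a truth
    junction), paralog joining (the two ends assign to different genes),
    repeat induced (shoulder identity above threshold), shifted (same
    strand, either end within ``shift_window`` of a truth junction), else
    unidentified.  False negatives are annotated junctions not detected,
    split into alignment failures (a truth spanning read existed) and
    sampling misses (no spanning read generated).
    """
    if truth_counts is None:
        raise ValueError("truth counts required")
    if "repeat_like" not in detected.columns:
        detected = apply_filters(detected, mode="none")

    truth_strand = {}
    for c, s, e, st in annotation.known_junction_keys:
        truth_strand[(c, s, e)] = st
    truth_keys = set(truth_counts)

    def _near(chrom, s, e, strand=None):
        for (tc, ts, te) in truth_keys:
            if tc != chrom:
                continue
            if min(abs(ts - s), abs(te - e)) <= shift_window:
                if strand is None or truth_strand.get((tc, ts, te)) == strand:
                    return (tc, ts, te)
        return None

    fp_rows = []
    for r in detected.itertuples():
        key = (r.chrom, r.intron_start, r.intron_end)
        if key in truth_keys:
            continue
        if (
            key in truth_strand
            and r.inferred_strand not in ("unknown", truth_strand[key])
        ):
            cls = "incorrect_strand"
        elif (
            r.motif_class in ("GC-AG", "AT-AC")
            and not r.annotated
            and _near(*key) is not None
        ):
            cls = "minor_form"
        elif _ends_in_two_genes(key, annotation):
            cls = "paralog_joining"
        elif r.repeat_like:
            cls = "repeat_induced"
        elif (
            r.inferred_strand != "unknown"
            and _near(*key, strand=r.inferred_strand) is not None
        ):
            cls = "shifted"
        else:
            cls = "unidentified"
        fp_rows.append(
            {
                "chrom": r.chrom,
                "intron_start": r.intron_start,
                "intron_end": r.intron_end,
                "error_class": cls,
            }
        )

    detected_keys = {
        (r.chrom, r.intron_start, r.intron_end) for r in detected.itertuples()
    }
    fn_rows = []
    for key in sorted(annotation.known_junction_intervals):
        if key in detected_keys:
            continue
        reason = "alignment_failure" if truth_counts.get(key, 0) > 0 else "sampling"
        fn_rows.append(
            {
                "chrom": key[0],
                "intron_start": key[1],
                "intron_end": key[2],
                "reason": reason,
            }
        )
    fp = pd.DataFrame(fp_rows, columns=["chrom", "intron_start", "intron_end", "error_class"])
    fn = pd.DataFrame(fn_rows, columns=["chrom", "intron_start", "intron_end", "reason"])
    return {"fp": fp, "fn": fn, "n_fp": len(fp), "n_fn": len(fn)}


def _ends_in_two_genes(key: tuple[str, int, int], annotation: Annotation) -> bool:
    chrom, s, e = key

    def _genes_at(pos):
        return {
            g.gene_id
            for g in annotation.genes.values()
            if g.chrom == chrom and g.start <= pos < g.end
        }

    a, b = _genes_at(s), _genes_at(e - 1)
    return bool(a) and bool(b) and not (a & b)
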