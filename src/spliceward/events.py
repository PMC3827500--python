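"""Pairwise splicing events: splice-graph bubbles, path junction sets, PSI.

Per gene, transcript models are decomposed into splice *sites* (exon
boundaries); sites are nodes of a directed graph whose edges are exon or
intron segments, plus virtual source/sink nodes for transcript termini.
A pairwise splicing event is a *bubble*: a region where two transcript
paths share boundary nodes but no interior node.  Each event maps to two
disjoint junction sets that interrogate the inclusion and exclusion paths
specifically, enabling a percent-spliced-in (PSI) estimate

    PSI = (inc_reads / n_inc_junctions)
          / (inc_reads / n_inc_junctions + exc_reads / n_exc_junctions)

i.e. reads *per junction* in each path, which balances paths composed of
different numbers of junctions.  A retained-intron event has a junction-free
exclusion path; its per-junction exclusion term is the mean of the left and
right intron read-through counts at the spliced junction's boundaries.

Inclusion orientation is deterministic: a junction-free path is always the
exclusion path; otherwise the path with more junctions, then with more
interior exonic bases, then with the smaller first interior coordinate, is
the inclusion path.

The structure code mirrors the site-marker convention used by graph-based
event classifiers: interior sites of both paths are ranked in genomic
order and written ``<rank>^`` for donors and ``<rank>-`` for acceptors;
an empty path is ``0``; the two path codes are joined (lexicographically
smaller first), so a cassette exon reads ``0,1-2^``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import Annotation, FormatError, TranscriptModel

logger = logging.getLogger(__name__)

SRC = "SRC"
SNK = "SNK"

#: edge list of one subpath: ordered (u, v, kind) with kind exon|intron|terminal
PathEdges = tuple[tuple[object, object, str], ...]


@dataclass
class SpliceGraph:
    gene_id: str
    chrom: str
    strand: str
    graph: nx.DiGraph
    paths: dict[str, tuple]  # transcript -> node sequence (incl SRC/SNK)


@dataclass
class SplicingEvent:
    gene_id: str
    chrom: str
    strand: str
    flank_left: object  # site position or SRC
    flank_right: object  # site position or SNK
    path_inclusion: PathEdges
    path_exclusion: PathEdges
    junctions_inclusion: frozenset
    junctions_exclusion: frozenset
    event_type: str
    structure_code: str
    is_internal: bool

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}:{self.flank_left}-{self.flank_right}:{self.structure_code}"

    def swapped(self) -> "SplicingEvent":
        """The same bubble with inclusion/exclusion roles exchanged."""
        return SplicingEvent(
            self.gene_id,
            self.chrom,
            self.strand,
            self.flank_left,
            self.flank_right,
            self.path_exclusion,
            self.path_inclusion,
            self.junctions_exclusion,
            self.junctions_inclusion,
            self.event_type,
            self.structure_code,
            self.is_internal,
        )


@dataclass
class EventQuant:
    inc_total_reads: int
    exc_total_reads: int
    inc_n_junctions: int
    exc_n_junctions: int
    psi: float  # NaN when undefined
    neighbor_coverage: int = 0
    quantifiable: bool = True


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _tx_nodes(t: TranscriptModel) -> tuple:
    nodes: list = [SRC]
    for s, e in t.exons:
        nodes.extend((s, e))
    nodes.append(SNK)
    return tuple(nodes)


def _tx_edges(nodes: tuple) -> PathEdges:
    out = []
    inner = nodes[1:-1]
    for i in range(len(inner) - 1):
        kind = "exon" if i % 2 == 0 else "intron"
        out.append((inner[i], inner[i + 1], kind))
    return tuple(
        [(SRC, inner[0], "terminal")] + out + [(inner[-1], SNK, "terminal")]
    )


def build_splice_graph(transcripts: Sequence[TranscriptModel]) -> SpliceGraph:
    """Build the per-gene splice graph (sites as nodes, segments as edges)."""
    if not transcripts:
        raise ValueError("at least one transcript required")
    genes = {t.gene_id for t in transcripts}
    if len(genes) > 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(genes)}")
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise FormatError(f"gene {transcripts[0].gene_id}: mixed strands")
    g = nx.DiGraph()
    paths = {}
    for t in transcripts:
        nodes = _tx_nodes(t)
        paths[t.transcript_id] = nodes
        for u, v, kind in _tx_edges(nodes):
            if g.has_edge(u, v):
                g[u][v]["transcripts"].add(t.transcript_id)
            else:
                g.add_edge(u, v, kind=kind, transcripts={t.transcript_id})
    return SpliceGraph(
        gene_id=transcripts[0].gene_id,
        chrom=transcripts[0].chrom,
        strand=transcripts[0].strand,
        graph=g,
        paths=paths,
    )


# ---------------------------------------------------------------------------
# Bubble enumeration
# ---------------------------------------------------------------------------


def _subpath_edges(nodes: Sequence, edges: PathEdges, lo: int, hi: int) -> PathEdges:
    return tuple(edges[lo:hi])


def _bubbles_of_pair(nodes_a: tuple, nodes_b: tuple):
    """Yield (flankL, flankR, idx ranges) of maximal bubbles of two paths."""
    set_b = set(nodes_b)
    common = [n for n in nodes_a if n in set_b]
    idx_a = {n: i for i, n in enumerate(nodes_a)}
    idx_b = {n: i for i, n in enumerate(nodes_b)}
    # common nodes must appear in the same order in both paths
    common = [n for n in common if n in idx_b]
    for c1, c2 in zip(common, common[1:]):
        ia1, ia2 = idx_a[c1], idx_a[c2]
        ib1, ib2 = idx_b[c1], idx_b[c2]
        if ia2 - ia1 == 1 and ib2 - ib1 == 1:
            continue  # same single edge or parallel identical segment
        interior_a = nodes_a[ia1 + 1 : ia2]
        interior_b = nodes_b[ib1 + 1 : ib2]
        if interior_a == interior_b:
            continue
        yield c1, c2, (ia1, ia2), (ib1, ib2)


def _path_junctions(chrom: str, edges: PathEdges) -> frozenset:
    return frozenset(
        (chrom, u, v) for u, v, kind in edges if kind == "intron"
    )


def _interior_exonic(edges: PathEdges) -> int:
    return sum(v - u for u, v, kind in edges if kind == "exon")


def _orient(pa: PathEdges, pb: PathEdges, chrom: str) -> tuple[PathEdges, PathEdges]:
    """Order two subpaths as (inclusion, exclusion); see module docstring."""
    ja, jb = len(_path_junctions(chrom, pa)), len(_path_junctions(chrom, pb))
    if ja == 0 and jb > 0:
        return pb, pa
    if jb == 0 and ja > 0:
        return pa, pb
    if ja != jb:
        return (pa, pb) if ja > jb else (pb, pa)
    ea, eb = _interior_exonic(pa), _interior_exonic(pb)
    if ea != eb:
        return (pa, pb) if ea > eb else (pb, pa)

    def _first_interior(p: PathEdges) -> float:
        # interior nodes are the u's of edges after the first (flank excluded)
        return min(
            (u for u, v, k in p[1:] if u not in (SRC, SNK)), default=np.inf
        )

    return (pa, pb) if _first_interior(pa) <= _first_interior(pb) else (pb, pa)


def _site_marker(node, edges: PathEdges) -> str:
    """'^' for a donor site (exon -> intron), '-' for an acceptor."""
    for u, v, kind in edges:
        if u == node:
            return "^" if kind == "intron" else "-"
    return "-"


def _structure_code(pa: PathEdges, pb: PathEdges) -> str:
    interiors = []
    for p in (pa, pb):
        nodes = []
        for u, v, k in p:
            if u not in (SRC, SNK) and u not in nodes:
                nodes.append(u)
        # drop the left flank (first node of the first edge if it is a flank)
        interiors.append(nodes)
    # interior nodes exclude flanks: flanks are shared between both paths
    flanks = set(interiors[0]) & set(interiors[1])
    interiors = [[n for n in nodes if n not in flanks] for nodes in interiors]
    ranked = sorted(set(interiors[0]) | set(interiors[1]))
    rank = {n: i + 1 for i, n in enumerate(ranked)}
    codes = []
    for p, nodes in zip((pa, pb), interiors):
        if not nodes:
            codes.append("0")
        else:
            codes.append("".join(f"{rank[n]}{_site_marker(n, p)}" for n in nodes))
    return ",".join(sorted(codes))


def classify_event(
    pa: PathEdges,
    pb: PathEdges,
    strand: str,
    at_source: bool,
    at_sink: bool,
) -> str:
    """Name the bubble pattern; pa is the inclusion path."""

    def _core(p: PathEdges) -> PathEdges:
        return tuple(e for e in p if e[2] != "terminal")

    ca, cb = _core(pa), _core(pb)
    ia = sum(1 for *_, k in ca if k == "intron")
    ib = sum(1 for *_, k in cb if k == "intron")
    ea = sum(1 for *_, k in ca if k == "exon")
    eb = sum(1 for *_, k in cb if k == "exon")

    if at_source or at_sink:
        five_prime = at_source if strand == "+" else at_sink
        if ia == 1 and ib == 1 and ea == 1 and eb == 1:
            return "AltFE" if five_prime else "AltLE"
        return "Unclassified"
    if ib == 0 and eb == 1:
        if ia == 1 and ea == 2:
            return "retintron"
        return "Unclassified"
    if ib == 1 and eb == 0:
        if ia == 2 and ea == 1:
            return "exonskip"
        if ia == 3 and ea == 2:
            return "skip2exons"
        return "Unclassified"
    if ia == 1 and ib == 1 and ea == 0 and eb == 0:
        # pure intron-edge pair sharing one flank: alt donor or acceptor
        # (whichever flank is shared decides which end varies)
        a_u, a_v = ca[0][0], ca[0][1]
        b_u, b_v = cb[0][0], cb[0][1]
        if a_v == b_v:
            return "altdonor" if strand == "+" else "altacceptor"
        if a_u == b_u:
            return "altacceptor" if strand == "+" else "altdonor"
        return "Unclassified"
    if ia == 1 and ib == 1 and ea == 1 and eb == 1:
        # exon+intron each: variation on one genomic side only
        a_introns = [(u, v) for u, v, k in ca if k == "intron"]
        b_introns = [(u, v) for u, v, k in cb if k == "intron"]
        (au, av), (bu, bv) = a_introns[0], b_introns[0]
        if av == bv and au != bu:
            return "altdonor" if strand == "+" else "altacceptor"
        if au == bu and av != bv:
            return "altacceptor" if strand == "+" else "altdonor"
        return "alt_donor_acceptor"
    if ia == 1 and ib == 1 and ea == 2 and eb == 2:
        return "alt_donor_acceptor"
    if ia == 2 and ib == 2 and ea == 1 and eb == 1:
        return "mutexcl"
    return "Unclassified"


def enumerate_events(annotation: Annotation) -> list[SplicingEvent]:
    """All deduplicated maximal pairwise bubbles over all genes.

    Overlapping first exons that differ only in their five-prime ends are
    excluded; other terminal bubbles are kept and flagged not internal.
    Results are invariant to transcript input order.
    """
    events: dict[tuple, SplicingEvent] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in annotation.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid in sorted(by_gene):
        txs = sorted(by_gene[gid], key=lambda t: t.transcript_id)
        if len(txs) < 2:
            continue
        sg = build_splice_graph(txs)
        tx_edges = {tid: _tx_edges(nodes) for tid, nodes in sg.paths.items()}
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                na, nb = sg.paths[txs[i].transcript_id], sg.paths[txs[j].transcript_id]
                ea_full, eb_full = (
                    tx_edges[txs[i].transcript_id],
                    tx_edges[txs[j].transcript_id],
                )
                for c1, c2, (ia1, ia2), (ib1, ib2) in _bubbles_of_pair(na, nb):
                    pa = ea_full[ia1:ia2]
                    pb = eb_full[ib1:ib2]
                    at_source, at_sink = c1 == SRC, c2 == SNK
                    if _is_five_prime_trim(pa, pb, sg.strand, at_source, at_sink):
                        continue
                    inc, exc = _orient(pa, pb, sg.chrom)
                    etype = classify_event(inc, exc, sg.strand, at_source, at_sink)
                    code = _structure_code(inc, exc)
                    key = (gid, c1, c2, code)
                    if key in events:
                        continue
                    events[key] = SplicingEvent(
                        gene_id=gid,
                        chrom=sg.chrom,
                        strand=sg.strand,
                        flank_left=c1,
                        flank_right=c2,
                        path_inclusion=inc,
                        path_exclusion=exc,
                        junctions_inclusion=_path_junctions(sg.chrom, inc)
                        - _path_junctions(sg.chrom, exc),
                        junctions_exclusion=_path_junctions(sg.chrom, exc)
                        - _path_junctions(sg.chrom, inc),
                        event_type=etype,
                        structure_code=code,
                        is_internal=not (at_source or at_sink),
                    )
    return sorted(events.values(), key=lambda e: e.event_id)


def _is_five_prime_trim(
    pa: PathEdges, pb: PathEdges, strand: str, at_source: bool, at_sink: bool
) -> bool:
    """True for first exons that differ only in their five-prime ends."""
    terminal_5p = at_source if strand == "+" else at_sink
    if not terminal_5p:
        return False

    def _core(p):
        return tuple(e for e in p if e[2] != "terminal")

    ca, cb = _core(pa), _core(pb)
    if len(ca) != 1 or len(cb) != 1:
        return False
    if ca[0][2] != "exon" or cb[0][2] != "exon":
        return False
    # both single exon edges ending (or starting) at the shared flank:
    # the two first exons overlap and differ only in the outer coordinate
    return True


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def paths_to_junctions(event: SplicingEvent) -> tuple[frozenset, frozenset]:
    return event.junctions_inclusion, event.junctions_exclusion


def neighbor_confounding(
    event: SplicingEvent, junction_coverage: Mapping[tuple[str, int, int], int]
) -> int:
    """Coverage of junctions joining interior exons to exons outside the event."""
    interior = set()
    for u, v, k in event.path_inclusion + event.path_exclusion:
        for n in (u, v):
            if n not in (SRC, SNK, event.flank_left, event.flank_right):
                interior.add(n)
    if not interior:
        return 0
    lo = event.flank_left if isinstance(event.flank_left, int) else -np.inf
    hi = event.flank_right if isinstance(event.flank_right, int) else np.inf
    own = set(event.junctions_inclusion) | set(event.junctions_exclusion)
    total = 0
    for (chrom, s, e), cov in junction_coverage.items():
        if chrom != event.chrom or (chrom, s, e) in own:
            continue
        s_in = lo < s < hi
        e_in = lo < e < hi
        if s_in == e_in:
            continue
        if (s_in and s in interior) or (e_in and e in interior):
            total += cov
    return total


def quantify_event(
    event: SplicingEvent,
    junction_coverage: Mapping[tuple[str, int, int], int],
    readthrough: Mapping[tuple[str, int, int], tuple[int, int]] | None = None,
) -> EventQuant:
    """PSI and path totals for one event from junction coverage tables."""
    inc_j = sorted(event.junctions_inclusion)
    exc_j = sorted(event.junctions_exclusion)
    inc_total = sum(junction_coverage.get(j, 0) for j in inc_j)
    exc_total = sum(junction_coverage.get(j, 0) for j in exc_j)

    inc_rate = inc_total / len(inc_j) if inc_j else 0.0
    if exc_j:
        exc_rate = exc_total / len(exc_j)
        quantifiable = bool(inc_j)
    elif event.event_type == "retintron" and inc_j:
        # exclusion (intron-retained) path has no junction; use the mean
        # read-through at the spliced junction's two boundaries
        if readthrough is None:
            return EventQuant(inc_total, 0, len(inc_j), 0, float("nan"), 0, False)
        lr = [readthrough.get(j, (0, 0)) for j in inc_j]
        exc_rate = float(np.mean([v for pair in lr for v in pair]))
        exc_total = int(round(exc_rate))
        quantifiable = True
    else:
        exc_rate = 0.0
        quantifiable = False

    denom = inc_rate + exc_rate
    psi = inc_rate / denom if (quantifiable and denom > 0) else float("nan")
    return EventQuant(
        inc_total_reads=int(inc_total),
        exc_total_reads=int(exc_total),
        inc_n_junctions=len(inc_j),
        exc_n_junctions=len(exc_j),
        psi=psi,
        neighbor_coverage=neighbor_confounding(event, junction_coverage),
        quantifiable=quantifiable,
    )


def quantify_events(
    events: Sequence[SplicingEvent],
    junction_coverage: Mapping[tuple[str, int, int], int],
    readthrough: Mapping[tuple[str, int, int], tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Event quantification table (one row per event, indexed by event id)."""
    rows = []
    for ev in events:
        q = quantify_event(ev, junction_coverage, readthrough)
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "event_type": ev.event_type,
                "structure_code": ev.structure_code,
                "is_internal": ev.is_internal,
                "inc_reads": q.inc_total_reads,
                "exc_reads": q.exc_total_reads,
                "inc_n": q.inc_n_junctions,
                "exc_n": q.exc_n_junctions,
                "psi": q.psi,
                "neighbor_coverage": q.neighbor_coverage,
                "quantifiable": q.quantifiable,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "event_type",
            "structure_code",
            "is_internal",
            "inc_reads",
            "exc_reads",
            "inc_n",
            "exc_n",
            "psi",
            "neighbor_coverage",
            "quantifiable",
        ],
    )
    return df.set_index("event_id")


# ---------------------------------------------------------------------------
# External event definitions (AStalavista-style)
# ---------------------------------------------------------------------------

_SITE_RE = re.compile(r"(\d+)([\^\-])")


@dataclass
class EventParseError:
    line_no: int
    message: str


def _attr_map(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        k, _, v = part.partition(" ")
        out[k] = v.strip().strip('"')
    return out


def _chain_junctions(
    chrom: str, left: str | None, chain: str, right: str | None, line_no: int
) -> frozenset:
    """Junctions of one variant: pair '^' donors with following '-' acceptors.

    Sites are 1-based: ``p^`` marks a donor after the exonic base ``p``
    (0-based intron start ``p``); ``a-`` marks an acceptor at the first
    exonic base ``a`` (0-based exclusive intron end ``a - 1``).
    """
    tokens: list[tuple[int, str]] = []
    for text in (left or "", chain, right or ""):
        for m in _SITE_RE.finditer(text):
            tokens.append((int(m.group(1)), m.group(2)))
    juncs = []
    for (pos, mark), (npos, nmark) in zip(tokens, tokens[1:]):
        if mark == "^" and nmark == "-":
            juncs.append((chrom, pos, npos - 1))
    return frozenset(juncs)


def parse_astalavista(
    path: str | Path, annotation: Annotation
) -> tuple[list[SplicingEvent], list[EventParseError]]:
    """Parse an external pairwise event file into SplicingEvents.

    Expects GTF-style ``as_event`` lines with ``structure``,
    ``splice_chain``, ``flanks``, ``transcript_id`` and ``gene_id``
    attributes; two comma-separated variants per record.  Terminal flanks
    may be ``null``.  Unparseable records are reported, not dropped
    silently.
    """
    known_tx = {t.transcript_id for t in annotation.transcripts}
    events: list[SplicingEvent] = []
    errors: list[EventParseError] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9 or fields[2] != "as_event":
                errors.append(EventParseError(line_no, "not an as_event record"))
                continue
            chrom, strand = fields[0], fields[6]
            attrs = _attr_map(fields[8])
            try:
                structure = attrs["structure"]
                chains = attrs.get("splice_chain", ",").split(",")
                flanks = attrs["flanks"].split(",")
                gene_id = attrs["gene_id"]
                tx_attr = attrs.get("transcript_id", "")
            except KeyError as exc:
                errors.append(EventParseError(line_no, f"missing attribute {exc}"))
                continue
            codes = structure.split(",")
            if len(codes) != 2 or len(chains) != 2 or len(flanks) != 2:
                errors.append(
                    EventParseError(line_no, "expected exactly two variants")
                )
                continue
            if not all(re.fullmatch(r"0|(\d+[\^\-])+", c) for c in codes):
                errors.append(
                    EventParseError(line_no, f"malformed structure {structure!r}")
                )
                continue
            bad_tx = None
            for tx_group in tx_attr.split(","):
                for tx in tx_group.split("/"):
                    if tx and tx not in known_tx:
                        bad_tx = tx
            if bad_tx is not None:
                errors.append(
                    EventParseError(line_no, f"unknown transcript {bad_tx!r}")
                )
                continue
            left = None if flanks[0] in ("null", "(null)") else flanks[0]
            right = None if flanks[1] in ("null", "(null)") else flanks[1]
            try:
                j1 = _chain_junctions(chrom, left, chains[0], right, line_no)
                j2 = _chain_junctions(chrom, left, chains[1], right, line_no)
            except FormatError as exc:
                errors.append(EventParseError(line_no, str(exc)))
                continue
            # orient: junction-free variant is exclusion; else larger set first
            if len(j1) == 0 and len(j2) > 0:
                j1, j2 = j2, j1
                codes = codes[::-1]
            elif len(j2) > len(j1):
                j1, j2 = j2, j1
                codes = codes[::-1]
            shared = j1 & j2
            events.append(
                SplicingEvent(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    flank_left=left,
                    flank_right=right,
                    path_inclusion=(),
                    path_exclusion=(),
                    junctions_inclusion=j1 - shared,
                    junctions_exclusion=j2 - shared,
                    event_type="external",
                    structure_code=",".join(sorted(codes)),
                    is_internal=left is not None and right is not None,
                )
            )
    return events, errors
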