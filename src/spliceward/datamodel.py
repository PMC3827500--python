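"""Domain model, FASTA/GTF IO, and deterministic toy fixtures.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open.  An exon ``(start, end)``
covers genomic bases ``start .. end-1``; the intron between two adjacent
exons of a transcript is ``[prev_exon.end, next_exon.start)`` and a junction
is keyed by ``(chrom, intron_start, intron_end, strand)``.  GTF input/output
converts to/from the 1-based inclusive convention at the boundary.

Donor/acceptor motifs are reported strand-oriented: an annotated canonical
intron reads donor ``GT`` / acceptor ``AG`` on either genomic strand (a minus
strand canonical intron has forward-strand genomic sequence ``CT .. AC``).
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import edlib
import gffutils
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Minimum intron length accepted as a splice gap, matching a common
#: aligner setting for compact invertebrate genomes.
MIN_INTRON = 42

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class FormatError(ValueError):
    """Malformed FASTA/GTF/report input."""


class ConfigError(ValueError):
    """Infeasible fixture or simulation configuration."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def percent_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length windows, 100*(w - d)/w.

    ``d`` is the Levenshtein edit distance, so a single indel slippage
    between the windows counts the same as a substitution.
    """
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    if not a:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return max(0.0, 100.0 * (len(a) - d) / len(a))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRef:
    """In-memory genome: chromosome name -> uppercase A/C/G/T/N sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        norm = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                # normalize IUPAC ambiguity codes and gaps to N
                seq = "".join(c if c in "ACGTN" else "N" for c in seq)
            norm[name] = seq
        self.sequences = norm

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.sequences[chrom]) or start > end:
            raise IndexError(
                f"coordinates [{start}, {end}) outside {chrom} "
                f"(length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class Junction:
    """An intron call: chrom + 0-based half-open intron interval + strand.

    ``donor_motif``/``acceptor_motif`` are the strand-oriented terminal
    dinucleotides of the intron (``GT``/``AG`` for a canonical intron).
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "unknown"
    donor_motif: str = "NN"
    acceptor_motif: str = "NN"

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError("intron_end must exceed intron_start")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of disjoint genomic exon intervals."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    """Derived per-gene span and merged exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]  # merged, sorted


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class Annotation:
    """A set of transcript models plus derived gene spans and junctions."""

    transcripts: list[TranscriptModel]
    genes: dict[str, GeneModel] = field(init=False)
    known_junction_keys: set[tuple[str, int, int, str]] = field(init=False)

    def __post_init__(self) -> None:
        per_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
        for t in self.transcripts:
            per_gene[t.gene_id].append(t)
        genes = {}
        for gid, txs in per_gene.items():
            chroms = {t.chrom for t in txs}
            strands = {t.strand for t in txs}
            if len(chroms) > 1 or len(strands) > 1:
                raise FormatError(
                    f"gene {gid}: transcripts on mixed chrom/strand"
                )
            exons = _merge_intervals(
                (s, e) for t in txs for s, e in t.exons
            )
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=txs[0].chrom,
                strand=txs[0].strand,
                start=min(t.start for t in txs),
                end=max(t.end for t in txs),
                exons=exons,
            )
        self.genes = genes
        self.known_junction_keys = {
            (t.chrom, s, e, t.strand)
            for t in self.transcripts
            for s, e in t.introns()
        }

    @property
    def known_junction_intervals(self) -> set[tuple[str, int, int]]:
        return {(c, s, e) for c, s, e, _ in self.known_junction_keys}

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.gene_id == gene_id]

    def known_junctions(self, genome: GenomeRef) -> set[Junction]:
        out = set()
        for t in self.transcripts:
            out.update(junctions_of(t, genome))
        return out


# ---------------------------------------------------------------------------
# Motifs and junction extraction
# ---------------------------------------------------------------------------


def forward_motifs(
    genome: GenomeRef, chrom: str, intron_start: int, intron_end: int
) -> tuple[str, str]:
    """Forward-genomic-strand terminal dinucleotides of an intron."""
    return (
        genome.fetch(chrom, intron_start, intron_start + 2),
        genome.fetch(chrom, intron_end - 2, intron_end),
    )


def oriented_motifs(
    genome: GenomeRef, chrom: str, intron_start: int, intron_end: int, strand: str
) -> tuple[str, str]:
    """Strand-oriented (donor, acceptor) dinucleotides of an intron."""
    d, a = forward_motifs(genome, chrom, intron_start, intron_end)
    if strand == "-":
        return revcomp(a), revcomp(d)
    return d, a


def junctions_of(t: TranscriptModel, genome: GenomeRef) -> list[Junction]:
    """One Junction per adjacent exon pair, with strand-oriented motifs."""
    out = []
    for s, e in t.introns():
        donor, acceptor = oriented_motifs(genome, t.chrom, s, e, t.strand)
        out.append(
            Junction(t.chrom, s, e, t.strand, donor, acceptor)
        )
    return out


# ---------------------------------------------------------------------------
# FASTA / GTF IO
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeRef:
    """Load a FASTA file, case-normalizing to uppercase."""
    seqs: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty or not FASTA-formatted")
    for rec in records:
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return GenomeRef(seqs)


def write_fasta(genome: GenomeRef, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gtf(path: str | Path) -> Annotation:
    """Parse exon features of a GTF file into an Annotation.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  GTF 1-based inclusive coordinates are
    converted to the internal 0-based half-open convention.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc

    per_tx: dict[str, dict] = {}
    n_exons = 0
    for feat in db.features_of_type("exon"):
        n_exons += 1
        attrs = feat.attributes
        if "transcript_id" not in attrs or not attrs["transcript_id"]:
            raise FormatError(f"{path}: exon feature lacks transcript_id")
        if "gene_id" not in attrs or not attrs["gene_id"]:
            raise FormatError(f"{path}: exon feature lacks gene_id")
        tid = attrs["transcript_id"][0]
        gid = attrs["gene_id"][0]
        entry = per_tx.setdefault(
            tid,
            {"gene": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []},
        )
        if entry["gene"] != gid or entry["chrom"] != feat.seqid:
            raise FormatError(f"{path}: transcript {tid} spans genes/chroms")
        entry["exons"].append((feat.start - 1, feat.end))
    if n_exons == 0:
        raise FormatError(f"{path}: no exon features found")

    transcripts = []
    for tid, entry in per_tx.items():
        try:
            transcripts.append(
                TranscriptModel(
                    gene_id=entry["gene"],
                    transcript_id=tid,
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    exons=sorted(entry["exons"]),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write exon features in GTF (1-based inclusive) form."""
    with open(path, "w") as fh:
        for t in sorted(
            annotation.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
        ):
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "spliceward",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Toy fixture generator
# ---------------------------------------------------------------------------

EVENT_TYPES = (
    "exonskip",
    "skip2exons",
    "altdonor",
    "altacceptor",
    "retintron",
    "mutexcl",
    "AltFE",
    "AltLE",
)

DEFAULT_EVENT_FRACTIONS: dict[str, float] = {
    "exonskip": 0.15,
    "altdonor": 0.10,
    "altacceptor": 0.10,
    "retintron": 0.10,
    "mutexcl": 0.10,
    "skip2exons": 0.05,
    "AltFE": 0.05,
    "AltLE": 0.05,
}


@dataclass
class FixtureConfig:
    """Parameters of the toy genome/annotation generator.

    Gene bodies are laid out on a single synthetic chromosome with random
    intergenic spacers.  A configurable fraction of genes carries a second
    isoform implementing exactly one planted pairwise splicing event, so
    every multi-isoform gene is an isolated event (its two isoforms belong
    to no other event).  Optional plantings create the raw material for the
    diagnosed aligner error classes: a proximal duplicated paralog gene, a
    repeat tract whose exon/intron shoulder windows are identical, a
    reverse-motif tract inside a forward-strand gene, a shifted copy of a
    true splice site pair, and an unannotated minor-form (AT-AC) site pair.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (120, 180)
    intron_len: tuple[int, int] = (70, 120)
    intergenic: tuple[int, int] = (250, 450)
    event_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_FRACTIONS)
    )
    minus_fraction: float = 0.3
    alt_shift: int = 12
    alt_terminal_exon_len: int = 90
    n_paralog_pairs: int = 0
    n_repeat_sites: int = 0
    n_wrong_strand_sites: int = 0
    n_shifted_sites: int = 0
    n_minor_sites: int = 0
    min_intron: int = MIN_INTRON
    chrom: str = "chrS"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.intron_len[0] < self.min_intron:
            raise ConfigError(
                f"intron_len minimum {self.intron_len[0]} below "
                f"min_intron {self.min_intron}"
            )
        if self.exon_len[0] < self.alt_shift + 30:
            raise ConfigError("exon_len minimum too small for alt_shift")
        unknown = set(self.event_fractions) - set(EVENT_TYPES)
        if unknown:
            raise ConfigError(f"unknown event types: {sorted(unknown)}")
        total = sum(self.event_fractions.values())
        if total > 1.0 + 1e-9:
            raise ConfigError("event fractions sum above 1")
        if not 0.0 <= self.minus_fraction <= 1.0:
            raise ConfigError("minus_fraction outside [0, 1]")
        planted = (
            self.n_repeat_sites
            + self.n_wrong_strand_sites
            + self.n_shifted_sites
            + self.n_minor_sites
        )
        if planted and self.intron_len[0] < 60:
            raise ConfigError("planted error sites require intron_len >= 60")


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    length: int
    iso_a: list[tuple[int, int]]
    iso_b: list[tuple[int, int]] | None
    event_type: str | None
    inc_juncs: list[tuple[int, int]]
    exc_juncs: list[tuple[int, int]]
    paralog_of: str | None = None


@dataclass
class FixtureSet:
    """A generated toy genome + annotation + truth manifest."""

    genome: GenomeRef
    annotation: Annotation
    manifest: dict

    def __iter__(self):  # allow (genome, annotation) unpacking
        return iter((self.genome, self.annotation))


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)].copy()


def _skeleton(
    rng: np.random.Generator, cfg: FixtureConfig, ev: str | None, strand: str
) -> _GenePlan:
    """Build one gene in gene-relative coordinates."""
    lo, hi = cfg.exons_per_gene
    n = int(rng.integers(lo, hi + 1))
    min_needed = {"skip2exons": 4, "mutexcl": 4}.get(ev, 3) if ev else max(lo, 1)
    n = max(n, min_needed)

    exon_lens = [int(rng.integers(*cfg.exon_len)) for _ in range(n)]
    intron_lens = [int(rng.integers(*cfg.intron_len)) for _ in range(n - 1)]

    # genomic side of terminal-exon events depends on strand
    terminal_side = None
    if ev == "AltFE":
        terminal_side = "left" if strand == "+" else "right"
    elif ev == "AltLE":
        terminal_side = "right" if strand == "+" else "left"
    if terminal_side == "left":
        intron_lens[0] = cfg.min_intron * 2 + cfg.alt_terminal_exon_len + 30
    elif terminal_side == "right":
        intron_lens[-1] = cfg.min_intron * 2 + cfg.alt_terminal_exon_len + 30

    k = None
    if ev in ("exonskip", "altdonor", "altacceptor", "retintron"):
        k = int(rng.integers(1, n - 1))
    elif ev in ("skip2exons", "mutexcl"):
        k = int(rng.integers(1, n - 2))
    if ev == "mutexcl" and exon_lens[k] <= exon_lens[k + 1]:
        # deterministic inclusion orientation: upstream exon is the longer one
        exon_lens[k], exon_lens[k + 1] = exon_lens[k + 1], exon_lens[k]
        if exon_lens[k] == exon_lens[k + 1]:
            exon_lens[k] += 7

    starts, ends = [], []
    pos = 0
    for i in range(n):
        starts.append(pos)
        pos += exon_lens[i]
        ends.append(pos)
        if i < n - 1:
            pos += intron_lens[i]
    length = pos
    iso_a = list(zip(starts, ends))

    iso_b: list[tuple[int, int]] | None = None
    inc: list[tuple[int, int]] = []
    exc: list[tuple[int, int]] = []
    d = cfg.alt_shift

    if ev == "exonskip":
        iso_b = iso_a[:k] + iso_a[k + 1 :]
        inc = [(ends[k - 1], starts[k]), (ends[k], starts[k + 1])]
        exc = [(ends[k - 1], starts[k + 1])]
    elif ev == "skip2exons":
        iso_b = iso_a[:k] + iso_a[k + 2 :]
        inc = [
            (ends[k - 1], starts[k]),
            (ends[k], starts[k + 1]),
            (ends[k + 1], starts[k + 2]),
        ]
        exc = [(ends[k - 1], starts[k + 2])]
    elif ev == "retintron":
        iso_b = iso_a[: k] + [(starts[k], ends[k + 1])] + iso_a[k + 2 :]
        inc = [(ends[k], starts[k + 1])]
        exc = []
    elif ev == "mutexcl":
        iso_a2 = iso_a[: k + 1] + iso_a[k + 2 :]  # uses exon k
        iso_b = iso_a[:k] + iso_a[k + 1 :]  # uses exon k+1
        inc = [(ends[k - 1], starts[k]), (ends[k], starts[k + 2])]
        exc = [(ends[k - 1], starts[k + 1]), (ends[k + 1], starts[k + 2])]
        iso_a = iso_a2
    elif ev in ("altdonor", "altacceptor"):
        # genomic-left shift realizes altdonor on + and altacceptor on -
        left_shift = (ev == "altdonor") == (strand == "+")
        if left_shift:
            j = k - 1 if k == n - 1 else k
            iso_b = list(iso_a)
            iso_b[j] = (starts[j], ends[j] - d)
            inc = [(ends[j], starts[j + 1])]
            exc = [(ends[j] - d, starts[j + 1])]
        else:
            j = k - 1 if k == n - 1 else k
            iso_b = list(iso_a)
            iso_b[j + 1] = (starts[j + 1] + d, ends[j + 1])
            inc = [(ends[j], starts[j + 1])]
            exc = [(ends[j], starts[j + 1] + d)]
    elif ev in ("AltFE", "AltLE"):
        alt_len = cfg.alt_terminal_exon_len
        if terminal_side == "left":
            alt_s = ends[0] + cfg.min_intron + 15
            alt_e = alt_s + alt_len
            iso_b = [(alt_s, alt_e)] + iso_a[1:]
            inc = [(ends[0], starts[1])]
            exc = [(alt_e, starts[1])]
        else:
            alt_s = ends[-2] + cfg.min_intron + 15
            alt_e = alt_s + alt_len
            iso_b = iso_a[:-1] + [(alt_s, alt_e)]
            inc = [(ends[-2], starts[-1])]
            exc = [(ends[-2], alt_s)]
    elif ev is not None:
        raise ConfigError(f"unknown event type {ev!r}")

    return _GenePlan(
        gene_id="",
        strand=strand,
        length=length,
        iso_a=iso_a,
        iso_b=iso_b,
        event_type=ev,
        inc_juncs=inc,
        exc_juncs=exc,
    )


def _plant_motifs(
    seq: np.ndarray, plan: _GenePlan, protected: set[int], offset: int = 0
) -> None:
    """Write splice-site dinucleotides for every junction of both isoforms."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    for iso in (plan.iso_a, plan.iso_b):
        if iso is None:
            continue
        for (s1, e1), (s2, e2) in zip(iso, iso[1:]):
            donors.add(e1)
            acceptors.add(s2)
    dd, aa = ("GT", "AG") if plan.strand == "+" else ("CT", "AC")
    for dpos in donors:
        seq[dpos : dpos + 2] = np.frombuffer(dd.encode(), dtype="S1")
        protected.update((offset + dpos, offset + dpos + 1))
    for apos in acceptors:
        seq[apos - 2 : apos] = np.frombuffer(aa.encode(), dtype="S1")
        protected.update((offset + apos - 2, offset + apos - 1))


def make_toy_fixture(config: FixtureConfig | None = None, seed: int = 0) -> FixtureSet:
    """Generate a deterministic toy genome + annotation + truth manifest."""
    cfg = config or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    # choose event types per gene
    labels = list(cfg.event_fractions)
    probs = [cfg.event_fractions[x] for x in labels]
    p_none = max(0.0, 1.0 - sum(probs))
    pvec = np.array(probs + [p_none], dtype=float)
    pvec = pvec / pvec.sum()
    choices = rng.choice(len(labels) + 1, size=cfg.n_genes, p=pvec)
    strands = np.where(rng.random(cfg.n_genes) < cfg.minus_fraction, "-", "+")

    plans: list[_GenePlan] = []
    for i in range(cfg.n_genes):
        ev = labels[choices[i]] if choices[i] < len(labels) else None
        strand = str(strands[i])
        plan = _skeleton(rng, cfg, ev, strand)
        plan.gene_id = f"G{i:03d}"
        plans.append(plan)

    # paralog pairs: duplicate single-isoform plus-strand gene bodies
    paralog_records = []
    if cfg.n_paralog_pairs:
        donors = [
            p for p in plans if p.iso_b is None and p.strand == "+"
        ]
        while len(donors) < cfg.n_paralog_pairs:
            plan = _skeleton(rng, cfg, None, "+")
            plan.gene_id = f"G{len(plans):03d}"
            plans.append(plan)
            donors.append(plan)
        for j in range(cfg.n_paralog_pairs):
            src = donors[j]
            copy = _GenePlan(
                gene_id=src.gene_id + "p",
                strand=src.strand,
                length=src.length,
                iso_a=list(src.iso_a),
                iso_b=None,
                event_type=None,
                inc_juncs=[],
                exc_juncs=[],
                paralog_of=src.gene_id,
            )
            # place the copy immediately after its source
            idx = plans.index(src)
            plans.insert(idx + 1, copy)

    # lay out the chromosome
    parts: list[np.ndarray] = []
    protected: set[int] = set()
    pos = 0
    offsets: dict[str, int] = {}
    gene_seqs: dict[str, np.ndarray] = {}
    for plan in plans:
        gap = int(rng.integers(*cfg.intergenic))
        if plan.paralog_of is not None:
            gap = 200
        parts.append(_rand_seq(rng, gap))
        pos += gap
        offsets[plan.gene_id] = pos
        if plan.paralog_of is not None:
            seq = gene_seqs[plan.paralog_of].copy()
        else:
            seq = _rand_seq(rng, plan.length)
            _plant_motifs(seq, plan, protected, offset=pos)
        gene_seqs[plan.gene_id] = seq
        parts.append(seq)
        pos += plan.length
    parts.append(_rand_seq(rng, 100))
    chrom_arr = np.concatenate(parts)
    chrom_len = len(chrom_arr)

    # absolute-coordinate transcripts and manifest events
    transcripts: list[TranscriptModel] = []
    events = []
    gene_entries = []
    for plan in plans:
        off = offsets[plan.gene_id]

        def _abs(ivals):
            return [(s + off, e + off) for s, e in ivals]

        tx_ids = [plan.gene_id + ".A"]
        transcripts.append(
            TranscriptModel(
                gene_id=plan.gene_id,
                transcript_id=plan.gene_id + ".A",
                chrom=cfg.chrom,
                strand=plan.strand,
                exons=_abs(plan.iso_a),
            )
        )
        if plan.iso_b is not None:
            tx_ids.append(plan.gene_id + ".B")
            transcripts.append(
                TranscriptModel(
                    gene_id=plan.gene_id,
                    transcript_id=plan.gene_id + ".B",
                    chrom=cfg.chrom,
                    strand=plan.strand,
                    exons=_abs(plan.iso_b),
                )
            )
            events.append(
                {
                    "gene_id": plan.gene_id,
                    "event_type": plan.event_type,
                    "chrom": cfg.chrom,
                    "strand": plan.strand,
                    "inclusion_tx": plan.gene_id + ".A",
                    "exclusion_tx": plan.gene_id + ".B",
                    "inclusion_junctions": [
                        (cfg.chrom, s + off, e + off) for s, e in plan.inc_juncs
                    ],
                    "exclusion_junctions": [
                        (cfg.chrom, s + off, e + off) for s, e in plan.exc_juncs
                    ],
                }
            )
        gene_entries.append(
            {
                "gene_id": plan.gene_id,
                "strand": plan.strand,
                "start": off,
                "end": off + plan.length,
                "transcripts": tx_ids,
                "paralog_of": plan.paralog_of,
            }
        )
        if plan.paralog_of is not None:
            paralog_records.append(
                {
                    "gene_a": plan.paralog_of,
                    "gene_b": plan.gene_id,
                    "offset": off - offsets[plan.paralog_of],
                }
            )

    # planted error-class sites (on plus-strand, non-paralog genes)
    def _plus_targets():
        out = []
        for plan in plans:
            if plan.strand != "+" or plan.paralog_of is not None:
                continue
            off = offsets[plan.gene_id]
            for (s1, e1), (s2, e2) in zip(plan.iso_a, plan.iso_a[1:]):
                out.append((plan.gene_id, e1 + off, s2 + off))
        return out

    targets = _plus_targets()
    rng.shuffle(targets)
    need = (
        cfg.n_repeat_sites
        + cfg.n_wrong_strand_sites
        + cfg.n_shifted_sites
        + cfg.n_minor_sites
    )
    if need > len(targets):
        raise ConfigError(
            f"not enough plus-strand introns ({len(targets)}) for "
            f"{need} planted error sites"
        )
    it = iter(targets)
    repeat_sites, wrong_strand_sites, shifted_sites, minor_sites = [], [], [], []

    def _set(seq_pos: int, text: str) -> None:
        for i, ch in enumerate(text):
            chrom_arr[seq_pos + i] = ch.encode()
            protected.add(seq_pos + i)

    for _ in range(cfg.n_repeat_sites):
        gid, istart, iend = next(it)
        p = istart - 12  # window [p-10, p+10) inside the upstream exon
        q = p + 60  # inside the intron: [q-10, q+10) clear of boundaries
        chrom_arr[q - 10 : q + 10] = chrom_arr[p - 10 : p + 10]
        protected.update(range(q - 10, q + 10))
        protected.update(range(p - 10, p + 10))
        repeat_sites.append({"gene_id": gid, "chrom": cfg.chrom, "start": p, "end": q})
    for _ in range(cfg.n_wrong_strand_sites):
        gid, istart, iend = next(it)
        x = istart + 6
        y = x + 44  # >= min intron, inside the intron
        _set(x, "CT")
        _set(y - 2, "AC")
        wrong_strand_sites.append(
            {"gene_id": gid, "chrom": cfg.chrom, "start": x, "end": y}
        )
    for _ in range(cfg.n_shifted_sites):
        gid, istart, iend = next(it)
        _set(istart + 4, "GT")
        _set(iend + 2, "AG")
        shifted_sites.append(
            {
                "gene_id": gid,
                "chrom": cfg.chrom,
                "start": istart + 4,
                "end": iend + 4,
                "true_start": istart,
                "true_end": iend,
            }
        )
    for _ in range(cfg.n_minor_sites):
        gid, istart, iend = next(it)
        _set(istart + 6, "AT")
        _set(iend + 4, "AC")
        minor_sites.append(
            {
                "gene_id": gid,
                "chrom": cfg.chrom,
                "start": istart + 6,
                "end": iend + 6,
                "true_start": istart,
                "true_end": iend,
            }
        )

    genome = GenomeRef({cfg.chrom: chrom_arr.tobytes().decode()})
    annotation = Annotation(transcripts)

    # guard: no true junction may accidentally look repeat-induced
    _scrub_repeat_lookalikes(genome, annotation, protected, rng, cfg)

    manifest = {
        "seed": int(seed),
        "chrom": cfg.chrom,
        "genes": gene_entries,
        "events": events,
        "paralogs": paralog_records,
        "repeat_sites": repeat_sites,
        "wrong_strand_sites": wrong_strand_sites,
        "shifted_sites": shifted_sites,
        "minor_sites": minor_sites,
    }
    return FixtureSet(genome, annotation, manifest)


def _scrub_repeat_lookalikes(
    genome: GenomeRef,
    annotation: Annotation,
    protected: set[int],
    rng: np.random.Generator,
    cfg: FixtureConfig,
    threshold: float = 80.0,
    window: int = 10,
) -> None:
    """Mutate free intron-interior bases so no annotated junction's
    shoulder windows exceed the repeat-identity threshold."""
    chrom = cfg.chrom
    arr = np.frombuffer(genome.sequences[chrom].encode(), dtype="S1").copy()
    changed = False
    for c, s, e in sorted(annotation.known_junction_intervals):
        if s < window or e + window > len(arr):
            continue
        for _ in range(100):
            don = percent_identity(
                arr[s - window : s].tobytes().decode(),
                arr[e - window : e].tobytes().decode(),
            )
            acc = percent_identity(
                arr[s : s + window].tobytes().decode(),
                arr[e : e + window].tobytes().decode(),
            )
            if max(don, acc) <= threshold:
                break
            # mutate a free base inside the intron end windows
            candidates = [
                p
                for p in list(range(e - window, e - 2)) + list(range(s + 2, s + window))
                if p not in protected
            ]
            if not candidates:
                break
            p = int(rng.choice(candidates))
            old = arr[p]
            alts = [b for b in b"ACGT" if bytes([b]) != old]
            arr[p] = bytes([int(rng.choice(alts))])
            changed = True
    if changed:
        genome.sequences[chrom] = arr.tobytes().decode()


def write_fixture(fixture: FixtureSet, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf and manifest.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(fixture.genome, paths["fasta"])
    write_gtf(fixture.annotation, paths["gtf"])
    with open(paths["manifest"], "w") as fh:
        json.dump(fixture.manifest, fh, indent=1)
    return paths
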