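"""Paired-end read simulator with modeled errors and full truth reporting.

Reads are drawn from spliced transcript templates (or, for a configurable
fraction of pairs, from the unspliced pre-mRNA template to emulate intron
retention), with fragment lengths from a normal distribution, sequencing
errors injected from an :mod:`spliceward.errormodel` model, the genomic
blocks of origin encoded in every read identifier, and a truth SAM that
represents a perfect alignment of every read.

Coverage accounting: per-transcript coverage ``X`` means an expected
``X``-fold base coverage of the spliced template, i.e.
``pairs = round(X * length / (2 * read_length))``; RPK mode uses
``pairs = round(rpk * length / 1000)``.  Rounding is half-even.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    Annotation,
    ConfigError,
    FormatError,
    GenomeRef,
    TranscriptModel,
    revcomp,
)
from .errormodel import (
    ErrorModel,
    builtin_model,
    consensus_quality_string,
    sample_read_errors,
)

logger = logging.getLogger(__name__)

_ID_SEP = "|"


@dataclass
class SimConfig:
    """Simulation parameters.  Exactly one coverage mode must be set."""

    coverage: float | None = None
    rpk: float | None = None
    abundance_table: Mapping[str, float] | None = None  # transcript -> RPK
    read_length: int = 76
    frag_mean: float = 200.0
    frag_sd: float = 20.0
    intron_retention: float = 0.20
    error_model: ErrorModel | str = "uniform"
    seed: int = 0
    min_overhang: int = 8
    min_intron: int = 42

    def validate(self) -> None:
        modes = sum(
            x is not None for x in (self.coverage, self.rpk, self.abundance_table)
        )
        if modes != 1:
            raise ConfigError(
                "exactly one of coverage, rpk, abundance_table must be set"
            )
        if self.frag_mean < self.read_length:
            raise ConfigError("frag_mean must be >= read_length")
        if not 0.0 <= self.intron_retention <= 1.0:
            raise ConfigError("intron_retention outside [0, 1]")

    def resolve_model(self) -> ErrorModel:
        if isinstance(self.error_model, ErrorModel):
            return self.error_model
        return builtin_model(self.error_model, self.read_length)


@dataclass
class TruthAlignment:
    """A perfect alignment of one simulated read."""

    qname: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    reverse: bool
    seq: str  # reference-orientation sequence (as stored in SAM)
    qual: str  # reference-orientation qualities

    @property
    def pos(self) -> int:
        return self.blocks[0][0]

    def cigar(self) -> str:
        parts = []
        for i, (s, e) in enumerate(self.blocks):
            if i:
                parts.append(f"{s - self.blocks[i - 1][1]}N")
            parts.append(f"{e - s}M")
        return "".join(parts)


@dataclass
class SimTruth:
    """Truth tables of a simulation run."""

    transcript_pairs: dict[str, int]
    junction_counts: dict[tuple[str, int, int], int]
    pair_table: pd.DataFrame  # transcript_id, kind, frag_len

    @property
    def total_pairs(self) -> int:
        return int(sum(self.transcript_pairs.values()))


@dataclass
class SimResult:
    reads1: list[tuple[str, str, str]]  # (id, seq, qual)
    reads2: list[tuple[str, str, str]]
    alignments: list[TruthAlignment]
    truth: SimTruth

    def write(self, outdir: str | Path, genome: GenomeRef) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq1": outdir / "sim_1.fastq",
            "fastq2": outdir / "sim_2.fastq",
            "sam": outdir / "truth.sam",
            "junctions": outdir / "truth_junctions.tsv",
            "transcripts": outdir / "truth_transcripts.tsv",
        }
        write_fastq(self.reads1, paths["fastq1"])
        write_fastq(self.reads2, paths["fastq2"])
        write_truth_sam(self.alignments, genome, paths["sam"])
        jt = pd.DataFrame(
            [
                {"chrom": c, "intron_start": s, "intron_end": e, "truth_coverage": n}
                for (c, s, e), n in sorted(self.truth.junction_counts.items())
            ]
        )
        jt.to_csv(paths["junctions"], sep="\t", index=False)
        tt = pd.DataFrame(
            [
                {"transcript_id": t, "pairs": n}
                for t, n in sorted(self.truth.transcript_pairs.items())
            ]
        )
        tt.to_csv(paths["transcripts"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Origin-encoding read identifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadOrigin:
    transcript_id: str
    kind: str  # spliced | unspliced
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mate: int
    serial: int

    def junctions(self, min_intron: int = 1) -> list[tuple[str, int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 - e1 >= min_intron:
                out.append((self.chrom, e1, s2))
        return out


def encode_origin(
    transcript_id: str,
    template_kind: str,
    chrom: str,
    genomic_blocks: Sequence[tuple[int, int]],
    mate: int,
    serial: int,
) -> str:
    """Encode a read's genomic origin into its identifier."""
    if template_kind not in ("spliced", "unspliced"):
        raise ValueError(f"bad template kind {template_kind!r}")
    if not genomic_blocks:
        raise ValueError("at least one genomic block required")
    blocks = ",".join(f"{s}-{e}" for s, e in genomic_blocks)
    return _ID_SEP.join(
        [transcript_id, template_kind, chrom, blocks, str(mate), str(serial)]
    )


def decode_origin(read_id: str) -> ReadOrigin:
    parts = read_id.split(_ID_SEP)
    if len(parts) != 6:
        raise FormatError(f"malformed origin-encoded read id {read_id!r}")
    tx, kind, chrom, blocks_s, mate_s, serial_s = parts
    if kind not in ("spliced", "unspliced"):
        raise FormatError(f"bad template kind in read id {read_id!r}")
    try:
        blocks = tuple(
            (int(b.split("-")[0]), int(b.split("-")[1]))
            for b in blocks_s.split(",")
        )
        mate = int(mate_s)
        serial = int(serial_s)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed origin-encoded read id {read_id!r}") from exc
    return ReadOrigin(tx, kind, chrom, blocks, mate, serial)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass
class _Template:
    transcript_id: str
    chrom: str
    kind: str
    seq: str
    exons: list[tuple[int, int]]  # genomic blocks composing the template
    cum: np.ndarray  # cumulative template offsets of exon starts

    def map_blocks(self, a: int, b: int) -> tuple[tuple[int, int], ...]:
        """Map template interval [a, b) to genomic blocks."""
        out = []
        for (gs, ge), off in zip(self.exons, self.cum):
            length = ge - gs
            lo = max(a, off)
            hi = min(b, off + length)
            if lo < hi:
                out.append((gs + (lo - off), gs + (hi - off)))
        return tuple(out)


def _make_templates(t: TranscriptModel, genome: GenomeRef) -> tuple[_Template, _Template]:
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    cum = np.cumsum([0] + [e - s for s, e in t.exons[:-1]])
    spliced = _Template(t.transcript_id, t.chrom, "spliced", seq, list(t.exons), cum)
    useq = genome.fetch(t.chrom, t.start, t.end)
    unspliced = _Template(
        t.transcript_id,
        t.chrom,
        "unspliced",
        useq,
        [(t.start, t.end)],
        np.array([0]),
    )
    return spliced, unspliced


def _pairs_for(t: TranscriptModel, cfg: SimConfig) -> int:
    L = t.spliced_length
    if cfg.coverage is not None:
        return int(np.round(cfg.coverage * L / (2 * cfg.read_length)))
    if cfg.rpk is not None:
        return int(np.round(cfg.rpk * L / 1000.0))
    rpk = cfg.abundance_table.get(t.transcript_id, 0.0)
    return int(np.round(rpk * L / 1000.0))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(annotation: Annotation, genome: GenomeRef, cfg: SimConfig) -> SimResult:
    """Simulate paired-end reads with truth reporting.

    Deterministic for a fixed config+seed: transcripts are processed in
    sorted order and all stochastic choices flow from one seeded generator
    (per-pair draw order: retention flag, fragment length, fragment start,
    then mate-1 and mate-2 error draws).
    """
    cfg.validate()
    if not annotation.transcripts:
        raise ConfigError("empty annotation")
    model = cfg.resolve_model()
    L = cfg.read_length
    rng = np.random.default_rng(cfg.seed)

    reads1: list[tuple[str, str, str]] = []
    reads2: list[tuple[str, str, str]] = []
    alignments: list[TruthAlignment] = []
    tx_pairs: dict[str, int] = {}
    pair_rows: list[tuple[str, str, int]] = []
    serial = 0
    qual_clean = consensus_quality_string(model, [])
    count_keys = np.array(list(model.mismatch_count_dist.keys()))
    count_probs = np.array(list(model.mismatch_count_dist.values()))
    count_probs = count_probs / count_probs.sum()

    for t in sorted(annotation.transcripts, key=lambda x: x.transcript_id):
        n_pairs = _pairs_for(t, cfg)
        if n_pairs <= 0:
            continue
        if t.spliced_length < L:
            logger.warning(
                "transcript %s shorter than read length; skipped", t.transcript_id
            )
            continue
        spliced, unspliced = _make_templates(t, genome)
        made = 0
        retained_flags = rng.random(n_pairs) < cfg.intron_retention
        mm_counts = rng.choice(count_keys, size=(n_pairs, 2), p=count_probs)
        for i in range(n_pairs):
            tpl = unspliced if retained_flags[i] else spliced
            tlen = len(tpl.seq)
            frag = None
            for _ in range(100):
                f = int(np.round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
                if L <= f <= tlen:
                    frag = f
                    break
            if frag is None:
                logger.warning(
                    "cannot draw a fragment for %s (template %d bp); pair skipped",
                    t.transcript_id,
                    tlen,
                )
                continue
            start = int(rng.integers(0, tlen - frag + 1))
            serial += 1
            made += 1
            pair_rows.append((t.transcript_id, tpl.kind, frag))

            # mate 1: forward at the fragment 5' end
            a1, b1 = start, start + L
            blocks1 = tpl.map_blocks(a1, b1)
            read1 = tpl.seq[a1:b1]
            pos1, subs1 = sample_read_errors(
                model, rng, ref_bases=read1, count=int(mm_counts[i, 0])
            )
            read1 = _apply_subs(read1, pos1, subs1)
            q1 = consensus_quality_string(model, pos1) if pos1 else qual_clean
            id1 = encode_origin(
                t.transcript_id, tpl.kind, tpl.chrom, blocks1, 1, serial
            )
            reads1.append((id1, read1, q1))
            alignments.append(
                TruthAlignment(id1, tpl.chrom, blocks1, False, read1, q1)
            )

            # mate 2: reverse complement of the fragment 3' end
            a2, b2 = start + frag - L, start + frag
            blocks2 = tpl.map_blocks(a2, b2)
            fwd2 = tpl.seq[a2:b2]
            read2 = revcomp(fwd2)
            pos2, subs2 = sample_read_errors(
                model, rng, ref_bases=read2, count=int(mm_counts[i, 1])
            )
            read2 = _apply_subs(read2, pos2, subs2)
            q2 = consensus_quality_string(model, pos2) if pos2 else qual_clean
            id2 = encode_origin(
                t.transcript_id, tpl.kind, tpl.chrom, blocks2, 2, serial
            )
            reads2.append((id2, read2, q2))
            alignments.append(
                TruthAlignment(id2, tpl.chrom, blocks2, True, revcomp(read2), q2[::-1])
            )
        if made:
            tx_pairs[t.transcript_id] = made

    if not alignments:
        raise ConfigError("simulation produced no reads; check coverage settings")

    junction_counts = truth_junction_coverage(
        alignments, min_overhang=cfg.min_overhang, min_intron=cfg.min_intron
    )
    truth = SimTruth(
        transcript_pairs=tx_pairs,
        junction_counts=dict(junction_counts),
        pair_table=pd.DataFrame(
            pair_rows, columns=["transcript_id", "kind", "frag_len"]
        ),
    )
    return SimResult(reads1, reads2, alignments, truth)


def _apply_subs(
    seq: str, positions: Sequence[int], subs: Sequence[tuple[str, str]]
) -> str:
    if not positions:
        return seq
    chars = list(seq)
    for p, (_ref, alt) in zip(positions, subs):
        chars[p] = alt
    return "".join(chars)


def truth_junction_coverage(
    source: Iterable[TruthAlignment] | Iterable[ReadOrigin] | Iterable[str],
    min_overhang: int = 8,
    min_intron: int = 42,
) -> Counter:
    """Per-junction spanning-read counts recomputed from truth records.

    A read supports junction (c, s, e) iff one of its block gaps equals the
    intron and both flanking blocks are at least ``min_overhang`` long.
    """
    counts: Counter = Counter()
    for item in source:
        if isinstance(item, str):
            item = decode_origin(item)
        chrom = item.chrom
        blocks = item.blocks
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 - e1 < min_intron:
                continue
            if e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                counts[(chrom, e1, s2)] += 1
    return counts


# ---------------------------------------------------------------------------
# Pool designs
# ---------------------------------------------------------------------------


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def simulate_null_pools(
    annotation: Annotation,
    genome: GenomeRef,
    rpk: float,
    n_pools: int,
    seed: int = 0,
    **cfg_kwargs,
) -> list[SimResult]:
    """Independent pools with every transcript at equal RPK (null design)."""
    if rpk <= 0:
        raise ConfigError("rpk must be positive")
    out = []
    for s in _child_seeds(seed, n_pools):
        cfg = SimConfig(rpk=rpk, seed=s, **cfg_kwargs)
        out.append(simulate(annotation, genome, cfg))
    return out


def simulate_delta_psi(
    events: Sequence[Mapping],
    annotation: Annotation,
    genome: GenomeRef,
    psi_a: float,
    psi_b: float,
    total_rpk: float = 1000.0,
    seed: int = 0,
    **cfg_kwargs,
) -> tuple[SimResult, SimResult]:
    """Two pools with designed PSI per event.

    ``events`` are manifest-style records with ``inclusion_tx`` and
    ``exclusion_tx``.  Within each event the two isoforms are simulated at
    RPK ``total_rpk * psi`` and ``total_rpk * (1 - psi)``, so the designed
    event-level difference is ``psi_a - psi_b`` for every event.  Events
    whose isoforms take part in any other event are rejected: isolation
    prevents cross-talk between designed proportions.
    """
    for psi in (psi_a, psi_b):
        if not 0.0 < psi < 1.0:
            raise ConfigError(f"psi={psi} outside (0, 1): ratio not simulable")
    seen: dict[str, str] = {}
    for ev in events:
        for tx in (ev["inclusion_tx"], ev["exclusion_tx"]):
            if tx in seen:
                raise ConfigError(
                    f"transcript {tx} shared between events "
                    f"({seen[tx]} and {ev['gene_id']}): events must be isolated"
                )
            seen[tx] = ev["gene_id"]

    def _table(psi: float) -> dict[str, float]:
        table: dict[str, float] = {}
        for ev in events:
            table[ev["inclusion_tx"]] = total_rpk * psi
            table[ev["exclusion_tx"]] = total_rpk * (1.0 - psi)
        return table

    seeds = _child_seeds(seed, 2)
    res_a = simulate(
        annotation, genome, SimConfig(abundance_table=_table(psi_a), seed=seeds[0], **cfg_kwargs)
    )
    res_b = simulate(
        annotation, genome, SimConfig(abundance_table=_table(psi_b), seed=seeds[1], **cfg_kwargs)
    )
    return res_a, res_b


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_sam(
    alignments: Iterable[TruthAlignment], genome: GenomeRef, path: str | Path
) -> None:
    """Write the perfect-alignment SAM (mapping quality 255, exact CIGARs)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        refs = {name: i for i, name in enumerate(genome.sequences)}
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.qname
            seg.reference_id = refs[a.chrom]
            seg.reference_start = a.pos
            seg.mapping_quality = 255
            seg.cigarstring = a.cigar()
            flag = 1 | 2
            if a.reverse:
                flag |= 16 | 128
            else:
                flag |= 32 | 64
            seg.flag = flag
            seg.query_sequence = a.seq
            seg.query_qualities = pysam.qualitystring_to_array(a.qual)
            out.write(seg)
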