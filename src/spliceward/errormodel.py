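"""Empirical sequencing-error models estimated from permissive alignments.

The model captures, for reads of uniform length L:

* the per-position mismatch frequency (fraction of reads mismatching at
  each cycle),
* per-position 4x4 substitution weights (reference base -> called base,
  diagonal zero), with a position-marginal fallback for sparse cells,
* the empirical distribution of per-read total mismatch counts, and
* two consensus (modal) quality strings, one for matched and one for
  mismatched positions.

Reverse-strand alignment records are reflected back into read orientation
(position ``L-1-pos``, bases complemented, qualities reversed) before
tallying, so the model is expressed in sequencing-cycle coordinates.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from scipy import stats

from .datamodel import revcomp

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

#: below this many observations a (position, ref-base) substitution row
#: falls back to the position-marginal substitution matrix
SPARSE_ROW_MIN = 10


class ModelError(ValueError):
    """Raised for empty/inconsistent model input or unknown model names."""


@dataclass
class MismatchRecord:
    """One ungapped alignment, in alignment orientation.

    ``mismatches`` holds (position, reference_base, called_base) triples;
    ``reverse`` marks a reverse-strand alignment whose coordinates must be
    reflected into read orientation during tallying.
    """

    length: int
    mismatches: list[tuple[int, str, str]]
    quals: str
    reverse: bool = False


@dataclass
class ErrorModel:
    read_length: int
    mismatch_rate_by_pos: np.ndarray  # (L,) frequencies in [0, 1]
    substitution_weights: np.ndarray  # (L, 4, 4) row-normalized where observed
    substitution_counts: np.ndarray  # (L, 4, 4) raw tallies (joint sampling)
    marginal_substitution: np.ndarray  # (4, 4) position-marginal weights
    mismatch_count_dist: dict[int, float]
    qual_match_by_pos: str
    qual_mismatch_by_pos: str
    name: str = "empirical"

    def validate(self) -> None:
        L = self.read_length
        if self.mismatch_rate_by_pos.shape != (L,):
            raise ModelError("mismatch rate vector has wrong length")
        if np.any(self.mismatch_rate_by_pos < 0) or np.any(
            self.mismatch_rate_by_pos > 1
        ):
            raise ModelError("mismatch rates outside [0, 1]")
        total = sum(self.mismatch_count_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ModelError("mismatch count distribution does not sum to 1")
        rows = self.substitution_weights.sum(axis=2)
        bad = (np.abs(rows - 1.0) > 1e-9) & (rows > 0)
        if np.any(bad):
            raise ModelError("substitution rows do not sum to 1")
        if len(self.qual_match_by_pos) != L or len(self.qual_mismatch_by_pos) != L:
            raise ModelError("quality strings must have length L")


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------


def _modal_qual(counter: Counter) -> str | None:
    """Most frequent quality character; ties broken toward higher quality."""
    if not counter:
        return None
    best = max(counter.items(), key=lambda kv: (kv[1], ord(kv[0])))
    return best[0]


def build_error_model(
    records: Iterable[MismatchRecord], read_length: int
) -> ErrorModel:
    """Tally an ErrorModel from a stream of ungapped alignment records."""
    L = read_length
    n_reads = 0
    pos_mm = np.zeros(L, dtype=np.int64)
    sub_counts = np.zeros((L, 4, 4), dtype=np.int64)
    count_hist: Counter = Counter()
    qual_match = [Counter() for _ in range(L)]
    qual_mismatch = [Counter() for _ in range(L)]

    for rec in records:
        if rec.length != L:
            raise ModelError(
                f"mixed read lengths: expected {L}, got {rec.length}"
            )
        n_reads += 1
        if rec.reverse:
            mms = [
                (L - 1 - p, revcomp(r), revcomp(a)) for p, r, a in rec.mismatches
            ]
            quals = rec.quals[::-1]
        else:
            mms = list(rec.mismatches)
            quals = rec.quals
        mm_pos = set()
        for p, ref, alt in mms:
            if ref not in _B2I or alt not in _B2I or ref == alt:
                continue
            mm_pos.add(p)
            pos_mm[p] += 1
            sub_counts[p, _B2I[ref], _B2I[alt]] += 1
        count_hist[len(mm_pos)] += 1
        for p in range(L):
            (qual_mismatch[p] if p in mm_pos else qual_match[p])[quals[p]] += 1

    if n_reads == 0:
        raise ModelError("empty alignment stream")

    rate = pos_mm / n_reads
    marginal_counts = sub_counts.sum(axis=0).astype(float)
    marg_rows = marginal_counts.sum(axis=1, keepdims=True)
    marginal = np.divide(
        marginal_counts, marg_rows, out=np.zeros_like(marginal_counts),
        where=marg_rows > 0,
    )
    weights = np.zeros((L, 4, 4), dtype=float)
    for p in range(L):
        for r in range(4):
            row = sub_counts[p, r].astype(float)
            tot = row.sum()
            if tot >= SPARSE_ROW_MIN:
                weights[p, r] = row / tot
            elif marg_rows[r, 0] > 0:
                weights[p, r] = marginal[r]
            elif tot > 0:
                weights[p, r] = row / tot

    qm, qx = [], []
    for p in range(L):
        m = _modal_qual(qual_match[p]) or "I"
        x = _modal_qual(qual_mismatch[p]) or m
        qm.append(m)
        qx.append(x)

    dist = {int(k): v / n_reads for k, v in sorted(count_hist.items())}
    model = ErrorModel(
        read_length=L,
        mismatch_rate_by_pos=rate,
        substitution_weights=weights,
        substitution_counts=sub_counts,
        marginal_substitution=marginal,
        mismatch_count_dist=dist,
        qual_match_by_pos="".join(qm),
        qual_mismatch_by_pos="".join(qx),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Alignment parsers
# ---------------------------------------------------------------------------


def iter_sam_records(source: str | Path | Iterable) -> Iterator[MismatchRecord]:
    """Yield MismatchRecords from SAM/BAM alignments (MD tag required).

    Gapped (spliced/indel) and unmapped records are skipped: the model is
    estimated from permissive *ungapped* alignments only.
    """
    if isinstance(source, (str, Path)):
        aln = pysam.AlignmentFile(str(source), check_sq=False)
        reads = aln
    else:
        reads = source
    for read in reads:
        if read.is_unmapped or read.query_sequence is None:
            continue
        if any(op in (1, 2, 3) for op, _ in (read.cigartuples or [])):
            continue
        if not read.has_tag("MD"):
            raise ModelError(f"read {read.query_name}: MD tag required")
        mms = []
        for qpos, rpos, refbase in read.get_aligned_pairs(with_seq=True):
            if qpos is None or rpos is None or refbase is None:
                continue
            if refbase.islower():
                mms.append((qpos, refbase.upper(), read.query_sequence[qpos]))
        quals = (
            "".join(chr(q + 33) for q in read.query_qualities)
            if read.query_qualities is not None
            else "I" * len(read.query_sequence)
        )
        yield MismatchRecord(
            length=len(read.query_sequence),
            mismatches=mms,
            quals=quals,
            reverse=read.is_reverse,
        )


def iter_bowtie_records(path: str | Path) -> Iterator[MismatchRecord]:
    """Yield MismatchRecords from bowtie map-format text lines.

    Columns: name, strand, reference, offset, sequence, qualities,
    reserved, comma-separated mismatch descriptors ``pos:REF>ALT``.
    """
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ModelError(f"bad bowtie map line: {line[:60]!r}")
            strand, seq, quals = fields[1], fields[4], fields[5]
            mms = []
            if len(fields) >= 8 and fields[7]:
                for token in fields[7].split(","):
                    pos_s, sub = token.split(":")
                    ref, alt = sub.split(">")
                    mms.append((int(pos_s), ref, alt))
            yield MismatchRecord(
                length=len(seq),
                mismatches=mms,
                quals=quals,
                reverse=(strand == "-"),
            )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_read_errors(
    model: ErrorModel,
    rng: np.random.Generator,
    ref_bases: str | None = None,
    count: int | None = None,
) -> tuple[list[int], list[tuple[str, str]]]:
    """Draw mismatch positions and substitutions for one read.

    The per-read mismatch count is drawn from the empirical count
    distribution; positions are drawn without replacement weighted by the
    per-position mismatch rates; each substitution comes from the
    position's substitution weights.  When ``ref_bases`` (the read's true
    sequence) is given the substitution is conditioned on the actual
    reference base at the drawn position, falling back to a uniform choice
    over the three alternatives when that base was never observed
    mismatching; without ``ref_bases`` the joint empirical (ref, alt)
    distribution at the position is sampled.  ``count`` overrides the
    count draw (used by callers that pre-draw counts in bulk).
    """
    L = model.read_length
    if count is None:
        counts = np.array(list(model.mismatch_count_dist.keys()))
        probs = np.array(list(model.mismatch_count_dist.values()))
        k = int(rng.choice(counts, p=probs / probs.sum()))
    else:
        k = int(count)  # pre-drawn by a vectorized caller
    if k > L:
        logger.warning("sampled mismatch count %d exceeds read length %d", k, L)
        k = L
    if k == 0:
        return [], []

    w = model.mismatch_rate_by_pos.astype(float)
    if w.sum() <= 0 or np.count_nonzero(w) < k:
        positions = rng.choice(L, size=k, replace=False)
    else:
        positions = rng.choice(L, size=k, replace=False, p=w / w.sum())
    positions = sorted(int(p) for p in positions)

    subs: list[tuple[str, str]] = []
    for p in positions:
        if ref_bases is not None:
            ref = ref_bases[p].upper()
            if ref in _B2I:
                row = model.substitution_weights[p, _B2I[ref]]
                if row.sum() > 0:
                    alt = BASES[int(rng.choice(4, p=row / row.sum()))]
                else:
                    alt = rng.choice([b for b in BASES if b != ref])
            else:  # N in the template: substitute uniformly
                ref = "N"
                alt = BASES[int(rng.integers(4))]
            subs.append((ref, str(alt)))
        else:
            joint = model.substitution_counts[p].astype(float).ravel()
            if joint.sum() > 0:
                idx = int(rng.choice(16, p=joint / joint.sum()))
            else:
                r = int(rng.integers(4))
                a = int(rng.choice([i for i in range(4) if i != r]))
                idx = r * 4 + a
            subs.append((BASES[idx // 4], BASES[idx % 4]))
    return positions, subs


def consensus_quality_string(
    model: ErrorModel, mismatch_positions: Sequence[int]
) -> str:
    """Positionwise splice of the match/mismatch consensus quality strings."""
    mm = set(mismatch_positions)
    if any(p < 0 or p >= model.read_length for p in mm):
        raise ValueError("mismatch position outside read")
    return "".join(
        model.qual_mismatch_by_pos[i] if i in mm else model.qual_match_by_pos[i]
        for i in range(model.read_length)
    )


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------


def _uniform_substitutions(L: int) -> np.ndarray:
    w = np.full((L, 4, 4), 1.0 / 3.0)
    for i in range(4):
        w[:, i, i] = 0.0
    return w


def _truncated_poisson(mean: float, L: int) -> dict[int, float]:
    ks = np.arange(0, L + 1)
    pmf = stats.poisson.pmf(ks, mean)
    pmf = pmf / pmf.sum()
    return {int(k): float(p) for k, p in zip(ks, pmf) if p > 1e-12}


def builtin_model(name: str, read_length: int = 76, rate: float = 0.01) -> ErrorModel:
    """Return a named built-in error model.

    ``uniform``: constant per-position mismatch rate, uniform substitutions,
    truncated-Poisson count distribution.  ``ramp``: mismatch rate rising
    toward the 3' end of the read with a slight elevation over the first
    five cycles, mimicking typical Illumina error profiles.
    """
    L = read_length
    if name == "uniform":
        rates = np.full(L, rate)
    elif name == "ramp":
        i = np.arange(L)
        rates = 0.004 + 0.016 * (i / max(L - 1, 1)) ** 2 + 0.006 * np.exp(-i / 2.0)
    else:
        raise ModelError(f"unknown built-in error model {name!r}")
    sub = _uniform_substitutions(L)
    # joint counts proportional to per-position rate x uniform substitution
    joint = (rates[:, None, None] * sub * 1000).astype(np.int64)
    model = ErrorModel(
        read_length=L,
        mismatch_rate_by_pos=rates,
        substitution_weights=sub,
        substitution_counts=joint,
        marginal_substitution=_uniform_substitutions(1)[0],
        mismatch_count_dist=_truncated_poisson(float(rates.sum()), L),
        qual_match_by_pos="I" * L,
        qual_mismatch_by_pos="#" * L,
        name=name,
    )
    model.validate()
    return model


def builtin_models(read_length: int = 76) -> dict[str, ErrorModel]:
    return {
        name: builtin_model(name, read_length) for name in ("uniform", "ramp")
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: ErrorModel, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "name": model.name,
        "read_length": model.read_length,
        "mismatch_rate_by_pos": model.mismatch_rate_by_pos.tolist(),
        "substitution_weights": model.substitution_weights.tolist(),
        "substitution_counts": model.substitution_counts.tolist(),
        "marginal_substitution": model.marginal_substitution.tolist(),
        "mismatch_count_dist": {str(k): v for k, v in model.mismatch_count_dist.items()},
        "qual_match_by_pos": model.qual_match_by_pos,
        "qual_mismatch_by_pos": model.qual_mismatch_by_pos,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> ErrorModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ModelError(f"unsupported model format in {path}")
    model = ErrorModel(
        read_length=payload["read_length"],
        mismatch_rate_by_pos=np.array(payload["mismatch_rate_by_pos"]),
        substitution_weights=np.array(payload["substitution_weights"]),
        substitution_counts=np.array(payload["substitution_counts"], dtype=np.int64),
        marginal_substitution=np.array(payload["marginal_substitution"]),
        mismatch_count_dist={
            int(k): v for k, v in payload["mismatch_count_dist"].items()
        },
        qual_match_by_pos=payload["qual_match_by_pos"],
        qual_mismatch_by_pos=payload["qual_mismatch_by_pos"],
        name=payload.get("name", "empirical"),
    )
    model.validate()
    return model
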