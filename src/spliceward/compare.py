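"""Between-sample comparison of splicing events.

Each event contributes a 2x2 table of total inclusion/exclusion junction
read counts per sample; a two-sided Fisher's exact test assesses the null
of equal inclusion proportions (comparing proportions absorbs differences
in sequencing depth and transcription).  Benjamini-Hochberg controls the
FDR across events.  Conservative call gates reproduce a stringent
differential-splicing workflow: BH-adjusted p below alpha, more than a
minimum number of junction reads in every path in both samples, an
absolute PSI difference above a floor, and — when replicate
quantifications are supplied — a between-sample raw p smaller than the
raw p observed between replicates.

Delta-PSI orientation is ``psi_b - psi_a`` throughout (sample order as
passed; documented on the CLI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: floor for p values entering -log10 transforms
P_FLOOR = 1e-300


@dataclass
class CompareThresholds:
    alpha: float = 0.01  # BH-adjusted significance
    min_path_reads: int = 10  # strict: require > min_path_reads in each path
    min_delta_psi: float = 0.20  # strict: require |dPSI| > min_delta_psi


def fet_event(inc_a: int, exc_a: int, inc_b: int, exc_b: int) -> float:
    """Two-sided Fisher's exact test p for one event's 2x2 count table.

    Degenerate tables (an all-zero row or column) return 1.0 by
    convention so that BH input length is stable.  Counts must be
    non-negative integers: the test is exact only on integer counts.
    """
    cells = (inc_a, exc_a, inc_b, exc_b)
    for c in cells:
        if isinstance(c, float) and not float(c).is_integer():
            raise TypeError(f"Fisher's exact test requires integer counts, got {c}")
        if c < 0:
            raise ValueError("negative count")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _psi(inc: float, exc: float, inc_n: int, exc_n: int) -> float:
    ri = inc / inc_n if inc_n else 0.0
    re = exc / exc_n if exc_n else 0.0
    return ri / (ri + re) if (ri + re) > 0 else float("nan")


def compare_events(
    quants_a: pd.DataFrame,
    quants_b: pd.DataFrame,
    replicate_pairs: Sequence[tuple[pd.DataFrame, pd.DataFrame]] | None = None,
    thresholds: CompareThresholds | None = None,
) -> pd.DataFrame:
    """Compare two event quantification tables (indexed by event id).

    Only events with inclusion-path coverage in either sample *and*
    exclusion-path coverage in either sample are tested; the rest are kept
    with ``tested = False``.  All gate verdicts are reported so the call
    criteria are auditable.  When ``replicate_pairs`` are given the
    replicate gate uses the minimum raw FET p across replicate pairs
    (the most conservative choice).
    """
    th = thresholds or CompareThresholds()
    missing_a = set(quants_b.index) - set(quants_a.index)
    missing_b = set(quants_a.index) - set(quants_b.index)
    if missing_a or missing_b:
        raise ValueError(
            "event universes differ between samples; unmatched: "
            f"{sorted(missing_a | missing_b)[:10]}"
        )
    idx = quants_a.index

    inc_a = quants_a["inc_reads"].astype(int)
    exc_a = quants_a["exc_reads"].astype(int)
    inc_b = quants_b.loc[idx, "inc_reads"].astype(int)
    exc_b = quants_b.loc[idx, "exc_reads"].astype(int)
    inc_n = quants_a["inc_n"].astype(int)
    exc_n = quants_a["exc_n"].astype(int)

    tested = ((inc_a > 0) | (inc_b > 0)) & ((exc_a > 0) | (exc_b > 0))
    quantifiable = (
        quants_a.get("quantifiable", pd.Series(True, index=idx)).astype(bool)
        & quants_b.loc[idx]
        .get("quantifiable", pd.Series(True, index=idx))
        .astype(bool)
    )
    tested &= quantifiable

    psi_a = np.array(
        [
            _psi(ia, ea, ni, ne)
            for ia, ea, ni, ne in zip(inc_a, exc_a, inc_n, exc_n)
        ]
    )
    psi_b = np.array(
        [
            _psi(ib, eb, ni, ne)
            for ib, eb, ni, ne in zip(inc_b, exc_b, inc_n, exc_n)
        ]
    )
    # retintron-style events carry their read-through-derived totals in
    # exc_reads with exc_n == 0: fall back to the stored psi estimates
    stored_a = quants_a["psi"].to_numpy(dtype=float)
    stored_b = quants_b.loc[idx, "psi"].to_numpy(dtype=float)
    use_stored = exc_n.to_numpy() == 0
    psi_a[use_stored] = stored_a[use_stored]
    psi_b[use_stored] = stored_b[use_stored]
    delta = psi_b - psi_a

    p_raw = np.ones(len(idx))
    for i, (ia, ea, ib, eb, t) in enumerate(
        zip(inc_a, exc_a, inc_b, exc_b, tested)
    ):
        if t:
            p_raw[i] = fet_event(ia, ea, ib, eb)
    p_adj = np.ones(len(idx))
    if tested.any():
        p_adj[tested.to_numpy()] = bh_adjust(p_raw[tested.to_numpy()])

    rep_p = np.full(len(idx), np.nan)
    if replicate_pairs:
        for ra, rb in replicate_pairs:
            for i, ev in enumerate(idx):
                if ev in ra.index and ev in rb.index:
                    p = fet_event(
                        int(ra.loc[ev, "inc_reads"]),
                        int(ra.loc[ev, "exc_reads"]),
                        int(rb.loc[ev, "inc_reads"]),
                        int(rb.loc[ev, "exc_reads"]),
                    )
                    rep_p[i] = p if np.isnan(rep_p[i]) else min(rep_p[i], p)

    min_path = np.minimum.reduce(
        [inc_a.to_numpy(), exc_a.to_numpy(), inc_b.to_numpy(), exc_b.to_numpy()]
    )
    gate_p = p_adj < th.alpha
    gate_reads = min_path > th.min_path_reads
    with np.errstate(invalid="ignore"):
        gate_dpsi = np.abs(delta) > th.min_delta_psi
    gate_rep = np.where(np.isnan(rep_p), True, p_raw < rep_p)
    call = tested.to_numpy() & gate_p & gate_reads & gate_dpsi & gate_rep

    out = pd.DataFrame(
        {
            "gene_id": quants_a.get("gene_id", pd.Series("", index=idx)),
            "event_type": quants_a.get("event_type", pd.Series("", index=idx)),
            "inc_a": inc_a,
            "exc_a": exc_a,
            "inc_b": inc_b,
            "exc_b": exc_b,
            "psi_a": psi_a,
            "psi_b": psi_b,
            "delta_psi": delta,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "replicate_p_raw": rep_p,
            "tested": tested,
            "gate_significant": gate_p,
            "gate_min_reads": gate_reads,
            "gate_delta_psi": gate_dpsi,
            "gate_replicates": gate_rep,
            "call": call,
        },
        index=idx,
    )
    return out


def volcano_table(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Delta-PSI vs -log10 raw p table for volcano plotting."""
    if comparisons.empty:
        return pd.DataFrame(columns=["delta_psi", "neg_log10_p", "call"])
    p = np.clip(comparisons["p_raw"].to_numpy(dtype=float), P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "delta_psi": comparisons["delta_psi"],
            "neg_log10_p": -np.log10(p),
            "call": comparisons["call"],
        },
        index=comparisons.index,
    )


def volcano_plot(comparisons: pd.DataFrame, path: str) -> None:
    """Optional cosmetic rendering of the volcano table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = volcano_table(comparisons)
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(tab["call"], "crimson", "gray")
    ax.scatter(tab["delta_psi"], tab["neg_log10_p"], s=8, c=colors, alpha=0.6)
    ax.set_xlabel("ΔPSI")
    ax.set_ylabel("-log10 p (Fisher's exact test)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
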