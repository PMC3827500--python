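"""Shared fixtures: a planted toy genome and a simulated read pool."""

from dataclasses import dataclass

import pytest
from hypothesis import settings

import spliceward as sw

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@dataclass
class FakeRead:
    """Minimal alignment record understood by the junction quantifier."""

    chrom: str
    blocks: tuple


@pytest.fixture(scope="session")
def toy() -> sw.FixtureSet:
    """Toy fixture with one planted instance of every aligner error class."""
    cfg = sw.FixtureConfig(
        n_genes=14,
        n_paralog_pairs=1,
        n_repeat_sites=1,
        n_wrong_strand_sites=1,
        n_shifted_sites=1,
        n_minor_sites=1,
    )
    return sw.make_toy_fixture(cfg, seed=42)


@pytest.fixture(scope="session")
def toy_sim(toy) -> sw.SimResult:
    """One simulated pool over the toy fixture at a moderate depth."""
    cfg = sw.SimConfig(rpk=300, seed=7)
    return sw.simulate(toy.annotation, toy.genome, cfg)


def spliced_reads(site, n=6, read_len=76, first_anchor=20, vary=True):
    """Doctored junction-spanning reads over a planted (chrom, start, end) site."""
    chrom, s, e = site
    reads = []
    for i in range(n):
        a = first_anchor + (i if vary else 0)
        reads.append(
            FakeRead(chrom, ((s - a, s), (e, e + (read_len - a))))
        )
    return reads
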