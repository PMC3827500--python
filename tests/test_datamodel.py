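"""Domain types, FASTA/GTF IO conventions, and the toy-fixture generator."""

import pytest

import spliceward as sw
from spliceward.datamodel import percent_identity


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chr1\nACGT\n")
    g = sw.read_fasta(p)
    assert g.sequences == {"chr1": "ACGT"}


def test_read_fasta_case_normalized(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c\nacgt\n")
    assert sw.read_fasta(p).sequences["c"] == "ACGT"


def test_read_fasta_duplicate_name_rejected(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c\nACGT\n>c\nTTTT\n")
    with pytest.raises(sw.FormatError):
        sw.read_fasta(p)


def test_read_fasta_empty_rejected(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text("")
    with pytest.raises(sw.FormatError):
        sw.read_fasta(p)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _gtf_line(chrom, start, end, strand, gene, tx):
    return (
        f'{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t'
        f'gene_id "{gene}"; transcript_id "{tx}";\n'
    )


def test_gtf_coordinates_convert_to_half_open(tmp_path):
    """GTF exons (1,100) and (201,300) define the intron [100, 200)."""
    p = tmp_path / "a.gtf"
    p.write_text(
        _gtf_line("c", 1, 100, "+", "g", "t") + _gtf_line("c", 201, 300, "+", "g", "t")
    )
    ann = sw.read_gtf(p)
    assert ann.known_junction_keys == {("c", 100, 200, "+")}
    assert ann.transcripts[0].exons == [(0, 100), (200, 300)]


def test_single_exon_transcript_yields_no_junction(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(_gtf_line("c", 1, 100, "+", "g", "t"))
    assert sw.read_gtf(p).known_junction_keys == set()


def test_shared_intron_counted_once(tmp_path):
    p = tmp_path / "a.gtf"
    lines = ""
    for tx in ("t1", "t2"):
        lines += _gtf_line("c", 1, 100, "+", "g", tx)
        lines += _gtf_line("c", 201, 300, "+", "g", tx)
    p.write_text(lines)
    assert len(sw.read_gtf(p).known_junction_keys) == 1


def test_gtf_missing_transcript_id_rejected(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text('c\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g";\n')
    with pytest.raises(sw.FormatError):
        sw.read_gtf(p)


def test_gtf_overlapping_exons_rejected(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        _gtf_line("c", 1, 100, "+", "g", "t") + _gtf_line("c", 50, 150, "+", "g", "t")
    )
    with pytest.raises(sw.FormatError):
        sw.read_gtf(p)


def test_gtf_round_trip(tmp_path, toy):
    """write_gtf(read_gtf(x)) preserves the annotation exactly."""
    p = tmp_path / "roundtrip.gtf"
    sw.write_gtf(toy.annotation, p)
    back = sw.read_gtf(p)
    orig = {t.transcript_id: (t.gene_id, t.strand, tuple(t.exons)) for t in toy.annotation.transcripts}
    reread = {t.transcript_id: (t.gene_id, t.strand, tuple(t.exons)) for t in back.transcripts}
    assert orig == reread
    assert back.known_junction_keys == toy.annotation.known_junction_keys


# ---------------------------------------------------------------------------
# Junction motifs
# ---------------------------------------------------------------------------


def _one_intron_genome(donor, acceptor, strand):
    # exon [0,20) | intron [20, 80) | exon [80, 100)
    seq = list("A" * 100)
    seq[20:22] = donor
    seq[78:80] = acceptor
    g = sw.GenomeRef({"c": "".join(seq)})
    t = sw.TranscriptModel("g", "t", "c", strand, [(0, 20), (80, 100)])
    return g, t


@pytest.mark.parametrize(
    "donor,acceptor,strand,expected",
    [
        ("GT", "AG", "+", ("GT", "AG")),  # canonical, plus strand
        ("CT", "AC", "-", ("GT", "AG")),  # canonical seen from minus strand
        ("AT", "AC", "+", ("AT", "AC")),  # minor form
    ],
)
def test_junction_motifs_strand_oriented(donor, acceptor, strand, expected):
    g, t = _one_intron_genome(donor, acceptor, strand)
    (j,) = sw.junctions_of(t, g)
    assert (j.donor_motif, j.acceptor_motif) == expected
    assert (j.intron_start, j.intron_end) == (20, 80)


def test_junctions_out_of_bounds_rejected():
    g = sw.GenomeRef({"c": "ACGT" * 5})
    t = sw.TranscriptModel("g", "t", "c", "+", [(0, 10), (60, 70)])
    with pytest.raises(IndexError):
        sw.junctions_of(t, g)


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------


def test_fixture_deterministic():
    cfg = sw.FixtureConfig(n_genes=10)
    a = sw.make_toy_fixture(cfg, seed=7)
    b = sw.make_toy_fixture(cfg, seed=7)
    assert a.genome.sequences == b.genome.sequences
    assert a.manifest == b.manifest


def test_fixture_exonskip_fraction_one():
    cfg = sw.FixtureConfig(n_genes=8, event_fractions={"exonskip": 1.0})
    fx = sw.make_toy_fixture(cfg, seed=1)
    assert len(fx.manifest["events"]) == 8
    assert all(e["event_type"] == "exonskip" for e in fx.manifest["events"])


def test_fixture_paralog_manifest(toy):
    (pair,) = toy.manifest["paralogs"]
    genes = {g["gene_id"] for g in toy.manifest["genes"]}
    assert pair["gene_a"] in genes and pair["gene_b"] in genes
    assert pair["offset"] > 0


def test_fixture_planted_motifs_are_canonical(toy):
    """Every annotated junction reads GT-AG after strand orientation."""
    for j in toy.annotation.known_junctions(toy.genome):
        assert (j.donor_motif, j.acceptor_motif) == ("GT", "AG")


def test_fixture_true_junctions_below_repeat_threshold(toy):
    for key in toy.annotation.known_junction_intervals:
        don, acc = sw.repeat_identity(toy.genome, key)
        assert max(don, acc) <= 80.0


def test_fixture_infeasible_intron_rejected():
    with pytest.raises(sw.ConfigError):
        sw.make_toy_fixture(sw.FixtureConfig(intron_len=(10, 20)), seed=0)


def test_percent_identity_brute_force_oracle():
    """edlib-based identity equals a DP Levenshtein oracle on random windows."""
    import numpy as np

    def lev(a, b):
        m, n = len(a), len(b)
        d = np.arange(n + 1)
        for i in range(1, m + 1):
            prev, d[0] = d[0], i
            for j in range(1, n + 1):
                cur = min(
                    d[j] + 1,
                    d[j - 1] + 1,
                    prev + (a[i - 1] != b[j - 1]),
                )
                prev, d[j] = d[j], cur
        return int(d[n])

    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    for _ in range(60):
        a = "".join(rng.choice(bases, 10))
        b = "".join(rng.choice(bases, 10))
        assert percent_identity(a, b) == pytest.approx(100 * (10 - lev(a, b)) / 10)
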