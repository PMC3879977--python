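"""Per-intron feature computations against brute-force recomputation."""
import math

import numpy as np
import pytest

from intronscape import io as iomod
from intronscape.features import (
    boundary_gc_profile,
    find_branch_point,
    gc_percent,
    intron_phase,
    longest_antisense_orf,
    longest_orf,
    relative_genic_position,
    splice_profile,
    splice_sites,
)
from intronscape.model import AnnotationSet, GeneModel, Intron, SequenceRecord, revcomp

import oracles


def make_intron(seq: str, coding_offset: int = 6, iid: str = "i1") -> Intron:
    return Intron(
        id=iid, gene_id="g", seq_id="c", strand="+", start=0, end=len(seq),
        ordinal=1, seq=seq, coding_offset=coding_offset, gc_percent=gc_percent(seq),
    )


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0), ("ANGC", 200 / 3)],
)
def test_gc_percent(seq, expected):
    assert gc_percent(seq) == pytest.approx(expected)


def test_gc_percent_edge_cases():
    assert math.isnan(gc_percent("NNN"))
    with pytest.raises(ValueError):
        gc_percent("")


@pytest.mark.parametrize("offset,phase", [(3, 0), (4, 1), (5, 2), (6, 0), (301, 1)])
def test_intron_phase(offset, phase):
    assert intron_phase(offset) == phase


@pytest.mark.parametrize(
    "seq,donor,acceptor",
    [
        ("GT" + "A" * 40 + "AG", "GT", "AG"),
        ("GC" + "A" * 40 + "AG", "GC", "AG"),
        ("GT" + "A" * 40 + "TG", "GT", "TG"),
        ("TT" + "A" * 40 + "CC", "other", "other"),
    ],
)
def test_splice_site_status(seq, donor, acceptor):
    ss = splice_sites(make_intron(seq))
    assert ss["donor_status"] == donor
    assert ss["acceptor_status"] == acceptor


class TestBranchPoint:
    def test_planted_motif_found_at_offset(self):
        L = 80
        off = 45
        seq = list("GT" + "A" * (L - 4) + "AG")
        start = L - off
        for k, c in enumerate("ACTGAC"):
            seq[start + k] = c
        hits = find_branch_point(make_intron("".join(seq)), "NCTGAC", (43, 52))
        assert [h.offset for h in hits] == [45]

    def test_outside_window_not_reported(self):
        L = 80
        seq = list("GT" + "A" * (L - 4) + "AG")
        for k, c in enumerate("ACTGAC"):
            seq[L - 30 + k] = c
        assert find_branch_point(make_intron("".join(seq)), "NCTGAC", (43, 52)) == []

    def test_wildcard_matches_any_base(self):
        L = 80
        seq = list("GT" + "A" * (L - 4) + "AG")
        for k, c in enumerate("TCTGAC"):
            seq[L - 45 + k] = c
        hits = find_branch_point(make_intron("".join(seq)), "NCTGAC", (43, 52))
        assert len(hits) == 1

    def test_inverted_window_raises(self):
        with pytest.raises(ValueError):
            find_branch_point(make_intron("GT" + "A" * 60 + "AG"), "NCTGAC", (52, 43))

    def test_full_window_equals_naive_scan(self):
        """With the window opened to the whole intron, the search reports
        exactly what a naive string scan finds."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            L = int(rng.integers(60, 200))
            seq = oracles.random_seq(rng, L)
            i = make_intron(seq)
            hits = find_branch_point(i, "NCTGAC", (6, L))
            assert sorted(h.offset for h in hits) == sorted(
                oracles.bf_branch_positions(seq, "NCTGAC", 6, L)
            )


def _flank_annotation(intron_seqs, up="ATGGCAGCT", down="GCTGCAGCTGCAGCTGCTTGA"):
    """One + strand gene per intron with fixed exon flanks."""
    a = AnnotationSet()
    parts = []
    pos = 0
    for k, body in enumerate(intron_seqs):
        gstart = pos
        parts.append(up)
        cds1 = (gstart, gstart + len(up))
        pos += len(up)
        parts.append(body)
        pos += len(body)
        cds2 = (pos, pos + len(down))
        parts.append(down)
        pos += len(down)
        gid = f"g{k}"
        a.genes[gid] = GeneModel(
            id=gid, seq_id="c", strand="+",
            exon_intervals=[cds1, cds2], cds_intervals=[cds1, cds2],
        )
    a.sequences["c"] = SequenceRecord(id="c", seq="".join(parts))
    iomod.extract_introns(a)
    return a


class TestSpliceProfile:
    def test_majority_consensus(self):
        seqs = ["GTGCGT" + "A" * 40 + "AG", "GTGCGT" + "A" * 40 + "AG", "GTGAGT" + "A" * 40 + "AG"]
        a = _flank_annotation(seqs)
        prof = splice_profile(a, a.introns, side="donor", window=(3, 6))
        assert prof.consensus.endswith("GTGCGT")
        assert prof.n == 3
        assert (prof.counts.sum(axis=0) == 3).all()

    def test_single_sequence_consensus_is_itself(self):
        a = _flank_annotation(["GTACGT" + "C" * 40 + "AG"])
        prof = splice_profile(a, a.introns, side="donor", window=(3, 6))
        assert prof.consensus == "GCT" + "GTACGT"

    def test_counts_match_naive_tally_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        seqs = ["GT" + oracles.random_seq(rng, 40) + "AG" for _ in range(12)]
        a = _flank_annotation(seqs)
        prof = splice_profile(a, a.introns, side="donor", window=(3, 6))
        windows = ["GCT" + s[:6] for s in seqs]
        assert (prof.counts == oracles.bf_splice_counts(windows)).all()
        prof2 = splice_profile(a, list(reversed(a.introns)), side="donor", window=(3, 6))
        assert prof2.consensus == prof.consensus
        assert (prof2.counts == prof.counts).all()

    def test_acceptor_side_window(self):
        a = _flank_annotation(["GT" + "A" * 40 + "TTTCAG"])
        prof = splice_profile(a, a.introns, side="acceptor", window=(3, 6))
        assert prof.consensus == "TTTCAG" + "GCT"


class TestBoundaryGcProfile:
    def test_uniform_composition(self):
        """All-G intron bodies against all-A flanks give 100 / 0 profiles."""
        a = _flank_annotation(
            ["GT" + "G" * 48 + "AG"], up="ATG" + "A" * 84, down="A" * 84 + "TAA"
        )
        prof = boundary_gc_profile(a.introns, a)
        body = prof.mean_gc["donor_intron"]
        assert np.nanmax(body) == 100.0 and np.nanmin(body) == 100.0
        exon = prof.mean_gc["donor_exon"]
        assert np.nanmax(exon) == 0.0

    def test_matches_bruteforce_on_random_introns(self):
        rng = np.random.default_rng(11)
        seqs = ["GT" + oracles.random_seq(rng, int(rng.integers(50, 120))) + "AG" for _ in range(20)]
        up = "ATG" + oracles.random_seq(rng, 90)
        down = oracles.random_seq(rng, 90) + "TGA"
        a = _flank_annotation(seqs, up=up, down=down)
        prof = boundary_gc_profile(a.introns, a)
        flanks = [(up, s, down) for s in seqs]
        mean, n = oracles.bf_boundary_gc_profile(flanks)
        for track in mean:
            assert (prof.n_per_position[track] == n[track]).all()
            both = ~np.isnan(mean[track])
            assert np.allclose(prof.mean_gc[track][both], mean[track][both])
            assert np.isnan(prof.mean_gc[track][~both]).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        seqs = ["GT" + oracles.random_seq(rng, 80) + "AG" for _ in range(8)]
        a = _flank_annotation(seqs)
        p1 = boundary_gc_profile(a.introns, a)
        p2 = boundary_gc_profile(list(reversed(a.introns)), a)
        for track in p1.mean_gc:
            assert np.allclose(p1.mean_gc[track], p2.mean_gc[track], equal_nan=True)


def test_relative_genic_position():
    g = GeneModel(id="g", seq_id="c", strand="+",
                  exon_intervals=[(0, 300)], cds_intervals=[(0, 300)])
    assert relative_genic_position(make_intron("GT" + "A" * 40 + "AG", 150), g) == 0.5
    assert relative_genic_position(make_intron("GT" + "A" * 40 + "AG", 3), g) == 0.01
    vals = [relative_genic_position(make_intron("GTAAAG", c), g) for c in (30, 60, 150, 297)]
    assert vals == sorted(vals)


class TestAntisenseOrf:
    def test_planted_orf_length(self):
        orf = "ATG" + "GCT" * 8 + "TAA"  # 30 nt
        body = revcomp("C" * 11 + orf + "C" * 10)
        i = make_intron(body)
        hit = longest_antisense_orf(i)
        assert hit is not None and hit["length"] == 30

    def test_no_start_codon_gives_none(self):
        i = make_intron(revcomp("C" * 60))
        assert longest_antisense_orf(i) is None

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            seq = oracles.random_seq(rng, int(rng.integers(60, 300)))
            got = longest_orf(seq)
            want = oracles.bf_longest_orf_any_frame(seq)
            if want is None:
                assert got is None
            else:
                assert got is not None and got["length"] == want[0]
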