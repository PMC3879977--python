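"""Repeat-intron family discovery: similarity graph, consensus, motif
blocks, subfamilies, remnant scan and nested detection."""
import numpy as np
import pytest

from intronscape.align import max_edits, scan_hits
from intronscape.discovery import (
    IntronFamily,
    assign_subfamilies,
    build_consensus,
    cluster_families,
    detect_nested,
    find_motif_blocks,
    pairwise_similarity,
    scan_remnants,
)
from intronscape.features import gc_percent
from intronscape.model import AnnotationSet, GeneModel, Intron, SequenceRecord, revcomp

import oracles


def make_intron(seq, iid, start=0, seq_id="c", gene="g"):
    return Intron(
        id=iid, gene_id=gene, seq_id=seq_id, strand="+", start=start,
        end=start + len(seq), ordinal=1, seq=seq, coding_offset=6,
        gc_percent=gc_percent(seq),
    )


RNG = np.random.default_rng(17)


class TestPairwiseSimilarity:
    def test_identical_introns_make_a_full_identity_edge(self):
        s = oracles.random_seq(RNG, 100)
        edges = pairwise_similarity([make_intron(s, "a"), make_intron(s, "b")])
        assert len(edges) == 1
        assert edges[0].identity == pytest.approx(100.0)
        assert edges[0].coverage == pytest.approx(100.0)

    def test_unrelated_random_introns_make_no_edge(self):
        rng = np.random.default_rng(1)
        a = make_intron(oracles.random_seq(rng, 100), "a")
        b = make_intron(oracles.random_seq(rng, 100), "b")
        assert pairwise_similarity([a, b], use_prefilter=False) == []

    def test_triangle_of_similar_introns(self):
        rng = np.random.default_rng(2)
        master = oracles.random_seq(rng, 120)
        introns = [make_intron(oracles.mutate(rng, master, 0.03), f"i{k}") for k in range(3)]
        edges = pairwise_similarity(introns)
        assert len(edges) == 3

    def test_prefilter_is_lossless_for_family_grade_pairs(self):
        """The k-mer prefilter finds every edge the unfiltered scan finds on
        a mixed set of family-grade repeat copies (within 10% of a master)
        and random singletons."""
        rng = np.random.default_rng(3)
        master = oracles.random_seq(rng, 150)
        introns = [make_intron(oracles.mutate(rng, master, 0.05), f"m{k}") for k in range(8)]
        introns += [make_intron(oracles.random_seq(rng, 150), f"r{k}") for k in range(12)]
        with_f = {(e.intron_a, e.intron_b) for e in pairwise_similarity(introns)}
        without = {(e.intron_a, e.intron_b) for e in pairwise_similarity(introns, use_prefilter=False)}
        assert with_f == without


class TestClustering:
    def test_component_below_min_size_is_singletons(self):
        s = oracles.random_seq(RNG, 100)
        introns = [make_intron(s, "a"), make_intron(s, "b"),
                   make_intron(oracles.random_seq(RNG, 100), "x")]
        edges = pairwise_similarity(introns)
        fams, singles = cluster_families(edges, introns, min_family_size=3)
        assert fams == [] and sorted(singles) == ["a", "b", "x"]

    def test_single_linkage_chains(self):
        """A-B and B-C edges without A-C still form one family."""
        from intronscape.discovery import SimilarityEdge

        introns = [make_intron("GT" + "A" * 60 + "AG", x) for x in "abc"]
        edges = [SimilarityEdge("a", "b", 90, 100), SimilarityEdge("b", "c", 90, 100)]
        fams, singles = cluster_families(edges, introns, min_family_size=3)
        assert len(fams) == 1 and sorted(fams[0].members) == ["a", "b", "c"]

    def test_family_ids_ordered_by_size(self):
        from intronscape.discovery import SimilarityEdge

        members = [make_intron("GTAAAG", f"x{k}") for k in range(7)]
        edges = [SimilarityEdge(f"x{k}", f"x{k+1}", 90, 100) for k in range(3)]
        edges += [SimilarityEdge("x5", "x6", 90, 100), SimilarityEdge("x4", "x5", 90, 100)]
        fams, _ = cluster_families(edges, members, min_family_size=3)
        assert [f.id for f in fams] == ["FAM001", "FAM002"]
        assert fams[0].size == 4 and fams[1].size == 3

    def test_membership_is_a_partition(self):
        rng = np.random.default_rng(5)
        m1 = oracles.random_seq(rng, 120)
        m2 = oracles.random_seq(rng, 120)
        introns = [make_intron(oracles.mutate(rng, m1, 0.05), f"a{k}") for k in range(5)]
        introns += [make_intron(oracles.mutate(rng, m2, 0.05), f"b{k}") for k in range(5)]
        edges = pairwise_similarity(introns)
        fams, singles = cluster_families(edges, introns, min_family_size=3)
        seen = [m for f in fams for m in f.members] + list(singles)
        assert sorted(seen) == sorted(i.id for i in introns)


class TestConsensus:
    def test_identical_members_reproduce_the_sequence(self):
        s = oracles.random_seq(RNG, 100)
        fam = IntronFamily(id="F", members=["a", "b", "c"])
        build_consensus(fam, {m: s for m in fam.members})
        assert fam.consensus == s
        assert (fam.conservation == 1.0).all()

    def test_single_mismatch_column_conservation(self):
        s = oracles.random_seq(np.random.default_rng(8), 100)
        variant = ("G" if s[50] != "G" else "C") + ""
        seqs = {f"m{k}": s for k in range(4)}
        seqs["m4"] = s[:50] + variant + s[51:]
        fam = IntronFamily(id="F", members=sorted(seqs))
        build_consensus(fam, seqs)
        assert fam.consensus == s
        assert fam.conservation[50] == pytest.approx(0.8)
        assert (np.delete(fam.conservation, 50) == 1.0).all()

    def test_consensus_recovers_master_within_two_edits(self):
        import edlib

        rng = np.random.default_rng(9)
        master = oracles.random_seq(rng, 150)
        seqs = {f"m{k:02d}": oracles.mutate(rng, master, 0.10) for k in range(20)}
        fam = IntronFamily(id="F", members=sorted(seqs))
        build_consensus(fam, seqs)
        d = edlib.align(fam.consensus, master, mode="NW")["editDistance"]
        assert d <= 2


class TestSubfamilies:
    def _family_with_blocks(self, rng, drop_block_in_half=True):
        blocks = [oracles.random_seq(rng, 45) for _ in range(3)]
        linker = lambda: oracles.random_seq(rng, 10)
        seqs = {}
        for k in range(12):
            parts = [blocks[0], linker(), blocks[1], linker(), blocks[2]]
            if drop_block_in_half and k >= 6:
                parts = [blocks[0], linker(), blocks[2]]
            seqs[f"m{k:02d}"] = oracles.mutate(rng, "".join(parts), 0.02)
        return seqs

    def test_block_presence_split(self):
        """Half the members lacking the middle block form a second subfamily."""
        rng = np.random.default_rng(21)
        seqs = self._family_with_blocks(rng)
        fam = IntronFamily(id="FAM001", members=sorted(seqs))
        build_consensus(fam, seqs, max_gap_fraction=0.6)
        find_motif_blocks(fam, block_min_len=20, block_min_conservation=0.8)
        assert len(fam.motif_blocks) >= 2
        assign_subfamilies([fam], seqs)
        labels = set(fam.subfamily_of.values())
        assert len([l for l in labels if l != "ambiguous"]) == 2

    def test_fully_conserved_family_is_one_subfamily(self):
        rng = np.random.default_rng(22)
        seqs = self._family_with_blocks(rng, drop_block_in_half=False)
        fam = IntronFamily(id="FAM001", members=sorted(seqs))
        build_consensus(fam, seqs)
        assign_subfamilies([fam], seqs)
        labels = set(fam.subfamily_of.values())
        assert labels == {"FAM001.S1"}


def _genome_with_plants(rng, block, n_plants, seq_len=20_000, identity=0.85):
    """Random sequence with degraded copies of ``block`` planted at known spots."""
    seq = list(oracles.random_seq(rng, seq_len))
    spots = np.linspace(500, seq_len - 500, n_plants).astype(int)
    for p in spots:
        copy = oracles.mutate(rng, block, 1 - identity)
        seq[p : p + len(copy)] = list(copy)
    return "".join(seq), list(spots)


class TestRemnantScan:
    def _annotation(self, seq):
        a = AnnotationSet()
        a.sequences["c"] = SequenceRecord(id="c", seq=seq)
        return a

    def test_plant_and_recover_with_context(self):
        rng = np.random.default_rng(31)
        block = oracles.random_seq(rng, 60)
        seq, spots = _genome_with_plants(rng, block, 5)
        a = self._annotation(seq)
        fam = IntronFamily(id="FAM001", members=[], consensus=block)
        hits = scan_remnants(a, [fam], min_identity=65, min_len=40, exclude_members=False)
        for p in spots:
            assert any(h.start - 70 <= p <= h.end for h in hits)
        assert all(h.context == "intergenic" for h in hits)

    def test_block_inside_intron_is_labeled_intronic(self):
        rng = np.random.default_rng(32)
        block = oracles.random_seq(rng, 60)
        intron_body = "GT" + oracles.random_seq(rng, 30) + block + oracles.random_seq(rng, 30) + "AG"
        up, down = "ATGGCAGCT", "GCTGCAGCTGCTTGA"
        seq = "A" * 50 + up + intron_body + down + "A" * 50
        a = self._annotation(seq)
        cds1 = (50, 50 + len(up))
        istart = cds1[1]
        cds2 = (istart + len(intron_body), istart + len(intron_body) + len(down))
        a.genes["g"] = GeneModel(id="g", seq_id="c", strand="+",
                                 exon_intervals=[cds1, cds2], cds_intervals=[cds1, cds2])
        from intronscape.io import extract_introns

        extract_introns(a)
        fam = IntronFamily(id="FAM001", members=[], consensus=block)
        hits = scan_remnants(a, [fam], exclude_members=False)
        assert hits and hits[0].context == "intronic"

    def test_repeat_free_genome_yields_nothing(self):
        rng = np.random.default_rng(33)
        a = self._annotation(oracles.random_seq(rng, 10_000))
        fam = IntronFamily(id="FAM001", members=[], consensus=oracles.random_seq(rng, 60))
        assert scan_remnants(a, [fam], exclude_members=False) == []

    def test_scan_hits_equal_full_dp_oracle(self):
        """The recursive best-hit scan finds the same intervals as the
        exhaustive semi-global DP sweep."""
        rng = np.random.default_rng(34)
        block = oracles.random_seq(rng, 60)
        for trial in range(3):
            seq, spots = _genome_with_plants(rng, block, 6, seq_len=15_000, identity=0.8)
            impl = scan_hits(block, seq, 65.0)
            want = oracles.bf_hit_intervals(block, seq, 65.0)
            # same hit set up to interval jitter: every oracle run overlaps
            # exactly one implementation hit and vice versa
            assert len(impl) == len(want)
            for s, e in want:
                assert sum(1 for h in impl if h.start < e and s < h.end) == 1


class TestNested:
    def _annotated_intron(self, body, fam_label=None):
        a = AnnotationSet()
        up, down = "ATGGCAGCT", "GCTGCAGCTGCTTGA"
        seq = "A" * 20 + up + body + down + "A" * 20
        cds1 = (20, 20 + len(up))
        cds2 = (cds1[1] + len(body), cds1[1] + len(body) + len(down))
        a.sequences["c"] = SequenceRecord(id="c", seq=seq)
        a.genes["g"] = GeneModel(id="g", seq_id="c", strand="+",
                                 exon_intervals=[cds1, cds2], cds_intervals=[cds1, cds2])
        from intronscape.io import extract_introns

        extract_introns(a)
        if fam_label:
            a.introns[0].class_label = f"ie:{fam_label}"
            a.introns[0].family_id = fam_label
        return a

    def test_inner_copy_is_nested(self):
        rng = np.random.default_rng(41)
        inner = oracles.random_seq(rng, 60)
        body = "GT" + oracles.random_seq(rng, 40) + inner + oracles.random_seq(rng, 40) + "AG"
        a = self._annotated_intron(body)
        fam = IntronFamily(id="FAMX", members=[], consensus=inner)
        recs = detect_nested(a, [fam])
        assert len(recs) == 1 and recs[0].kind == "nested"

    def test_boundary_overlap_is_merged(self):
        rng = np.random.default_rng(42)
        inner = oracles.random_seq(rng, 60)
        body = "GT" + inner[2:] + oracles.random_seq(rng, 60) + "AG"
        a = self._annotated_intron(body)
        fam = IntronFamily(id="FAMX", members=[], consensus=inner)
        recs = detect_nested(a, [fam])
        assert len(recs) == 1 and recs[0].kind == "merged"

    def test_unrelated_intron_gives_no_record(self):
        rng = np.random.default_rng(43)
        body = "GT" + oracles.random_seq(rng, 120) + "AG"
        a = self._annotated_intron(body)
        fam = IntronFamily(id="FAMX", members=[], consensus=oracles.random_seq(rng, 60))
        assert detect_nested(a, [fam]) == []


def test_distinct_masters_never_merge():
    """Two planted families from masters below 50% identity come out as two
    families, never one."""
    rng = np.random.default_rng(51)
    m1 = oracles.random_seq(rng, 140)
    m2 = oracles.random_seq(rng, 140)
    introns = [make_intron(oracles.mutate(rng, m1, 0.05), f"a{k}") for k in range(6)]
    introns += [make_intron(oracles.mutate(rng, m2, 0.05), f"b{k}") for k in range(6)]
    edges = pairwise_similarity(introns)
    fams, _ = cluster_families(edges, introns, min_family_size=3)
    assert len(fams) == 2
    for f in fams:
        kinds = {m[0] for m in f.members}
        assert len(kinds) == 1
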