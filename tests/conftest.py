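"""Shared fixtures: a tiny hand-built annotation and a session-scoped
full-size simulation reused by the acceptance tests."""
from __future__ import annotations

import pytest

from intronscape import io as iomod
from intronscape import simulate as sim
from intronscape.model import AnnotationSet, GeneModel, SequenceRecord, revcomp


def build_two_gene_annotation() -> AnnotationSet:
    """One chromosome, a + strand two-exon gene and a - strand two-exon gene.

    gene1 (+): CDS [10,16) + [76,106), 60-nt intron between.
    gene2 (-): CDS [150,180) + [240,246) on the minus strand.
    """
    up = "A" * 10
    cds1a = "ATGGCA"
    intron1 = "GT" + "C" * 23 + "ACTGAC" + "C" * 25 + "TCTG" + "AG"  # 62 nt
    cds1b = "GGTTGCGCAGCCGCAGCTGCTGCTGCTTGA"
    mid = "T" * 44
    # gene2 sense (transcript) pieces; genomic is the reverse complement
    cds2a = "ATGCCGCCTCCACCGCCACCTCCACCACCG"
    intron2 = "GT" + "A" * 56 + "AG"
    cds2b = "GCGTGA"
    gene2_sense = cds2a + intron2 + cds2b
    tail = "G" * 10
    seq = up + cds1a + intron1 + cds1b + mid + revcomp(gene2_sense) + tail
    a = AnnotationSet()
    a.sequences["chr1"] = SequenceRecord(id="chr1", seq=seq)
    g1_cds = [(10, 16), (16 + len(intron1), 16 + len(intron1) + len(cds1b))]
    a.genes["gene1"] = GeneModel(
        id="gene1", seq_id="chr1", strand="+",
        exon_intervals=list(g1_cds), cds_intervals=list(g1_cds),
        protein="", mrna_id="gene1.m1",
    )
    g2_start = len(up + cds1a + intron1 + cds1b + mid)
    L2 = len(gene2_sense)
    # sense [0,30) and [90,96) map to genomic [g2_start+L2-30, g2_start+L2) and [g2_start, g2_start+6)
    g2_cds = [(g2_start, g2_start + len(cds2b)), (g2_start + L2 - len(cds2a), g2_start + L2)]
    a.genes["gene2"] = GeneModel(
        id="gene2", seq_id="chr1", strand="-",
        exon_intervals=list(g2_cds), cds_intervals=list(g2_cds),
        protein="", mrna_id="gene2.m1",
    )
    for g in a.genes.values():
        joined = "".join(seq[s:e] for s, e in g.cds_intervals)
        if g.strand == "-":
            joined = revcomp(joined)
        g.protein = iomod.translate_cds(joined)
    return a


@pytest.fixture
def tiny_annotation() -> AnnotationSet:
    a = build_two_gene_annotation()
    iomod.extract_introns(a)
    return a


@pytest.fixture(scope="session")
def invaded_simulation():
    """Full-scale study conditions: 2-Mb genome, 800 genes, one low-GC
    region, 2000 canonical + 300 BOC1 introns and one 300-copy IE family
    with phase bias (0.2, 0.2, 0.6)."""
    cfg = sim.SimConfig()
    state = sim.simulate_genome(cfg, seed=20131120)
    sim.simulate_invasion(state)
    emission = sim.emit(state)
    return state, emission


@pytest.fixture(scope="session")
def discovered_families(invaded_simulation):
    from intronscape.discovery import discover_families

    state, emission = invaded_simulation
    families, singletons, edges = discover_families(emission.annotation)
    return families, singletons, edges
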