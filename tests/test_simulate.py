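"""Simulator: realized statistics concentrate on configured values, truth
records line up with the emitted annotation, and runs are deterministic."""
import numpy as np
import pytest
from scipy import stats

from intronscape import io as iomod
from intronscape import simulate as sim
from intronscape.features import gc_percent
from intronscape.model import revcomp


def small_cfg(**kw):
    base = dict(
        chromosomes=[sim.ChromosomeSpec(length=300_000)],
        n_genes=120,
        n_canonical=300,
        n_boc1=60,
        ie_families=[sim.IeFamilySpec(n_copies=60)],
    )
    base.update(kw)
    return sim.SimConfig(**base)


def test_zero_genes_gives_empty_annotation():
    cfg = sim.SimConfig(
        chromosomes=[sim.ChromosomeSpec(length=50_000)],
        n_genes=0, n_canonical=0, n_boc1=0, ie_families=[],
    )
    st = sim.simulate_genome(cfg, 1)
    em = sim.emit(st)
    assert em.annotation.genes == {}
    assert em.annotation.introns == []
    assert sum(r.length for r in em.annotation.sequences.values()) > 0


def test_planted_canonical_termini_and_truth_alignment():
    st = sim.simulate_genome(small_cfg(), 2)
    sim.simulate_invasion(st)
    em = sim.emit(st)
    em.annotation.validate()
    derived = {i.id: i for i in em.annotation.introns}
    for rec in st.truth.intron_records:
        i = derived[rec["intron_id"]]
        assert (i.start, i.end) == (rec["start"], rec["end"])
        if rec["class"] in ("canonical", "ie"):
            assert i.donor2 == "GT" and i.acceptor2 == "AG"


def test_gc_zone_targets_realized():
    """10-kb window GC concentrates on the per-zone targets."""
    cfg = sim.SimConfig(
        chromosomes=[
            sim.ChromosomeSpec(
                length=600_000,
                zones=[sim.ZoneSpec(0.5, 0.65), sim.ZoneSpec(0.5, 0.55, is_low_gc=True)],
            )
        ],
        n_genes=120, n_canonical=200, n_boc1=0, ie_families=[],
        canonical_gc=0.60,
    )
    st = sim.simulate_genome(cfg, 3)
    em = sim.emit(st)
    seq = em.annotation.sequences["chr1"].seq
    (region,) = st.truth.boc1_regions["chr1"]
    for lo, hi, target in ((0, region[0], 0.65), (region[0], region[1], 0.55)):
        for w in range(lo, hi - 10_000, 10_000):
            window = seq[w : w + 10_000]
            assert abs(gc_percent(window) / 100.0 - target) < 0.03


def test_boc1_confined_to_low_gc_region():
    st = sim.simulate_genome(small_cfg(), 4)
    em = sim.emit(st)
    (region,) = st.truth.boc1_regions["chr1"]
    for rec in st.truth.intron_records:
        if rec["class"] == "boc1":
            assert region[0] <= rec["start"] and rec["end"] <= region[1]
        if rec["class"] == "canonical":
            assert not (region[0] <= rec["start"] and rec["end"] <= region[1])


def test_spliceability_no_internal_stops():
    st = sim.simulate_genome(small_cfg(), 5)
    sim.simulate_invasion(st)
    sa, sb = sim.simulate_divergence(st)
    for state in (sa, sb):
        em = sim.emit(state)
        assert all("*" not in g.protein for g in em.annotation.genes.values())


class TestInvasion:
    def test_uniform_insertion_when_bias_off(self):
        """With w=0 the insertion counts are uniform across genes
        (chi-square goodness of fit, p > 0.01)."""
        cfg = small_cfg(
            n_canonical=0, n_boc1=0,
            ie_families=[sim.IeFamilySpec(n_copies=2000, gc_bias_w=0.0)],
        )
        st = sim.simulate_genome(cfg, 6)
        sim.simulate_invasion(st)
        counts = np.array([len(g.introns) for g in st.genes()])
        chi2, p = stats.chisquare(counts)
        assert p > 0.01

    def test_gc_bias_depletes_low_gc_zone(self):
        cfg = small_cfg(n_canonical=0, n_boc1=0,
                        ie_families=[sim.IeFamilySpec(n_copies=1000, gc_bias_w=4.0)])
        st = sim.simulate_genome(cfg, 7)
        sim.simulate_invasion(st)
        low = [g for g in st.genes() if g.zone_low_gc]
        high = [g for g in st.genes() if not g.zone_low_gc]
        per_low = np.mean([len(g.introns) for g in low])
        per_high = np.mean([len(g.introns) for g in high])
        assert per_low < per_high / 2

    def test_phase_bias_recovered(self):
        cfg = small_cfg(n_canonical=0, n_boc1=0,
                        ie_families=[sim.IeFamilySpec(n_copies=2000,
                                                      phase_bias=(0.2, 0.2, 0.6))])
        st = sim.simulate_genome(cfg, 8)
        sim.simulate_invasion(st)
        phases = [i.coding_offset % 3 for g in st.genes() for i in g.introns]
        frac2 = np.mean(np.array(phases) == 2)
        assert abs(frac2 - 0.6) < 0.03


class TestDivergence:
    @pytest.mark.parametrize("q,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_retention(self, q, expected):
        cfg = small_cfg()
        cfg.divergence.q_class = {"canonical": q, "boc1": q, "ie": q}
        cfg.divergence.gains_per_lineage = 0
        st = sim.simulate_genome(cfg, 9)
        sim.simulate_invasion(st)
        sim.simulate_divergence(st)
        for cls, rec in st.truth.realized_shared.items():
            assert rec["fraction_shared"] == pytest.approx(expected)

    def test_target_fraction_realized(self):
        cfg = small_cfg(n_canonical=2000, n_genes=300,
                        chromosomes=[sim.ChromosomeSpec(length=900_000)])
        cfg.divergence.q_class = {"canonical": 0.47, "boc1": 0.73, "ie": 0.0}
        st = sim.simulate_genome(cfg, 10)
        sim.simulate_invasion(st)
        sim.simulate_divergence(st)
        assert abs(st.truth.realized_shared["canonical"]["fraction_shared"] - 0.47) < 0.01


class TestDegrade:
    def test_remnant_identity_and_placement(self):
        cfg = small_cfg()
        cfg.degrade.n_degrade = 20
        cfg.degrade.indel_rate = 0.0
        cfg.degrade.truncate_prob = 0.0
        st = sim.simulate_genome(cfg, 11)
        sim.simulate_invasion(st)
        sim.degrade_elements(st)
        em = sim.emit(st)
        assert len(st.truth.remnants) == 20
        genome = em.annotation.sequences
        for r in st.truth.remnants:
            piece = genome[r.seq_id].seq[r.start:r.end]
            assert piece == r.seq or piece == revcomp(r.seq)

    def test_deletion_bias_fraction(self):
        rng = np.random.default_rng(12)
        frac = sim.indel_deletion_fraction(rng, 10_000, del_ins_ratio=2.0)
        assert abs(frac - 2 / 3) < 0.03

    def test_zero_degradation_rate_preserves_sequences(self):
        rng = np.random.default_rng(13)
        s = "ACGT" * 30
        out, n = sim.mutate_seq(rng, s, 0.0)
        assert out == s and n == 0


class TestFragments:
    def test_error_rate_realized(self):
        rng = np.random.default_rng(14)
        base = "ACGT" * 30_000
        mutated, applied = sim.mutate_seq(rng, base, 0.01)
        rate = sum(1 for a, b in zip(base, mutated) if a != b) / len(base)
        assert abs(rate - 0.01) < 0.002

    def test_zero_error_fragments_match_source_lineage(self):
        cfg = small_cfg()
        cfg.fragments.error_rate = 0.0
        cfg.fragments.n = 40
        cfg.divergence.q_class = {"canonical": 1.0, "boc1": 1.0, "ie": 0.5}
        cfg.divergence.substitution_rate = 0.0
        st = sim.simulate_genome(cfg, 15)
        sim.simulate_invasion(st)
        sa, sb = sim.simulate_divergence(st)
        frags, events = sim.emit_fragments(sa, sb, seed=1)
        genome_b = sim.emit(sb).annotation.sequences["chr1"].seq
        for f in frags[:10]:
            assert f.seq in genome_b or revcomp(f.seq) in genome_b

    def test_pap_truth_types_present(self):
        cfg = small_cfg()
        cfg.divergence.q_class = {"canonical": 1.0, "boc1": 1.0, "ie": 0.5}
        st = sim.simulate_genome(cfg, 16)
        sim.simulate_invasion(st)
        sa, sb = sim.simulate_divergence(st)
        frags, events = sim.emit_fragments(sa, sb, seed=2)
        kinds = {e.event_type for e in events}
        assert kinds == {"absent_in_fragment", "novel_in_fragment"}
        assert all(e.support >= 1 for e in events)


def test_seeded_runs_are_byte_identical(tmp_path):
    outs = []
    for run in range(2):
        cfg = small_cfg()
        st = sim.simulate_genome(cfg, 99)
        sim.simulate_invasion(st)
        em = sim.emit(st)
        d = tmp_path / f"run{run}"
        paths = iomod.write_tables(em.annotation, d)
        outs.append({k: open(p, "rb").read() for k, p in paths.items()})
    assert outs[0] == outs[1]
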