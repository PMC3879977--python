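"""Synthetic genomes with a known intron landscape, and everything derived
from them: repeat-intron (IE) invasions, diverged strain pairs, degenerate
remnants, and read-like fragment sets — all with full ground truth.

The simulator works on a *blueprint*: genes are stored as a coding sequence
plus a list of planted introns at coding offsets, chromosomes as ordered
spacers and genes grouped into GC zones. Genomic coordinates exist only at
emission time, which is a pure function of the blueprint, so a state can be
emitted repeatedly (and after further edits) without drift. All randomness
flows through one seeded generator held by the state.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .features import gc_percent
from .io import extract_introns, translate_cds
from .model import AnnotationSet, GeneModel, Intron, SequenceRecord, revcomp

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ZoneSpec:
    fraction: float
    gc: float
    is_low_gc: bool = False  # BOC-like: hosts the short AT-rich introns


@dataclass
class ChromosomeSpec:
    length: int = 2_000_000
    zones: list[ZoneSpec] = field(
        default_factory=lambda: [
            ZoneSpec(0.40, 0.60),
            ZoneSpec(0.25, 0.42, is_low_gc=True),
            ZoneSpec(0.35, 0.60),
        ]
    )


@dataclass
class IeFamilySpec:
    name: str = "IEA"
    master_len: int = 150
    master_gc: float = 0.55
    donor: str = "GT"  # GC for the GC-donor variant
    acceptor: str = "AG"  # TG for the noncanonical variant
    n_copies: int = 300
    divergence: float = 0.10  # per-copy substitution rate drawn U[0, divergence]
    gc_bias_w: float = 4.0  # insertion probability ~ (gene CDS GC)^w
    phase_bias: tuple[float, float, float] = (0.2, 0.2, 0.6)


@dataclass
class DivergenceSpec:
    substitution_rate: float = 0.02  # per lineage
    # target shared-position fraction per class (see methods note)
    q_class: dict = field(
        default_factory=lambda: {"canonical": 0.47, "boc1": 0.73, "ie": 0.0}
    )
    gains_per_lineage: int = 50  # post-split IE copies per lineage, never shared
    exact_retention: bool = True


@dataclass
class DegradeSpec:
    n_degrade: int = 20
    target_identity: float = 0.80
    indel_rate: float = 0.02
    del_ins_ratio: float = 2.0
    truncate_prob: float = 0.5
    core_len: int = 50
    p_intergenic: float = 0.5


@dataclass
class FragmentSpec:
    n: int = 400
    length: int = 800
    error_rate: float = 0.01
    # composition of the stratified fragment set
    frac_excision: float = 0.50
    frac_novel: float = 0.25
    min_flank: int = 60  # clearance kept around a PAP locus inside a fragment


@dataclass
class SimConfig:
    chromosomes: list[ChromosomeSpec] = field(default_factory=lambda: [ChromosomeSpec()])
    n_genes: int = 800
    cds_codons: tuple[int, int] = (150, 450)  # uniform, incl. start/stop codons
    n_canonical: int = 2000
    canonical_len: tuple[int, int] = (60, 300)
    canonical_gc: float = 0.52
    branch_motif: str = "NCTGAC"
    branch_window: tuple[int, int] = (43, 52)
    n_boc1: int = 300
    boc1_len: tuple[int, int] = (45, 74)
    boc1_gc: float = 0.27
    boc1_noncanonical_acceptor: float = 0.10
    ie_families: list[IeFamilySpec] = field(default_factory=lambda: [IeFamilySpec()])
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    degrade: DegradeSpec = field(default_factory=DegradeSpec)
    fragments: FragmentSpec = field(default_factory=FragmentSpec)


# ---------------------------------------------------------------------------
# blueprint

@dataclass
class SimIntron:
    uid: int
    cls: str  # canonical | boc1 | ie
    family: Optional[str]
    seq: str
    coding_offset: int
    identity_to_master: float = 100.0
    post_split: bool = False
    # divergence bookkeeping (set by simulate_divergence on the ancestor)
    fate: Optional[str] = None  # joint | lost_A | lost_B


@dataclass
class SimGene:
    id: str
    cds: str  # sense CDS incl. start and stop codons
    strand: str
    zone_low_gc: bool
    introns: list[SimIntron] = field(default_factory=list)

    def used_offsets(self) -> set[int]:
        return {i.coding_offset for i in self.introns}


@dataclass
class SimSpacer:
    uid: int
    seq: str


@dataclass
class SimZone:
    gc: float
    is_low_gc: bool
    items: list = field(default_factory=list)  # SimSpacer | SimGene alternating


@dataclass
class SimChromosome:
    id: str
    zones: list[SimZone] = field(default_factory=list)


@dataclass
class RemnantTruth:
    family: str
    target_identity: float
    context: str  # intergenic | intronic
    seq: str
    # placement: spacer uid or (gene_id, intron uid) + offset within host
    host: tuple
    offset: int
    # resolved at emission
    seq_id: str = ""
    start: int = -1
    end: int = -1


@dataclass
class PapTruth:
    event_type: str  # absent_in_fragment | novel_in_fragment
    family: str
    ref_seq_id: str
    ref_start: int  # intron interval (absent) or insertion point (novel: start==end)
    ref_end: int
    gene_id: str
    support: int = 0


@dataclass
class GroundTruth:
    intron_records: list = field(default_factory=list)  # dicts, coordinates at emission
    ortholog_map: dict = field(default_factory=dict)
    realized_shared: dict = field(default_factory=dict)
    remnants: list[RemnantTruth] = field(default_factory=list)
    pap_events: list[PapTruth] = field(default_factory=list)
    boc1_regions: dict = field(default_factory=dict)  # seq_id -> [(start, end)]
    masters: dict = field(default_factory=dict)  # family -> master sequence


@dataclass
class SimState:
    cfg: SimConfig
    rng: np.random.Generator
    chromosomes: list[SimChromosome] = field(default_factory=list)
    truth: GroundTruth = field(default_factory=GroundTruth)
    label: str = "ancestor"
    _uid: int = 0

    def next_uid(self) -> int:
        self._uid += 1
        return self._uid

    def genes(self) -> list[SimGene]:
        return [
            it
            for ch in self.chromosomes
            for z in ch.zones
            for it in z.items
            if isinstance(it, SimGene)
        ]


# ---------------------------------------------------------------------------
# sequence helpers

def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)]) if n > 0 else ""


def mutate_seq(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protect: int = 0,
    frame_guard: bool = False,
) -> tuple[str, int]:
    """Substitute bases at ``rate``; the first/last ``protect`` bases are kept.

    With ``frame_guard`` a substitution creating an in-frame stop codon is
    reverted (used for CDS mutation so translations stay open). Returns the
    mutated sequence and the number of substitutions applied.
    """
    n = len(seq)
    if n == 0 or rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    eligible = np.arange(protect, n - protect)
    if eligible.size == 0:
        return seq, 0
    nmut = rng.binomial(eligible.size, rate)
    if nmut == 0:
        return seq, 0
    pos = rng.choice(eligible, size=nmut, replace=False)
    applied = 0
    for p in sorted(pos):
        old = arr[p]
        new = BASES[rng.integers(4)]
        while new == old:
            new = BASES[rng.integers(4)]
        arr[p] = new
        if frame_guard:
            c0 = (p // 3) * 3
            codon = "".join(arr[c0 : c0 + 3])
            if codon in _STOPS:
                arr[p] = old
                continue
        applied += 1
    return "".join(arr), applied


def _random_cds(rng: np.random.Generator, codons: int, gc: float) -> str:
    body = random_dna(rng, 3 * (codons - 2), gc)
    chars = list(body)
    for c0 in range(0, len(chars), 3):
        if "".join(chars[c0 : c0 + 3]) in _STOPS:
            chars[c0] = "C"
    return "ATG" + "".join(chars) + "TGA"


def _canonical_intron_seq(rng: np.random.Generator, cfg: SimConfig) -> str:
    L = int(rng.integers(cfg.canonical_len[0], cfg.canonical_len[1] + 1))
    body = random_dna(rng, L - 4, cfg.canonical_gc)
    seq = list("GT" + body + "AG")
    lo, hi = cfg.branch_window
    off = int(rng.integers(lo, hi + 1))  # motif start to 3' terminal base, inclusive
    start = L - off
    motif = cfg.branch_motif
    if start >= 2 and start + len(motif) <= L - 2:
        for k, c in enumerate(motif):
            seq[start + k] = BASES[rng.integers(4)] if c == "N" else c
    return "".join(seq)


def _boc1_intron_seq(rng: np.random.Generator, cfg: SimConfig) -> str:
    L = int(rng.integers(cfg.boc1_len[0], cfg.boc1_len[1] + 1))
    body = random_dna(rng, L - 4, cfg.boc1_gc)
    acc = "AG"
    if rng.random() < cfg.boc1_noncanonical_acceptor:
        acc = "TG" if rng.random() < 0.5 else "CG"
    return "GT" + body + acc


# ---------------------------------------------------------------------------
# stage 1: genome

def simulate_genome(cfg: SimConfig, seed: int) -> SimState:
    """Chromosomes with per-zone GC targets, genes, and the singleton intron
    classes (canonical everywhere except the low-GC zone, which hosts the
    short AT-rich class instead)."""
    state = SimState(cfg=cfg, rng=np.random.default_rng(seed))
    rng = state.rng
    total_len = sum(ch.length for ch in cfg.chromosomes)
    gene_alloc = _allocate(rng, cfg.n_genes, [ch.length / total_len for ch in cfg.chromosomes])
    gene_counter = 0
    for ci, chspec in enumerate(cfg.chromosomes):
        chrom = SimChromosome(id=f"chr{ci + 1}")
        fracs = [z.fraction for z in chspec.zones]
        fracs = [f / sum(fracs) for f in fracs]
        zone_genes = _allocate(rng, gene_alloc[ci], fracs)
        for zi, zspec in enumerate(chspec.zones):
            zone = SimZone(gc=zspec.gc, is_low_gc=zspec.is_low_gc)
            ngenes = zone_genes[zi]
            genes = []
            coding_total = 0
            for _ in range(ngenes):
                gene_counter += 1
                codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
                cds = _random_cds(rng, codons, zspec.gc)
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    SimGene(
                        id=f"g{gene_counter:05d}",
                        cds=cds,
                        strand=strand,
                        zone_low_gc=zspec.is_low_gc,
                    )
                )
                coding_total += len(cds)
            zone_target = int(round(chspec.length * fracs[zi]))
            spacer_budget = zone_target - coding_total
            if spacer_budget < (ngenes + 1) * 20:
                raise ValueError(
                    f"infeasible packing: {ngenes} genes exceed zone of {zone_target} nt"
                )
            cuts = np.sort(rng.choice(spacer_budget - (ngenes + 1) * 20 + 1, size=ngenes, replace=True))
            lengths = np.diff(np.concatenate(([0], cuts, [spacer_budget - (ngenes + 1) * 20]))) + 20
            items = []
            for gi in range(ngenes):
                items.append(SimSpacer(state.next_uid(), random_dna(rng, int(lengths[gi]), zspec.gc)))
                items.append(genes[gi])
            items.append(SimSpacer(state.next_uid(), random_dna(rng, int(lengths[ngenes]), zspec.gc)))
            zone.items = items
            chrom.zones.append(zone)
        state.chromosomes.append(chrom)
    _plant_singletons(state)
    return state


def _allocate(rng: np.random.Generator, n: int, probs: list[float]) -> list[int]:
    if n == 0:
        return [0] * len(probs)
    return list(rng.multinomial(n, probs))


def _insert_intron(
    state: SimState, gene: SimGene, seq: str, cls: str, family: Optional[str],
    phase: Optional[int] = None, identity: float = 100.0, post_split: bool = False,
) -> Optional[SimIntron]:
    """Plant one intron at a fresh coding offset inside [3, cds_len-3]."""
    cds_len = len(gene.cds)
    used = gene.used_offsets()
    lo, hi = 3, cds_len - 3
    if phase is None:
        cand = [c for c in range(lo, hi + 1) if c not in used]
    else:
        first = lo + ((phase - lo) % 3)
        cand = [c for c in range(first, hi + 1, 3) if c not in used]
    if not cand:
        return None
    c = int(state.rng.choice(cand))
    intr = SimIntron(
        uid=state.next_uid(),
        cls=cls,
        family=family,
        seq=seq,
        coding_offset=c,
        identity_to_master=identity,
        post_split=post_split,
    )
    gene.introns.append(intr)
    return intr


def _plant_singletons(state: SimState) -> None:
    cfg, rng = state.cfg, state.rng
    genes = state.genes()
    normal = [g for g in genes if not g.zone_low_gc]
    low = [g for g in genes if g.zone_low_gc]
    for _ in range(cfg.n_canonical):
        if not normal:
            break
        g = normal[int(rng.integers(len(normal)))]
        _insert_intron(state, g, _canonical_intron_seq(rng, cfg), "canonical", None)
    for _ in range(cfg.n_boc1):
        if not low:
            break
        g = low[int(rng.integers(len(low)))]
        _insert_intron(state, g, _boc1_intron_seq(rng, cfg), "boc1", None)


# ---------------------------------------------------------------------------
# stage 2: IE invasion

def make_master(rng: np.random.Generator, spec: IeFamilySpec) -> str:
    body = random_dna(rng, spec.master_len - 4, spec.master_gc)
    return spec.donor + body + spec.acceptor


def _ie_copy(rng: np.random.Generator, master: str, spec: IeFamilySpec) -> tuple[str, float]:
    rate = float(rng.uniform(0.0, spec.divergence))
    seq, applied = mutate_seq(rng, master, rate, protect=2)
    identity = 100.0 * (1.0 - applied / len(master))
    return seq, identity


def _gene_weights(genes: list[SimGene], w: float) -> np.ndarray:
    gcs = np.array([gc_percent(g.cds) / 100.0 for g in genes])
    weights = np.power(gcs, w)
    return weights / weights.sum()


def simulate_invasion(state: SimState, n_copies_override: Optional[dict] = None) -> SimState:
    """Insert IE copies: gene chosen with probability proportional to its CDS
    GC raised to the bias weight, coding offset drawn per the phase-bias
    vector, always on the sense strand with termini intact."""
    cfg, rng = state.cfg, state.rng
    genes = state.genes()
    if not genes:
        return state
    for spec in cfg.ie_families:
        if spec.name not in state.truth.masters:
            state.truth.masters[spec.name] = make_master(rng, spec)
        master = state.truth.masters[spec.name]
        probs = _gene_weights(genes, spec.gc_bias_w)
        n = (n_copies_override or {}).get(spec.name, spec.n_copies)
        phases = rng.choice(3, size=n, p=np.array(spec.phase_bias))
        for j in range(n):
            seq, ident = _ie_copy(rng, master, spec)
            for _attempt in range(20):
                g = genes[int(rng.choice(len(genes), p=probs))]
                intr = _insert_intron(
                    state, g, seq, "ie", spec.name, phase=int(phases[j]), identity=ident
                )
                if intr is not None:
                    break
    return state


# ---------------------------------------------------------------------------
# stage 3: strain divergence

def simulate_divergence(state: SimState) -> tuple[SimState, SimState]:
    """Split the ancestor into two strains.

    The per-class parameter ``q_class`` is the *target shared-position
    fraction* 2s/(n_A+n_B); internally the joint-retention probability is
    q/(2-q), and with ``exact_retention`` the allocation uses exact counts so
    the realized fraction equals the target up to rounding. Introns not
    retained jointly are dropped from one lineage chosen fairly. Post-split
    IE gains are added per lineage and never shared; sequences then mutate
    at the substitution rate (CDS with a reading-frame stop guard, intron
    termini preserved)."""
    cfg, rng = state.cfg, state.rng
    by_class: dict[str, list[SimIntron]] = {}
    for g in state.genes():
        for i in g.introns:
            by_class.setdefault(i.cls, []).append(i)
    realized = {}
    for cls, introns in sorted(by_class.items()):
        q = cfg.divergence.q_class.get(cls, 1.0)
        n = len(introns)
        p_joint = q / (2.0 - q) if q < 1.0 else 1.0
        order = rng.permutation(n)
        if cfg.divergence.exact_retention:
            n_joint = int(round(n * p_joint))
            fates = ["joint"] * n_joint
            loss = n - n_joint
            fates += ["lost_A"] * (loss // 2) + ["lost_B"] * (loss - loss // 2)
            if loss % 2 and rng.random() < 0.5:
                for k in range(len(fates)):
                    if fates[k] == "lost_A":
                        fates[k] = "lost_B"
                        break
        else:
            fates = []
            for _ in range(n):
                if rng.random() < p_joint:
                    fates.append("joint")
                else:
                    fates.append("lost_A" if rng.random() < 0.5 else "lost_B")
        for idx, fate in zip(order, fates):
            introns[int(idx)].fate = fate
        n_joint_real = sum(1 for i in introns if i.fate == "joint")
        n_a = sum(1 for i in introns if i.fate in ("joint", "lost_B"))
        n_b = sum(1 for i in introns if i.fate in ("joint", "lost_A"))
        realized[cls] = {
            "n_ancestral": n,
            "n_A": n_a,
            "n_B": n_b,
            "n_shared": n_joint_real,
            "fraction_shared": 2.0 * n_joint_real / (n_a + n_b) if n_a + n_b else float("nan"),
        }
    strain_a = copy.deepcopy(state)
    strain_a.label = "A"
    strain_b = copy.deepcopy(state)
    strain_b.label = "B"
    # disjoint uid namespaces so lineage-specific gains can never collide
    strain_a._uid += 1_000_000
    strain_b._uid += 2_000_000
    for st, lost in ((strain_a, "lost_A"), (strain_b, "lost_B")):
        for g in st.genes():
            g.introns = [i for i in g.introns if i.fate != lost]
    # post-split gains, drawn from the ancestor's rng for determinism
    gains = cfg.divergence.gains_per_lineage
    for st in (strain_a, strain_b):
        if gains and cfg.ie_families:
            st.rng = rng  # share the generator during gain insertion
            simulate_invasion(
                st, n_copies_override={sp.name: gains for sp in cfg.ie_families}
            )
            for g in st.genes():
                for i in g.introns:
                    if i.fate is None and i.cls == "ie":
                        i.post_split = True
                        i.fate = "gain_" + st.label
    # independent substitution drift per lineage
    for st in (strain_a, strain_b):
        st.rng = np.random.default_rng(rng.integers(2**31 - 1))
        _mutate_state(st, cfg.divergence.substitution_rate)
    truth = state.truth
    truth.realized_shared = realized
    truth.ortholog_map = {g.id: g.id for g in state.genes()}
    strain_a.truth = truth
    strain_b.truth = truth
    return strain_a, strain_b


def _mutate_state(state: SimState, rate: float) -> None:
    rng = state.rng
    for ch in state.chromosomes:
        for z in ch.zones:
            for it in z.items:
                if isinstance(it, SimSpacer):
                    it.seq, _ = mutate_seq(rng, it.seq, rate)
                else:
                    it.cds, _ = mutate_seq(rng, it.cds, rate, protect=3, frame_guard=True)
                    for i in it.introns:
                        i.seq, _ = mutate_seq(rng, i.seq, rate, protect=2)


# ---------------------------------------------------------------------------
# stage 4: remnant degradation

def degrade_elements(state: SimState) -> SimState:
    """Move a sample of IE copies out of intron context as degenerate
    remnants: mutated toward the target identity, indels with the configured
    deletion bias, optionally truncated to a core window, then placed in a
    spacer (intergenic) or inside a surviving canonical intron (intronic)."""
    cfg, rng = state.cfg, state.rng
    d = cfg.degrade
    ies = [(g, i) for g in state.genes() for i in g.introns if i.cls == "ie"]
    if not ies:
        return state
    take = min(d.n_degrade, len(ies))
    picked = rng.choice(len(ies), size=take, replace=False)
    spacers = [
        it for ch in state.chromosomes for z in ch.zones for it in z.items
        if isinstance(it, SimSpacer) and len(it.seq) > 200
    ]
    canon = [
        (g, i) for g in state.genes() for i in g.introns
        if i.cls == "canonical" and len(i.seq) > 100
    ]
    for idx in sorted(picked):
        gene, intr = ies[int(idx)]
        gene.introns.remove(intr)
        seq = intr.seq
        if rng.random() < d.truncate_prob and len(seq) > d.core_len:
            start = int(rng.integers(0, len(seq) - d.core_len + 1))
            seq = seq[start : start + d.core_len]
        seq, _ = mutate_seq(rng, seq, 1.0 - d.target_identity)
        seq = _apply_indels(rng, seq, d.indel_rate, d.del_ins_ratio)
        if d.p_intergenic >= 1.0 or (spacers and (not canon or rng.random() < d.p_intergenic)):
            sp = spacers[int(rng.integers(len(spacers)))]
            off = int(rng.integers(50, len(sp.seq) - 50))
            sp.seq = sp.seq[:off] + seq + sp.seq[off:]
            host: tuple = ("spacer", sp.uid)
            context = "intergenic"
        else:
            hg, hi = canon[int(rng.integers(len(canon)))]
            off = int(rng.integers(20, len(hi.seq) - 20))
            hi.seq = hi.seq[:off] + seq + hi.seq[off:]
            host = ("intron", hi.uid)
            context = "intronic"
        state.truth.remnants.append(
            RemnantTruth(
                family=intr.family or "",
                target_identity=100.0 * d.target_identity,
                context=context,
                seq=seq,
                host=host,
                offset=off,
            )
        )
    return state


def _apply_indels(rng: np.random.Generator, seq: str, rate: float, del_ins_ratio: float) -> str:
    if rate <= 0 or len(seq) < 10:
        return seq
    n_events = rng.binomial(len(seq), rate)
    p_del = del_ins_ratio / (1.0 + del_ins_ratio)
    out = seq
    for _ in range(n_events):
        if len(out) < 10:
            break
        p = int(rng.integers(2, len(out) - 2))
        size = int(rng.integers(1, 4))
        if rng.random() < p_del:
            out = out[:p] + out[p + size :]
        else:
            out = out[:p] + random_dna(rng, size, 0.5) + out[p:]
    return out


def indel_deletion_fraction(rng: np.random.Generator, n_draws: int, del_ins_ratio: float) -> float:
    """Empirical deletion fraction of the indel process (diagnostic helper)."""
    p_del = del_ins_ratio / (1.0 + del_ins_ratio)
    return float(np.mean(rng.random(n_draws) < p_del))


# ---------------------------------------------------------------------------
# emission

@dataclass
class GeneLayout:
    gene_id: str
    seq_id: str
    strand: str
    gene_start: int
    gene_end: int
    cds_len: int
    # per intron: (uid, cls, family, coding_offset, genomic start, genomic end)
    introns: list[tuple] = field(default_factory=list)

    def coding_to_genomic(self, c: int) -> int:
        """Genomic coordinate of the junction after ``c`` coding nt (the point
        where an absent intron would sit)."""
        sense = c + sum(e - s for (_u, _c, _f, off, s, e) in self.introns if off < c)
        if self.strand == "+":
            return self.gene_start + sense
        return self.gene_end - sense


@dataclass
class Emission:
    annotation: AnnotationSet
    layouts: dict[str, GeneLayout]


def emit(state: SimState) -> Emission:
    """Materialise the blueprint: genome sequences, gene models, introns with
    genomic coordinates, truth coordinate resolution."""
    a = AnnotationSet()
    layouts: dict[str, GeneLayout] = {}
    spacer_pos: dict[int, int] = {}
    for ch in state.chromosomes:
        parts: list[str] = []
        pos = 0
        region_start = None
        regions = []
        for z in ch.zones:
            if z.is_low_gc and region_start is None:
                region_start = pos
            for it in z.items:
                if isinstance(it, SimSpacer):
                    spacer_pos[it.uid] = pos
                    parts.append(it.seq)
                    pos += len(it.seq)
                else:
                    gene_seq, layout = _emit_gene(it, ch.id, pos)
                    parts.append(gene_seq)
                    pos += len(gene_seq)
                    layouts[it.id] = layout
            if z.is_low_gc:
                regions.append((region_start, pos))
                region_start = None
        seq = "".join(parts)
        a.sequences[ch.id] = SequenceRecord(id=ch.id, seq=seq)
        if regions:
            state.truth.boc1_regions[ch.id] = regions
    # gene models + introns
    for gid, layout in layouts.items():
        gene = _gene_model_from_layout(state, gid, layout)
        a.genes[gid] = gene
        seq = a.sequences[layout.seq_id].seq
        joined = "".join(seq[s:e] for s, e in gene.cds_intervals)
        if gene.strand == "-":
            joined = revcomp(joined)
        gene.protein = translate_cds(joined)
    extract_introns(a)
    _resolve_truth(state, layouts, spacer_pos)
    return Emission(annotation=a, layouts=layouts)


def _emit_gene(g: SimGene, seq_id: str, pos: int) -> tuple[str, GeneLayout]:
    introns = sorted(g.introns, key=lambda i: i.coding_offset)
    sense_parts = []
    prev = 0
    sense_ivals = []  # (uid, cls, family, offset, sense start, sense end)
    cursor = 0
    for i in introns:
        sense_parts.append(g.cds[prev : i.coding_offset])
        cursor += i.coding_offset - prev
        sense_ivals.append((i.uid, i.cls, i.family, i.coding_offset, cursor, cursor + len(i.seq)))
        sense_parts.append(i.seq)
        cursor += len(i.seq)
        prev = i.coding_offset
    sense_parts.append(g.cds[prev:])
    sense = "".join(sense_parts)
    L = len(sense)
    genomic = sense if g.strand == "+" else revcomp(sense)
    layout = GeneLayout(
        gene_id=g.id,
        seq_id=seq_id,
        strand=g.strand,
        gene_start=pos,
        gene_end=pos + L,
        cds_len=len(g.cds),
    )
    for (uid, cls, fam, off, ss, se) in sense_ivals:
        if g.strand == "+":
            gs, ge = pos + ss, pos + se
        else:
            gs, ge = pos + L - se, pos + L - ss
        layout.introns.append((uid, cls, fam, off, gs, ge))
    layout.introns.sort(key=lambda t: t[4])
    return genomic, layout


def _gene_model_from_layout(state: SimState, gid: str, layout: GeneLayout) -> GeneModel:
    ivals = sorted((s, e) for (_u, _c, _f, _o, s, e) in layout.introns)
    cds = []
    prev = layout.gene_start
    for s, e in ivals:
        cds.append((prev, s))
        prev = e
    cds.append((prev, layout.gene_end))
    return GeneModel(
        id=gid,
        seq_id=layout.seq_id,
        strand=layout.strand,
        exon_intervals=list(cds),
        cds_intervals=list(cds),
        mrna_id=f"{gid}.m1",
    )


def _resolve_truth(state: SimState, layouts: dict[str, GeneLayout], spacer_pos: dict[int, int]) -> None:
    records = []
    for g in state.genes():
        layout = layouts[g.id]
        by_uid = {u: (s, e) for (u, _c, _f, _o, s, e) in layout.introns}
        introns_sorted = sorted(g.introns, key=lambda i: i.coding_offset)
        for ordinal, i in enumerate(introns_sorted, start=1):
            s, e = by_uid[i.uid]
            records.append(
                {
                    "uid": i.uid,
                    "intron_id": f"{g.id}.i{ordinal}",
                    "gene_id": g.id,
                    "seq_id": layout.seq_id,
                    "start": s,
                    "end": e,
                    "class": i.cls,
                    "family": i.family,
                    "coding_offset": i.coding_offset,
                    "phase": i.coding_offset % 3,
                    "length": len(i.seq),
                    "identity_to_master": i.identity_to_master,
                    "post_split": i.post_split,
                    "fate": i.fate,
                }
            )
    state.truth.intron_records = records
    intron_pos = {}
    for g in state.genes():
        layout = layouts[g.id]
        for (u, _c, _f, _o, s, e) in layout.introns:
            intron_pos[u] = (layout.seq_id, s, e)
    for r in state.truth.remnants:
        kind, host_uid = r.host
        if kind == "spacer":
            if host_uid in spacer_pos:
                base = spacer_pos[host_uid]
                seq_id = _spacer_seq_id(state, host_uid)
                r.seq_id, r.start, r.end = seq_id, base + r.offset, base + r.offset + len(r.seq)
        else:
            if host_uid in intron_pos:
                seq_id, s, e = intron_pos[host_uid]
                # offset is in sense orientation of the host intron
                strand = _intron_strand(state, host_uid)
                if strand == "+":
                    r.seq_id, r.start, r.end = seq_id, s + r.offset, s + r.offset + len(r.seq)
                else:
                    r.seq_id, r.start, r.end = seq_id, e - r.offset - len(r.seq), e - r.offset


def _spacer_seq_id(state: SimState, uid: int) -> str:
    for ch in state.chromosomes:
        for z in ch.zones:
            for it in z.items:
                if isinstance(it, SimSpacer) and it.uid == uid:
                    return ch.id
    return ""


def _intron_strand(state: SimState, uid: int) -> str:
    for ch in state.chromosomes:
        for z in ch.zones:
            for it in z.items:
                if isinstance(it, SimGene):
                    for i in it.introns:
                        if i.uid == uid:
                            return it.strand
    return "+"


# ---------------------------------------------------------------------------
# stage 5: fragments

@dataclass
class Fragment:
    id: str
    seq: str
    source: str = ""


def emit_fragments(
    ref_state: SimState,
    alt_state: SimState,
    seed: Optional[int] = None,
) -> tuple[list[Fragment], list[PapTruth]]:
    """Read-like fragments from the non-reference lineage with per-base error,
    stratified over presence/absence loci.

    Excision fragments cover a locus where the reference carries an IE the
    fragment lineage lacks; novel fragments cover a fragment-lineage IE the
    reference lacks; neutral fragments avoid every differing locus. PAP truth
    is recorded in reference coordinates with supporting-fragment counts."""
    cfg = ref_state.cfg
    fs = cfg.fragments
    rng = np.random.default_rng(seed) if seed is not None else ref_state.rng
    ref_em = emit(ref_state)
    alt_em = emit(alt_state)
    all_ref_only, all_alt_only = _differing_loci(ref_state, alt_state, ref_em, alt_em)
    # sample only isolated loci: a PAP locus within a fragment length of any
    # other repeat copy (differing or shared) is ambiguous — near-identical
    # copies let the aligner trade the structural gap between loci — so such
    # loci are not a fair sensitivity target (see methods note); neutral
    # fragments still avoid every differing locus
    ie_marks = [
        (layout.seq_id, s, e)
        for layout in alt_em.layouts.values()
        for (_u, cls, _f, _o, s, e) in layout.introns
        if cls == "ie"
    ]
    ref_only, alt_only = _isolated_loci(all_ref_only, all_alt_only, fs.length, ie_marks)
    events: list[PapTruth] = []
    frags: list[Fragment] = []
    n_exc = int(round(fs.n * fs.frac_excision))
    n_nov = int(round(fs.n * fs.frac_novel))
    n_neu = fs.n - n_exc - n_nov
    counter = 0

    def _sample_around(seq: str, lo: int, hi: int) -> Optional[tuple[int, str]]:
        """Fragment window covering [lo, hi) with >= min_flank clearance."""
        span = hi - lo
        room = fs.length - span - 2 * fs.min_flank
        if room < 0 or len(seq) < fs.length:
            return None
        off = int(rng.integers(0, room + 1))
        start = lo - fs.min_flank - off
        if start < 0 or start + fs.length > len(seq):
            start = max(0, min(len(seq) - fs.length, start))
            if not (start + fs.min_flank <= lo and hi + fs.min_flank <= start + fs.length):
                return None
        return start, seq[start : start + fs.length]

    def _finish(seq: str, tag: str) -> Fragment:
        nonlocal counter
        counter += 1
        seq, _ = mutate_seq(rng, seq, fs.error_rate)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        return Fragment(id=f"frag{counter:05d}", seq=seq, source=tag)

    # excision: reference-only IE loci, sampled from the ALT genome around the junction
    ev_by_key: dict[tuple, PapTruth] = {}
    for k in range(n_exc):
        if not ref_only:
            break
        loc = ref_only[k % len(ref_only)]
        alt_seq = alt_em.annotation.sequences[loc["alt_seq_id"]].seq
        got = _sample_around(alt_seq, loc["alt_pos"], loc["alt_pos"])
        if got is None:
            continue
        _, window = got
        frags.append(_finish(window, "excision"))
        key = ("absent_in_fragment", loc["ref_seq_id"], loc["ref_start"], loc["family"])
        ev = ev_by_key.get(key)
        if ev is None:
            ev = PapTruth(
                event_type="absent_in_fragment",
                family=loc["family"],
                ref_seq_id=loc["ref_seq_id"],
                ref_start=loc["ref_start"],
                ref_end=loc["ref_end"],
                gene_id=loc["gene_id"],
            )
            ev_by_key[key] = ev
            events.append(ev)
        ev.support += 1
    for k in range(n_nov):
        if not alt_only:
            break
        loc = alt_only[k % len(alt_only)]
        alt_seq = alt_em.annotation.sequences[loc["alt_seq_id"]].seq
        got = _sample_around(alt_seq, loc["alt_start"], loc["alt_end"])
        if got is None:
            continue
        _, window = got
        frags.append(_finish(window, "novel"))
        key = ("novel_in_fragment", loc["ref_seq_id"], loc["ref_pos"], loc["family"])
        ev = ev_by_key.get(key)
        if ev is None:
            ev = PapTruth(
                event_type="novel_in_fragment",
                family=loc["family"],
                ref_seq_id=loc["ref_seq_id"],
                ref_start=loc["ref_pos"],
                ref_end=loc["ref_pos"],
                gene_id=loc["gene_id"],
            )
            ev_by_key[key] = ev
            events.append(ev)
        ev.support += 1
    # neutral: windows that avoid all differing loci
    avoid: dict[str, list[tuple[int, int]]] = {}
    for loc in all_ref_only:
        avoid.setdefault(loc["alt_seq_id"], []).append((loc["alt_pos"] - 5, loc["alt_pos"] + 5))
    for loc in all_alt_only:
        avoid.setdefault(loc["alt_seq_id"], []).append((loc["alt_start"] - 5, loc["alt_end"] + 5))
    seq_ids = sorted(alt_em.annotation.sequences)
    made = 0
    attempts = 0
    while made < n_neu and attempts < 50 * n_neu:
        attempts += 1
        sid = seq_ids[int(rng.integers(len(seq_ids)))]
        seq = alt_em.annotation.sequences[sid].seq
        if len(seq) <= fs.length:
            continue
        start = int(rng.integers(0, len(seq) - fs.length))
        if any(start < e and s < start + fs.length for s, e in avoid.get(sid, ())):
            continue
        frags.append(_finish(seq[start : start + fs.length], "neutral"))
        made += 1
    ref_state.truth.pap_events = events
    return frags, events


def _differing_loci(
    ref_state: SimState, alt_state: SimState, ref_em: Emission, alt_em: Emission
) -> tuple[list[dict], list[dict]]:
    """IE loci present in exactly one lineage, in both coordinate systems."""
    def _index(state: SimState) -> dict[int, SimIntron]:
        return {i.uid: i for g in state.genes() for i in g.introns}

    ref_introns = _index(ref_state)
    alt_introns = _index(alt_state)
    ref_only = []
    alt_only = []
    for g in ref_state.genes():
        ref_layout = ref_em.layouts[g.id]
        alt_layout = alt_em.layouts.get(g.id)
        if alt_layout is None:
            continue
        for i in g.introns:
            if i.cls != "ie":
                continue
            if i.uid not in alt_introns:
                s, e = _uid_interval(ref_layout, i.uid)
                ref_only.append(
                    {
                        "gene_id": g.id,
                        "family": i.family,
                        "ref_seq_id": ref_layout.seq_id,
                        "ref_start": s,
                        "ref_end": e,
                        "alt_seq_id": alt_layout.seq_id,
                        "alt_pos": alt_layout.coding_to_genomic(i.coding_offset),
                    }
                )
    for g in alt_state.genes():
        alt_layout = alt_em.layouts[g.id]
        ref_layout = ref_em.layouts.get(g.id)
        if ref_layout is None:
            continue
        for i in g.introns:
            if i.cls != "ie":
                continue
            if i.uid not in ref_introns:
                s, e = _uid_interval(alt_layout, i.uid)
                alt_only.append(
                    {
                        "gene_id": g.id,
                        "family": i.family,
                        "alt_seq_id": alt_layout.seq_id,
                        "alt_start": s,
                        "alt_end": e,
                        "ref_seq_id": ref_layout.seq_id,
                        "ref_pos": ref_layout.coding_to_genomic(i.coding_offset),
                    }
                )
    return ref_only, alt_only


def _isolated_loci(
    ref_only: list[dict],
    alt_only: list[dict],
    min_separation: int,
    extra_marks: Optional[list[tuple[str, int, int]]] = None,
) -> tuple[list[dict], list[dict]]:
    """Drop differing loci with another differing locus — or any interval in
    ``extra_marks`` (e.g. shared repeat copies) — within ``min_separation``
    nt (fragment-lineage coordinates)."""
    marks: list[tuple[str, int, int]] = []
    for loc in ref_only:
        marks.append((loc["alt_seq_id"], loc["alt_pos"], loc["alt_pos"]))
    for loc in alt_only:
        marks.append((loc["alt_seq_id"], loc["alt_start"], loc["alt_end"]))
    marks.extend(extra_marks or [])

    def _n_close(sid: str, lo: int, hi: int) -> int:
        return sum(
            1 for msid, ms, me in marks
            if msid == sid and ms < hi + min_separation and lo - min_separation < me
        )

    # a differing alt_only locus is itself also an alt IE interval in
    # extra_marks, so it counts twice; a ref_only junction counts once
    return (
        [l for l in ref_only if _n_close(l["alt_seq_id"], l["alt_pos"], l["alt_pos"]) == 1],
        [l for l in alt_only if _n_close(l["alt_seq_id"], l["alt_start"], l["alt_end"])
         == (2 if extra_marks else 1)],
    )


def _uid_interval(layout: GeneLayout, uid: int) -> tuple[int, int]:
    for (u, _c, _f, _o, s, e) in layout.introns:
        if u == uid:
            return s, e
    raise KeyError(uid)
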