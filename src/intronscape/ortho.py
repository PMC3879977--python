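"""Ortholog pairing and intron-position projection between two strains.

One-to-one orthologs come from reciprocal best hits over global protein
alignments (an externally supplied ortholog list is accepted instead);
intron positions are projected into protein-alignment columns as
(column, phase) keys and compared per class.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import align_proteins, infix_distance, max_edits, protein_score
from .model import AnnotationSet, Intron


@dataclass
class PositionKey:
    intron_id: str
    column: int  # 0-based alignment column of the residue whose codon hosts the intron
    phase: int
    class_label: str


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    aln_a: str = ""
    aln_b: str = ""
    score: float = 0.0
    positions_a: list[PositionKey] = field(default_factory=list)
    positions_b: list[PositionKey] = field(default_factory=list)


def reciprocal_best_hits(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    min_score: float = 50.0,
) -> list[tuple[str, str]]:
    """Gene pairs where each protein is the other's best global-alignment
    partner (BLOSUM62, affine gaps). Ties break toward the smallest partner
    id; pairs scoring below ``min_score`` are dropped."""
    if not proteins_a or not proteins_b:
        return []
    ids_a = sorted(proteins_a)
    ids_b = sorted(proteins_b)
    best_for_a: dict[str, tuple[float, str]] = {}
    best_for_b: dict[str, tuple[float, str]] = {}
    for ga in ids_a:
        pa = proteins_a[ga]
        for gb in ids_b:
            s = protein_score(pa, proteins_b[gb])
            if ga not in best_for_a or s > best_for_a[ga][0]:
                best_for_a[ga] = (s, gb)
            if gb not in best_for_b or s > best_for_b[gb][0]:
                best_for_b[gb] = (s, ga)
    pairs = []
    for ga in ids_a:
        s, gb = best_for_a[ga]
        if s >= min_score and best_for_b[gb][1] == ga:
            pairs.append((ga, gb))
    return pairs


def align_protein_pair(p_a: str, p_b: str) -> tuple[str, str, float]:
    """Deterministic global protein alignment (delegates to the shared aligner)."""
    if not p_a or not p_b:
        raise ValueError("cannot align an empty protein")
    return align_proteins(p_a, p_b)


def _column_of_residue(gapped: str, residue_index: int) -> int:
    """Alignment column (0-based) of the ``residue_index``-th (1-based) residue."""
    seen = 0
    for col, c in enumerate(gapped):
        if c != "-":
            seen += 1
            if seen == residue_index:
                return col
    return len(gapped) - 1  # intron beyond the aligned protein (stop-adjacent)


def project_intron_positions(
    pair: OrthologPair,
    introns_a: Sequence[Intron],
    introns_b: Sequence[Intron],
) -> OrthologPair:
    """Fill (column, phase) keys for both genes' introns.

    For an intron after ``c`` coding nt: residue r = ceil(c/3) (1-based),
    phase = c mod 3; phase 0 means the intron follows residue r's codon,
    phases 1/2 that it interrupts it. Introns mapping into a gap column keep
    their own column; the comparison then simply finds no match."""
    def _keys(gapped: str, introns: Sequence[Intron]) -> list[PositionKey]:
        out = []
        for i in sorted(introns, key=lambda x: x.ordinal):
            c = i.coding_offset
            r = (c + 2) // 3
            col = _column_of_residue(gapped, r)
            out.append(
                PositionKey(intron_id=i.id, column=col, phase=c % 3, class_label=i.class_label)
            )
        return out

    pair.positions_a = _keys(pair.aln_a, introns_a)
    pair.positions_b = _keys(pair.aln_b, introns_b)
    return pair


def build_pairs(
    a: AnnotationSet,
    b: AnnotationSet,
    ortholog_map: Optional[dict[str, str]] = None,
) -> list[OrthologPair]:
    """Align and project every ortholog pair.

    ``ortholog_map`` (gene_a -> gene_b) bypasses RBH — the hook for callers
    with an external orthology."""
    if ortholog_map is None:
        prots_a = {g.id: g.protein for g in a.genes.values() if g.protein}
        prots_b = {g.id: g.protein for g in b.genes.values() if g.protein}
        mapping = dict(reciprocal_best_hits(prots_a, prots_b))
    else:
        mapping = ortholog_map
    introns_a: dict[str, list[Intron]] = {}
    for i in a.introns:
        introns_a.setdefault(i.gene_id, []).append(i)
    introns_b: dict[str, list[Intron]] = {}
    for i in b.introns:
        introns_b.setdefault(i.gene_id, []).append(i)
    pairs = []
    for ga in sorted(mapping):
        gb = mapping[ga]
        if ga not in a.genes or gb not in b.genes:
            continue
        pa, pb = a.genes[ga].protein, b.genes[gb].protein
        if not pa or not pb:
            continue
        aln_a, aln_b, score = align_protein_pair(pa, pb)
        pair = OrthologPair(gene_a=ga, gene_b=gb, aln_a=aln_a, aln_b=aln_b, score=score)
        project_intron_positions(pair, introns_a.get(ga, ()), introns_b.get(gb, ()))
        pairs.append(pair)
    return pairs


def _base_class(label: str) -> str:
    return "ie" if label.startswith("ie") else label


@dataclass
class SharedPositionReport:
    per_class: pd.DataFrame
    cross_class: pd.DataFrame
    shared_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (id_a, id_b, class)


def shared_position_report(pairs: Iterable[OrthologPair]) -> SharedPositionReport:
    """Per-class shared-position statistics over all ortholog pairs.

    ``fraction_shared`` = 2*n_shared / (n_a + n_b) (symmetric); per-strain
    fractions are also emitted. Matches whose two introns carry different
    classes are tallied in the cross-class matrix, not as shared."""
    n_a: dict[str, int] = {}
    n_b: dict[str, int] = {}
    n_shared: dict[str, int] = {}
    cross: dict[tuple[str, str], int] = {}
    shared_pairs: list[tuple[str, str, str]] = []
    for pair in pairs:
        for k in pair.positions_a:
            n_a[_base_class(k.class_label)] = n_a.get(_base_class(k.class_label), 0) + 1
        by_key_b = {(k.column, k.phase): k for k in pair.positions_b}
        for k in pair.positions_b:
            n_b[_base_class(k.class_label)] = n_b.get(_base_class(k.class_label), 0) + 1
        for ka in pair.positions_a:
            kb = by_key_b.get((ka.column, ka.phase))
            if kb is None:
                continue
            ca, cb = _base_class(ka.class_label), _base_class(kb.class_label)
            if ca == cb:
                n_shared[ca] = n_shared.get(ca, 0) + 1
                shared_pairs.append((ka.intron_id, kb.intron_id, ca))
            else:
                cross[(ca, cb)] = cross.get((ca, cb), 0) + 1
    classes = sorted(set(n_a) | set(n_b))
    rows = []
    for c in classes:
        na, nb, s = n_a.get(c, 0), n_b.get(c, 0), n_shared.get(c, 0)
        rows.append(
            {
                "class": c,
                "n_a": na,
                "n_b": nb,
                "n_shared": s,
                "fraction_shared": 2.0 * s / (na + nb) if na + nb else float("nan"),
                "fraction_a": s / na if na else float("nan"),
                "fraction_b": s / nb if nb else float("nan"),
            }
        )
    cross_rows = [
        {"class_a": ca, "class_b": cb, "n": n} for (ca, cb), n in sorted(cross.items())
    ]
    return SharedPositionReport(
        per_class=pd.DataFrame(rows),
        cross_class=pd.DataFrame(cross_rows, columns=["class_a", "class_b", "n"]),
        shared_pairs=shared_pairs,
    )


@dataclass
class ConservedRemnantRecord:
    intron_a: str
    intron_b: str
    family_id: str
    side: str  # a | b | both
    identity: float


def conserved_intron_remnants(
    report: SharedPositionReport,
    families,
    introns_a: dict[str, Intron],
    introns_b: dict[str, Intron],
    min_identity: float = 65.0,
    min_len: int = 40,
) -> list[ConservedRemnantRecord]:
    """Among shared canonical intron pairs, find repeat-family remnants buried
    in either intron's interior (semi-global block/consensus match at the
    remnant identity floor)."""
    out = []
    queries = []
    for f in families:
        if len(f.consensus) >= min_len:
            queries.append((f.id, f.consensus))
        for name, block, _ in f.motif_blocks:
            if len(block) >= min_len:
                queries.append((f.id, block))
    for id_a, id_b, cls in report.shared_pairs:
        if cls != "canonical":
            continue
        ia, ib = introns_a.get(id_a), introns_b.get(id_b)
        if ia is None or ib is None:
            continue
        for fam_id, q in queries:
            k = max_edits(len(q), min_identity)
            hit_a = infix_distance(q, ia.seq, k=k) >= 0
            hit_b = infix_distance(q, ib.seq, k=k) >= 0
            if hit_a or hit_b:
                side = "both" if (hit_a and hit_b) else ("a" if hit_a else "b")
                ident = min_identity  # floor; exact identity recomputed on demand
                out.append(
                    ConservedRemnantRecord(
                        intron_a=id_a, intron_b=id_b, family_id=fam_id, side=side, identity=ident
                    )
                )
                break
    return out
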