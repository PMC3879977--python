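"""Seed-and-align fragment mapping and presence/absence polymorphism calls.

Fragments (Sanger-scale read surrogates) are anchored on a reference genome
with an exact k-mer index, chained on a dominant diagonal, then aligned
semi-globally with edlib. Indel gaps in the alignment become PAP events:
a deletion gap matching an annotated repeat-intron interval means the
fragment lineage lacks that intron (absent_in_fragment); an insertion gap
whose sequence matches a repeat-family consensus at a novel transcribed
position is a novel insertion (novel_in_fragment). Both flanks must align
at the flank identity floor, so calls near fragment ends are suppressed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .align import infix_affine, max_edits
from .model import AnnotationSet, revcomp


@dataclass
class Fragment:
    id: str
    seq: str
    source: str = ""


@dataclass
class FragmentAlignment:
    fragment_id: str
    seq_id: str
    ref_start: int
    ref_end: int
    strand: str  # strand of the reference the (possibly flipped) fragment matches
    identity: float
    frag_aligned: str  # gapped fragment (oriented to reference forward strand)
    ref_aligned: str


@dataclass
class PapEvent:
    seq_id: str
    ref_start: int
    ref_end: int  # == ref_start for novel insertions
    event_type: str  # absent_in_fragment | novel_in_fragment
    family_id: str
    flank_len_5: int
    flank_len_3: int
    flank_identity_5: float
    flank_identity_3: float
    fragment_id: str


@dataclass
class SeedIndex:
    k: int
    positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    seq_ids: list[str] = field(default_factory=list)


def build_seed_index(a: AnnotationSet, k: int = 21) -> SeedIndex:
    """Exact k-mer -> (seq_id, position) map over the forward genome strand.

    Reverse-strand queries are served by looking up the reverse complement of
    the fragment, which is equivalent to indexing both strands. N-containing
    k-mers are skipped."""
    if k < 8:
        raise ValueError("seed k must be >= 8")
    idx = SeedIndex(k=k)
    for sid, rec in a.sequences.items():
        idx.seq_ids.append(sid)
        s = rec.seq
        for p in range(len(s) - k + 1):
            km = s[p : p + k]
            if "N" in km:
                continue
            idx.positions.setdefault(km, []).append((sid, p))
    return idx


def _seed_hits(frag: str, idx: SeedIndex, stride: int = 4, max_per_seed: int = 8):
    hits: dict[tuple[str, str], list[tuple[int, int]]] = {}
    k = idx.k
    for orient, seq in (("+", frag), ("-", revcomp(frag))):
        for q in range(0, len(seq) - k + 1, stride):
            lst = idx.positions.get(seq[q : q + k])
            if not lst or len(lst) > max_per_seed:
                continue
            for sid, p in lst:
                hits.setdefault((sid, orient), []).append((q, p))
    return hits


def align_fragment(
    fragment: Fragment,
    idx: SeedIndex,
    a: AnnotationSet,
    min_identity: float = 90.0,
    min_aln_len: int = 100,
    max_indel: int = 2000,
) -> list[FragmentAlignment]:
    """Best non-overlapping alignments of a strand-unknown fragment.

    Seeds are grouped per reference sequence and orientation, the dominant
    diagonal band selects a colinear chain, and the fragment is aligned
    semi-globally into the chained reference span (padded by ``max_indel``
    for structural differences)."""
    groups = _seed_hits(fragment.seq, idx)
    results: list[FragmentAlignment] = []
    for (sid, orient), hits in sorted(groups.items()):
        if len(hits) < 3:
            continue
        seq = fragment.seq if orient == "+" else revcomp(fragment.seq)
        ref = a.sequences[sid].seq
        # dominant diagonal: mode of (ref pos - frag pos) within a tolerance band
        diags = sorted(p - q for q, p in hits)
        best_band, band_lo = 0, diags[0]
        i = 0
        for j in range(len(diags)):
            while diags[j] - diags[i] > max_indel:
                i += 1
            if j - i + 1 > best_band:
                best_band, band_lo = j - i + 1, diags[i]
        chain = [(q, p) for q, p in hits if band_lo <= p - q <= band_lo + max_indel]
        if len(chain) < 3:
            continue
        # project the fragment ends through the extreme chain diagonals
        diag_min = min(p - q for q, p in chain)
        diag_max = max(p - q for q, p in chain)
        lo = max(0, diag_min - 50)
        hi = min(len(ref), diag_max + len(seq) + 50)
        window = ref[lo:hi]
        res = infix_affine(seq, window)
        if res is None:
            continue
        # substitution-level identity: a real structural indel (the signal
        # PAP calling looks for) must not push a fragment below the floor
        if res["identity_matched"] < min_identity:
            continue
        s, e = res["target_span"]
        if e - s < min_aln_len:
            continue
        results.append(
            FragmentAlignment(
                fragment_id=fragment.id,
                seq_id=sid,
                ref_start=lo + s,
                ref_end=lo + e,
                strand=orient,
                identity=res["identity_matched"],
                frag_aligned=res["query_aligned"],
                ref_aligned=res["target_aligned"],
            )
        )
    # best-scoring non-overlapping selection (identity, then length)
    results.sort(key=lambda r: (-r.identity, -(r.ref_end - r.ref_start), r.seq_id, r.ref_start))
    chosen: list[FragmentAlignment] = []
    for r in results:
        if all(
            r.seq_id != c.seq_id or r.ref_end <= c.ref_start or c.ref_end <= r.ref_start
            for c in chosen
        ):
            chosen.append(r)
    return chosen


def _gap_runs(aln: FragmentAlignment):
    """Indel runs in the alignment: ('del', ref interval) where the fragment
    lacks reference bases; ('ins', ref point, inserted seq) where it carries
    extra bases."""
    runs = []
    ref_pos = aln.ref_start
    i = 0
    fa, ra = aln.frag_aligned, aln.ref_aligned
    n = len(fa)
    while i < n:
        if fa[i] == "-":
            j = i
            while j < n and fa[j] == "-":
                j += 1
            runs.append(("del", ref_pos, ref_pos + (j - i), ""))
            ref_pos += j - i
            i = j
        elif ra[i] == "-":
            j = i
            while j < n and ra[j] == "-":
                j += 1
            runs.append(("ins", ref_pos, ref_pos, fa[i:j]))
            i = j
        else:
            ref_pos += 1
            i += 1
    return runs


def _flank_stats(aln: FragmentAlignment, col_lo: int, col_hi: int, min_flank: int):
    """Fragment-base counts and identities for the alignment flanks around
    columns [col_lo, col_hi)."""
    fa, ra = aln.frag_aligned, aln.ref_aligned

    def _one(cols) -> tuple[int, float]:
        frag_bases = 0
        matches = 0
        columns = 0
        for c in cols:
            if fa[c] != "-":
                frag_bases += 1
            columns += 1
            if fa[c] == ra[c] and fa[c] != "-":
                matches += 1
            if frag_bases >= min_flank:
                break
        return frag_bases, (100.0 * matches / columns if columns else 0.0)

    len5, id5 = _one(range(col_lo - 1, -1, -1))
    len3, id3 = _one(range(col_hi, len(fa)))
    return len5, id5, len3, id3


def _columns_of_run(aln: FragmentAlignment, run) -> tuple[int, int]:
    """Alignment-column interval of an indel run (recomputed by rescanning)."""
    kind, rs, re_, ins = run
    ref_pos = aln.ref_start
    fa, ra = aln.frag_aligned, aln.ref_aligned
    for i in range(len(fa)):
        if kind == "del" and fa[i] == "-" and ref_pos == rs:
            j = i
            while j < len(fa) and fa[j] == "-":
                j += 1
            return i, j
        if kind == "ins" and ra[i] == "-" and ref_pos == rs and fa[i:].startswith(ins[:1]):
            j = i
            while j < len(fa) and ra[j] == "-":
                j += 1
            if fa[i:j] == ins:
                return i, j
        if ra[i] != "-":
            ref_pos += 1
    raise ValueError("indel run not found in alignment")


def _family_match(seq: str, families, min_identity: float = 65.0) -> Optional[str]:
    """Family whose consensus matches ``seq`` semi-globally at the identity
    floor; the shorter of the two must align over its full length, which
    enforces the coverage requirement by construction."""
    for f in families:
        if not f.consensus:
            continue
        short, long_ = (seq, f.consensus) if len(seq) <= len(f.consensus) else (f.consensus, seq)
        k = max_edits(len(short), min_identity)
        res = edlib.align(short, long_, mode="HW", task="distance", k=k)
        if res["editDistance"] >= 0:
            return f.id
    return None


def call_pap_events(
    alignments: Sequence[FragmentAlignment],
    a: AnnotationSet,
    families,
    min_flank: int = 40,
    min_flank_identity: float = 90.0,
    slack: int = 5,
    min_ie_len: int = 40,
    dedup: bool = True,
) -> list[PapEvent]:
    """PAP events from fragment alignments.

    absent_in_fragment: a deletion gap matching a labeled repeat-intron
    interval within +/- ``slack``. novel_in_fragment: an insertion gap of at
    least ``min_ie_len`` whose sequence matches a family consensus, at a
    point inside an annotated transcribed region, sense-strand after
    orienting to the gene. Events deduplicate by (seq_id, position, family)
    with supporting-fragment counts kept on the first representative."""
    ie_loci: dict[str, list] = {}
    for i in a.introns:
        if i.class_label.startswith("ie"):
            ie_loci.setdefault(i.seq_id, []).append(i)
    gene_spans: dict[str, list] = {}
    for g in a.genes.values():
        gene_spans.setdefault(g.seq_id, []).append(g)
    events: list[PapEvent] = []
    for aln in alignments:
        for run in _gap_runs(aln):
            kind, rs, re_, ins = run
            if kind == "del":
                match = None
                for i in ie_loci.get(aln.seq_id, ()):
                    if abs(i.start - rs) <= slack and abs(i.end - re_) <= slack:
                        match = i
                        break
                if match is None:
                    continue
                col_lo, col_hi = _columns_of_run(aln, run)
                l5, i5, l3, i3 = _flank_stats(aln, col_lo, col_hi, min_flank)
                if l5 < min_flank or l3 < min_flank or i5 < min_flank_identity or i3 < min_flank_identity:
                    continue
                events.append(
                    PapEvent(
                        seq_id=aln.seq_id,
                        ref_start=match.start,
                        ref_end=match.end,
                        event_type="absent_in_fragment",
                        family_id=(match.family_id or match.class_label.split(":", 1)[-1]),
                        flank_len_5=l5,
                        flank_len_3=l3,
                        flank_identity_5=i5,
                        flank_identity_3=i3,
                        fragment_id=aln.fragment_id,
                    )
                )
            else:
                if len(ins) < min_ie_len:
                    continue
                host = None
                for g in gene_spans.get(aln.seq_id, ()):
                    gs, ge = g.span
                    if gs <= rs <= ge:
                        host = g
                        break
                if host is None:
                    continue
                # orient the inserted sequence to the gene's sense strand
                sense_ins = ins if host.strand == "+" else revcomp(ins)
                fam = _family_match(sense_ins, families)
                if fam is None:
                    continue
                # skip if the reference already has this family's intron here
                already = any(
                    abs(i.start - rs) <= slack and (i.family_id == fam)
                    for i in ie_loci.get(aln.seq_id, ())
                )
                if already:
                    continue
                col_lo, col_hi = _columns_of_run(aln, run)
                l5, i5, l3, i3 = _flank_stats(aln, col_lo, col_hi, min_flank)
                if l5 < min_flank or l3 < min_flank or i5 < min_flank_identity or i3 < min_flank_identity:
                    continue
                events.append(
                    PapEvent(
                        seq_id=aln.seq_id,
                        ref_start=rs,
                        ref_end=rs,
                        event_type="novel_in_fragment",
                        family_id=fam,
                        flank_len_5=l5,
                        flank_len_3=l3,
                        flank_identity_5=i5,
                        flank_identity_3=i3,
                        fragment_id=aln.fragment_id,
                    )
                )
    if not dedup:
        return events
    return deduplicate_events(events)


@dataclass
class UniquePapEvent:
    seq_id: str
    ref_start: int
    ref_end: int
    event_type: str
    family_id: str
    support: int
    fragment_ids: list[str]


def deduplicate_events(events: Sequence[PapEvent], slack: int = 5) -> list[UniquePapEvent]:
    """Collapse per-fragment events into unique loci with support counts."""
    out: list[UniquePapEvent] = []
    for e in sorted(events, key=lambda e: (e.seq_id, e.event_type, e.family_id, e.ref_start)):
        merged = False
        for u in out:
            if (
                u.seq_id == e.seq_id
                and u.event_type == e.event_type
                and u.family_id == e.family_id
                and abs(u.ref_start - e.ref_start) <= slack
            ):
                if e.fragment_id not in u.fragment_ids:
                    u.support += 1
                    u.fragment_ids.append(e.fragment_id)
                merged = True
                break
        if not merged:
            out.append(
                UniquePapEvent(
                    seq_id=e.seq_id,
                    ref_start=e.ref_start,
                    ref_end=e.ref_end,
                    event_type=e.event_type,
                    family_id=e.family_id,
                    support=1,
                    fragment_ids=[e.fragment_id],
                )
            )
    return out
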