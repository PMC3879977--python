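"""Per-intron and per-class sequence features.

Covers GC content, phase, splice-site dinucleotide status, branch-point
motif search, donor/acceptor base-count profiles, boundary GC meta-profiles
(with splice-signal trimming), relative genic position and antisense ORFs.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

from .model import revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .model import AnnotationSet, GeneModel, Intron

BASES = "ACGT"
BASE_ORDER = {b: k for k, b in enumerate(BASES)}  # consensus ties break A<C<G<T


def gc_percent(seq: str) -> float:
    """GC percentage of ``seq``; N excluded from the denominator.

    Returns NaN for an all-N sequence, raises on an empty one.
    """
    if not seq:
        raise ValueError("gc_percent of an empty sequence is undefined")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return math.nan
    return 100.0 * gc / (gc + at)


def intron_phase(coding_offset: int) -> int:
    """Phase of an intron after ``coding_offset`` coding nucleotides.

    0 = between codons, 1/2 = after the first/second base of a codon.
    """
    if coding_offset < 1:
        raise ValueError("coding_offset must be >= 1")
    return coding_offset % 3


def splice_sites(intron: "Intron") -> dict[str, str]:
    """Terminal dinucleotides and their canonical/noncanonical status.

    Donor GT is canonical, GC noncanonical-but-spliceable; acceptor AG is
    canonical with TG/CG the noncanonical variants seen in this system.
    """
    d, a = intron.donor2, intron.acceptor2
    donor_status = d if d in ("GT", "GC") else "other"
    acceptor_status = a if a in ("AG", "TG", "CG") else "other"
    return {
        "donor2": d,
        "acceptor2": a,
        "donor_status": donor_status,
        "acceptor_status": acceptor_status,
    }


@dataclass
class BranchPointHit:
    intron_id: str
    motif: str
    offset: int  # nt from motif start to the intron 3' terminal base, inclusive


def _motif_regex(motif: str) -> re.Pattern:
    return re.compile("".join("[ACGT]" if c == "N" else c for c in motif.upper()))


def find_branch_point(
    intron: "Intron",
    motif: str = "NCTGAC",
    window: tuple[int, int] = (43, 52),
    anchor: str = "start",
) -> list[BranchPointHit]:
    """All matches of ``motif`` whose offset from the acceptor falls in ``window``.

    The offset counts from the anchored motif base to the intron's 3'
    terminal base, inclusive. ``anchor`` selects whether the window is
    measured to the motif's first ("start") or last ("end") base.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"inverted branch-point window {window}")
    m = len(motif)
    if anchor == "start" and lo < m:
        raise ValueError("window minimum must be >= motif length when anchored at start")
    pat = _motif_regex(motif)
    L = intron.length
    hits = []
    for match in _overlapping_matches(pat, intron.seq):
        p = match
        off_start = L - p  # positions p..L-1 inclusive
        off = off_start if anchor == "start" else off_start - (m - 1)
        if lo <= off <= hi:
            hits.append(BranchPointHit(intron_id=intron.id, motif=motif, offset=off))
    return hits


def _overlapping_matches(pat: re.Pattern, seq: str) -> Iterable[int]:
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


@dataclass
class SpliceProfile:
    """Per-position base counts over a boundary window, with majority consensus."""

    side: str  # "donor" or "acceptor"
    window: tuple[int, int]  # (exon nt, intron nt)
    counts: np.ndarray  # shape (4, span), rows A,C,G,T
    n: int
    skipped: int

    @property
    def consensus(self) -> str:
        out = []
        for col in self.counts.T:
            best = int(np.argmax(col))  # argmax returns first max: A<C<G<T tie-break
            out.append(BASES[best])
        return "".join(out)


def _exon_flank(intron: "Intron", gene: "GeneModel", a: "AnnotationSet", side: str, width: int) -> str:
    """Exonic sequence adjacent to the intron, in transcript orientation.

    ``side="5"`` returns up to ``width`` nt of the upstream exon ending at
    the donor; ``side="3"`` the downstream exon starting at the acceptor.
    The flank is capped at the adjacent CDS piece.
    """
    seq = a.sequences[intron.seq_id].seq
    pieces = gene.cds_intervals
    want_upstream = (side == "5") == (intron.strand == "+")
    if want_upstream:
        # genomic piece ending at intron.start
        for s, e in pieces:
            if e == intron.start:
                frag = seq[max(s, intron.start - width) : intron.start]
                break
        else:
            return ""
    else:
        for s, e in pieces:
            if s == intron.end:
                frag = seq[intron.end : min(e, intron.end + width)]
                break
        else:
            return ""
    return frag if intron.strand == "+" else revcomp(frag)


def splice_profile(
    a: "AnnotationSet",
    introns: Iterable["Intron"],
    side: str = "donor",
    window: tuple[int, int] = (3, 6),
) -> SpliceProfile:
    """Base-count matrix over [exon|intron] at the donor (or mirrored at the acceptor).

    For the donor the window reads ``exon_nt`` exon bases then ``intron_nt``
    intron bases 5'->3'; for the acceptor, ``intron_nt`` intron bases then
    ``exon_nt`` exon bases. Introns with insufficient exon flank are skipped
    and counted.
    """
    exon_nt, intron_nt = window
    span = exon_nt + intron_nt
    counts = np.zeros((4, span), dtype=np.int64)
    n = 0
    skipped = 0
    for i in introns:
        gene = a.genes[i.gene_id]
        if side == "donor":
            flank = _exon_flank(i, gene, a, "5", exon_nt)
            if len(flank) < exon_nt or i.length < intron_nt:
                skipped += 1
                continue
            window_seq = flank[-exon_nt:] + i.seq[:intron_nt]
        else:
            flank = _exon_flank(i, gene, a, "3", exon_nt)
            if len(flank) < exon_nt or i.length < intron_nt:
                skipped += 1
                continue
            window_seq = i.seq[-intron_nt:] + flank[:exon_nt]
        if any(c not in BASE_ORDER for c in window_seq):
            skipped += 1
            continue
        for pos, c in enumerate(window_seq):
            counts[BASE_ORDER[c], pos] += 1
        n += 1
    return SpliceProfile(side=side, window=window, counts=counts, n=n, skipped=skipped)


@dataclass
class GcProfile:
    """Mean GC indicator per position around both exon/intron boundaries.

    Tracks are in transcript orientation. Exon positions run toward the
    boundary (index -1 = closest kept exon base); intron positions run away
    from it. Positions never covered have ``n == 0`` and NaN mean.
    """

    exon_window: int = 80
    intron_window: int = 40
    exon_trim: int = 3
    intron_trim: int = 6
    # four tracks: donor_exon, donor_intron, acceptor_intron, acceptor_exon
    mean_gc: dict[str, np.ndarray] = field(default_factory=dict)
    n_per_position: dict[str, np.ndarray] = field(default_factory=dict)
    cds_baseline_gc: float = math.nan
    n: int = 0


def boundary_gc_profile(
    introns: Iterable["Intron"],
    a: "AnnotationSet",
    exon_window: int = 80,
    intron_window: int = 40,
    exon_trim: int = 3,
    intron_trim: int = 6,
) -> GcProfile:
    """Boundary GC meta-profile for a class subset of introns.

    The ``exon_trim`` exon bases and ``intron_trim`` intron bases adjacent
    to each splice site are discarded to omit splice-site signals; the next
    ``exon_window`` / ``intron_window`` positions are then averaged across
    introns (GC indicator per position). Also reports the mean GC of coding
    sequences of genes hosting at least one intron of the subset.
    """
    introns = list(introns)
    tracks = {
        "donor_exon": np.zeros(exon_window),
        "donor_intron": np.zeros(intron_window),
        "acceptor_intron": np.zeros(intron_window),
        "acceptor_exon": np.zeros(exon_window),
    }
    ns = {k: np.zeros(len(v), dtype=np.int64) for k, v in tracks.items()}
    host_genes: dict[str, None] = {}
    n_used = 0
    for i in introns:
        gene = a.genes[i.gene_id]
        host_genes.setdefault(i.gene_id)
        up = _exon_flank(i, gene, a, "5", exon_window + exon_trim)
        down = _exon_flank(i, gene, a, "3", exon_window + exon_trim)
        body = i.seq
        usable = body[intron_trim : len(body) - intron_trim]
        # donor exon: positions -exon_window..-1 (rightmost = closest to boundary)
        ex5 = up[:-exon_trim] if exon_trim else up
        for k, c in enumerate(reversed(ex5[-exon_window:])):
            if c in "GCAT":
                tracks["donor_exon"][exon_window - 1 - k] += c in "GC"
                ns["donor_exon"][exon_window - 1 - k] += 1
        for k, c in enumerate(usable[:intron_window]):
            if c in "GCAT":
                tracks["donor_intron"][k] += c in "GC"
                ns["donor_intron"][k] += 1
        for k, c in enumerate(reversed(usable[-intron_window:] if usable else "")):
            if c in "GCAT":
                tracks["acceptor_intron"][intron_window - 1 - k] += c in "GC"
                ns["acceptor_intron"][intron_window - 1 - k] += 1
        ex3 = down[exon_trim:] if exon_trim else down
        for k, c in enumerate(ex3[:exon_window]):
            if c in "GCAT":
                tracks["acceptor_exon"][k] += c in "GC"
                ns["acceptor_exon"][k] += 1
        n_used += 1
    mean_gc = {}
    for k in tracks:
        with np.errstate(invalid="ignore"):
            mean_gc[k] = np.where(ns[k] > 0, 100.0 * tracks[k] / np.maximum(ns[k], 1), np.nan)
    baseline = math.nan
    if host_genes:
        gcs = []
        for gid in host_genes:
            g = a.genes[gid]
            seq = a.sequences[g.seq_id].seq
            joined = "".join(seq[s:e] for s, e in g.cds_intervals)
            gcs.append(gc_percent(joined))
        baseline = float(np.mean(gcs))
    return GcProfile(
        exon_window=exon_window,
        intron_window=intron_window,
        exon_trim=exon_trim,
        intron_trim=intron_trim,
        mean_gc=mean_gc,
        n_per_position=ns,
        cds_baseline_gc=baseline,
        n=n_used,
    )


def relative_genic_position(intron: "Intron", gene: "GeneModel") -> float:
    """Fractional position of the intron within the CDS, in (0, 1)."""
    return intron.coding_offset / gene.cds_length


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(seq: str) -> Optional[dict]:
    """Longest ATG->stop ORF (stop included) in the three forward frames of ``seq``."""
    best = None
    L = len(seq)
    for frame in range(3):
        start = None
        for p in range(frame, L - 2, 3):
            codon = seq[p : p + 3]
            if start is None:
                if codon == "ATG":
                    start = p
            elif codon in _STOPS:
                length = p + 3 - start
                if best is None or length > best["length"]:
                    best = {"length": length, "interval": (start, p + 3)}
                start = None
    return best


def longest_antisense_orf(intron: "Intron") -> Optional[dict]:
    """Longest ORF on the reverse complement of the intron, or None.

    The interval is in reverse-complement coordinates.
    """
    return longest_orf(revcomp(intron.seq))
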