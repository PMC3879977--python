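"""Alignment primitives shared across discovery, ortholog and PAP stages.

DNA edit-distance work goes through edlib; protein alignment and DNA local
(Smith-Waterman) alignment go through Biopython's PairwiseAligner. Helper
results are plain dataclasses so downstream code never touches the backends
directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


# ---------------------------------------------------------------------------
# pairwise DNA similarity (identity/coverage of a local alignment)

@dataclass
class LocalAlignment:
    identity: float  # % matches over aligned columns
    coverage: float  # % of the shorter sequence covered by the aligned region
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]


@lru_cache(maxsize=None)
def _dna_local_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -5
    al.extend_gap_score = -2
    return al


def local_align_dna(query: str, target: str) -> Optional[LocalAlignment]:
    """Best local DNA alignment; identity over aligned columns, coverage over
    the shorter input. Returns None when nothing aligns."""
    al = _dna_local_aligner()
    try:
        alns = al.align(query, target)
        if len(alns) == 0:
            return None
        best = alns[0]
    except (ValueError, OverflowError):  # empty input / huge ties
        return None
    qa, ta = best.aligned
    if len(qa) == 0:
        return None
    matches = 0
    columns = 0
    for (qs, qe), (ts, te) in zip(qa, ta):
        for i in range(qe - qs):
            columns += 1
            if query[qs + i] == target[ts + i]:
                matches += 1
    # gap columns between aligned blocks
    for k in range(1, len(qa)):
        columns += (qa[k][0] - qa[k - 1][1]) + (ta[k][0] - ta[k - 1][1])
    qspan = (qa[0][0], qa[-1][1])
    tspan = (ta[0][0], ta[-1][1])
    shorter = min(len(query), len(target))
    aligned_short = (qspan[1] - qspan[0]) if len(query) <= len(target) else (tspan[1] - tspan[0])
    return LocalAlignment(
        identity=100.0 * matches / columns if columns else 0.0,
        coverage=100.0 * aligned_short / shorter if shorter else 0.0,
        score=float(best.score),
        query_span=qspan,
        target_span=tspan,
    )


def infix_distance(query: str, target: str, k: int = -1) -> int:
    """Minimum edit distance of ``query`` aligned semi-globally inside ``target``.

    Returns -1 if the distance exceeds ``k`` (when ``k >= 0``).
    """
    return edlib.align(query, target, mode="HW", task="distance", k=k)["editDistance"]


def infix_align(query: str, target: str, k: int = -1) -> Optional[dict]:
    """Semi-global alignment of ``query`` inside ``target`` with path.

    Returns dict with distance, identity (% matches over columns), and the
    target interval of the best location, or None if above ``k``.
    """
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    nice = edlib.getNiceAlignment(res, query, target)
    cols = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    paired = sum(
        1 for qc, tc in zip(nice["query_aligned"], nice["target_aligned"])
        if qc != "-" and tc != "-"
    )
    return {
        "distance": res["editDistance"],
        "identity": 100.0 * matches / cols if cols else 0.0,
        # substitution-level identity: gap columns (structural indels) excluded
        "identity_matched": 100.0 * matches / paired if paired else 0.0,
        "target_span": (s, e + 1),
        "cigar": res["cigar"],
        "query_aligned": nice["query_aligned"],
        "target_aligned": nice["target_aligned"],
    }


def global_align_dna(query: str, target: str) -> dict:
    """Global (NW) DNA alignment with path, via edlib."""
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    cols = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    return {
        "distance": res["editDistance"],
        "identity": 100.0 * matches / cols if cols else 0.0,
        "cigar": res["cigar"],
        "query_aligned": nice["query_aligned"],
        "target_aligned": nice["target_aligned"],
    }


@lru_cache(maxsize=None)
def _dna_infix_aligner() -> Align.PairwiseAligner:
    # affine gaps so one long structural indel beats scattered repeat-pairing;
    # reference (target) end gaps free = semi-global containment of the query
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -4
    al.open_gap_score = -10
    al.extend_gap_score = -0.5
    # free end gaps on the target (the attribute pair depends on the
    # Biopython generation; "insertion" is the newer name for a target gap)
    names = (
        ("open_left_insertion_score", "extend_left_insertion_score",
         "open_right_insertion_score", "extend_right_insertion_score")
        if hasattr(al, "open_left_insertion_score")
        else ("target_left_open_gap_score", "target_left_extend_gap_score",
              "target_right_open_gap_score", "target_right_extend_gap_score")
    )
    for name in names:
        setattr(al, name, 0)
    return al


def infix_affine(query: str, target: str) -> Optional[dict]:
    """Affine-gap semi-global alignment of ``query`` inside ``target``.

    Unlike unit-cost edit distance, affine scoring keeps a structural indel
    in one contiguous gap instead of trading it against repeat copies
    elsewhere in the window. Returns the same dict shape as
    :func:`infix_align` (restricted to the aligned target span).
    """
    try:
        best = _dna_infix_aligner().align(target, query)[0]
    except (ValueError, OverflowError, MemoryError):
        return None
    t_blocks, q_blocks = best.aligned
    if len(t_blocks) == 0:
        return None
    out_q: list[str] = []
    out_t: list[str] = []
    pq, pt = q_blocks[0][0], t_blocks[0][0]
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        while pq < qs:
            out_q.append(query[pq]); out_t.append("-"); pq += 1
        while pt < ts:
            out_q.append("-"); out_t.append(target[pt]); pt += 1
        for i in range(te - ts):
            out_q.append(query[qs + i]); out_t.append(target[ts + i])
        pq, pt = qe, te
    # query overhangs beyond the last aligned block stay part of the alignment
    while pq < len(query):
        out_q.append(query[pq]); out_t.append("-"); pq += 1
    qa, ta = "".join(out_q), "".join(out_t)
    matches = sum(1 for a, b in zip(qa, ta) if a == b and a != "-")
    paired = sum(1 for a, b in zip(qa, ta) if a != "-" and b != "-")
    cols = len(qa)
    return {
        "distance": None,
        "score": float(best.score),
        "identity": 100.0 * matches / cols if cols else 0.0,
        "identity_matched": 100.0 * matches / paired if paired else 0.0,
        "target_span": (int(t_blocks[0][0]), int(t_blocks[-1][1])),
        "query_aligned": qa,
        "target_aligned": ta,
    }


# ---------------------------------------------------------------------------
# multi-hit semi-global scan (remnant detection)

@dataclass
class ScanHit:
    start: int
    end: int
    distance: int
    identity: float


def max_edits(query_len: int, min_identity: float) -> int:
    """Edit budget for a hit: floor(m * (1 - r)) with r = min_identity/100."""
    return int(np.floor(query_len * (1.0 - min_identity / 100.0)))


def scan_hits(query: str, target: str, min_identity: float) -> list[ScanHit]:
    """All non-overlapping semi-global occurrences of ``query`` in ``target``
    with edit distance <= the ``max_edits`` budget, found by best-hit-and-split
    recursion. Hits are returned sorted by start."""
    k = max_edits(len(query), min_identity)
    hits: list[ScanHit] = []
    margin = len(query) + k  # context kept around splits so flanking hits survive

    def _scan(lo: int, hi: int) -> None:
        if hi - lo < max(4, len(query) - k):
            return
        res = edlib.align(query, target[lo:hi], mode="HW", task="path", k=k)
        if res["editDistance"] < 0:
            return
        s, e = res["locations"][0]
        nice = edlib.getNiceAlignment(res, query, target[lo:hi])
        cols = len(nice["matched_aligned"])
        matches = nice["matched_aligned"].count("|")
        hits.append(
            ScanHit(
                start=lo + s,
                end=lo + e + 1,
                distance=res["editDistance"],
                identity=100.0 * matches / cols if cols else 0.0,
            )
        )
        _scan(lo, lo + s)
        _scan(lo + e + 1, hi)

    _scan(0, len(target))
    _ = margin  # splits exclude the hit exactly; overlapping hits merge downstream
    return sorted(hits, key=lambda h: h.start)


# ---------------------------------------------------------------------------
# protein alignment

@lru_cache(maxsize=None)
def _protein_aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def protein_score(p_a: str, p_b: str, mode: str = "global") -> float:
    return float(_protein_aligner(mode).score(p_a, p_b))


def align_proteins(p_a: str, p_b: str) -> tuple[str, str, float]:
    """Deterministic global protein alignment (BLOSUM62, affine -11/-1).

    Returns gapped strings of equal length plus the score.
    """
    al = _protein_aligner("global")
    best = al.align(p_a, p_b)[0]
    ga, gb = _gapped_from_aligned(p_a, p_b, best.aligned)
    return ga, gb, float(best.score)


def _gapped_from_aligned(a: str, b: str, aligned) -> tuple[str, str]:
    qa, ta = aligned  # aligned[0] refers to the first ("target") sequence = a
    out_a: list[str] = []
    out_b: list[str] = []
    pa = pb = 0
    for (as_, ae), (bs, be) in zip(qa, ta):
        # unaligned stretches before this block become gap columns
        while pa < as_:
            out_a.append(a[pa]); out_b.append("-"); pa += 1
        while pb < bs:
            out_a.append("-"); out_b.append(b[pb]); pb += 1
        for i in range(ae - as_):
            out_a.append(a[as_ + i]); out_b.append(b[bs + i])
        pa, pb = ae, be
    while pa < len(a):
        out_a.append(a[pa]); out_b.append("-"); pa += 1
    while pb < len(b):
        out_a.append("-"); out_b.append(b[pb]); pb += 1
    return "".join(out_a), "".join(out_b)
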