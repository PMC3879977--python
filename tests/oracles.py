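"""Independent brute-force oracles used by the test suite (and the
acceptance script). Everything here is written as plainly as possible —
naive loops, full DP matrices — and never calls the implementation paths
it is used to check."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def bf_gc_indicator(base: str):
    if base in "GC":
        return 1
    if base in "AT":
        return 0
    return None


def bf_boundary_gc_profile(intron_flanks, exon_window=80, intron_window=40,
                           exon_trim=3, intron_trim=6):
    """Naive per-position averaging. ``intron_flanks`` is a list of
    (upstream_exon, intron_seq, downstream_exon) in transcript orientation,
    exon flanks already capped at the adjacent CDS piece."""
    tracks = {
        "donor_exon": [[] for _ in range(exon_window)],
        "donor_intron": [[] for _ in range(intron_window)],
        "acceptor_intron": [[] for _ in range(intron_window)],
        "acceptor_exon": [[] for _ in range(exon_window)],
    }
    for up, body, down in intron_flanks:
        ex5 = up[:-exon_trim] if exon_trim else up
        ex5 = ex5[-exon_window:]
        for k, c in enumerate(ex5[::-1]):
            v = bf_gc_indicator(c)
            if v is not None:
                tracks["donor_exon"][exon_window - 1 - k].append(v)
        usable = body[intron_trim: len(body) - intron_trim]
        for k, c in enumerate(usable[:intron_window]):
            v = bf_gc_indicator(c)
            if v is not None:
                tracks["donor_intron"][k].append(v)
        for k, c in enumerate(usable[-intron_window:][::-1]):
            v = bf_gc_indicator(c)
            if v is not None:
                tracks["acceptor_intron"][intron_window - 1 - k].append(v)
        ex3 = down[exon_trim:] if exon_trim else down
        for k, c in enumerate(ex3[:exon_window]):
            v = bf_gc_indicator(c)
            if v is not None:
                tracks["acceptor_exon"][k].append(v)
    mean = {}
    n = {}
    for name, cols in tracks.items():
        mean[name] = np.array([100.0 * np.mean(col) if col else np.nan for col in cols])
        n[name] = np.array([len(col) for col in cols])
    return mean, n


def bf_branch_positions(seq: str, motif: str, lo: int, hi: int):
    """Naive scan: offsets (motif start to 3' terminal base, inclusive) of
    every match with offset in [lo, hi]."""
    L = len(seq)
    m = len(motif)
    out = []
    for p in range(L - m + 1):
        ok = all(motif[k] == "N" or seq[p + k] == motif[k] for k in range(m))
        if ok:
            off = L - p
            if lo <= off <= hi:
                out.append(off)
    return out


def bf_longest_orf_any_frame(seq: str):
    """Longest ATG..stop ORF over the three forward frames, by enumerating
    every ATG and scanning codon by codon."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for s in range(len(seq) - 2):
        if seq[s:s + 3] != "ATG":
            continue
        p = s + 3
        while p + 3 <= len(seq):
            if seq[p:p + 3] in stops:
                length = p + 3 - s
                if best is None or length > best[0]:
                    best = (length, (s, p + 3))
                break
            p += 3
    return best


def bf_splice_counts(windows):
    """Position x base counts by naive tallying; windows are equal-length strings."""
    span = len(windows[0])
    counts = np.zeros((4, span), dtype=int)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for w in windows:
        for pos, c in enumerate(w):
            counts[order[c], pos] += 1
    return counts


def bf_semiglobal_profile(query: str, target: str) -> np.ndarray:
    """Full semi-global DP (free target prefix/suffix): best edit distance of
    the whole query ending at each target position. Plain row-by-row DP with
    a column-wise running-minimum for insertions."""
    m = len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    col = np.arange(1, m + 1, dtype=np.int64)
    idx = np.arange(m, dtype=np.int64)
    out = np.empty(len(target), dtype=np.int64)
    for j, c in enumerate(target.encode()):
        sub = (q != c).astype(np.int64)
        prev_shift = np.concatenate(([0], col[:-1]))
        tmp = np.minimum(prev_shift + sub, col + 1)
        col = np.minimum.accumulate(tmp - idx) + idx
        out[j] = col[-1]
    return out


def bf_hit_intervals(query: str, target: str, min_identity: float):
    """Exhaustive scan oracle: end positions where the semi-global distance
    is within the edit budget, grouped into maximal runs and widened to
    [end - len(query) - d, end)."""
    k = int(np.floor(len(query) * (1.0 - min_identity / 100.0)))
    prof = bf_semiglobal_profile(query, target)
    ends = np.where(prof <= k)[0]
    if ends.size == 0:
        return []
    runs = []
    start = prev = ends[0]
    for e in ends[1:]:
        if e == prev + 1:
            prev = e
            continue
        runs.append((start, prev))
        start = prev = e
    runs.append((start, prev))
    out = []
    for s, e in runs:
        d = int(prof[s:e + 1].min())
        out.append((max(0, s - len(query) - d + 1), e + 1))
    # one degraded occurrence can surface as several nearby end-position
    # runs; merge overlapping intervals so each occurrence is one hit
    merged = [out[0]]
    for s, e in out[1:]:
        if s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def bf_gotoh_score(a: str, b: str, matrix, open_pen=-11, extend_pen=-1) -> float:
    """Affine-gap global alignment score by explicit three-matrix DP."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_pen + extend_pen * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_pen + extend_pen * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_pen, X[i - 1][j] + extend_pen,
                          Y[i - 1][j] + open_pen)
            Y[i][j] = max(M[i][j - 1] + open_pen, Y[i][j - 1] + extend_pen,
                          X[i][j - 1] + open_pen)
    return float(max(M[n][m], X[n][m], Y[n][m]))


def mutate(rng: np.random.Generator, seq: str, rate: float, protect: int = 0) -> str:
    """Independent per-position substitution helper for planted fixtures."""
    out = list(seq)
    for i in range(protect, len(seq) - protect):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.random.default_rng(rng.integers(2**31)).choice(list("ACGT"), size=n, p=p))
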