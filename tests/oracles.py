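"""Independent reference implementations used as test oracles.

These deliberately transliterate the stated detection and scoring rules in the
most direct way (string slicing, dense enumeration, textbook formulas) without
sharing code with the production paths they check.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "?"}


# ---------------------------------------------------------------------------
# MITE scanning
# ---------------------------------------------------------------------------

def brute_candidates_string(seq: str, *, tir_min=5, tir_max=60, tsd_min=2,
                            tsd_max=20, max_len=1500, max_mm=1):
    """Pure-string enumeration of every raw candidate (tiny inputs only).

    Yields (start, end, tir_len, tir_mm, tsd_len) with maximal TIR/TSD per body.
    """
    n = len(seq)
    out = []
    for s in range(n):
        for d in range(2 * tir_min, min(max_len - 1, n - s) + 1):
            e = s + d
            # maximal TIR: largest t with cumulative outer mismatches <= max_mm
            best_t = best_mm = 0
            mm = 0
            for t in range(1, min(tir_max, d // 2) + 1):
                a, b = seq[s + t - 1], seq[e - t]
                if COMP[a] != b or a == "N" or b == "N":
                    mm += 1
                if mm > max_mm:
                    break
                if t >= tir_min:
                    best_t, best_mm = t, mm
            if best_t < tir_min:
                continue
            # maximal exact TSD
            best_k = 0
            for k in range(tsd_min, tsd_max + 1):
                if s - k < 0 or e + k > n:
                    break
                left, right = seq[s - k:s], seq[e:e + k]
                if left == right and "N" not in left:
                    best_k = k
            if best_k:
                out.append((s, e, best_t, best_mm, best_k))
    return out


def dense_candidates(seq: str, *, tir_min=5, tir_max=60, tsd_min=2, tsd_max=20,
                     max_len=1500, max_mm=1):
    """Dense vectorized enumeration of raw candidates (up to ~50 kb).

    Per body length it evaluates the full TIR mismatch profile for every start,
    then verifies TSDs by direct string comparison at the surviving loci.
    """
    n = len(seq)
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int16)
    for x, y in [("A", 1), ("C", 2), ("G", 3), ("T", 4), ("N", 9)]:
        lut[ord(x)] = y
    a = lut[code]
    # complement codes; N (9) maps to 0 which matches nothing
    comp_lut = np.zeros(16, dtype=np.int16)
    for x, y in [(1, 4), (4, 1), (2, 3), (3, 2)]:
        comp_lut[x] = y
    ac = comp_lut[a]

    out = []
    for d in range(2 * tir_min, min(max_len - 1, n) + 1):
        width = n - d
        if width <= 0:
            break
        t_cap = min(tir_max, d // 2)
        mm = np.zeros(width, dtype=np.int16)
        best_t = np.zeros(width, dtype=np.int16)
        best_mm = np.zeros(width, dtype=np.int16)
        alive = np.ones(width, dtype=bool)
        for t in range(1, t_cap + 1):
            mm += a[t - 1:t - 1 + width] != ac[d - t:d - t + width]
            alive &= mm <= max_mm
            if t >= tir_min:
                best_t[alive] = t
                best_mm[alive] = mm[alive]
        for s in np.nonzero(best_t >= tir_min)[0].tolist():
            e = s + d
            best_k = 0
            for k in range(tsd_min, tsd_max + 1):
                if s - k < 0 or e + k > n:
                    break
                left = seq[s - k:s]
                if left == seq[e:e + k] and "N" not in left:
                    best_k = k
            if best_k:
                out.append((s, e, int(best_t[s]), int(best_mm[s]), best_k))
    return out


def resolve_reference(cands):
    """Reference overlap resolution: best-per-start, best-per-end, then greedy
    suppression in priority order (combined TIR+TSD length desc, mismatches
    asc, TIR desc, leftmost), all written as plain Python."""
    def prio(c):
        s, e, t, m, k = c
        return (-(t + k), m, -t, s, e)

    best_start: dict[int, tuple] = {}
    for c in cands:
        s, e, t, m, k = c
        key = (-(t + k), m, -t, e)
        if s not in best_start or key < best_start[s][0]:
            best_start[s] = (key, c)
    stage1 = [v[1] for v in best_start.values()]

    best_end: dict[int, tuple] = {}
    for c in stage1:
        s, e, t, m, k = c
        key = (-(t + k), m, -t, s)
        if e not in best_end or key < best_end[e][0]:
            best_end[e] = (key, c)
    stage2 = sorted((v[1] for v in best_end.values()), key=prio)

    accepted = []
    for c in stage2:
        s, e = c[0], c[1]
        span = e - s
        if any(min(e, ae) - max(s, as_) > 0 and
               5 * (min(e, ae) - max(s, as_)) > 4 * max(span, ae - as_)
               for as_, ae in accepted):
            continue
        accepted.append((s, e))
        yield c


def brute_scan(seq: str, **kw):
    """Full reference scan: dense enumeration + reference overlap resolution."""
    return sorted(resolve_reference(dense_candidates(seq, **kw)))


# ---------------------------------------------------------------------------
# alignment / statistics oracles
# ---------------------------------------------------------------------------

def needleman_wunsch_free_ends(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Textbook full-matrix DP with free end gaps; returns the optimal score."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    return max(H[n, :].max(), H[:, m].max())


def pearson_chi_square(observed, expected):
    """Plain-sum Pearson statistic over a 2-way table."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    r, c = obs.shape
    return stat, (r - 1) * (c - 1)


def hamming_hits(read: str, consensus: str, max_mm: int):
    """All ungapped end-to-end placements of `read` on the forward strand."""
    L, n = len(read), len(consensus)
    hits = []
    for pos in range(n - L + 1):
        window = consensus[pos:pos + L]
        mm = sum(1 for x, y in zip(read, window)
                 if x != y or x == "N" or y == "N")
        if mm <= max_mm:
            hits.append((pos, mm))
    return hits
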