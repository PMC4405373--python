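"""De novo structural detection of MITE candidates.

A candidate locus is a genomic interval (the element *body*, TSD excluded) whose
termini form a terminal inverted repeat (TIR) of 5-60 bp with at most
``max_tir_mismatch`` mismatches, flanked on both sides by an identical direct
repeat (the target site duplication, TSD) of 2-20 bp, with body length below
``max_element_len``.  ``N`` never matches any base.

For a fixed body ``[s, e)`` the reported TIR length is the *largest*
``t`` (up to ``tir_max`` and half the body) whose outer-aligned Hamming
mismatch count stays within budget; the reported TSD is the longest exact
direct repeat within the allowed length range.

Overlap resolution (the raw enumeration is massively redundant on real-sized
sequences) is deterministic and happens in three stages:

1. per body start, keep the best candidate by the priority key;
2. per body end, keep the best by the same key;
3. greedy non-maximum suppression in global priority order: a candidate is
   dropped if it overlaps an already accepted one by more than 80% of *both*
   spans, i.e. only near-duplicate parses of the same locus compete; distinct
   structures that merely overlap are all reported.

The priority key ranks candidates by total structural evidence — TIR length
plus TSD length, descending — then fewer TIR mismatches, longer TIR, leftmost
start, leftmost end.  Ranking on the combined length keeps superfamilies with
short TIRs but long TSDs (Mutator-like: 5 bp TIR, 10 bp TSD) from being
shadowed by chance medium-TIR candidates, which outnumber any fixed structure
in AT-rich background sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dna import at_fraction, complement_codes, encode
from .core_io import GenomeSequence, PipelineConfig

__all__ = [
    "MiteCandidate",
    "scan_genome",
    "filter_candidates",
    "extract_element_sequences",
    "structure_at",
]


@dataclass(frozen=True)
class MiteCandidate:
    """A located structural candidate; ``[start, end)`` is the body, TSD excluded."""

    contig: str
    start: int
    end: int
    tsd: str
    tir_length: int
    tir_mismatches: int
    n_count: int = 0
    at_fraction: float = 0.0
    tsd_right: str | None = None
    sequence: str | None = field(default=None, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tsd_pair(self) -> tuple[str, str]:
        return self.tsd, self.tsd if self.tsd_right is None else self.tsd_right

    def key(self) -> tuple:
        return (self.contig, self.start, self.end, self.tsd,
                self.tir_length, self.tir_mismatches)


# ---------------------------------------------------------------------------
# raw enumeration
# ---------------------------------------------------------------------------

def _scan_contig_raw(arr: np.ndarray, cfg: PipelineConfig):
    """Enumerate all candidate tuples on one encoded contig.

    Returns int32 arrays (start, end, tir_len, tir_mm, tsd_len).
    """
    n = arr.size
    comp = complement_codes(arr)
    tmin, tmax = cfg.tir_min, cfg.tir_max
    kmin, kmax = cfg.tsd_min, cfg.tsd_max
    mm_max = cfg.max_tir_mismatch
    d_lo = 2 * tmin
    d_hi = min(cfg.max_element_len - 1, n - 2 * kmin)

    # sentinel-padded copies so flank windows never wrap and N never matches:
    # left flanks read from pad_a (N -> -2), right flanks from pad_b (N -> -3)
    pad = kmax
    pad_a = np.full(n + 2 * pad, -8, dtype=np.int8)
    pad_b = np.full(n + 2 * pad, -9, dtype=np.int8)
    pad_a[pad:pad + n] = arr
    pad_b[pad:pad + n] = arr
    pad_a[pad:pad + n][arr == 4] = -2
    pad_b[pad:pad + n][arr == 4] = -3
    koffs = np.arange(pad)

    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    tirs: list[np.ndarray] = []
    mms: list[np.ndarray] = []
    tsds: list[np.ndarray] = []

    for d in range(d_lo, d_hi + 1):
        s_lo = kmin
        s_hi = n - d - kmin  # inclusive; right TSD of kmin must fit
        if s_hi < s_lo:
            break
        width = s_hi - s_lo + 1

        # necessary TIR condition on the outermost tmin bases
        mm = np.zeros(width, dtype=np.int16)
        for j in range(tmin):
            a = arr[s_lo + j: s_lo + j + width]
            b = comp[s_lo + d - 1 - j: s_lo + d - 1 - j + width]
            mm += a != b
        seed = np.nonzero(mm <= mm_max)[0]
        if seed.size == 0:
            continue
        s0 = seed + s_lo

        # TSD: longest exact direct repeat with length in [kmin, kmax]
        # immediately flanking the body [s, s+d)
        left = pad_a[s0[:, None] + koffs]            # bases s-kmax .. s-1
        right = pad_b[(s0 + d)[:, None] + pad + koffs]  # bases s+d .. s+d+kmax-1
        best_k = np.zeros(s0.size, dtype=np.int16)
        for k in range(kmin, kmax + 1):
            match = (left[:, pad - k:] == right[:, :k]).all(axis=1)
            best_k[match] = k  # k ascending -> ends at the maximum
        has_tsd = best_k >= kmin
        if not has_tsd.any():
            continue
        s1 = s0[has_tsd]
        k1 = best_k[has_tsd]

        # maximal TIR length and its mismatch count
        t_cap = min(tmax, d // 2)
        cum = np.zeros(s1.size, dtype=np.int16)
        best_t = np.zeros(s1.size, dtype=np.int16)
        best_mm = np.zeros(s1.size, dtype=np.int16)
        right = s1 + d - 1
        for t in range(1, t_cap + 1):
            cum += arr[s1 + (t - 1)] != comp[right - (t - 1)]
            if t >= tmin:
                ok = cum <= mm_max
                best_t[ok] = t
                best_mm[ok] = cum[ok]
        keep = best_t >= tmin
        s2 = s1[keep]
        starts.append(s2.astype(np.int32))
        ends.append((s2 + d).astype(np.int32))
        tirs.append(best_t[keep].astype(np.int32))
        mms.append(best_mm[keep].astype(np.int32))
        tsds.append(k1[keep].astype(np.int32))

    if not starts:
        z = np.zeros(0, dtype=np.int32)
        return z, z, z, z, z
    return (np.concatenate(starts), np.concatenate(ends), np.concatenate(tirs),
            np.concatenate(mms), np.concatenate(tsds))


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def _best_per_group(group: np.ndarray, order_keys: tuple[np.ndarray, ...]) -> np.ndarray:
    """Indices of the best-priority row within each value of ``group``."""
    order = np.lexsort(order_keys + (group,))
    g = group[order]
    first = np.ones(g.size, dtype=bool)
    first[1:] = g[1:] != g[:-1]
    return order[first]


def _resolve_arrays(start, end, tir, mm, tsd) -> np.ndarray:
    """Deterministic overlap resolution; returns indices of accepted candidates."""
    idx = np.arange(start.size)
    strength = tir + tsd
    # stage 1: best per start
    keep = _best_per_group(start, (end, -tir, mm, -strength))
    idx, start, end, tir, mm, tsd, strength = (
        a[keep] for a in (idx, start, end, tir, mm, tsd, strength))
    # stage 2: best per end
    keep = _best_per_group(end, (start, -tir, mm, -strength))
    idx, start, end, tir, mm, tsd, strength = (
        a[keep] for a in (idx, start, end, tir, mm, tsd, strength))
    # stage 3: greedy NMS in priority order
    order = np.lexsort((end, start, -tir, mm, -strength))
    bucket_size = 1024
    buckets: dict[int, list[tuple[int, int]]] = {}
    accepted: list[int] = []
    s_o = start[order].tolist()
    e_o = end[order].tolist()
    for row, (s, e) in enumerate(zip(s_o, e_o)):
        span = e - s
        conflict = False
        for b in range(s // bucket_size, (e - 1) // bucket_size + 1):
            for (as_, ae) in buckets.get(b, ()):
                ov = min(e, ae) - max(s, as_)
                if ov > 0 and 5 * ov > 4 * max(span, ae - as_):
                    conflict = True
                    break
            if conflict:
                break
        if conflict:
            continue
        accepted.append(row)
        for b in range(s // bucket_size, (e - 1) // bucket_size + 1):
            buckets.setdefault(b, []).append((s, e))
    return idx[order[np.array(accepted, dtype=np.int64)]] if accepted else np.zeros(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def scan_genome(genome: GenomeSequence | Sequence[GenomeSequence],
                config: PipelineConfig | None = None,
                *, resolve_overlaps: bool = True) -> list[MiteCandidate]:
    """Scan contig(s) for TIR+TSD structural candidates.

    With ``resolve_overlaps=False`` the full raw enumeration is returned
    (useful for the monotonicity properties; it is huge on real-sized input).
    Output is sorted by (contig, start, end).
    """
    cfg = config or PipelineConfig()
    contigs = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    out: list[MiteCandidate] = []
    for contig in contigs:
        arr = encode(contig.residues)
        start, end, tir, mm, tsd = _scan_contig_raw(arr, cfg)
        if start.size and resolve_overlaps:
            sel = _resolve_arrays(start, end, tir, mm, tsd)
            start, end, tir, mm, tsd = (a[sel] for a in (start, end, tir, mm, tsd))
        out.extend(_materialize(contig, start, end, tir, mm, tsd))
    out.sort(key=lambda c: (c.contig, c.start, c.end))
    return out


def _materialize(contig: GenomeSequence, start, end, tir, mm, tsd
                 ) -> Iterable[MiteCandidate]:
    seq = contig.residues
    for s, e, t, m, k in zip(start.tolist(), end.tolist(), tir.tolist(),
                             mm.tolist(), tsd.tolist()):
        body = seq[s:e]
        yield MiteCandidate(
            contig=contig.id, start=s, end=e,
            tsd=seq[s - k:s], tir_length=t, tir_mismatches=m,
            n_count=body.count("N"), at_fraction=at_fraction(body),
            sequence=body,
        )


def filter_candidates(candidates: Iterable[MiteCandidate],
                      config: PipelineConfig | None = None,
                      log: dict | None = None) -> list[MiteCandidate]:
    """Apply the candidate quality filters.

    A candidate is retained iff its body contains at most ``max_candidate_n``
    (default 2) ``N`` residues and its two TSD copies are identical.  Attrition
    per rule is recorded in *log* when a dict is supplied.
    """
    cfg = config or PipelineConfig()
    kept: list[MiteCandidate] = []
    dropped_n = dropped_tsd = 0
    for c in candidates:
        left, right = c.tsd_pair
        if c.n_count > cfg.max_candidate_n:
            dropped_n += 1
        elif left != right:
            dropped_tsd += 1
        else:
            kept.append(c)
    if log is not None:
        log["dropped_n_filter"] = dropped_n
        log["dropped_tsd_mismatch"] = dropped_tsd
        log["kept"] = len(kept)
    return kept


def extract_element_sequences(genome: GenomeSequence | Sequence[GenomeSequence],
                              candidates: Iterable[MiteCandidate],
                              include_tsd: bool = False) -> list[tuple[str, str]]:
    """Extract candidate sequences as (id, sequence) FASTA-ready records.

    Ids encode the locus as ``contig:start-end``; with ``include_tsd`` the
    slice is extended by the TSD length on both sides.
    """
    contigs = {genome.id: genome} if isinstance(genome, GenomeSequence) else \
        {g.id: g for g in genome}
    records: list[tuple[str, str]] = []
    for c in candidates:
        if c.contig not in contigs:
            raise ValueError(f"candidate on unknown contig {c.contig!r}")
        seq = contigs[c.contig].residues
        pad = len(c.tsd) if include_tsd else 0
        lo, hi = c.start - pad, c.end + pad
        if lo < 0 or hi > len(seq):
            raise ValueError(
                f"candidate {c.contig}:{c.start}-{c.end} (pad {pad}) out of bounds"
            )
        records.append((f"{c.contig}:{c.start}-{c.end}", seq[lo:hi]))
    return records


def structure_at(contig: GenomeSequence, start: int, end: int,
                 config: PipelineConfig | None = None,
                 slop: int = 10, context: int = 40) -> MiteCandidate | None:
    """Re-detect TIR+TSD structure at a locus (used to flag mined copies intact).

    Scans a small window around ``[start, end)`` and returns the best local
    candidate whose boundaries fall within ``slop`` of the given interval,
    or None if the locus has no such structure.
    """
    cfg = config or PipelineConfig()
    lo = max(0, start - context)
    hi = min(len(contig), end + context)
    window = GenomeSequence(id=contig.id, residues=contig.residues[lo:hi])
    hits = []
    for c in scan_genome(window, cfg):
        cs, ce = c.start + lo, c.end + lo
        if abs(cs - start) <= slop and abs(ce - end) <= slop:
            hits.append((c, cs, ce))
    if not hits:
        return None
    best, cs, ce = min(
        hits, key=lambda h: (-(h[0].tir_length + len(h[0].tsd)),
                             h[0].tir_mismatches, -h[0].tir_length,
                             h[1], h[2]))
    return MiteCandidate(
        contig=contig.id, start=cs, end=ce, tsd=best.tsd,
        tir_length=best.tir_length, tir_mismatches=best.tir_mismatches,
        n_count=best.n_count, at_fraction=best.at_fraction,
        sequence=best.sequence,
    )
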