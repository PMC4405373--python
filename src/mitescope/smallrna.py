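"""Small-RNA mapping onto family consensi and density summaries.

Reads (16-30 nt) are aligned ungapped and end-to-end at every offset of every
consensus, on both strands; a read keeps all equal-best placements with at
most ``max_mismatch`` mismatches (default 2, the conventional short-read
setting).  ``N`` matches nothing.  Length histograms count each read once
regardless of multi-mapping; positional densities give multi-mapped reads
fractional weight so total density equals total mapped read length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._dna import revcomp

__all__ = [
    "ReadHit",
    "DensityProfile",
    "map_reads",
    "length_distribution",
    "positional_density",
]

MIN_READ_LEN = 16
MAX_READ_LEN = 30


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    family: str
    position: int  # 0-based on the consensus
    strand: str  # "sense" | "antisense"
    mismatches: int
    read_length: int


@dataclass
class DensityProfile:
    family: str
    sense: np.ndarray
    antisense: np.ndarray

    @property
    def total(self) -> float:
        return float(self.sense.sum() + self.antisense.sum())


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    # N (or anything unexpected) encodes as 4 and matches nothing because the
    # read side flips it to 5
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def map_reads(reads: Sequence[tuple[str, str]] | Sequence[dict],
              consensi: dict[str, str], max_mismatch: int = 2
              ) -> list[ReadHit]:
    """Map reads to consensi; returns all equal-best hits per read.

    *reads* are ``(id, sequence)`` tuples or dicts with ``id``/``seq`` keys.
    A read is reported only if its best placement has <= ``max_mismatch``
    mismatches, and then every placement tying that best count is returned
    (across all consensi and both strands).
    """
    pairs = [(r["id"], r["seq"]) if isinstance(r, dict) else tuple(r)
             for r in reads]
    for rid, seq in pairs:
        if not MIN_READ_LEN <= len(seq) <= MAX_READ_LEN:
            raise ValueError(f"read {rid!r}: length {len(seq)} outside "
                             f"{MIN_READ_LEN}-{MAX_READ_LEN} nt")

    # window matrices per (family, read length)
    windows: dict[tuple[str, int], np.ndarray] = {}
    enc = {name: _encode(seq) for name, seq in consensi.items()}

    def get_windows(name: str, length: int) -> np.ndarray | None:
        key = (name, length)
        if key not in windows:
            arr = enc[name]
            if arr.size < length:
                windows[key] = np.zeros((0, length), dtype=np.int8)
            else:
                windows[key] = np.lib.stride_tricks.sliding_window_view(
                    arr, length)
        return windows[key]

    # group identical sequences so each distinct sequence is aligned once
    by_seq: dict[str, list[str]] = defaultdict(list)
    for rid, seq in pairs:
        by_seq[seq].append(rid)

    hits: list[ReadHit] = []
    names = sorted(consensi)
    for seq, rids in sorted(by_seq.items()):
        length = len(seq)
        fwd = _encode(seq).astype(np.int8)
        fwd_probe = np.where(fwd == 4, 5, fwd)  # read N matches nothing
        rev_probe = _encode(revcomp(seq)).astype(np.int8)
        rev_probe = np.where(rev_probe == 4, 5, rev_probe)
        best = max_mismatch + 1
        placements: list[tuple[str, int, str, int]] = []
        for name in names:
            win = get_windows(name, length)
            if win.shape[0] == 0:
                continue
            for probe, strand in ((fwd_probe, "sense"), (rev_probe, "antisense")):
                mm = (win != probe[None, :]).sum(axis=1)
                lo = int(mm.min()) if mm.size else best
                if lo > best:
                    continue
                if lo < best:
                    best = lo
                    placements = []
                for pos in np.nonzero(mm == lo)[0].tolist():
                    placements.append((name, pos, strand, lo))
        if best <= max_mismatch:
            for rid in rids:
                for name, pos, strand, mmn in placements:
                    hits.append(ReadHit(read_id=rid, family=name, position=pos,
                                        strand=strand, mismatches=mmn,
                                        read_length=length))
    hits.sort(key=lambda h: (h.read_id, h.family, h.position, h.strand))
    return hits


def length_distribution(hits: Iterable[ReadHit]) -> dict[int, int]:
    """Reads per length (16-30 nt); each read id counted once."""
    seen: dict[str, int] = {}
    for h in hits:
        seen[h.read_id] = h.read_length
    out = {length: 0 for length in range(MIN_READ_LEN, MAX_READ_LEN + 1)}
    for length in seen.values():
        out[length] += 1
    return out


def positional_density(hits: Iterable[ReadHit], consensi: dict[str, str]
                       ) -> dict[str, DensityProfile]:
    """Per-position sense/antisense coverage, fractional for multi-mappers.

    Each read distributes weight 1/(number of placements) over the positions
    each placement covers, so summed density equals summed mapped read length.
    """
    hits = list(hits)
    multiplicity: dict[str, int] = defaultdict(int)
    for h in hits:
        multiplicity[h.read_id] += 1
    profiles = {name: DensityProfile(name, np.zeros(len(seq)), np.zeros(len(seq)))
                for name, seq in consensi.items()}
    for h in hits:
        prof = profiles[h.family]
        track = prof.sense if h.strand == "sense" else prof.antisense
        track[h.position:h.position + h.read_length] += 1.0 / multiplicity[h.read_id]
    return profiles
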