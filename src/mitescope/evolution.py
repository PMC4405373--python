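"""Family history: K2P divergence, burst detection, identity groups, NJ trees.

Pairwise distances use the Kimura 2-parameter model,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over comparable
sites (pairwise deletion of gap and N columns).  Family members are multiply
aligned with MAFFT before distances are taken (as divergence studies align
copies before handing them to a distance program); single pairs use a global
affine-gap aligner (match +1, mismatch -1, gap open -4, extend -1, free end
gaps).  The histogram of all pairwise distances within a family shows one
mode per amplification episode; peaks are local maxima whose prominence
reaches 10% of the pair count.  Trees are canonical Saitou-Nei neighbor
joining with deterministic tie-breaking.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from scipy.signal import find_peaks

from .core_io import write_fasta

__all__ = [
    "AlignedPair",
    "DistanceMatrix",
    "BurstProfile",
    "SaturatedDistanceError",
    "align_pair",
    "k2p_distance",
    "family_distance_matrix",
    "burst_histogram",
    "identity_groups",
    "nj_tree",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturatedDistanceError(ValueError):
    """Raised when substitution saturation puts the K2P log out of domain."""


@dataclass(frozen=True)
class AlignedPair:
    """Transition/transversion proportions of one aligned sequence pair."""

    p_transition: float
    q_transversion: float
    comparable_sites: int

    def __post_init__(self) -> None:
        if self.comparable_sites <= 0:
            raise ValueError("no comparable sites (all columns gapped or N)")
        if self.p_transition < 0 or self.q_transversion < 0:
            raise ValueError("proportions must be non-negative")
        if self.p_transition + self.q_transversion > 1 + 1e-12:
            raise ValueError("P + Q cannot exceed 1")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray
    saturated_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def condensed(self) -> np.ndarray:
        """Finite upper-triangle entries."""
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.d[iu]
        return vals[np.isfinite(vals)]


@dataclass(frozen=True)
class BurstProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: tuple[tuple[float, float], ...]  # (bin center, prominence)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# pairwise alignment and K2P
# ---------------------------------------------------------------------------

def _make_distance_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    try:  # attribute names changed across Biopython releases
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner

_DIST_ALIGNER = _make_distance_aligner()


def align_pair(a: str, b: str) -> AlignedPair:
    """Globally align two sequences and tally P/Q over comparable sites.

    Alignment is global with affine gaps (match +1, mismatch -1, open -4,
    extend -1, free end gaps); gap and N columns are excluded pairwise.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if a == b:
        comparable = sum(ch != "N" for ch in a)
        if comparable == 0:
            raise ValueError("no comparable sites (all columns gapped or N)")
        return AlignedPair(0.0, 0.0, comparable)
    aln = _DIST_ALIGNER.align(a, b)[0]
    return pair_from_alignment(str(aln[0]), str(aln[1]))


def pair_from_alignment(row_a: str, row_b: str) -> AlignedPair:
    """Tally an explicit pair of aligned rows (equal length, ``-`` for gaps)."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    comparable = transitions = transversions = 0
    for x, y in zip(row_a, row_b):
        if x in "-N" or y in "-N":
            continue
        comparable += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    return AlignedPair(transitions / comparable if comparable else 0.0,
                       transversions / comparable if comparable else 0.0,
                       comparable)


def k2p_distance(pair: AlignedPair) -> float:
    """Kimura 2-parameter distance; raises ``SaturatedDistanceError`` when the
    observed proportions exceed the model's domain."""
    P, Q = pair.p_transition, pair.q_transversion
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} outside the K2P domain")
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def k2p_from_sequences(a: str, b: str) -> float:
    return k2p_distance(align_pair(a, b))


# ---------------------------------------------------------------------------
# family distance matrix
# ---------------------------------------------------------------------------

def mafft_msa(sequences: Sequence[str]) -> list[str]:
    """Multiple alignment of family members via the MAFFT CLI (FFT-NS-2)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH; required for family MSAs")
    with tempfile.TemporaryDirectory(prefix="mitescope_msa_") as tmp:
        path = Path(tmp) / "members.fa"
        write_fasta([(f"m{i}", s) for i, s in enumerate(sequences)], path)
        proc = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", "--maxiterate", "0", str(path)],
            check=True, capture_output=True, text=True)
    rows: dict[str, list[str]] = {}
    name = ""
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            rows[name] = []
        elif line:
            rows[name].append(line)
    return ["".join(rows[f"m{i}"]).upper() for i in range(len(sequences))]


def family_distance_matrix(sequences: Sequence[str],
                           ids: Sequence[str] | None = None) -> DistanceMatrix:
    """All-pairs K2P distances for one family.

    Members are multiply aligned with MAFFT, then P/Q are tallied per pair
    with pairwise deletion of gap/N columns.  Saturated pairs are recorded
    separately and stored as NaN; if every pair is saturated a
    :class:`SaturatedDistanceError` is raised.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    names = tuple(ids) if ids is not None else tuple(
        f"seq_{i + 1}" for i in range(len(seqs)))
    if len(names) != len(seqs):
        raise ValueError("ids length mismatch")
    rows = seqs if len({len(s) for s in seqs}) == 1 and all(
        "-" not in s for s in seqs) and _ungapped_ok(seqs) else mafft_msa(seqs)

    lut = np.full(256, -1, dtype=np.int8)  # A0 G1 C2 T3; gap/N stay -1
    for ch, v in zip("AGCT", range(4)):
        lut[ord(ch)] = v
    mat = np.stack([lut[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows])
    valid = mat >= 0
    purine = (mat == 0) | (mat == 1)

    n = len(seqs)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    ok = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                d[i, j] = d[j, i] = np.nan
                saturated.append((names[i], names[j]))
                continue
            diff = both & (mat[i] != mat[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            try:
                dist = k2p_distance(AlignedPair(ts / comparable, tv / comparable,
                                                comparable))
                ok += 1
            except SaturatedDistanceError:
                dist = np.nan
                saturated.append((names[i], names[j]))
            d[i, j] = d[j, i] = dist
    if ok == 0:
        raise SaturatedDistanceError("all pairs saturated")
    if saturated:
        warnings.warn(f"{len(saturated)} saturated pair(s) excluded from the "
                      "distance matrix", stacklevel=2)
    return DistanceMatrix(ids=names, d=d, saturated_pairs=tuple(saturated))


def _ungapped_ok(seqs: list[str]) -> bool:
    """Equal-length members skip the MSA only when no pair prefers a gapped
    alignment over the columnwise one (checked on the affine aligner's score
    for the most divergent-looking pair)."""
    ref = seqs[0]
    worst = max(seqs[1:], key=lambda s: sum(x != y for x, y in zip(ref, s)))
    mismatches = sum(x != y for x, y in zip(ref, worst))
    score = _DIST_ALIGNER.score(ref, worst)
    return score <= len(ref) - 2 * mismatches


# ---------------------------------------------------------------------------
# burst histogram
# ---------------------------------------------------------------------------

def burst_histogram(matrix: DistanceMatrix | np.ndarray,
                    bin_width: float = 0.02,
                    prominence_fraction: float = 0.10) -> BurstProfile:
    """Histogram of pairwise distances with amplification-burst peaks.

    Peaks are local maxima of the binned counts (zero-padded, so boundary
    modes count) with prominence >= ``prominence_fraction`` of the total pair
    count; the number of peaks is read as the number of amplification rounds.
    """
    if isinstance(matrix, DistanceMatrix):
        values = matrix.condensed()
    else:
        values = np.asarray(matrix, dtype=float)
        values = values[np.isfinite(values)]
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    hi = max(values.max() if values.size else 0.0, bin_width)
    n_bins = int(np.ceil(hi / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    padded = np.concatenate([[0], counts, [0]]).astype(float)
    threshold = prominence_fraction * max(values.size, 1)
    idx, props = find_peaks(padded, prominence=threshold)
    centers = [(edges[i - 1] + edges[i]) / 2 for i in idx]
    peaks = tuple((float(c), float(p))
                  for c, p in zip(centers, props["prominences"]))
    return BurstProfile(bin_edges=edges, counts=counts, peaks=peaks)


# ---------------------------------------------------------------------------
# identity groups
# ---------------------------------------------------------------------------

def identity_groups(sequences: Sequence[str]) -> list[list[int]]:
    """Partition indices by exact sequence equality.

    Groups are ordered by descending size, ties by first occurrence; members
    keep input order.
    """
    seen: dict[str, list[int]] = {}
    for i, s in enumerate(sequences):
        seen.setdefault(s, []).append(i)
    return sorted(seen.values(), key=lambda g: (-len(g), g[0]))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: str | None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick(self) -> str:
        return self._fmt() + ";"

    def _fmt(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{child._fmt()}:{blen:.10g}"
                         for child, blen in self.children)
        return f"({inner})"


def nj_tree(matrix: DistanceMatrix) -> str:
    """Canonical Saitou-Nei neighbor joining; returns a newick string.

    Ties in the Q criterion break toward the lowest index pair; negative
    branch lengths are clamped to zero with the deficit moved to the sister
    edge.  The result is unrooted (trifurcating root for >= 3 taxa).
    """
    d = np.array(matrix.d, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: list[_Node] = [_Node(label=name) for name in matrix.ids]
    if n == 2:
        half = d[0, 1] / 2.0
        root = _Node(None, [(nodes[0], half), (nodes[1], half)])
        return root.newick()

    active = list(range(n))
    dist = d.copy()
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = dist[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = _Node(None, [(nodes[i], li), (nodes[j], lj)])
        new_dists = 0.5 * (dist[i, active] + dist[j, active] - dij)
        grown = np.zeros((dist.shape[0] + 1, dist.shape[0] + 1))
        grown[:-1, :-1] = dist
        for k_loc, k in enumerate(active):
            grown[-1, k] = grown[k, -1] = new_dists[k_loc]
        dist = grown
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [dist.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return root.newick()


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj
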