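"""Family building: clustering, consensus, remnant mining, classification.

Candidates are clustered into families by single-linkage over pairwise
sequence identity (>= 90% by default), mirroring all-vs-all homology grouping;
families with fewer than three members are discarded.  Each family gets a
majority-rule consensus, which is then used to mine degraded (remnant) copies
genome-wide with a local-alignment search; hits are kept at identity >= 0.90
and consensus coverage >= 0.80.  Superfamilies are assigned from the TSD/TIR
signature and families are named ``NxY#`` (x = species letter, Y = superfamily
code, # = rank by copy number).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import networkx as nx
import numpy as np
from Bio import Align

from .core_io import GenomeSequence, PipelineConfig, write_fasta
from .scanner import MiteCandidate, structure_at

__all__ = [
    "MiteCopy",
    "MiteFamily",
    "pairwise_identity",
    "filter_by_repeat_evidence",
    "cluster_families",
    "build_consensus",
    "mine_remnants",
    "classify_superfamily",
    "name_families",
]

SUPERFAMILY_CODES = {
    "Stowaway-like": "S",
    "Tourist-like": "T",
    "hAT-like": "h",
    "Merlin-like": "Me",
    "Mutator-like": "Mu",
    "Unknown": "N",
}


@dataclass(frozen=True)
class MiteCopy:
    """One genomic copy of a family; intact copies retain TIR+TSD structure."""

    contig: str
    start: int
    end: int
    intact: bool
    identity_to_consensus: float = 1.0
    coverage_of_consensus: float = 1.0
    sequence: str | None = field(default=None, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MiteFamily:
    """A clustered MITE family with consensus and classification."""

    members: list[MiteCandidate]
    consensus: str = ""
    copies: list[MiteCopy] = field(default_factory=list)
    superfamily: str = "Unknown"
    tsd_pattern: str = ""
    tir_length: int = 0
    tgt_start: bool = False
    name: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_copies(self) -> int:
        return len(self.copies) if self.copies else len(self.members)

    @property
    def n_intact(self) -> int:
        if self.copies:
            return sum(c.intact for c in self.copies)
        return len(self.members)

    @property
    def total_bp(self) -> int:
        if self.copies:
            return sum(c.length for c in self.copies)
        return sum(m.length for m in self.members)


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    try:  # attribute names changed across Biopython releases
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner

_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Global alignment with free end gaps (match +1, mismatch -1, gap -2).

    Returns ``(identity, coverage)``: identity is matches over aligned columns
    excluding terminal gap columns; coverage is the aligned span of the
    shorter sequence over its length.  ``N`` matches nothing.
    """
    identity, coverage, _ = aligned_identity(a, b)
    return identity, coverage


def aligned_identity(a: str, b: str) -> tuple[float, float, int]:
    """Like :func:`pairwise_identity` but also returns the core column count."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0, 0
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_cols += a1 - a0
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y and x != "N":
                matches += 1
    a_span = int(blocks_a[-1][1] - blocks_a[0][0])
    b_span = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = aligned_cols + (a_span - aligned_cols) + (b_span - aligned_cols)
    short_span, short_len = (a_span, len(a)) if len(a) <= len(b) else (b_span, len(b))
    identity = matches / columns if columns else 0.0
    coverage = short_span / short_len
    return identity, coverage, columns


def alignment_score(a: str, b: str) -> float:
    """Optimal score under the module's scoring scheme (for cross-checks)."""
    return float(_ALIGNER.score(a, b))


# ---------------------------------------------------------------------------
# repeat-evidence prefilter
# ---------------------------------------------------------------------------

def filter_by_repeat_evidence(candidates: Sequence[MiteCandidate],
                              genome: Sequence[GenomeSequence] | GenomeSequence,
                              k: int = 16, collapse: bool = True,
                              log: dict | None = None) -> list[MiteCandidate]:
    """Keep the candidate parses best supported by multi-copy evidence.

    A genuine MITE exists in several near-identical copies, so most of its
    body ``k``-mers recur elsewhere in the genome, while chance structural
    parses of unique sequence have essentially none.  Each candidate is scored
    ``repeated k-mers - unique k-mers``: the score is maximal for the parse
    whose span coincides with the repeated unit (sub-parses lose repeated
    k-mers, over-extended parses pay for the unique flanks they drag in).
    Candidates with non-positive scores are dropped; with ``collapse`` (the
    default), overlapping parses of one locus (>50% of the shorter span) are
    then collapsed onto the best-scoring one.  This stands in for the
    multi-copy requirement of de novo repeat finders and keeps the downstream
    all-vs-all clustering tractable.
    """
    contigs = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    counts: Counter = Counter()
    for c in contigs:
        codes, tally = np.unique(_kmer_codes(c.residues, k), return_counts=True)
        for code, t in zip(codes.tolist(), tally.tolist()):
            counts[code] += t
    scored: list[tuple[float, MiteCandidate]] = []
    for cand in candidates:
        seq = cand.sequence
        if seq is None or len(seq) < k:
            continue
        codes = _kmer_codes(seq, k)
        if not codes.size:
            continue
        repeated = sum(counts[int(x)] >= 2 for x in codes)
        score = 2 * repeated - codes.size
        if score > 0:
            scored.append((score, cand))
    if not collapse:
        kept = [c for _, c in scored]
    else:
        kept = []
        accepted: dict[str, list[tuple[int, int]]] = defaultdict(list)
        order = sorted(range(len(scored)),
                       key=lambda i: (-scored[i][0],
                                      -(scored[i][1].tir_length + len(scored[i][1].tsd)),
                                      scored[i][1].contig, scored[i][1].start))
        for i in order:
            cand = scored[i][1]
            span = cand.length
            conflict = any(
                min(cand.end, e) - max(cand.start, s) > 0 and
                2 * (min(cand.end, e) - max(cand.start, s)) > min(span, e - s)
                for s, e in accepted[cand.contig])
            if not conflict:
                accepted[cand.contig].append((cand.start, cand.end))
                kept.append(cand)
        kept.sort(key=lambda c: (c.contig, c.start))
    if log is not None:
        log["repeat_evidence_in"] = len(candidates)
        log["repeat_evidence_kept"] = len(kept)
    return kept


_KMER_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _KMER_LUT[ord(_b)] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed k-mer codes; windows containing N are dropped."""
    codes = _KMER_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j:j + n]
        out = (out << 2) | np.where(col >= 0, col, 0)
        valid &= col >= 0
    return out[valid]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_families(candidates: Sequence[MiteCandidate],
                     identity_threshold: float = 0.90,
                     min_family_size: int = 3,
                     config: PipelineConfig | None = None,
                     log: dict | None = None) -> list[MiteFamily]:
    """Single-linkage clustering of candidates at >= ``identity_threshold``.

    An edge additionally requires the shorter sequence to be covered at
    >= ``min_edge_coverage`` and an aligned core of >= ``min_edge_columns``
    columns (so trivially short overlaps cannot chain unrelated families).
    Components smaller than ``min_family_size`` are discarded and logged.
    Within each family, redundant overlapping parses of the same locus are
    collapsed onto the strongest one.
    """
    cfg = config or PipelineConfig()
    seqs = [c.sequence or "" for c in candidates]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(candidates)))
    for i, j in _candidate_pairs(seqs):
        ident, cov, cols = aligned_identity(seqs[i], seqs[j])
        if (ident >= identity_threshold and cov >= cfg.min_edge_coverage
                and cols >= cfg.min_edge_columns):
            graph.add_edge(i, j)

    families: list[MiteFamily] = []
    discarded = 0
    components = sorted(nx.connected_components(graph),
                        key=lambda comp: (-len(comp), min(comp)))
    for comp in components:
        members = [candidates[i] for i in sorted(comp)]
        members = _dedupe_members(members)
        if len(members) < min_family_size:
            discarded += 1
            continue
        families.append(MiteFamily(members=members))
    if log is not None:
        log["clustered_candidates"] = len(candidates)
        log["families"] = len(families)
        log["discarded_small_components"] = discarded
    return families


def _candidate_pairs(seqs: list[str], k: int = 10, min_shared: int = 3,
                     screen_frac: float = 0.35) -> Iterable[tuple[int, int]]:
    """Candidate edge generation: shared-k-mer index then a fast edit-distance
    screen; only surviving pairs reach the exact aligner."""
    index: dict[int, list[int]] = defaultdict(list)
    kmer_sets: list[set[int]] = []
    for i, s in enumerate(seqs):
        ks = set(_kmer_codes(s, k).tolist()) if len(s) >= k else set()
        kmer_sets.append(ks)
        for code in ks:
            index[code].append(i)
    shared: Counter = Counter()
    for members in index.values():
        if len(members) < 2 or len(members) > 200:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                shared[(members[a], members[b])] += 1
    short = [i for i, s in enumerate(seqs) if len(s) < 3 * k]
    pairs = {p for p, n in shared.items() if n >= min_shared}
    for i in short:  # too short for reliable k-mer evidence: screen all pairs
        for j in range(len(seqs)):
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    for i, j in sorted(pairs):
        a, b = seqs[i], seqs[j]
        if not a or not b:
            continue
        query, target = (a, b) if len(a) <= len(b) else (b, a)
        res = edlib.align(query, target, mode="HW", task="distance",
                          k=max(1, int(screen_frac * len(query))))
        if res["editDistance"] != -1:
            yield i, j


def _dedupe_members(members: list[MiteCandidate]) -> list[MiteCandidate]:
    """Drop members overlapping a stronger member by more than half the
    shorter span (redundant alternative parses of one locus)."""
    ranked = sorted(members, key=lambda c: (-(c.tir_length + len(c.tsd)),
                                            c.tir_mismatches, c.start, c.end))
    kept: list[MiteCandidate] = []
    for c in ranked:
        redundant = False
        for other in kept:
            if other.contig != c.contig:
                continue
            ov = min(c.end, other.end) - max(c.start, other.start)
            if ov > 0 and 2 * ov > min(c.length, other.length):
                redundant = True
                break
        if not redundant:
            kept.append(c)
    kept.sort(key=lambda c: (c.contig, c.start))
    return kept


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def build_consensus(family: MiteFamily | Sequence[MiteCandidate]) -> str:
    """Center-star majority consensus of family member sequences.

    The star is the member sharing the most 10-mers with the others (ties:
    longer, then first).  Every member is aligned to the star and its residues
    are projected onto star columns; each column takes the majority residue
    (ties resolved alphabetically, gaps last); majority-gap columns are
    dropped.  Deterministic by construction.
    """
    members = family.members if isinstance(family, MiteFamily) else list(family)
    seqs = [m.sequence or "" for m in members]
    if not seqs or any(not s for s in seqs):
        raise ValueError("consensus requires at least one non-empty member")
    if len(seqs) == 1:
        return seqs[0]
    kmer_sets = [set(_kmer_codes(s, 10).tolist()) for s in seqs]
    scores = []
    for i, ks in enumerate(kmer_sets):
        total = sum(len(ks & other) for j, other in enumerate(kmer_sets) if j != i)
        scores.append((-total, -len(seqs[i]), i))
    star = min(scores)[2]
    star_seq = seqs[star]

    profile = [Counter() for _ in star_seq]
    for i, s in enumerate(seqs):
        if i == star:
            for pos, ch in enumerate(star_seq):
                profile[pos][ch] += 1
            continue
        aln = _ALIGNER.align(star_seq, s)[0]
        covered = np.full(len(star_seq), -1, dtype=np.int64)
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            covered[a0:a1] = np.arange(b0, b1)
        for pos, qpos in enumerate(covered.tolist()):
            profile[pos][s[qpos] if qpos >= 0 else "-"] += 1

    order = {ch: i for i, ch in enumerate("ACGTN-")}
    out = []
    for counter in profile:
        best = min(counter.items(), key=lambda kv: (-kv[1], order[kv[0]]))[0]
        if best != "-":
            out.append(best)
    return "".join(out)


# ---------------------------------------------------------------------------
# remnant mining (local alignment via blastn)
# ---------------------------------------------------------------------------

def mine_remnants(consensus: str,
                  genome: GenomeSequence | Sequence[GenomeSequence],
                  remnant_identity: float = 0.90,
                  remnant_coverage: float = 0.80,
                  config: PipelineConfig | None = None) -> list[MiteCopy]:
    """Genome-wide local-alignment search of a family consensus.

    Hits are retained iff nucleotide identity >= ``remnant_identity`` and
    consensus (query) coverage >= ``remnant_coverage``; overlapping hits are
    merged keeping the higher-identity one.  A hit is flagged intact when it
    is full-length (coverage >= 0.95) and TIR+TSD structure is re-detected at
    the locus; anything else is a fragment copy.
    """
    copies = mine_remnants_batch({"consensus": consensus}, genome,
                                 remnant_identity, remnant_coverage, config)
    return copies.get("consensus", [])


def mine_remnants_batch(consensi: dict[str, str],
                        genome: GenomeSequence | Sequence[GenomeSequence],
                        remnant_identity: float = 0.90,
                        remnant_coverage: float = 0.80,
                        config: PipelineConfig | None = None,
                        ) -> dict[str, list[MiteCopy]]:
    """Mine several consensi against one genome with a shared search database."""
    cfg = config or PipelineConfig()
    contigs = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    by_id = {c.id: c for c in contigs}
    for name, seq in consensi.items():
        if not seq:
            raise ValueError(f"empty consensus {name!r}")
    hits = _blastn_hits(consensi, contigs)

    out: dict[str, list[MiteCopy]] = {name: [] for name in consensi}
    for name, rows in hits.items():
        qlen = len(consensi[name])
        kept = []
        for pident, length, sstart, send, sseqid, qstart, qend in rows:
            identity = pident / 100.0
            coverage = (qend - qstart + 1) / qlen
            if identity >= remnant_identity and coverage >= remnant_coverage:
                lo, hi = (sstart, send) if sstart <= send else (send, sstart)
                kept.append((identity, coverage, sseqid, lo - 1, hi))
        kept.sort(key=lambda h: (-h[0], -h[1], h[2], h[3]))
        chosen: list[tuple[float, float, str, int, int]] = []
        for hit in kept:
            _, _, sid, lo, hi = hit
            if any(sid == c[2] and min(hi, c[4]) - max(lo, c[3]) > 0
                   and 2 * (min(hi, c[4]) - max(lo, c[3])) > min(hi - lo, c[4] - c[3])
                   for c in chosen):
                continue
            chosen.append(hit)
        for identity, coverage, sid, lo, hi in sorted(chosen, key=lambda h: (h[2], h[3])):
            contig = by_id[sid]
            cand = structure_at(contig, lo, hi, cfg) if coverage >= 0.95 else None
            if cand is not None:
                lo, hi = cand.start, cand.end
            out[name].append(MiteCopy(
                contig=sid, start=lo, end=hi, intact=cand is not None,
                identity_to_consensus=identity, coverage_of_consensus=coverage,
                sequence=contig.residues[lo:hi],
            ))
    return out


def _blastn_hits(consensi: dict[str, str], contigs: list[GenomeSequence]
                 ) -> dict[str, list[tuple]]:
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastn/makeblastdb not found on PATH; remnant "
                           "mining requires the NCBI BLAST+ suite")
    with tempfile.TemporaryDirectory(prefix="mitescope_blast_") as tmp:
        tmp = Path(tmp)
        write_fasta(contigs, tmp / "genome.fa")
        write_fasta(sorted(consensi.items()), tmp / "query.fa")
        subprocess.run(
            ["makeblastdb", "-in", str(tmp / "genome.fa"), "-dbtype", "nucl",
             "-out", str(tmp / "db")],
            check=True, capture_output=True)
        proc = subprocess.run(
            ["blastn", "-query", str(tmp / "query.fa"), "-db", str(tmp / "db"),
             "-dust", "no", "-evalue", "1e-5", "-word_size", "11",
             "-perc_identity", "85",
             "-outfmt", "6 qseqid pident length sstart send sseqid qstart qend"],
            check=True, capture_output=True, text=True)
    hits: dict[str, list[tuple]] = defaultdict(list)
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        hits[f[0]].append((float(f[1]), int(f[2]), int(f[3]), int(f[4]),
                           f[5], int(f[6]), int(f[7])))
    return hits


# ---------------------------------------------------------------------------
# classification and naming
# ---------------------------------------------------------------------------

def classify_superfamily(tsd_pattern: str | int, tir_length: int,
                         tir_sequence: str = "") -> tuple[str, bool]:
    """Assign a superfamily from the TSD/TIR signature.

    TA -> Stowaway-like; 3 bp -> Tourist-like; 8 bp with TIR 24-34 bp ->
    Merlin-like, otherwise hAT-like; 10 bp -> Mutator-like; anything else is
    Unknown.  The second return value flags the recurrent novel signature of a
    5-6 bp TSD with a TIR beginning ``TGT``.
    """
    if isinstance(tsd_pattern, str):
        tsd_len = len(tsd_pattern)
        is_ta = tsd_pattern.upper() == "TA"
    else:
        tsd_len = int(tsd_pattern)
        is_ta = False
    tgt = tsd_len in (5, 6) and tir_sequence.upper().startswith("TGT")
    if is_ta:
        return "Stowaway-like", tgt
    if tsd_len == 3:
        return "Tourist-like", tgt
    if tsd_len == 8:
        if 24 <= tir_length <= 34:
            return "Merlin-like", tgt
        return "hAT-like", tgt
    if tsd_len == 10:
        return "Mutator-like", tgt
    return "Unknown", tgt


def classify_family(family: MiteFamily) -> MiteFamily:
    """Derive TSD pattern / TIR length from members and set the superfamily."""
    tsds = Counter(m.tsd for m in family.members)
    modal_tsd, modal_n = tsds.most_common(1)[0]
    if modal_tsd.upper() == "TA" and modal_n * 2 >= len(family.members):
        pattern: str | int = "TA"
    else:
        lengths = Counter(len(m.tsd) for m in family.members)
        pattern = lengths.most_common(1)[0][0]
    tir_len = int(np.median([m.tir_length for m in family.members]))
    tir_seq = (family.consensus or family.members[0].sequence or "")[:max(tir_len, 3)]
    label, tgt = classify_superfamily(pattern, tir_len, tir_seq)
    family.superfamily = label
    family.tgt_start = tgt
    family.tsd_pattern = pattern if isinstance(pattern, str) else f"{pattern}bp"
    family.tir_length = tir_len
    return family


def name_families(families: Sequence[MiteFamily], species_letter: str
                  ) -> list[MiteFamily]:
    """Assign ``N<x><Y><#>`` names, numbering within (species, superfamily)
    by descending copy number, then discovery order."""
    if not species_letter:
        raise ValueError("species letter required")
    counters: dict[str, int] = defaultdict(int)
    order = sorted(range(len(families)),
                   key=lambda i: (-families[i].n_copies, i))
    for i in order:
        fam = families[i]
        code = SUPERFAMILY_CODES[fam.superfamily]
        counters[code] += 1
        fam.name = f"N{species_letter}{code}{counters[code]}"
    return list(families)
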