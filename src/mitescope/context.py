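"""Genomic context analyses: gene association, insertion-bias null, TIS
re-annotation, reciprocal best hits and insertion-polymorphism candidates.

An element is *gene-associated* when its span intersects a CDS extended by a
flank (300/200/100/0 bp are the standard settings).  Whether association is
enriched or depleted is judged against a Monte-Carlo null that replaces the
observed elements with length-matched intervals placed uniformly at random
without overlap, followed by a Pearson chi-square contingency test (no
continuity correction).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from ._dna import at_fraction, revcomp
from .core_io import GeneModel, GenomeSequence

__all__ = [
    "AssociationResult",
    "MipCandidate",
    "associate_with_genes",
    "simulate_association_null",
    "chi_square_bias_test",
    "association_analysis",
    "reannotate_tis",
    "reciprocal_best_hits",
    "find_mip_candidates",
]


@dataclass(frozen=True)
class AssociationResult:
    flank_bp: int
    n_elements: int
    n_associated: int
    null_mean_fraction: float = float("nan")
    null_replicates: int = 0
    chi_square: float = float("nan")
    p_value: float = float("nan")

    @property
    def fraction(self) -> float:
        return self.n_associated / self.n_elements if self.n_elements else 0.0


@dataclass(frozen=True)
class MipCandidate:
    """A syntenic locus with a MITE in one species' gene flank but not the
    other's — an in-silico insertion-polymorphism candidate."""

    gene_a: str
    gene_b: str
    contig_a: str
    region_a: tuple[int, int]
    contig_b: str
    region_b: tuple[int, int]
    collinear_neighbors: int


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def _merged_windows(genes: Iterable[GeneModel], flank_bp: int
                    ) -> dict[str, tuple[list[int], list[int]]]:
    windows: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        windows.setdefault(g.contig_id, []).append(
            (max(0, g.cds_start - flank_bp), g.cds_end + flank_bp))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for contig, spans in windows.items():
        spans.sort()
        out: list[list[int]] = []
        for lo, hi in spans:
            if out and lo <= out[-1][1]:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[contig] = ([s for s, _ in out], [e for _, e in out])
    return merged


def _count_hits(intervals: Sequence[tuple[str, int, int]],
                windows: dict[str, tuple[list[int], list[int]]]) -> int:
    hits = 0
    for contig, start, end in intervals:
        if contig not in windows:
            continue
        starts, ends = windows[contig]
        # windows are merged/disjoint: only the last window starting before
        # `end` can overlap the element
        i = bisect_right(starts, end - 1) - 1
        if i >= 0 and ends[i] > start:
            hits += 1
    return hits


def associate_with_genes(elements: Sequence, genes: Sequence[GeneModel],
                         flank_bp: int) -> AssociationResult:
    """Count elements whose span intersects any flank-extended CDS window."""
    intervals = [(getattr(e, "contig", None) or e.contig_id, e.start, e.end)
                 for e in elements]
    windows = _merged_windows(genes, flank_bp)
    return AssociationResult(flank_bp=flank_bp, n_elements=len(intervals),
                             n_associated=_count_hits(intervals, windows))


def simulate_association_null(genome: Sequence[GenomeSequence],
                              genes: Sequence[GeneModel],
                              element_lengths: Sequence[int], flank_bp: int,
                              replicates: int, seed: int) -> np.ndarray:
    """Null distribution of the associated fraction.

    Per replicate, intervals with the observed length spectrum are placed
    uniformly at random on the genome without mutual overlap and their
    associated fraction is recorded.  Deterministic under *seed*.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    contigs = list(genome)
    lengths = np.asarray(element_lengths, dtype=int)
    if lengths.size and lengths.max() > max(len(c) for c in contigs):
        raise ValueError("an element is longer than every contig")
    windows = _merged_windows(genes, flank_bp)
    sizes = np.array([len(c) for c in contigs], dtype=float)
    probs = sizes / sizes.sum()
    rng = np.random.default_rng(seed)

    fractions = np.empty(replicates)
    for rep in range(replicates):
        placed: dict[str, list[tuple[int, int]]] = {c.id: [] for c in contigs}
        intervals: list[tuple[str, int, int]] = []
        for ln in lengths.tolist():
            ok = False
            for _ in range(1000):
                ci = int(rng.choice(len(contigs), p=probs))
                contig = contigs[ci]
                if len(contig) < ln:
                    continue
                start = int(rng.integers(0, len(contig) - ln + 1))
                end = start + ln
                if any(start < e and s < end for s, e in placed[contig.id]):
                    continue
                placed[contig.id].append((start, end))
                intervals.append((contig.id, start, end))
                ok = True
                break
            if not ok:
                raise RuntimeError("random placement infeasible: genome too "
                                   "crowded for the requested elements")
        fractions[rep] = (_count_hits(intervals, windows) / len(intervals)
                          if intervals else 0.0)
    return fractions


def chi_square_bias_test(observed, expected) -> tuple[float, int, float]:
    """Pearson chi-square over a 2-way table, no continuity correction.

    Returns ``(statistic, df, p)`` with ``df = (r-1)(c-1)`` and the p-value
    from the upper tail.  Zero expected cells raise a ValueError advising
    pooling.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    exp = np.atleast_2d(np.asarray(expected, dtype=float))
    if obs.shape != exp.shape:
        raise ValueError("observed and expected shapes differ")
    if (exp <= 0).any():
        raise ValueError("expected count of zero; pool sparse categories "
                         "before testing")
    stat = float(((obs - exp) ** 2 / exp).sum())
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    if df == 0:
        raise ValueError("degenerate table (single row or column)")
    return stat, df, float(stats.chi2.sf(stat, df))


def association_analysis(elements: Sequence, genome: Sequence[GenomeSequence],
                         genes: Sequence[GeneModel], flank_bp: int,
                         replicates: int, seed: int) -> AssociationResult:
    """Observed association plus Monte-Carlo control and chi-square verdict.

    The control row of the contingency table uses the mean null fraction over
    *replicates* random placements.
    """
    obs = associate_with_genes(elements, genes, flank_bp)
    if obs.n_elements == 0:
        return obs
    lengths = [e.end - e.start for e in elements]
    null = simulate_association_null(genome, genes, lengths, flank_bp,
                                     replicates, seed)
    null_mean = float(null.mean())
    exp_assoc = max(null_mean * obs.n_elements, 1e-9)
    table_obs = [[obs.n_associated, obs.n_elements - obs.n_associated]]
    table_exp = [[exp_assoc, obs.n_elements - exp_assoc]]
    # 2x2 sample-vs-control contingency: second row is the null expectation
    observed2 = np.array(table_obs + table_exp)
    margins_exp = _expected_from_margins(observed2)
    stat, df, p = chi_square_bias_test(observed2, margins_exp)
    return AssociationResult(
        flank_bp=flank_bp, n_elements=obs.n_elements,
        n_associated=obs.n_associated, null_mean_fraction=null_mean,
        null_replicates=replicates, chi_square=stat, p_value=p)


def _expected_from_margins(table: np.ndarray) -> np.ndarray:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows @ cols / table.sum()


# ---------------------------------------------------------------------------
# TIS re-annotation
# ---------------------------------------------------------------------------

def reannotate_tis(genes: Sequence[GeneModel], genome: Sequence[GenomeSequence],
                   window: int = 30, motif_window: int = 10,
                   at_threshold: float = 0.80,
                   log: list | None = None) -> list[GeneModel]:
    """Revise start codons using promoter-proximal motif evidence.

    For each gene the 30 nt up- and downstream of the annotated ATG are
    scanned for in-frame candidate ATGs.  A candidate is supported when a
    CCC-like (``CCN``/``NCC``) or GGG-like (``GGN``/``NGG``) motif occurs in
    the 10 nt immediately upstream AND the 30 nt upstream of the candidate is
    AT-rich (> 0.80).  Candidates are examined by increasing distance, the
    current start first, so a supported annotation is left untouched and the
    operation is idempotent.  Genes whose annotated start is not ATG are
    skipped with a log entry.
    """
    by_id = {c.id: c for c in genome}
    revised: list[GeneModel] = []
    for gene in genes:
        contig = by_id[gene.contig_id]
        offset = _revised_offset(gene, contig, window, motif_window,
                                 at_threshold)
        if offset is None:
            if log is not None:
                log.append((gene.gene_id, "skipped_non_atg"))
            revised.append(gene)
            continue
        if offset == 0:
            revised.append(gene)
            continue
        if gene.strand == "+":
            new = GeneModel(gene.gene_id, gene.contig_id, "+",
                            gene.cds_start + offset, gene.cds_end)
        else:
            new = GeneModel(gene.gene_id, gene.contig_id, "-",
                            gene.cds_start, gene.cds_end - offset)
        if log is not None:
            log.append((gene.gene_id, "revised", gene.cds_start, gene.cds_end,
                        new.cds_start, new.cds_end))
        revised.append(new)
    return revised


def _gene_frame_seq(gene: GeneModel, contig: GenomeSequence, pad: int) -> str:
    """Sequence in gene orientation, padded by *pad* around the start codon."""
    seq = contig.residues
    if gene.strand == "+":
        lo = max(0, gene.cds_start - pad)
        return seq[lo:gene.cds_end], gene.cds_start - lo
    hi = min(len(seq), gene.cds_end + pad)
    return revcomp(seq[gene.cds_start:hi]), hi - gene.cds_end


def _revised_offset(gene: GeneModel, contig: GenomeSequence, window: int,
                    motif_window: int, at_threshold: float) -> int | None:
    """Offset (in gene orientation, multiple of 3) of the chosen start, 0 for
    unchanged, None when the annotated start is not ATG."""
    oriented, start_pos = _gene_frame_seq(gene, contig, pad=window + 30)
    if oriented[start_pos:start_pos + 3] != "ATG":
        return None
    cds_len = len(oriented) - start_pos
    offsets = sorted(
        (o for o in range(-window, window + 1, 3) if -start_pos <= o),
        key=lambda o: (abs(o), -o))  # nearest first; downstream breaks ties
    for off in offsets:
        pos = start_pos + off
        if pos + 3 > len(oriented) or off >= cds_len - 3:
            continue
        if oriented[pos:pos + 3] != "ATG":
            continue
        upstream10 = oriented[max(0, pos - motif_window):pos]
        if not _has_ccc_ggg_motif(upstream10):
            continue
        upstream30 = oriented[max(0, pos - 30):pos]
        if len(upstream30) < 10:
            continue
        if at_fraction(upstream30) > at_threshold:
            return off
    return 0


def _has_ccc_ggg_motif(seq: str) -> bool:
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if tri[:2] in ("CC", "GG") or tri[1:] in ("CC", "GG"):
            return True
    return False


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def reciprocal_best_hits(proteins_a: dict[str, str], proteins_b: dict[str, str]
                         ) -> list[tuple[str, str]]:
    """Mutual-best-match ortholog pairs under BLOSUM62 global alignment.

    A pair (a, b) is reported iff b is a's unique best-scoring partner and
    vice versa; score ties produce no pair.
    """
    if not proteins_a or not proteins_b:
        raise ValueError("both protein sets must be non-empty")
    aligner = _protein_aligner()
    ids_a, ids_b = sorted(proteins_a), sorted(proteins_b)
    scores = np.full((len(ids_a), len(ids_b)), -np.inf)
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            scores[i, j] = aligner.score(proteins_a[a].replace("*", ""),
                                         proteins_b[b].replace("*", ""))
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(ids_a):
        j = int(np.argmax(scores[i]))
        if (scores[i] == scores[i, j]).sum() > 1:
            continue
        i_back = int(np.argmax(scores[:, j]))
        if i_back != i or (scores[:, j] == scores[i_back, j]).sum() > 1:
            continue
        pairs.append((a, ids_b[j]))
    return pairs


# ---------------------------------------------------------------------------
# MIP candidates from synteny
# ---------------------------------------------------------------------------

def find_mip_candidates(orthologs: Sequence[tuple[str, str]],
                        genes_a: Sequence[GeneModel],
                        genes_b: Sequence[GeneModel],
                        mites_a: Sequence, mites_b: Sequence,
                        flank_bp: int = 300,
                        min_block: int = 3) -> list[MipCandidate]:
    """Insertion-polymorphism candidates from syntenic ortholog blocks.

    Syntenic blocks are maximal runs of >= ``min_block`` ortholog pairs that
    are consecutive along both genomes (consistent order or strictly reversed).
    Within a block, a candidate is emitted when species A's gene has a MITE in
    its 5'-flank (``flank_bp`` upstream of the CDS, strand-aware) while the
    homologous flank in species B contains none.
    """
    ga = {g.gene_id: g for g in genes_a}
    gb = {g.gene_id: g for g in genes_b}
    rank_a = _gene_ranks(genes_a)
    rank_b = _gene_ranks(genes_b)
    pairs = [p for p in orthologs if p[0] in ga and p[1] in gb]
    pairs.sort(key=lambda p: rank_a[p[0]])

    blocks: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    direction = 0
    for pair in pairs:
        if not current:
            current, direction = [pair], 0
            continue
        pa, pb = current[-1]
        same_contigs = (ga[pair[0]].contig_id == ga[pa].contig_id
                        and gb[pair[1]].contig_id == gb[pb].contig_id)
        step_a = rank_a[pair[0]][1] - rank_a[pa][1]
        step_b = rank_b[pair[1]][1] - rank_b[pb][1]
        ok = same_contigs and step_a == 1 and step_b in (-1, 1) and (
            direction == 0 or step_b == direction)
        if ok:
            current.append(pair)
            direction = step_b
        else:
            blocks.append(current)
            current, direction = [pair], 0
    if current:
        blocks.append(current)

    out: list[MipCandidate] = []
    for block in blocks:
        if len(block) < min_block:
            continue
        for a_id, b_id in block:
            fa = _five_prime_flank(ga[a_id], flank_bp)
            fb = _five_prime_flank(gb[b_id], flank_bp)
            if _any_overlap(mites_a, ga[a_id].contig_id, fa) and not \
                    _any_overlap(mites_b, gb[b_id].contig_id, fb):
                out.append(MipCandidate(
                    gene_a=a_id, gene_b=b_id,
                    contig_a=ga[a_id].contig_id, region_a=fa,
                    contig_b=gb[b_id].contig_id, region_b=fb,
                    collinear_neighbors=len(block) - 1))
    return out


def _gene_ranks(genes: Sequence[GeneModel]) -> dict[str, tuple[str, int]]:
    ranks: dict[str, tuple[str, int]] = {}
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig, gs in by_contig.items():
        gs.sort(key=lambda g: g.cds_start)
        for i, g in enumerate(gs):
            ranks[g.gene_id] = (contig, i)
    return ranks


def _five_prime_flank(gene: GeneModel, flank_bp: int) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.cds_start - flank_bp), gene.cds_start
    return gene.cds_end, gene.cds_end + flank_bp


def _any_overlap(elements: Sequence, contig: str, span: tuple[int, int]) -> bool:
    lo, hi = span
    for e in elements:
        e_contig = getattr(e, "contig", None) or e.contig_id
        if e_contig == contig and e.start < hi and lo < e.end:
            return True
    return False
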