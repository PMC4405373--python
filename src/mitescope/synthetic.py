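"""Synthetic genomes with planted MITE families and full ground truth.

The generator emulates the statistical structure the analysis pipeline assumes:
small AT-rich genomes; element families defined by a TSD rule, a TIR and an
internal region; copy bursts at one or more divergence levels; degraded
remnant copies; CDS annotations; and small-RNA reads enriched at element
termini.

Divergence model
----------------
Mutations are substitutions only, drawn per site from the exact Kimura
2-parameter transition matrix for the requested branch distance (transitions :
transversions = 2 : 1 by default), so K2P estimates are additive along
lineages in expectation.  Bursts are modelled along a *master
lineage*: the oldest burst copies the family founder, younger bursts copy a
master that has itself drifted toward the present.  Copies within a burst at
level ``l`` then sit at pairwise K2P distance ``~2*l`` of each other, and every
pair involving an older burst sits at twice the older level, so a family with
``k`` distinct levels shows exactly ``k`` modes in its pairwise-distance
histogram — the signature of ``k`` amplification rounds.

Insertion-site hygiene: after planting an intact copy the immediate flanks are
resampled until the locus' locally best structural parse is exactly the
planted one.  Real genomes do contain structurally ambiguous insertions (a TSD
whose duplication extends the inverted repeat, e.g. the palindromic ``TA``);
unambiguous truth loci are required for coordinate-exact recall to be a
well-defined quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._dna import gc_at_probs, revcomp
from .core_io import GeneModel, GenomeSequence, PipelineConfig
from .scanner import scan_genome

__all__ = [
    "FamilySpec",
    "TruthRecord",
    "default_family_specs",
    "burst_demo_specs",
    "family_copies",
    "generate_genome",
    "generate_small_rna_reads",
    "generate_gene_annotations",
    "k2p_substitution_probs",
    "mutate_sequence",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: default read-length weights for the small-RNA simulator (18-29 nt, peaked
#: at 24-25 nt as element-derived small RNA populations are)
DEFAULT_LENGTH_WEIGHTS = {
    18: 2, 19: 3, 20: 4, 21: 5, 22: 6, 23: 9,
    24: 24, 25: 18, 26: 9, 27: 5, 28: 3, 29: 2,
}


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint of one planted MITE family.

    ``tsd`` is either the literal duplication sequence (e.g. ``"TA"`` for
    Stowaway-like families) or an integer length, in which case each copy
    duplicates a random host ``k``-mer.  ``divergence_levels`` lists
    ``(K2P level, fraction of copies)`` pairs; fractions must sum to 1.
    """

    name: str
    tsd: str | int
    tir: str
    internal_length: int
    copy_number: int
    divergence_levels: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    remnant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 5 <= len(self.tir) <= 60:
            raise ValueError(f"{self.name}: TIR must be 5-60 bp")
        tsd_len = len(self.tsd) if isinstance(self.tsd, str) else self.tsd
        if not 2 <= tsd_len <= 20:
            raise ValueError(f"{self.name}: TSD must be 2-20 bp")
        if self.element_length >= 1500:
            raise ValueError(f"{self.name}: element length must be < 1500 bp")
        total = sum(f for _, f in self.divergence_levels)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: divergence fractions must sum to 1")
        if not 0.0 <= self.remnant_fraction <= 1.0:
            raise ValueError(f"{self.name}: remnant_fraction must be in [0, 1]")
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")

    @property
    def tsd_length(self) -> int:
        return len(self.tsd) if isinstance(self.tsd, str) else self.tsd

    @property
    def element_length(self) -> int:
        return 2 * len(self.tir) + self.internal_length


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted copy; ``[start, end)`` is the element body
    (TSD excluded), on the package's 0-based half-open convention."""

    family: str
    contig: str
    start: int
    end: int
    intact: bool
    divergence: float
    tsd: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def default_family_specs(copy_number: int = 20,
                         divergence_levels=((0.0, 0.5), (0.02, 0.5)),
                         remnant_fraction: float = 0.10) -> list[FamilySpec]:
    """Five families, one per recognized superfamily signature.

    TSD/TIR signatures follow the superfamily taxonomy: TA for Stowaway-like,
    3 bp for Tourist-like, 8 bp with short TIR for hAT-like, 8 bp with 24-34 bp
    TIR for Merlin-like, 10 bp with minimal TIR for Mutator-like.
    """
    return [
        FamilySpec("stowaway", "TA", "CTCCCTCCGTTGGC", 250, copy_number,
                   divergence_levels, remnant_fraction),
        FamilySpec("tourist", 3, "GGGCATGCAGTG", 220, copy_number,
                   divergence_levels, remnant_fraction),
        FamilySpec("hat", 8, "CAGGGCTCCGCAAAG", 300, copy_number,
                   divergence_levels, remnant_fraction),
        FamilySpec("merlin", 8, "GCACGATCTTACCCAGGTGCTCCGACAC", 340,
                   copy_number, divergence_levels, remnant_fraction),
        FamilySpec("mutator", 10, "CGGCC", 280, copy_number,
                   divergence_levels, remnant_fraction),
    ]


def burst_demo_specs() -> tuple[FamilySpec, FamilySpec]:
    """Reference two- and three-burst families for amplification-history demos.

    Pairwise-distance modes fall at twice each divergence level; levels and
    copy fractions are chosen so every amplification round clears the 10%
    prominence rule of the burst detector at the default 0.02 bin width.
    """
    two = FamilySpec("burst2", "TA", "CTCCCTCCGTTGGC", 700, 36,
                     divergence_levels=((0.025, 0.45), (0.155, 0.55)))
    three = FamilySpec("burst3", "TA", "CTCCCTCCGTTGGC", 700, 48,
                       divergence_levels=((0.025, 0.44), (0.095, 0.26),
                                          (0.185, 0.30)))
    return two, three


def family_copies(spec: FamilySpec, seed: int, at_content: float = 0.65
                  ) -> list[tuple[str, float, bool]]:
    """Materialize the copies of one family without planting them in a genome.

    Returns ``(element_sequence, divergence_level, intact)`` triples; useful
    for divergence/burst analyses that do not need genomic context.
    """
    return _build_family_copies(spec, np.random.default_rng(seed), at_content)


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

def k2p_substitution_probs(level: float, ts_tv: float = 2.0
                           ) -> tuple[float, float]:
    """Exact K2P per-site outcome probabilities for a branch of length *level*.

    *level* is the expected number of substitutions per site (the K2P branch
    distance); *ts_tv* is the expected transition/transversion ratio on an
    infinitesimal branch.  Returns ``(p_transition, p_transversion_total)``
    from the closed-form Kimura transition matrix, so that simulated branches
    are exactly what the K2P estimator inverts — distances add along lineages
    in expectation.
    """
    if level < 0:
        raise ValueError("divergence level must be >= 0")
    if level == 0:
        return 0.0, 0.0
    # rates: alpha for the transition, beta for each of two transversions;
    # ts_tv = alpha / (2*beta), level = (alpha + 2*beta) * t
    beta_t = level / (2.0 * (ts_tv + 1.0))
    alpha_t = 2.0 * ts_tv * beta_t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) \
        - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    p_tv = 0.5 - 0.5 * np.exp(-4.0 * beta_t)
    return float(p_ts), float(p_tv)


def mutate_sequence(seq: str, level: float, rng: np.random.Generator,
                    ts_tv: float = 2.0) -> str:
    """Evolve a sequence along a branch of K2P distance *level*.

    Per-site outcomes follow the exact Kimura transition matrix (substitutions
    only, no indels); ``N`` sites are left untouched.
    """
    if level == 0.0 or not seq:
        return seq
    p_ts, p_tv = k2p_substitution_probs(level, ts_tv)
    chars = list(seq)
    u = rng.random(len(chars))
    pick = rng.integers(0, 2, size=len(chars))
    for i, (x, j) in enumerate(zip(u.tolist(), pick.tolist())):
        base = chars[i]
        if base == "N":
            continue
        if x < p_ts:
            chars[i] = _TRANSITION[base]
        elif x < p_ts + p_tv:
            chars[i] = _TRANSVERSIONS[base][j]
    return "".join(chars)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, at_content: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=gc_at_probs(at_content))])


def _allocate_counts(total: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of *total* over *fractions*."""
    raw = [total * f for f in fractions]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _build_family_copies(spec: FamilySpec, rng: np.random.Generator,
                         at_content: float) -> list[tuple[str, float, bool]]:
    """Materialize (element_sequence, level, intact) for every copy of a family.

    Element sequences exclude the TSD.  Bursts run along a master lineage from
    the oldest level to the youngest; TIRs are kept exact so that intact copies
    stay structurally recognizable.
    """
    founder_internal = _random_dna(rng, spec.internal_length, at_content)
    levels = sorted(spec.divergence_levels, key=lambda lv: -lv[0])  # oldest first
    counts = _allocate_counts(spec.copy_number, [f for _, f in levels])

    copies: list[tuple[str, float]] = []
    master = founder_internal
    prev_level = levels[0][0]
    for (level, _), count in zip(levels, counts):
        master = mutate_sequence(master, prev_level - level, rng)
        prev_level = level
        for _ in range(count):
            internal = mutate_sequence(master, level, rng)
            copies.append((spec.tir + internal + revcomp(spec.tir), level))

    n_remnant = int(round(spec.remnant_fraction * len(copies)))
    remnant_idx = set(rng.choice(len(copies), size=n_remnant, replace=False).tolist())
    out: list[tuple[str, float, bool]] = []
    for i, (seq, level) in enumerate(copies):
        if i in remnant_idx:
            keep = rng.uniform(0.40, 0.95)
            cut = max(1, int(round(len(seq) * keep)))
            seq = seq[:cut] if rng.random() < 0.5 else seq[len(seq) - cut:]
            out.append((seq, level, False))
        else:
            out.append((seq, level, True))
    return out


def _copy_tsd(spec: FamilySpec, rng: np.random.Generator, at_content: float) -> str:
    if isinstance(spec.tsd, str):
        return spec.tsd
    return _random_dna(rng, spec.tsd, at_content)


def _locally_unambiguous(context: str, body_offset: int, body_len: int,
                         cfg: PipelineConfig) -> bool:
    """True iff the planted body survives local scanning at exact coordinates
    (i.e. no alternative parse of the same locus outranks it)."""
    target = (body_offset, body_offset + body_len)
    return any((c.start, c.end) == target
               for c in scan_genome(GenomeSequence("w", context), cfg))


def generate_genome(length: int | Sequence[int], at_content: float,
                    family_specs: Sequence[FamilySpec], seed: int,
                    *, min_gap: int = 120, flank_context: int = 60,
                    config: PipelineConfig | None = None,
                    ) -> tuple[list[GenomeSequence], list[TruthRecord]]:
    """Generate contig(s) of i.i.d. background DNA with planted elements.

    ``length`` is one contig length or a list of lengths.  Elements are placed
    non-overlapping with at least ``min_gap`` background bases between
    insertion points; requested copies that do not fit raise ``ValueError``.
    Identical arguments and seed give byte-identical output.
    """
    if not 0.40 <= at_content <= 0.85:
        raise ValueError("at_content must be in [0.40, 0.85]")
    lengths = [length] if isinstance(length, int) else list(length)
    if any(n <= 0 for n in lengths):
        raise ValueError("contig lengths must be positive")
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)

    # materialize all copies, then assign them to contigs proportionally
    jobs: list[tuple[FamilySpec, str, float, bool]] = []
    for spec in family_specs:
        for seq, level, intact in _build_family_copies(spec, rng, at_content):
            jobs.append((spec, seq, level, intact))
    order = rng.permutation(len(jobs))

    total_bg = sum(lengths)
    need = sum(len(j[1]) + 2 * j[0].tsd_length + min_gap for j in jobs)
    if need > 0.8 * total_bg:
        raise ValueError(
            f"requested elements need ~{need} bp of margin but only "
            f"{total_bg} bp of genome were requested"
        )

    weights = np.array(lengths, dtype=float) / total_bg
    per_contig: list[list[int]] = [[] for _ in lengths]
    for j in order.tolist():
        per_contig[int(rng.choice(len(lengths), p=weights))].append(j)

    contigs: list[GenomeSequence] = []
    truth: list[TruthRecord] = []
    for ci, (clen, job_ids) in enumerate(zip(lengths, per_contig)):
        name = f"sim_{ci + 1}" if len(lengths) > 1 else "sim_1"
        background = np.frombuffer(
            _random_dna(rng, clen, at_content).encode(), dtype=np.uint8
        ).copy()
        # choose insertion points in background coordinates, left to right
        spans = [len(jobs[j][1]) + 2 * jobs[j][0].tsd_length for j in job_ids]
        if job_ids:
            slack = clen - 2 * flank_context - sum(min_gap for _ in spans)
            if slack <= 0:
                raise ValueError(f"contig {name}: too short for requested copies")
            cuts = np.sort(rng.uniform(0, slack, size=len(spans)))
            points = [int(flank_context + cuts[i] + i * min_gap)
                      for i in range(len(spans))]
        else:
            points = []

        pieces: list[str] = []
        pos = 0  # background cursor
        out_len = 0
        for j, point in zip(job_ids, points):
            spec, elem, level, intact = jobs[j]
            # hygiene may perturb flanking background bases, so resolve the
            # insert before copying the upstream background segment
            insert, tsd = _hygienic_insert(
                spec, elem, intact, background, point, rng, at_content, cfg,
                flank_context)
            pieces.append(background[pos:point].tobytes().decode())
            out_len += point - pos
            pos = point
            body_start = out_len + len(tsd)
            pieces.append(insert)
            out_len += len(insert)
            truth.append(TruthRecord(
                family=spec.name, contig=name, start=body_start,
                end=body_start + len(elem), intact=intact, divergence=level,
                tsd=tsd,
            ))
        pieces.append(background[pos:].tobytes().decode())
        contigs.append(GenomeSequence(id=name, residues="".join(pieces)))
    truth.sort(key=lambda t: (t.contig, t.start))
    return contigs, truth


def _hygienic_insert(spec: FamilySpec, elem: str, intact: bool,
                     background: np.ndarray, point: int,
                     rng: np.random.Generator, at_content: float,
                     cfg: PipelineConfig, flank_context: int,
                     max_tries: int = 25) -> tuple[str, str]:
    """Return (tsd + element + tsd, tsd), resampling TSD/flanks for intact
    copies until the local parse is unambiguous.  Remnants carry no TSD."""
    if not intact:
        return elem, ""
    w = flank_context
    for attempt in range(max_tries):
        tsd = _copy_tsd(spec, rng, at_content)
        left = background[max(0, point - w):point].tobytes().decode()
        right = background[point:point + w].tobytes().decode()
        context = left + tsd + elem + tsd + right
        if _locally_unambiguous(context, len(left) + len(tsd), len(elem), cfg):
            return tsd + elem + tsd, tsd
        # perturb the nearest flanking bases and retry
        for offset in range(1, 7):
            if point - offset >= 0:
                background[point - offset] = ord(
                    _random_dna(rng, 1, at_content))
            if point + offset - 1 < background.size:
                background[point + offset - 1] = ord(
                    _random_dna(rng, 1, at_content))
    raise RuntimeError(
        f"{spec.name}: could not realize an unambiguous insertion site "
        f"after {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# small RNA reads
# ---------------------------------------------------------------------------

def generate_small_rna_reads(consensi: dict[str, str], n_reads: int,
                             terminal_bias: float, seed: int,
                             length_weights: dict[int, float] | None = None,
                             ) -> list[dict]:
    """Draw small-RNA reads as substrings of family consensi.

    ``terminal_bias`` is the fraction of reads whose start falls in the outer
    20% of the consensus (both ends pooled); strands are symmetric.  Each read
    dict carries id, seq and its truth (family, start, strand, length).
    """
    if not 0.0 <= terminal_bias <= 1.0:
        raise ValueError("terminal_bias must be in [0, 1]")
    weights = dict(length_weights or DEFAULT_LENGTH_WEIGHTS)
    lengths = sorted(weights)
    if lengths[0] < 16 or lengths[-1] > 30:
        raise ValueError("read lengths must be within 16-30 nt")
    max_len = lengths[-1]
    for name, seq in consensi.items():
        if len(seq) < max_len:
            raise ValueError(f"consensus {name!r} shorter than max read length")
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    names = sorted(consensi)
    rng = np.random.default_rng(seed)

    reads: list[dict] = []
    for i in range(n_reads):
        fam = names[int(rng.integers(len(names)))]
        seq = consensi[fam]
        read_len = int(rng.choice(lengths, p=probs))
        lo, hi = 0, len(seq) - read_len  # inclusive start range
        if rng.random() < terminal_bias:
            edge = max(1, int(0.2 * len(seq)))
            left_hi = min(hi, edge - 1)
            right_lo = max(lo, len(seq) - edge - read_len + 1)
            if rng.random() < 0.5 and left_hi >= lo:
                start = int(rng.integers(lo, left_hi + 1))
            else:
                start = int(rng.integers(right_lo, hi + 1))
        else:
            start = int(rng.integers(lo, hi + 1))
        frag = seq[start:start + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append({
            "id": f"read_{i + 1}",
            "seq": frag if strand == "+" else revcomp(frag),
            "family": fam,
            "start": start,
            "length": read_len,
            "strand": strand,
        })
    return reads


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def generate_gene_annotations(genome: Sequence[GenomeSequence], n_genes: int,
                              mean_cds_len: int, seed: int,
                              truth: Sequence[TruthRecord] = (),
                              flanks: Sequence[int] = (300, 200, 100, 0),
                              ) -> tuple[list[GeneModel], dict[int, set[str]]]:
    """Place non-overlapping CDS models on the genome.

    Returns the genes plus, per flank size, the set of gene ids that have a
    planted element within that flank of their CDS (the association truth).
    """
    contigs = list(genome)
    if not contigs or all(len(c) == 0 for c in contigs):
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    total = sum(len(c) for c in contigs)
    weights = np.array([len(c) / total for c in contigs])

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c.id: [] for c in contigs}
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 50 * n_genes:
            raise ValueError(
                f"could not place {n_genes} non-overlapping genes "
                f"(placed {len(genes)})"
            )
        contig = contigs[int(rng.choice(len(contigs), p=weights))]
        cds_len = max(90, int(rng.normal(mean_cds_len, mean_cds_len / 5)))
        cds_len -= cds_len % 3
        if cds_len >= len(contig):
            continue
        start = int(rng.integers(0, len(contig) - cds_len))
        end = start + cds_len
        if any(start < e and s < end for s, e in occupied[contig.id]):
            continue
        occupied[contig.id].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"gene_{len(genes) + 1:04d}",
                               contig_id=contig.id, strand=strand,
                               cds_start=start, cds_end=end))

    associated: dict[int, set[str]] = {f: set() for f in flanks}
    for g in genes:
        for f in flanks:
            lo, hi = g.cds_start - f, g.cds_end + f
            for t in truth:
                if t.contig == g.contig_id and t.start < hi and lo < t.end:
                    associated[f].add(g.gene_id)
                    break
    return genes, associated
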