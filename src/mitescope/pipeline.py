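"""End-to-end orchestration: scan -> filter -> cluster -> consensus -> mine ->
classify -> name -> diverge -> associate, with a reproducible run report.

The pipeline is a pure function of (inputs, config, seed): rerunning with the
same arguments produces an identical report.  Stage boundaries log record
counts so attrition through the filters is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .context import AssociationResult, association_analysis
from .core_io import (GeneModel, GenomeSequence, PipelineConfig,
                      write_element_table, write_fasta)
from .evolution import (BurstProfile, SaturatedDistanceError, burst_histogram,
                        family_distance_matrix, nj_tree)
from .families import (MiteCopy, MiteFamily, aligned_identity,
                       build_consensus, classify_family, cluster_families,
                       filter_by_repeat_evidence, mine_remnants_batch,
                       name_families)
from .scanner import filter_candidates, scan_genome

__all__ = ["RunReport", "run_pipeline", "summarize_superfamilies"]

SUPERFAMILY_ORDER = ("Stowaway-like", "Tourist-like", "hAT-like",
                     "Merlin-like", "Mutator-like", "Unknown")


@dataclass
class RunReport:
    stage_counts: dict[str, int]
    superfamily_summary: pd.DataFrame
    genome_fraction: float
    associations: list[AssociationResult]
    families: list[MiteFamily]
    config: dict
    seed: int
    burst_peaks: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "stage_counts": self.stage_counts,
            "genome_fraction": round(self.genome_fraction, 6),
            "superfamilies": self.superfamily_summary.to_dict(orient="records"),
            "burst_peaks": self.burst_peaks,
            "associations": [
                {
                    "flank_bp": a.flank_bp,
                    "n_elements": a.n_elements,
                    "n_associated": a.n_associated,
                    "fraction": round(a.fraction, 6),
                    "null_mean_fraction": (None if np.isnan(a.null_mean_fraction)
                                           else round(a.null_mean_fraction, 6)),
                    "null_replicates": a.null_replicates,
                    "chi_square": (None if np.isnan(a.chi_square)
                                   else round(a.chi_square, 6)),
                    "p_value": (None if np.isnan(a.p_value)
                                else round(a.p_value, 6)),
                }
                for a in self.associations
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(genome: Sequence[GenomeSequence],
                 genes: Sequence[GeneModel] = (),
                 config: PipelineConfig | None = None,
                 *, species_letter: str = "b",
                 association_flanks: Sequence[int] = (300, 200, 100, 0),
                 null_replicates: int = 200,
                 outdir: str | Path | None = None,
                 compute_trees: bool = True) -> RunReport:
    """Run the full discovery/characterization workflow on one genome."""
    cfg = config or PipelineConfig()
    contigs = list(genome)
    counts: dict[str, int] = {}
    log_lines: list[str] = []

    def log(stage: str, n: int) -> None:
        counts[stage] = n
        log_lines.append(f"{stage}\t{n}")

    candidates = scan_genome(contigs, cfg)
    log("candidates", len(candidates))
    flog: dict = {}
    filtered = filter_candidates(candidates, cfg, log=flog)
    log("filtered", len(filtered))
    supported = filter_by_repeat_evidence(filtered, contigs, log=flog)
    log("repeat_supported", len(supported))

    families = cluster_families(supported, cfg.family_identity,
                                cfg.min_family_size, cfg, log=flog)
    log("families", len(families))

    for fam in families:
        fam.consensus = build_consensus(fam)
        classify_family(fam)

    mined = mine_remnants_batch(
        {f"family_{i}": fam.consensus for i, fam in enumerate(families)},
        contigs, cfg.remnant_identity, cfg.remnant_coverage, cfg)
    for i, fam in enumerate(families):
        fam.copies = _merge_copies(fam, mined.get(f"family_{i}", []))
    _resolve_cross_family_claims(families, log_lines)
    name_families(families, species_letter)
    log("copies", sum(f.n_copies for f in families))
    log("intact_copies", sum(f.n_intact for f in families))

    burst_peaks: dict[str, int] = {}
    trees: dict[str, str] = {}
    histograms: dict[str, BurstProfile] = {}
    for fam in families:
        seqs = [c.sequence for c in fam.copies if c.intact and c.sequence]
        ids = [f"{c.contig}:{c.start}-{c.end}" for c in fam.copies
               if c.intact and c.sequence]
        if len(seqs) < 2:
            continue
        try:
            matrix = family_distance_matrix(seqs, ids)
        except SaturatedDistanceError:
            log_lines.append(f"{fam.name}\tall pairs saturated; skipped")
            continue
        prof = burst_histogram(matrix, cfg.histogram_bin)
        histograms[fam.name] = prof
        burst_peaks[fam.name] = prof.n_peaks
        if compute_trees and len(seqs) >= 3 and np.isfinite(matrix.d).all():
            trees[fam.name] = nj_tree(matrix)

    associations: list[AssociationResult] = []
    if genes:
        all_copies = [c for f in families for c in f.copies]
        for flank in association_flanks:
            associations.append(association_analysis(
                all_copies, contigs, genes, flank, null_replicates,
                seed=cfg.rng_seed + flank))

    total_len = sum(len(c) for c in contigs)
    occupied = sum(f.total_bp for f in families)
    summary = summarize_superfamilies(families, contigs)
    report = RunReport(
        stage_counts=counts, superfamily_summary=summary,
        genome_fraction=occupied / total_len if total_len else 0.0,
        associations=associations, families=families,
        config=cfg.to_dict(), seed=cfg.rng_seed, burst_peaks=burst_peaks,
    )
    if outdir is not None:
        _write_artifacts(Path(outdir), report, contigs, trees, histograms,
                         log_lines)
    return report


def _merge_copies(fam: MiteFamily, mined: list[MiteCopy]) -> list[MiteCopy]:
    """Mined hits plus any clustered member not rediscovered by mining."""
    copies = list(mined)
    for m in fam.members:
        overlapped = any(
            c.contig == m.contig and
            min(c.end, m.end) - max(c.start, m.start) > 0.5 * min(
                c.length, m.length)
            for c in copies)
        if not overlapped:
            ident, cov, _ = aligned_identity(m.sequence or "", fam.consensus)
            copies.append(MiteCopy(
                contig=m.contig, start=m.start, end=m.end, intact=True,
                identity_to_consensus=round(ident, 4),
                coverage_of_consensus=round(cov, 4), sequence=m.sequence))
    copies.sort(key=lambda c: (c.contig, c.start))
    return copies


def _resolve_cross_family_claims(families: list[MiteFamily],
                                 log_lines: list[str]) -> None:
    """No genomic interval may be claimed by two families: on conflict the
    higher-identity claim wins (ties: larger family)."""
    claims = [
        (copy.identity_to_consensus, fam.n_copies, fi, ci, copy)
        for fi, fam in enumerate(families)
        for ci, copy in enumerate(fam.copies)
    ]
    claims.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    taken: dict[str, list[tuple[int, int]]] = {}
    drop: dict[int, set[int]] = {}
    for ident, _, fi, ci, copy in claims:
        spans = taken.setdefault(copy.contig, [])
        clash = any(min(copy.end, e) - max(copy.start, s) >
                    0.5 * min(copy.length, e - s) for s, e in spans)
        if clash:
            drop.setdefault(fi, set()).add(ci)
            log_lines.append(
                f"overlap\tfamily {fi} copy {copy.contig}:{copy.start}-"
                f"{copy.end} yielded to a stronger claim")
        else:
            spans.append((copy.start, copy.end))
    for fi, bad in drop.items():
        families[fi].copies = [c for i, c in enumerate(families[fi].copies)
                               if i not in bad]


def summarize_superfamilies(families: Sequence[MiteFamily],
                            genome: Sequence[GenomeSequence]) -> pd.DataFrame:
    """Per-superfamily family/element/bp totals plus a totals row."""
    rows = []
    for sf in SUPERFAMILY_ORDER:
        fams = [f for f in families if f.superfamily == sf]
        if not fams:
            continue
        rows.append({
            "superfamily": sf,
            "families": len(fams),
            "elements": sum(f.n_copies for f in fams),
            "total_bp": sum(f.total_bp for f in fams),
        })
    total = {
        "superfamily": "Total",
        "families": sum(r["families"] for r in rows),
        "elements": sum(r["elements"] for r in rows),
        "total_bp": sum(r["total_bp"] for r in rows),
    }
    rows.append(total)
    return pd.DataFrame(rows, columns=["superfamily", "families", "elements",
                                       "total_bp"])


def _write_artifacts(outdir: Path, report: RunReport,
                     contigs: list[GenomeSequence], trees: dict[str, str],
                     histograms: dict[str, BurstProfile],
                     log_lines: list[str]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    report.superfamily_summary.to_csv(outdir / "report.tsv", sep="\t",
                                      index=False)
    (outdir / "config.snapshot.json").write_text(
        json.dumps(report.config, indent=2, sort_keys=True) + "\n")

    fam_dir = outdir / "families"
    fam_dir.mkdir(exist_ok=True)
    consensi = []
    all_copies = []
    for fam in report.families:
        consensi.append((fam.name or "unnamed", fam.consensus))
        recs = [(f"{c.contig}:{c.start}-{c.end}", c.sequence or "")
                for c in fam.copies if c.sequence]
        if recs:
            write_fasta(recs, fam_dir / f"{fam.name}.fasta")
        for c in fam.copies:
            all_copies.append(_CopyRow(c.contig, c.start, c.end, fam.name,
                                       c.intact))
    write_fasta(consensi, outdir / "consensus.fasta")
    write_element_table(all_copies, outdir / "copies.bed")

    hist_dir = outdir / "histograms"
    hist_dir.mkdir(exist_ok=True)
    for name, prof in histograms.items():
        with open(hist_dir / f"{name}.tsv", "w") as fh:
            fh.write("bin_start\tbin_end\tcount\n")
            for i, count in enumerate(prof.counts.tolist()):
                fh.write(f"{prof.bin_edges[i]:.4f}\t{prof.bin_edges[i+1]:.4f}"
                         f"\t{count}\n")
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for name, nwk in trees.items():
        (tree_dir / f"{name}.nwk").write_text(nwk + "\n")
    (outdir / "logs").mkdir(exist_ok=True)
    (outdir / "logs" / "run.log").write_text("\n".join(log_lines) + "\n")


@dataclass
class _CopyRow:
    contig: str
    start: int
    end: int
    family: str | None
    intact: bool
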