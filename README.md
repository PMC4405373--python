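# mitescope

Genome-wide discovery and evolutionary characterization of **miniature
inverted-repeat transposable elements (MITEs)** in small, AT-rich genomes
such as those of microsporidian parasites.

MITEs are short (< 1.5 kb) non-autonomous DNA transposons that carry no
coding capacity and are recognizable purely by structure: a **terminal
inverted repeat** (TIR, 5–60 bp) at both ends, flanked by an identical
**target site duplication** (TSD, 2–20 bp) created on insertion. Their
TSD/TIR signature diagnoses the superfamily (TA → *Stowaway*-like, 3 bp →
*Tourist*-like, 8 bp → *hAT*- or *Merlin*-like depending on TIR length,
10 bp → *Mutator*-like), and the distribution of pairwise divergences within
a family records its amplification history.

`mitescope` implements the full workflow as a tested, reusable library + CLI:

* **structural scanning** — exhaustive TIR+TSD detection with deterministic
  overlap resolution (parameters: TIR 5–60 bp, ≤ 1 mismatch; TSD 2–20 bp;
  body < 1500 bp);
* **family building** — single-linkage clustering at ≥ 90 % identity
  (families with < 3 members discarded), majority-rule consensus,
  genome-wide remnant mining (identity ≥ 0.90, consensus coverage ≥ 0.80),
  superfamily classification and `NxY#` naming;
* **divergence analysis** — Kimura 2-parameter distances
  (`d = −½ ln[(1−2P−Q)·√(1−2Q)]`), pairwise-distance histograms with
  amplification-burst peak calling, 100 %-identity grouping, and
  Saitou–Nei neighbor-joining trees;
* **genomic context** — gene-association counts at 300/200/100/0 bp CDS
  flanks against a Monte-Carlo placement null with a Pearson chi-square
  verdict; translation-initiation-site re-annotation from CCC/GGG-like
  motifs in AT-rich context; reciprocal-best-hit orthologs and synteny-based
  insertion-polymorphism (MIP) candidates;
* **small RNAs** — ungapped mapping of 16–30 nt reads onto family consensi
  (≤ 2 mismatches, all equal-best loci), length histograms and
  strand-resolved positional densities;
* **simulation** — a first-class synthetic-genome generator that plants MITE
  families with controlled TSD/TIR structure, burst-structured divergence
  (exact K2P substitution model), degraded remnants, gene annotations and
  terminal-biased small-RNA reads, with complete ground truth.

## Worked example

Simulate a 300 kb genome with the five default families (12 copies each),
then run the full pipeline:

```python
from mitescope.pipeline import run_pipeline
from mitescope.synthetic import (default_family_specs, generate_genome,
                                 generate_gene_annotations)

specs = default_family_specs(copy_number=12)
contigs, truth = generate_genome(300_000, 0.65, specs, seed=7)
genes, _ = generate_gene_annotations(contigs, 90, 900, seed=8, truth=truth)
report = run_pipeline(contigs, genes, null_replicates=200)
print(report.superfamily_summary.to_string(index=False))
print(f"genome fraction occupied: {report.genome_fraction:.4%}")
for a in report.associations:
    print(f"flank {a.flank_bp:>3}: {a.n_associated}/{a.n_elements} associated "
          f"({a.fraction:.1%}); null mean {a.null_mean_fraction:.3f}; "
          f"chi2={a.chi_square:.2f}, p={a.p_value:.3f}")
```

which prints

```
  superfamily  families  elements  total_bp
Stowaway-like         1        11      3058
 Tourist-like         1        13      2827
     hAT-like         1        12      3815
  Merlin-like         1        12      4687
 Mutator-like         1        12      3289
        Total         5        60     17676
genome fraction occupied: 5.5487%
flank 300: 34/60 associated (56.7%); null mean 0.490; chi2=0.71, p=0.400
flank 200: 29/60 associated (48.3%); null mean 0.432; chi2=0.32, p=0.570
flank 100: 27/60 associated (45.0%); null mean 0.388; chi2=0.48, p=0.490
flank   0: 23/60 associated (38.3%); null mean 0.346; chi2=0.18, p=0.671
```

All five planted families are recovered and classified into the correct
superfamilies with `NxY#` names (`NbS1`, `NbT1`, `Nbh1`, `NbMe1`, `NbMu1`);
the 60 recovered copies occupy 5.5 % of the genome, and the chi-square test
against the placement null finds no insertion bias toward genes at any flank
size (p ≥ 0.4) — exactly what the generator, which places elements uniformly,
should produce.

The same workflow is available from the shell:

```bash
mitescope simulate --length 300000 --copies 12 --genes 90 --seed 7 --outdir sim
mitescope run sim/genome.fasta --genes sim/genes.gff --seed 7 --outdir results
```

which writes `report.json`, the superfamily table, per-family FASTA, a
BED-compatible copy table, divergence histograms, newick trees and a run log
under `results/`. Other subcommands (`scan`, `cluster`, `mine`, `diverge`,
`associate`, `reannotate`, `smallrna`, `mip`) expose the individual stages.

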