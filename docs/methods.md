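# Methods

This note documents the models and procedures implemented in `mitescope`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic data do and do not emulate.

## Structural detection

A MITE candidate is an interval `[s, e)` (the element *body*; the TSD is not
part of the body) satisfying three conditions:

* **TIR** — the outermost `t` bases of the body reverse-complement-match the
  last `t` bases, for some `t` between `tir_min` (5) and `tir_max` (60),
  with at most `max_tir_mismatch` (1) Hamming mismatches counted from the
  outside in. No indels are allowed inside TIRs. For a fixed body the
  reported TIR is the largest such `t`; because the mismatch count is
  non-decreasing in `t`, this is well defined.
* **TSD** — an exact direct repeat of length `tsd_min`..`tsd_max` (2..20)
  immediately flanks the body on both sides; the longest such repeat is
  reported. `N` never matches any base, on either comparison.
* **length** — body length below `max_element_len` (1500 bp).

The scanner evaluates, per body length, a vectorized necessary TIR condition
(mismatches over the outermost `tir_min` bases), verifies TSDs at the
surviving positions through fixed-width flank windows, and then computes the
maximal TIR per candidate. A dense test-suite oracle re-derives the same
definition by direct enumeration; the two agree exactly on random 50 kb
sequences.

### Overlap resolution

Short TIR/TSD criteria are weakly specific: i.i.d. AT-rich sequence is
saturated with parses (about 3 candidates per base before resolution at
AT = 0.65). Resolution is deterministic: (1) per body start, keep the best
candidate; (2) per body end, keep the best; (3) greedy suppression in global
priority order, where two candidates compete only if they overlap by more
than 80 % of *both* spans — i.e. only alternative parses of the same locus.
The priority key is combined structural evidence (TIR length + TSD length,
descending), then fewer TIR mismatches, longer TIR, leftmost. Ranking on
the combined length keeps short-TIR/long-TSD superfamilies (Mutator-like:
5 bp TIR, 10 bp TSD) competitive with chance medium-TIR candidates, which a
TIR-first ranking systematically suppresses.

Some loci are *intrinsically* ambiguous: a TSD whose duplication is
self-complementary (the TA of Stowaway-like elements is its own reverse
complement) extends the inverted repeat, so the locus supports two equally
valid structural readings shifted by the TSD length. No structure-only
detector can resolve these; the synthetic generator therefore resamples
insertion-site flanks until each planted copy's parse is locally
unambiguous, making coordinate-exact recall a well-defined quantity.
Real genomes will contain a minority of such ambiguous boundaries.

### Candidate filters and repeat evidence

Candidates with more than 2 `N` bases in the body or mismatched TSD copies
are removed. Before clustering, candidates are scored by genome-wide
multi-copy support: `(number of body 16-mers occurring at ≥ 2 genomic
positions) − (number occurring once)`. The score is maximal when the
candidate span coincides with the repeated unit — sub-parses lose repeated
16-mers, over-extended parses pay for unique flanking sequence — so
non-positive scores are dropped and each locus collapses to its
best-supported parse. This plays the role of the multi-copy requirement
built into de novo repeat finders and reduces ~10⁵ resolved parses per Mb
to roughly the set of genuine repeat copies.

## Families

**Identity.** Pairwise identity uses global alignment with free end gaps
(match +1, mismatch −1, gap −2); identity = matches / aligned columns
between the first and last aligned positions, coverage = aligned span of
the shorter sequence / its length.

**Clustering.** Single linkage over edges with identity ≥ 0.90 (mirroring
all-vs-all homology grouping, where any qualifying hit joins two elements),
with two guards: shorter-sequence coverage ≥ 0.60 and an aligned core of
≥ 30 columns. Without the column floor, a random 10–15 bp candidate is
contained at ≥ 90 % identity inside long candidates with probability of
order 10⁻⁴ per pair, and single linkage would chain unrelated families
through such fragments — the floor emulates the E-value threshold below
which a homology search would never report a hit. Components with fewer
than 3 members are discarded. Candidate edges are pre-screened by shared
10-mers and a banded edit-distance bound; only surviving pairs are aligned
exactly.

**Consensus.** Center-star majority: the star is the member sharing the
most 10-mers with the rest; every member is aligned to the star and
projected onto star columns; each column takes the majority residue (ties
alphabetical, gaps last; majority-gap columns are dropped). Insertions
relative to the star are not represented — adequate for families whose
copies differ by substitutions and truncations, which is what the
substitution-only simulator produces; tandem micro-insertions in real
copies would be flattened.

**Remnant mining.** Each consensus is searched genome-wide with `blastn`
(dust off, word size 11); hits are kept at identity ≥ 0.90 and consensus
coverage ≥ 0.80, overlapping hits merged keeping the higher identity. A hit
is flagged *intact* when it is full-length (coverage ≥ 0.95) and TIR+TSD
structure is re-detected at the locus by a local re-scan; intactness is by
definition a property of full-length elements, and a structure-only check
mis-flags truncated fragments through chance micro-parses near the hit
bounds.

**Classification and naming.** TSD "TA" → Stowaway-like; 3 bp →
Tourist-like; 8 bp with TIR 24–34 bp → Merlin-like, otherwise hAT-like;
10 bp → Mutator-like; anything else Unknown, with a flag for the recurrent
novel signature of a 5–6 bp TSD and a TIR beginning `TGT`. Families are
named `N<species letter><code><rank>` with codes S/T/h/Me/Mu/N, ranked by
copy number within each (species, superfamily).

## Divergence and bursts

Distances are Kimura 2-parameter: `d = −½ ln[(1−2P−Q)·√(1−2Q)]` with P/Q
the transition/transversion proportions over comparable sites (pairwise
deletion of gap and N columns). Family members are multiply aligned with
MAFFT before distances are taken, as divergence studies align copies before
estimating distances; an equal-length fast path skips the MSA when the
affine aligner confirms the columnwise alignment is already optimal for the
most divergent pair. Single pairs use global affine alignment (match +1,
mismatch −1, gap open −4, extend −1, free end gaps); unit-cost edit-distance
paths were rejected because they buy spurious gaps in low-complexity
AT-rich sequence and bias K2P down by ~10 %.

The pairwise-distance histogram (bin width 0.02) is scanned for local
maxima with prominence ≥ 10 % of the pair count (zero-padded so boundary
modes count); the peak count is read as the number of amplification rounds.
Saturated pairs (log argument ≤ 0) are excluded and reported separately.

Neighbor joining is the canonical Saitou–Nei algorithm with the Q-criterion,
lowest-index tie-breaking, and negative branch lengths clamped to zero with
the deficit moved to the sister edge; output is an unrooted newick string.
On additive matrices the implementation recovers the generating topology
exactly (property-tested on random 6-taxon trees).

## Genomic context

An element is **gene-associated** when its span intersects any CDS extended
by the flank (300/200/100/0 bp supported). The null model places intervals
with the observed length spectrum uniformly at random without mutual
overlap and records the associated fraction per replicate. The bias test is
Pearson chi-square on the sample-vs-control contingency table without
continuity correction, df = (r−1)(c−1).

Calibration note: non-overlap placement induces negative correlation
between elements, so at high genome occupancy the test becomes conservative
(measured type-I ≈ 0.02 at 20 % occupancy). At the study conditions used
for calibration — 500 kb, 150 genes, 100 elements of 150 bp (~3 %
occupancy) — the type-I error is 0.044–0.048 at α = 0.05.

**TIS re-annotation.** For each gene the 30 nt up- and downstream of the
annotated ATG are scanned for in-frame candidate ATGs; a candidate is
supported when a CCC-like (`CCN`/`NCC`) or GGG-like (`GGN`/`NGG`) triplet
occurs within the 10 nt immediately upstream *and* the 30 nt upstream of
the candidate are AT-rich (> 0.80 — the window to which the AT criterion
applies is a design choice, recorded here). Candidates are examined by
increasing distance with the current start first, so supported annotations
are never moved and the operation is idempotent.

**Orthologs and MIP candidates.** Reciprocal best hits use BLOSUM62 global
alignment with the package's own aligner; score ties yield no pair.
Syntenic blocks are maximal runs of ≥ 3 ortholog pairs consecutive along
both genomes (consistent or strictly reversed order). A MIP candidate is a
block member whose 5′ flank (strand-aware, 300 bp) contains a MITE in one
species and none in the homologous flank of the other.

## Small RNAs

Reads (16–30 nt) are aligned ungapped, end-to-end, at every offset of every
consensus on both strands; a read is reported at all loci tying its best
mismatch count, provided that count is ≤ 2 (the conventional short-read
mapping tolerance; configurable). Length histograms count each read once;
positional densities weight multi-mapped reads by 1/loci, so summed density
equals summed mapped read length exactly (an invariant the tests assert),
and reverse-complementing the read set swaps the sense and antisense
profiles exactly.

## The synthetic genome generator

The generator is the package's study instrument, not a fixture: it produces
i.i.d. background DNA at a requested AT fraction (default 0.65, typical of
the small AT-rich genomes this pipeline targets), plants element copies as
`TSD + TIR + internal + revcomp(TIR) + TSD` at non-overlapping positions,
and emits ground-truth records for every copy.

* **Substitutions** follow the exact Kimura transition matrix for the
  requested branch distance (ts:tv = 2:1), so K2P estimates are additive
  along lineages in expectation. A single-hit-per-site scheme was rejected:
  it makes pairwise distances sub-additive and shifts histogram modes.
* **Bursts** run along a master lineage: the oldest burst copies the family
  founder; younger bursts copy a master that has drifted toward the
  present. Copies of a burst at level `l` sit at pairwise distance ~2·l,
  and every cross-burst pair sits at twice the older level, so a family
  with k levels shows exactly k histogram modes. TIRs and TSDs are kept
  exact so intact copies stay structurally recognizable. The reference
  burst conditions (`burst_demo_specs`: levels 0.025/0.155 at 36 copies and
  0.025/0.095/0.185 at 48 copies, internal length 700) put the modes at bin
  centers and give every round enough pair mass to clear the 10 %
  prominence rule.
* **Remnants** are 5′- or 3′-truncated at a uniform point retaining 40–95 %
  of the element and carry no TSD, so the mining coverage filter has both
  passing and failing cases.
* **Insertion-site hygiene** (see above) resamples flanks until each intact
  copy's parse is locally unambiguous.
* **Small-RNA reads** are substrings of consensi, strand-symmetric, with a
  length distribution peaked at 24–25 nt and a configurable fraction
  (default 0.7) starting in the outer 20 % of the consensus.

What this does **not** emulate: indels and tandem duplications within
copies, transposase ORFs, segmental duplications, nested insertions,
GC-content heterogeneity along the genome, and sequencing error in reads.
Passing tests therefore demonstrate correctness of the implemented
definitions and robust recovery under substitution-type divergence — not
performance on assemblies with high indel rates or heavily nested repeat
landscapes.

## Problem sizes used by the test suite and acceptance script

Scanner-vs-enumeration equivalence runs on twenty random 50 kb sequences;
planted-family recovery on one 1 Mb genome with five families × 20 copies
(half the copies undiverged, half at level 0.02, 10 % remnants); burst
detection on 50 seeds per condition; null calibration on 1000 simulated
tests; small-RNA invariants on 10,000 reads. These sizes were chosen as the
smallest at which the quantities of interest are statistically stable.

## Known limitations

* TIR mismatches are Hamming-only; an indel inside a TIR shifts the frame
  and shortens the detected repeat.
* The 1500 bp limit applies to the element body (TSD excluded); the N-count
  filter likewise applies to the body only.
* The consensus cannot represent insertions relative to the star member.
* blastn and MAFFT are required external tools for mining and family MSAs.
* Structural ambiguity at self-complementary TSD boundaries is resolved by
  a deterministic preference, not by copy-alignment boundary refinement.
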