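"""Clustering, consensus, mining, classification and naming."""

import numpy as np
import pytest

from mitescope import GenomeSequence, PipelineConfig
from mitescope._dna import revcomp
from mitescope.families import (MiteFamily, alignment_score, build_consensus,
                                classify_superfamily, cluster_families,
                                filter_by_repeat_evidence, mine_remnants,
                                name_families, pairwise_identity)
from mitescope.scanner import MiteCandidate
from mitescope.synthetic import mutate_sequence

from conftest import random_dna
from oracles import needleman_wunsch_free_ends


def cand(seq, start=0, contig="c1", tsd="TA", tir=10, mm=0):
    return MiteCandidate(contig=contig, start=start, end=start + len(seq),
                         tsd=tsd, tir_length=tir, tir_mismatches=mm,
                         sequence=seq)


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 100)
        assert pairwise_identity(s, s) == (1.0, 1.0)

    def test_five_substitutions_give_095(self, rng):
        s = list(random_dna(rng, 100))
        t = s.copy()
        for i in (3, 21, 44, 67, 90):
            t[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[i]]
        ident, cov = pairwise_identity("".join(s), "".join(t))
        assert ident == pytest.approx(0.95) and cov == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(30, 160)))
        b = mutate_sequence(a, 0.15, rng)[: int(rng.integers(25, len(a) + 1))]
        assert alignment_score(a, b) == needleman_wunsch_free_ends(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestClustering:
    def test_five_near_identical_copies_form_one_family(self, rng):
        base = random_dna(rng, 200)
        cands = [cand(mutate_sequence(base, 0.01, rng), start=i * 500)
                 for i in range(5)]
        fams = cluster_families(cands)
        assert len(fams) == 1 and fams[0].size == 5

    def test_two_member_component_is_discarded(self, rng):
        base = random_dna(rng, 200)
        log = {}
        fams = cluster_families(
            [cand(base, 0), cand(base, 600)], log=log)
        assert fams == [] and log["discarded_small_components"] == 1

    def test_single_linkage_chains_transitive_neighbors(self, rng):
        # A~B and B~C above threshold, A~C below: one family of three
        base = random_dna(rng, 300)
        a = base
        b = mutate_sequence(base, 0.055, rng)
        c = mutate_sequence(b, 0.055, rng)
        ia, _ = pairwise_identity(a, b)
        ib, _ = pairwise_identity(b, c)
        ic, _ = pairwise_identity(a, c)
        assert ia >= 0.9 and ib >= 0.9 and ic < 0.9
        fams = cluster_families([cand(a, 0), cand(b, 600), cand(c, 1200)])
        assert len(fams) == 1 and fams[0].size == 3

    def test_unrelated_sequences_do_not_cluster(self, rng):
        cands = [cand(random_dna(rng, 250), start=i * 500) for i in range(6)]
        assert cluster_families(cands) == []

    def test_short_fragment_cannot_chain_families(self, rng):
        # a 20 bp fragment contained in both 250-mers must not link them
        fam_a = random_dna(rng, 250)
        fam_b = random_dna(rng, 250)
        bridge = fam_a[:10] + fam_b[-10:]
        cands = ([cand(mutate_sequence(fam_a, 0.01, rng), i * 400)
                  for i in range(3)]
                 + [cand(mutate_sequence(fam_b, 0.01, rng), 2000 + i * 400)
                    for i in range(3)]
                 + [cand(bridge, 4000)])
        fams = cluster_families(cands)
        assert len(fams) == 2
        assert {f.size for f in fams} == {3}


class TestRepeatEvidence:
    def test_multicopy_parse_kept_unique_parse_dropped(self, rng):
        bg = random_dna(rng, 30_000)
        elem = random_dna(rng, 300)
        seq = bg[:5000]
        positions = []
        for i in range(4):
            positions.append(len(seq))
            seq += elem + bg[5000 + i * 600: 5000 + (i + 1) * 600]
        genome = GenomeSequence("c1", seq)
        copies = [cand(elem, start=p) for p in positions]
        lone = cand(seq[1000:1300], start=1000)
        kept = filter_by_repeat_evidence(copies + [lone], genome)
        assert lone not in kept and len(kept) == 4

    def test_overextended_parse_loses_to_exact_one(self, rng):
        bg = random_dna(rng, 20_000)
        elem = random_dna(rng, 300)
        seq = bg[:4000]
        positions = []
        for i in range(4):
            positions.append(len(seq))
            seq += elem + bg[4000 + i * 500: 4000 + (i + 1) * 500]
        genome = GenomeSequence("c1", seq)
        exact = cand(elem, start=positions[0])
        padded = cand(seq[positions[1] - 150:positions[1] + 450],
                      start=positions[1] - 150)
        kept = filter_by_repeat_evidence(
            [exact, padded] + [cand(elem, start=p) for p in positions[2:]],
            genome)
        assert exact in kept and padded not in kept


class TestConsensus:
    def test_identical_members_give_that_sequence(self, rng):
        s = random_dna(rng, 120)
        fam = MiteFamily(members=[cand(s, i * 200) for i in range(3)])
        assert build_consensus(fam) == s

    def test_majority_column_wins(self):
        seqs = ["AACGT", "AACGT", "AGCGT"]
        fam = MiteFamily(members=[cand(s, i * 10) for i, s in enumerate(seqs)])
        assert build_consensus(fam) == "AACGT"

    def test_tie_breaks_alphabetically(self):
        # two members disagree A vs G in one column: A wins the tie
        seqs = ["ATCGATCG", "GTCGATCG"]
        fam = MiteFamily(members=[cand(s, i * 10) for i, s in enumerate(seqs)])
        assert build_consensus(fam)[0] == "A"


class TestMining:
    def _genome_with_copies(self, rng):
        consensus = random_dna(rng, 300)
        degraded = mutate_sequence(consensus, 0.055, rng)[:255]  # 85% coverage
        short = mutate_sequence(consensus, 0.055, rng)[:210]     # 70% coverage
        bg = random_dna(rng, 6000)
        seq = (bg[:1000] + consensus + bg[1000:3000] + degraded
               + bg[3000:5000] + short + bg[5000:])
        return consensus, GenomeSequence("c1", seq), (1000, 3300, 5555)

    def test_thresholds_applied_to_identity_and_coverage(self, rng):
        consensus, genome, (full_at, deg_at, short_at) = \
            self._genome_with_copies(rng)
        copies = mine_remnants(consensus, genome)
        hits = sorted((c.start, c.end) for c in copies)
        # the full copy and the 85%-coverage degraded copy are reported
        assert any(abs(s - full_at) < 20 for s, _ in hits)
        assert any(abs(s - deg_at) < 20 for s, _ in hits)
        # the 70%-coverage fragment fails the coverage rule
        assert not any(abs(s - short_at) < 20 for s, _ in hits)

    def test_intact_flagging_requires_structure(self, rng):
        tir = "GGCCGACCGGTCGGACGCTC"
        internal = random_dna(rng, 200)
        elem = tir + internal + revcomp(tir)
        bg = random_dna(rng, 9000)
        seq = bg[:2000]
        starts = []
        for i in range(2):  # two intact copies with TSDs
            tsd = random_dna(rng, 4)
            starts.append(len(seq) + len(tsd))
            seq += tsd + elem + tsd + bg[2000 + i * 800:2000 + (i + 1) * 800]
        frag_at = len(seq)
        seq += elem[:200] + bg[4000:]  # truncated copy, no TSD
        genome = GenomeSequence("c1", seq)
        copies = mine_remnants(elem, genome, remnant_coverage=0.5)
        by_pos = {c.start: c for c in copies}
        for s in starts:
            match = [c for c in copies if abs(c.start - s) <= 5]
            assert match and match[0].intact
        frag = [c for c in copies if abs(c.start - frag_at) <= 15]
        assert frag and not frag[0].intact


class TestClassification:
    @pytest.mark.parametrize("tsd, tir_len, tir_seq, label", [
        ("TA", 12, "CTCCCT", "Stowaway-like"),
        (3, 10, "GGGCAT", "Tourist-like"),
        (8, 28, "GCACGA", "Merlin-like"),
        (8, 12, "CAGGGC", "hAT-like"),
        (10, 5, "CGGCC", "Mutator-like"),
        (4, 10, "ACGT", "Unknown"),
    ])
    def test_signature_table(self, tsd, tir_len, tir_seq, label):
        got, _ = classify_superfamily(tsd, tir_len, tir_seq)
        assert got == label

    def test_tgt_start_flag_on_5bp_tsd(self):
        label, tgt = classify_superfamily(5, 10, "TGTAAGGC")
        assert label == "Unknown" and tgt is True

    def test_classification_is_total(self, rng):
        for _ in range(50):
            tsd = int(rng.integers(2, 21))
            label, _ = classify_superfamily(tsd, int(rng.integers(5, 61)),
                                            random_dna(rng, 10))
            assert label in {"Stowaway-like", "Tourist-like", "hAT-like",
                             "Merlin-like", "Mutator-like", "Unknown"}


class TestNaming:
    def _family(self, superfamily, n_members, rng, offset=0):
        fam = MiteFamily(members=[cand(random_dna(rng, 100),
                                       offset + i * 300) for i in range(n_members)])
        fam.superfamily = superfamily
        return fam

    def test_species_and_code_compose(self, rng):
        fams = [self._family("Stowaway-like", 3, rng)]
        name_families(fams, "b")
        assert fams[0].name == "NbS1"

    def test_unknown_superfamily_uses_n(self, rng):
        fams = [self._family("Unknown", 3, rng)]
        name_families(fams, "c")
        assert fams[0].name == "NcN1"

    def test_numbering_by_descending_copy_number(self, rng):
        small = self._family("hAT-like", 4, rng)
        big = self._family("hAT-like", 9, rng, offset=5000)
        name_families([small, big], "b")
        assert big.name == "Nbh1" and small.name == "Nbh2"
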