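"""Gene association, Monte-Carlo null, chi-square, TIS re-annotation,
reciprocal best hits and MIP candidates."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from mitescope import GeneModel, GenomeSequence
from mitescope._dna import revcomp
from mitescope.context import (_expected_from_margins, associate_with_genes,
                               chi_square_bias_test, find_mip_candidates,
                               reannotate_tis, reciprocal_best_hits,
                               simulate_association_null)
from mitescope.synthetic import generate_genome, mutate_sequence

from conftest import random_dna
from oracles import pearson_chi_square


class Element:
    def __init__(self, contig, start, end):
        self.contig, self.start, self.end = contig, start, end


class TestAssociation:
    GENES = [GeneModel("g1", "c1", "+", 1000, 2000)]

    @pytest.mark.parametrize("flank, expected", [(300, 1), (200, 0), (0, 0)])
    def test_element_250bp_upstream(self, flank, expected):
        el = Element("c1", 500, 750)  # ends 250 bp before the CDS
        res = associate_with_genes([el], self.GENES, flank)
        assert res.n_associated == expected

    def test_flank_zero_requires_cds_overlap(self):
        inside = Element("c1", 1500, 1600)
        outside = Element("c1", 2000, 2100)  # abuts, half-open: no overlap
        res = associate_with_genes([inside, outside], self.GENES, 0)
        assert res.n_associated == 1

    def test_association_monotone_in_flank(self, rng):
        genes = [GeneModel(f"g{i}", "c1", "+", s, s + 600)
                 for i, s in enumerate(range(2000, 50_000, 5000))]
        elements = [Element("c1", int(p), int(p) + 200)
                    for p in rng.integers(0, 49_000, 40)]
        counts = [associate_with_genes(elements, genes, f).n_associated
                  for f in (0, 100, 200, 300)]
        assert counts == sorted(counts)


class TestNullSimulation:
    def test_null_mean_matches_coverage_expectation(self):
        contigs, _ = generate_genome(300_000, 0.65, [], seed=1)
        genes = [GeneModel(f"g{i}", "sim_1", "+", s, s + 500)
                 for i, s in enumerate(range(5000, 295_000, 10_000))]
        # short elements: P(hit) ~ fraction of placeable starts near windows
        fractions = simulate_association_null(
            contigs, genes, [10] * 200, 300, 300, seed=2)
        windows = 29  # genes placed every 10 kb
        covered = windows * (500 + 600 + 10)  # window + flanks + element slack
        expected = covered / 300_000
        se = np.sqrt(expected * (1 - expected) / (200 * 300))
        assert abs(fractions.mean() - expected) < 3 * se + 0.003

    def test_single_replicate_is_reproducible(self):
        contigs, _ = generate_genome(100_000, 0.65, [], seed=3)
        genes = [GeneModel("g", "sim_1", "+", 1000, 2000)]
        a = simulate_association_null(contigs, genes, [100] * 20, 300, 1, 5)
        b = simulate_association_null(contigs, genes, [100] * 20, 300, 1, 5)
        assert a == b

    def test_zero_genes_give_zero_fraction(self):
        contigs, _ = generate_genome(50_000, 0.65, [], seed=4)
        fr = simulate_association_null(contigs, [], [100] * 10, 300, 5, 6)
        assert (fr == 0).all()


class TestChiSquare:
    def test_margin_example(self):
        obs = [[30, 70], [20, 80]]
        stat, df, p = chi_square_bias_test(
            obs, _expected_from_margins(np.array(obs, float)))
        assert stat == pytest.approx(2.6667, abs=1e-4) and df == 1
        # closed-form 2x2: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 30, 70, 20, 80
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed, rel=1e-12)

    def test_observed_equals_expected(self):
        table = [[25, 75], [40, 60]]
        stat, df, p = chi_square_bias_test(table, table)
        assert stat == 0 and p == 1.0

    def test_matches_textbook_oracle_on_random_tables(self, rng):
        for _ in range(50):
            obs = rng.integers(5, 200, size=(2, 3)).astype(float)
            exp = _expected_from_margins(obs)
            stat, df, p = chi_square_bias_test(obs, exp)
            o_stat, o_df = pearson_chi_square(obs, exp)
            assert stat == pytest.approx(o_stat) and df == o_df
            s2, p2, d2, _ = scipy_stats.chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(s2) and p == pytest.approx(p2)

    def test_zero_expected_cell_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            chi_square_bias_test([[1, 2]], [[0, 3]])


class TestReannotateTis:
    def _genome(self, seq):
        return [GenomeSequence("c1", seq)]

    def test_supported_downstream_start_is_adopted(self):
        seq = list("A" * 200)
        seq[60:63] = "ATG"            # annotated start, no motif support
        seq[72:75] = "ATG"            # in-frame alternative at +12
        seq[69:71] = "CC"             # CCC-like motif just upstream of it
        genes = [GeneModel("g", "c1", "+", 60, 150)]
        out = reannotate_tis(genes, self._genome("".join(seq)))
        assert out[0].cds_start == 72

    def test_no_motif_leaves_annotation_unchanged(self):
        seq = list("A" * 200)
        seq[60:63] = "ATG"
        seq[72:75] = "ATG"            # alternative but motif-less
        genes = [GeneModel("g", "c1", "+", 60, 150)]
        out = reannotate_tis(genes, self._genome("".join(seq)))
        assert out[0].cds_start == 60

    def test_gc_rich_context_blocks_revision(self):
        seq = list("A" * 200)
        for i in range(42, 72, 2):    # make the upstream window GC-rich
            seq[i] = "G"
        seq[60:63] = "ATG"
        seq[72:75] = "ATG"
        seq[69:71] = "CC"
        genes = [GeneModel("g", "c1", "+", 60, 150)]
        out = reannotate_tis(genes, self._genome("".join(seq)))
        assert out[0].cds_start == 60

    def test_minus_strand_revision(self):
        plus = list("A" * 200)
        plus[60:63] = "ATG"
        plus[72:75] = "ATG"
        plus[69:71] = "CC"
        seq = revcomp("".join(plus))
        # plus-coordinates flip: gene on '-' covering the mirrored interval
        genes = [GeneModel("g", "c1", "-", 200 - 150, 200 - 60)]
        out = reannotate_tis(genes, self._genome(seq))
        assert out[0].cds_end == 200 - 72

    def test_idempotent_on_random_gene_sets(self, rng):
        contigs, _ = generate_genome(60_000, 0.70, [], seed=9)
        seq = list(contigs[0].residues)
        genes = []
        for i, s in enumerate(range(2000, 58_000, 4000)):
            seq[s:s + 3] = "ATG"
            genes.append(GeneModel(f"g{i}", "sim_1", "+", s, s + 900))
        genome = [GenomeSequence("sim_1", "".join(seq))]
        once = reannotate_tis(genes, genome)
        twice = reannotate_tis(once, genome)
        assert once == twice

    def test_non_atg_start_skipped_with_log(self):
        genes = [GeneModel("g", "c1", "+", 10, 40)]
        log = []
        out = reannotate_tis(genes, self._genome("C" * 100), log=log)
        assert out == genes and log[0][1] == "skipped_non_atg"


AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n=60):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def perturb_protein(rng, seq, n_sub=6):
    chars = list(seq)
    for i in rng.choice(len(chars), size=n_sub, replace=False):
        chars[i] = AA[int(rng.integers(0, 20))]
    return "".join(chars)


class TestReciprocalBestHits:
    def test_identical_proteomes_pair_one_to_one(self, rng):
        prots = {f"p{i}": random_protein(rng) for i in range(5)}
        other = {f"q{i}": prots[f"p{i}"] for i in range(5)}
        pairs = reciprocal_best_hits(prots, other)
        assert pairs == [(f"p{i}", f"q{i}") for i in range(5)]

    def test_non_reciprocal_best_is_dropped(self, rng):
        a_seq = random_protein(rng)
        # b's best partner is a_close, not a_far
        a_far = perturb_protein(rng, a_seq, 12)
        proteins_a = {"a_far": a_far}
        proteins_b = {"b": a_seq}
        extra_a = {"a_close": perturb_protein(rng, a_seq, 2), "a_far": a_far}
        pairs = reciprocal_best_hits(extra_a, proteins_b)
        assert pairs == [("a_close", "b")]

    def test_truth_recovery_with_paralogs(self, rng):
        n = 20
        ancestors = [random_protein(rng, 60) for _ in range(n)]
        prots_a = {f"a{i}": perturb_protein(rng, s, 3)
                   for i, s in enumerate(ancestors)}
        prots_b = {f"b{i}": perturb_protein(rng, s, 3)
                   for i, s in enumerate(ancestors)}
        for i in range(2):  # 10% paralogs in B
            prots_b[f"b_par{i}"] = perturb_protein(rng, ancestors[i], 8)
        pairs = reciprocal_best_hits(prots_a, prots_b)
        true = {(f"a{i}", f"b{i}") for i in range(n)}
        assert len(true & set(pairs)) >= 0.95 * n


class TestMipCandidates:
    def _setup(self):
        genes_a = [GeneModel(f"a{i}", "cA", "+", i * 2000, i * 2000 + 900)
                   for i in range(5)]
        genes_b = [GeneModel(f"b{i}", "cB", "+", i * 2000, i * 2000 + 900)
                   for i in range(5)]
        orthologs = [(f"a{i}", f"b{i}") for i in range(5)]
        return genes_a, genes_b, orthologs

    def test_asymmetric_insertion_is_reported(self):
        genes_a, genes_b, orthologs = self._setup()
        mite_a = [Element("cA", 3800, 3950)]  # in a2's 5'-flank (4000)
        out = find_mip_candidates(orthologs, genes_a, genes_b, mite_a, [])
        assert len(out) == 1 and out[0].gene_a == "a2"
        assert out[0].collinear_neighbors >= 2

    def test_insertion_in_both_species_is_not_polymorphic(self):
        genes_a, genes_b, orthologs = self._setup()
        mite_a = [Element("cA", 3800, 3950)]
        mite_b = [Element("cB", 3850, 3990)]
        out = find_mip_candidates(orthologs, genes_a, genes_b, mite_a, mite_b)
        assert out == []

    def test_blocks_shorter_than_three_are_ignored(self):
        genes_a, genes_b, orthologs = self._setup()
        # break collinearity: only a scrambled 2-pair run remains around a2
        orthologs = [("a0", "b3"), ("a1", "b1"), ("a2", "b2"), ("a3", "b0"),
                     ("a4", "b4")]
        mite_a = [Element("cA", 3800, 3950)]
        out = find_mip_candidates(orthologs, genes_a, genes_b, mite_a, [])
        assert out == []

    def test_eighteen_planted_asymmetric_insertions(self, rng):
        n = 40
        genes_a = [GeneModel(f"a{i}", "cA", "+", i * 3000, i * 3000 + 1000)
                   for i in range(n)]
        genes_b = [GeneModel(f"b{i}", "cB", "+", i * 3000, i * 3000 + 1000)
                   for i in range(n)]
        orthologs = [(f"a{i}", f"b{i}") for i in range(n)]
        chosen = sorted(rng.choice(range(1, n), size=18, replace=False))
        mites_a = [Element("cA", i * 3000 - 250, i * 3000 - 100)
                   for i in chosen]
        out = find_mip_candidates(orthologs, genes_a, genes_b, mites_a, [])
        assert len(out) == 18
        assert {c.gene_a for c in out} == {f"a{i}" for i in chosen}
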