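"""K2P distances, burst histograms, identity groups and NJ trees."""

import numpy as np
import pytest

from mitescope.evolution import (AlignedPair, BurstProfile, DistanceMatrix,
                                 SaturatedDistanceError, burst_histogram,
                                 family_distance_matrix, identity_groups,
                                 k2p_distance, k2p_from_sequences, nj_tree)
from mitescope.synthetic import (FamilySpec, burst_demo_specs, family_copies,
                                 mutate_sequence)

from conftest import random_dna


class TestK2P:
    def test_identical_sequences_give_zero(self, rng):
        s = random_dna(rng, 100)
        assert k2p_from_sequences(s, s) == 0.0

    def test_closed_form_value(self):
        d = k2p_distance(AlignedPair(0.10, 0.05, 1000))
        assert d == pytest.approx(0.17018, abs=1e-4)

    def test_distance_dominates_p_distance(self, rng):
        # multiple-hit correction can only stretch the observed p-distance
        for _ in range(300):
            P = rng.uniform(0, 0.35)
            Q = rng.uniform(0, min(0.4, (1 - 2 * P) * 0.95))
            if 1 - 2 * P - Q <= 0:
                continue
            assert k2p_distance(AlignedPair(P, Q, 500)) >= P + Q - 1e-12

    def test_reduces_to_jukes_cantor_when_rates_are_symmetric(self):
        # with transitions = 1/3 of changes (P = p/3, Q = 2p/3), K2P equals
        # the Jukes-Cantor transform of the total p-distance
        for p in (0.05, 0.15, 0.3, 0.5):
            d = k2p_distance(AlignedPair(p / 3, 2 * p / 3, 1000))
            jc = -0.75 * np.log(1 - 4 * p / 3)
            assert d == pytest.approx(jc, rel=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(SaturatedDistanceError):
            k2p_distance(AlignedPair(0.45, 0.15, 100))


class TestFamilyDistanceMatrix:
    def test_identical_members_give_zero_matrix(self, rng):
        s = random_dna(rng, 150)
        m = family_distance_matrix([s, s, s])
        assert np.allclose(m.d, 0)

    def test_star_simulation_recovers_twice_the_branch_length(self, rng):
        base = random_dna(rng, 1200)
        members = [mutate_sequence(base, 0.1, rng) for _ in range(8)]
        m = family_distance_matrix(members)
        assert m.condensed().mean() == pytest.approx(0.2, abs=0.02)

    def test_matrix_matches_scalar_recomputation(self, rng):
        base = random_dna(rng, 400)
        members = [mutate_sequence(base, 0.05, rng) for _ in range(4)]
        m = family_distance_matrix(members)
        for i in range(4):
            for j in range(i + 1, 4):
                assert m.d[i, j] == pytest.approx(
                    k2p_from_sequences(members[i], members[j]), abs=1e-9)

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        base = random_dna(rng, 300)
        m = family_distance_matrix(
            [mutate_sequence(base, 0.08, rng) for _ in range(5)])
        assert np.allclose(m.d, m.d.T) and np.allclose(np.diag(m.d), 0)


class TestBurstHistogram:
    def test_single_recent_burst_gives_one_peak_in_first_bins(self, rng):
        base = random_dna(rng, 600)
        members = [mutate_sequence(base, 0.005, rng) for _ in range(10)]
        prof = burst_histogram(family_distance_matrix(members))
        assert prof.n_peaks == 1 and prof.peaks[0][0] < 0.05

    def test_two_divergence_levels_give_two_peaks(self):
        spec, _ = burst_demo_specs()
        copies = family_copies(spec, seed=11)
        prof = burst_histogram(family_distance_matrix([s for s, _, _ in copies]))
        assert prof.n_peaks == 2

    def test_three_divergence_levels_give_three_peaks(self):
        _, spec = burst_demo_specs()
        copies = family_copies(spec, seed=12)
        prof = burst_histogram(family_distance_matrix([s for s, _, _ in copies]))
        assert prof.n_peaks == 3

    def test_pair_count_conservation(self, rng):
        base = random_dna(rng, 500)
        members = [mutate_sequence(base, 0.02, rng) for _ in range(7)]
        prof = burst_histogram(family_distance_matrix(members))
        assert prof.counts.sum() == 7 * 6 // 2


class TestIdentityGroups:
    def test_counts_and_order(self):
        groups = identity_groups(["s", "s", "s", "t", "t"])
        assert [len(g) for g in groups] == [3, 2]

    def test_all_distinct_gives_singletons(self, rng):
        seqs = [random_dna(rng, 30) for _ in range(6)]
        assert [len(g) for g in identity_groups(seqs)] == [1] * 6

    def test_24_groups_with_leading_sizes(self, rng):
        # mirror of a family whose 112 intact copies fall into 24
        # identity groups led by 38 and 29 identical elements
        sizes = [38, 29] + [2] * 10 + [1] * 12
        assert len(sizes) == 24 and sum(sizes) == 99
        seqs = []
        for i, n in enumerate(sizes):
            s = random_dna(np.random.default_rng(1000 + i), 80)
            seqs.extend([s] * n)
        groups = identity_groups(seqs)
        assert len(groups) == 24
        assert [len(g) for g in groups[:2]] == [38, 29]

    def test_equivalence_refinement_under_concatenation(self, rng):
        # grouping by (x + y) refines grouping by x
        xs = [random_dna(rng, 20) for _ in range(4)] * 3
        ys = [random_dna(rng, 10) for _ in range(len(xs))]
        coarse = identity_groups(xs)
        fine = identity_groups([x + y for x, y in zip(xs, ys)])
        for g in fine:
            assert any(set(g) <= set(c) for c in coarse)


class TestNeighborJoining:
    def test_two_taxa_bisect_the_distance(self):
        m = DistanceMatrix(("A", "B"), np.array([[0, 0.4], [0.4, 0]]))
        assert nj_tree(m) == "(A:0.2,B:0.2);"

    def test_three_taxon_branch_lengths(self):
        m = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        assert nj_tree(m) == "(A:0.5,B:1.5,C:2.5);"

    def test_additive_six_taxon_topology_recovery(self):
        import dendropy
        ok = 0
        for trial in range(30):
            tree, names, mat = _random_additive_tree(trial)
            nwk = nj_tree(DistanceMatrix(tuple(names), mat))
            ns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=nwk, schema="newick",
                                   taxon_namespace=ns)
            t2 = dendropy.Tree.get(data=tree, schema="newick",
                                   taxon_namespace=ns)
            t1.is_rooted = t2.is_rooted = False
            t1.update_bipartitions(); t2.update_bipartitions()
            ok += dendropy.calculate.treecompare.symmetric_difference(
                t1, t2) == 0
        assert ok == 30

    def test_distance_matrix_requires_symmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0]], float))

    def test_two_burst_family_is_two_monophyletic_clades(self):
        import dendropy
        spec, _ = burst_demo_specs()
        good = 0
        for seed in range(10):
            copies = family_copies(spec, seed=300 + seed)
            seqs = [s for s, _, _ in copies]
            labels = [f"L{lev:.3f}_{i}" for i, (_, lev, _) in enumerate(copies)]
            m = family_distance_matrix(seqs, labels)
            tree = dendropy.Tree.get(data=nj_tree(m), schema="newick")
            tree.is_rooted = False
            recent = set(l for l in labels if l.startswith("L0.025"))
            tree.update_bipartitions()
            taxa = [t for t in tree.taxon_namespace if t.label in recent]
            mask = tree.taxon_namespace.taxa_bitmask(taxa=taxa)
            every = tree.taxon_namespace.all_taxa_bitmask()
            good += any(b.leafset_bitmask in (mask, ~mask & every)
                        for b in tree.bipartition_encoding)
        assert good >= 9


def _random_additive_tree(seed: int):
    """A random 6-leaf binary tree (newick), its leaf names and the exact
    path-length matrix, built by sequential joining independently of NJ."""
    import dendropy
    rng = np.random.default_rng(seed)
    names = [f"t{i}" for i in range(6)]
    nodes = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        bi, bj = rng.uniform(0.05, 1.0, 2)
        joined = f"({nodes[i]}:{bi:.6f},{nodes[j]}:{bj:.6f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(joined)
    newick = nodes[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    dist = np.zeros((6, 6))
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            if a != b:
                dist[a, b] = pdm.distance(taxa[na], taxa[nb])
    return newick, names, dist
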