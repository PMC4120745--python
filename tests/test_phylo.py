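import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineorf1.phylo import (Alignment, DistanceMatrix, bootstrap_support,
                            delineate_subgroups, distance_matrix,
                            fitch_parsimony, neighbor_joining,
                            pairwise_identity)


class TestPairwiseIdentity:
    def test_identical_rows_are_100(self):
        assert pairwise_identity("MKVLLA", "MKVLLA") == 100.0

    def test_gapped_columns_excluded(self):
        assert pairwise_identity("AC-T", "AG-T") == pytest.approx(200 / 3)

    def test_all_gap_overlap_is_missing(self):
        assert pairwise_identity("A--", "-A-") is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("AA", "AAA")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from("ACDE-"), min_size=4, max_size=30))
    def test_symmetry(self, chars):
        a = "".join(chars)
        b = a[::-1]
        assert pairwise_identity(a, b) == pairwise_identity(b, a)


class TestDistanceModels:
    def test_identical_rows_give_zero_under_every_model(self):
        aln = Alignment(("a", "b"), ("MKVL", "MKVL"))
        for model in ("p", "poisson", "kimura_aa"):
            assert distance_matrix(aln, model).values[0, 1] == 0.0

    def test_poisson_closed_form_at_p_point_one(self):
        rows = ("A" * 9 + "C", "A" * 9 + "G")
        d = distance_matrix(Alignment(("a", "b"), rows), "poisson").values[0, 1]
        assert d == pytest.approx(-math.log(0.9), abs=1e-9)

    def test_corrections_are_ordered_over_the_valid_range(self):
        for p in np.linspace(0.01, 0.84, 40):
            poisson = -math.log(1 - p)
            kimura = -math.log(1 - p - 0.2 * p * p)
            assert kimura >= poisson >= p

    def test_saturated_pairs_hit_the_ceiling_and_are_flagged(self):
        rows = ("ACDEFGHIKL", "LKIHGFEDCA")  # p = 1
        dm = distance_matrix(Alignment(("a", "b"), rows), "kimura_aa", ceiling=9.0)
        assert dm.values[0, 1] == 9.0 and dm.saturated[0, 1]

    def test_undefined_pair_is_named(self):
        aln = Alignment(("a", "b", "c"), ("A-", "-A", "AA"))
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            distance_matrix(aln)


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_three_taxa_solve_the_three_point_equations(self):
        values = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), values))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.dendropy_tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_exact_on_additive_six_taxon_matrices(self, random_tree_factory, rng):
        for _ in range(10):
            true, dm = random_tree_factory(6, rng)
            est = neighbor_joining(dm)
            assert est.bipartitions() == true.bipartitions()
            pdm = est.dendropy_tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in est.dendropy_tree.taxon_namespace}
            for i, a in enumerate(dm.ids):
                for j, b in enumerate(dm.ids):
                    if i < j:
                        assert abs(pdm.distance(taxa[a], taxa[b])
                                   - dm.values[i, j]) < 1e-9

    def test_taxon_order_permutation_keeps_the_topology(self, random_tree_factory, rng):
        _, dm = random_tree_factory(8, rng)
        perm = rng.permutation(8)
        shuffled = DistanceMatrix(
            tuple(dm.ids[i] for i in perm), dm.values[np.ix_(perm, perm)]
        )
        assert neighbor_joining(dm).bipartitions() == \
            neighbor_joining(shuffled).bipartitions()


class TestBootstrap:
    def test_duplicated_signal_columns_give_full_support(self):
        # every column identical: every resample reproduces the same matrix
        col = ("A", "A", "C", "C", "G")
        rows = tuple(c * 30 for c in col)
        aln = Alignment(("a", "b", "c", "d", "e"), rows)
        tree = bootstrap_support(aln, "p", n_reps=100, seed=0)
        assert tree.supports and all(v == 100.0 for v in tree.supports.values())

    def test_supports_are_percentages_on_internal_splits_only(self, default_dataset):
        elements, _ = default_dataset
        ids = tuple(sorted(e.id for e in elements))[:12]
        by = {e.id: e for e in elements}
        aln = Alignment(ids, tuple(by[i].ape_seq for i in ids))
        tree = bootstrap_support(aln, n_reps=100, seed=0)
        n = len(ids)
        for split, support in tree.supports.items():
            assert 0.0 <= support <= 100.0
            assert 1 < len(split) < n - 1

    def test_seed_stability_within_ten_points(self, default_dataset):
        elements, _ = default_dataset
        ids = tuple(sorted(e.id for e in elements))[:12]
        by = {e.id: e for e in elements}
        aln = Alignment(ids, tuple(by[i].ape_seq + by[i].rt_seq for i in ids))
        t1 = bootstrap_support(aln, n_reps=500, seed=1)
        t2 = bootstrap_support(aln, n_reps=500, seed=2)
        for split in t1.supports:
            assert abs(t1.supports[split] - t2.supports[split]) < 10


class TestFitch:
    def test_uniform_labels_cost_nothing(self, random_tree_factory, rng):
        tree, _ = random_tree_factory(6, rng)
        assert fitch_parsimony(tree, {f"t{i}": "x" for i in range(6)}) == 0

    def test_two_monophyletic_labels_cost_one(self):
        from lineorf1.io_formats import read_newick

        tree = read_newick("(((a,b),c),((d,e),f));")
        labels = {"a": "L", "b": "L", "c": "L", "d": "R", "e": "R", "f": "R"}
        assert fitch_parsimony(tree, labels) == 1

    def test_matches_exhaustive_minimum_on_small_trees(self, random_tree_factory, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            tree, _ = random_tree_factory(n, rng)
            labels = {f"t{i}": "ABC"[int(rng.integers(0, 3))] for i in range(n)}
            assert fitch_parsimony(tree, labels) == _brute_fitch(tree, labels)

    def test_unlabeled_leaf_rejected(self, random_tree_factory, rng):
        tree, _ = random_tree_factory(5, rng)
        with pytest.raises(ValueError, match="unlabeled"):
            fitch_parsimony(tree, {"t0": "x"})


def _brute_fitch(tree, labels):
    states = sorted(set(labels.values()))
    internals = [nd for nd in tree.dendropy_tree.postorder_node_iter()
                 if not nd.is_leaf()]
    best = math.inf
    for assign in itertools.product(states, repeat=len(internals)):
        amap = dict(zip(internals, assign))
        cost = 0
        for nd in tree.dendropy_tree.postorder_node_iter():
            if nd.parent_node is None:
                continue
            s1 = labels[nd.taxon.label] if nd.is_leaf() else amap[nd]
            cost += s1 != amap[nd.parent_node]
        best = min(best, cost)
    return best


class TestDelineation:
    def _tree_and_types(self, seed=21):
        from lineorf1.architecture import classify_orf1, architecture_from_hits
        from lineorf1.domain_scan import annotate_orf1
        from lineorf1.profiles import default_library
        from lineorf1.synthetic import SimulationConfig, generate_dataset

        cfg = SimulationConfig(seed=seed, phd_gain_rate=0, phd_loss_rate=0,
                               esterase_gain_rate=0)
        elements, truth = generate_dataset(cfg)
        library = default_library()
        types = {}
        for e in elements:
            hits = annotate_orf1(e.orf1_seq, library, seed=seed)
            types[e.id] = classify_orf1(architecture_from_hits(hits, len(e.orf1_seq)))
        ids = tuple(sorted(e.id for e in elements))
        by = {e.id: e for e in elements}
        aln = Alignment(ids, tuple(by[i].ape_seq + by[i].rt_seq for i in ids))
        tree = bootstrap_support(aln, n_reps=100, seed=seed)
        return tree, types, truth

    def test_congruent_simulation_recovers_the_lineages(self):
        tree, types, truth = self._tree_and_types()
        groups = delineate_subgroups(tree, types, support_floor=70)
        lineage_sets = {
            frozenset(lf for lf, lin in truth.true_lineages.items() if lin == name)
            for name in ("CR1", "L2", "Jockey")
        }
        assert set(groups) == lineage_sets

    def test_unreachable_floor_gives_singletons(self):
        tree, types, _ = self._tree_and_types()
        groups = delineate_subgroups(tree, types, support_floor=101)
        assert all(len(g) == 1 for g in groups)

    def test_merge_flag_pools_only_same_type_groups(self):
        tree, types, truth = self._tree_and_types()
        plain = delineate_subgroups(tree, types, support_floor=70)
        merged = delineate_subgroups(tree, types, support_floor=70,
                                     merge_same_type=True)
        # all three lineages carry distinct types, so merging changes nothing
        assert set(plain) == set(merged)
        # force two non-sister clades onto one type: they must now merge
        forced = dict(types)
        sample_cr1 = next(lf for lf in forced if lf.startswith("CR1"))
        target = forced[next(lf for lf in forced if lf.startswith("Jockey"))]
        for lf in forced:
            if lf.startswith("CR1"):
                forced[lf] = target
        plain_f = delineate_subgroups(tree, forced, support_floor=70)
        merged_f = delineate_subgroups(tree, forced, support_floor=70,
                                       merge_same_type=True)
        assert len(merged_f) < len(plain_f)
        assert any(lf.startswith("Jockey") and sample_cr1 in g
                   for g in merged_f for lf in g)
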