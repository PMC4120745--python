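import numpy as np
import pytest

from lineorf1.congruence import (build_orf1_tree, detect_embeddings,
                                 permutation_test)
from lineorf1.io_formats import Element, read_newick
from lineorf1.synthetic import (SimulationConfig, generate_dataset,
                                propose_ht_event, simulate_lineage_tree)


def _labels(tree, mapping):
    return {leaf: mapping(leaf) for leaf in tree.leaf_ids}


class TestDetectEmbeddings:
    def test_identical_trees_yield_no_candidates(self):
        nwk = "(((a1:1,a2:1):1,(a3:1,a4:1):1):2,((b1:1,b2:1):1,(b3:1,b4:1):1):2);"
        t1, t2 = read_newick(nwk), read_newick(nwk)
        labels = _labels(t1, lambda lf: lf[0].upper())
        assert detect_embeddings(t1, t2, labels) == []

    def test_two_position_embedding_reported_once(self):
        # ORF2: CR1 and L2 each monophyletic. ORF1: the four CR1 leaves sit
        # as two separate cherries inside the L2 clade.
        orf2 = read_newick(
            "(((c1:1,c2:1):1,(c3:1,c4:1):1):2,"
            "((l1:1,l2:1):1,((l3:1,l4:1):1,((l5:1,l6:1):1,(l7:1,l8:1):1):1):1):2);"
        )
        orf1 = read_newick(
            "((l1:1,l2:1):2,(((c1:1,c2:1):1,(l3:1,l4:1):1):1,"
            "((c3:1,c4:1):1,((l5:1,l6:1):1,(l7:1,l8:1):1):1):1):2);"
        )
        labels = _labels(orf2, lambda lf: "CR1" if lf.startswith("c") else "L2")
        candidates = detect_embeddings(orf2, orf1, labels)
        assert len(candidates) == 1
        (cand,) = candidates
        assert cand.focal_lineage == "CR1" and cand.host_lineage == "L2"
        assert cand.focal_leaves == frozenset({"c1", "c2", "c3", "c4"})
        assert cand.n_embedding_positions == 2
        assert cand.delta_fitch > 0

    def test_leaf_set_mismatch_lists_offenders(self):
        t1 = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = read_newick("((a:1,b:1):1,(c:1,e:1):1);")
        with pytest.raises(ValueError, match="only-in-ORF2=\\['d'\\]"):
            detect_embeddings(t1, t2, {x: "L" for x in "abcde"})

    def test_simulated_transfer_recovers_the_recipient_set(self):
        cfg0 = SimulationConfig(seed=23)
        tree, _ = simulate_lineage_tree(cfg0)
        event = propose_ht_event(tree, "CR1", "L2")
        cfg = SimulationConfig(seed=23, ht_events=(event,))
        elements, truth = generate_dataset(cfg)
        orf1 = build_orf1_tree(elements, "rrm_cchc_block", n_boot=0, seed=23)
        shared = set(orf1.leaf_ids)
        from lineorf1.phylo import Alignment, distance_matrix, neighbor_joining

        by = {e.id: e for e in elements}
        ids = tuple(sorted(shared))
        orf2 = neighbor_joining(distance_matrix(Alignment(
            ids, tuple(by[i].ape_seq + by[i].rt_seq for i in ids))))
        labels = {i: truth.true_lineages[i] for i in ids}
        candidates = detect_embeddings(orf2, orf1, labels)
        assert len(candidates) == 1
        assert candidates[0].focal_leaves == frozenset(event.recipient_leaves)
        # the diagnostic pattern: monophyletic in ORF2, broken into the host
        assert orf2.is_monophyletic(candidates[0].focal_leaves)


class TestPermutationTest:
    def test_single_focal_leaf_is_never_significant(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);")
        labels = {lf: ("X" if lf == "a" else "Y") for lf in tree.leaf_ids}
        assert permutation_test(tree, labels, "X", n_perm=99, seed=0) == 1.0

    def test_perfect_clade_of_ten_in_forty_is_significant(self):
        from lineorf1.synthetic import simulate_yule_tree
        import dendropy

        tree = simulate_yule_tree(40, seed=6)
        # label a true 10-leaf-ish clade as focal
        best = None
        for node in tree.dendropy_tree.postorder_internal_node_iter():
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            if best is None or abs(len(leaves) - 10) < abs(len(best) - 10):
                best = leaves
        labels = {lf: ("F" if lf in set(best) else "R") for lf in tree.leaf_ids}
        p = permutation_test(tree, labels, "F", n_perm=999, seed=0)
        assert p <= 0.05

    def test_random_labels_give_calibrated_p_values(self):
        # p should be roughly uniform: check mean and spread over 60 reps
        from lineorf1.synthetic import simulate_yule_tree

        tree = simulate_yule_tree(16, seed=8)
        rng = np.random.default_rng(0)
        ps = []
        for k in range(60):
            perm = rng.permutation(16)
            labels = {lf: ("F" if perm[i] < 5 else "R")
                      for i, lf in enumerate(tree.leaf_ids)}
            ps.append(permutation_test(tree, labels, "F", n_perm=199, seed=k))
        assert 0.3 < np.mean(ps) < 0.75
        assert sum(p <= 0.2 for p in ps) < 30

    def test_absent_focal_lineage_rejected(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="absent"):
            permutation_test(tree, {x: "Y" for x in "abcd"}, "X", n_perm=99)


class TestBuildOrf1Tree:
    def test_identical_blocks_give_star_tree(self, library_by_name, rng):
        from tests.conftest import random_protein

        rrm, cchc = library_by_name["RRM"], library_by_name["CCHC"]
        orf1 = (random_protein(rng, 10) + rrm.consensus + "G" * 8
                + cchc.consensus + random_protein(rng, 10))
        elements = [Element(id=f"e{i}", orf1_seq=orf1, ape_seq="M" * 10,
                            rt_seq="K" * 10, lineage="L2") for i in range(4)]
        tree = build_orf1_tree(elements, "rrm_cchc_block", n_boot=0, seed=0)
        assert set(tree.leaf_ids) == {f"e{i}" for i in range(4)}
        internal = [nd.edge.length for nd in tree.dendropy_tree
                    if nd.parent_node is not None and not nd.is_leaf()]
        assert all(length == 0 for length in internal)

    def test_no_transfer_dataset_keeps_lineages_monophyletic(self):
        # all lineages share the full block so the ORF1 tree covers everyone
        arch = ("RRM", "RRM", "CCHC", "CCHC", "CCHC")
        cfg = SimulationConfig(seed=31, phd_gain_rate=0, phd_loss_rate=0,
                               esterase_gain_rate=0,
                               root_architectures={"CR1": arch, "L2": arch,
                                                   "Jockey": arch})
        elements, truth = generate_dataset(cfg)
        tree = build_orf1_tree(elements, "rrm_cchc_block", n_boot=0, seed=31)
        for lineage in ("CR1", "L2", "Jockey"):
            members = [lf for lf in tree.leaf_ids
                       if truth.true_lineages[lf] == lineage]
            assert tree.is_monophyletic(members)

    def test_element_lacking_the_region_is_excluded(self):
        cfg = SimulationConfig(seed=17)
        elements, truth = generate_dataset(cfg)
        tree = build_orf1_tree(elements, "rrm_cchc_block", n_boot=0, seed=17)
        # the default CR1 background (PHD+RRM) has no CCHC: never in the tree
        assert not any(lf.startswith("CR1") for lf in tree.leaf_ids)

    def test_full_orf1_region_uses_raw_sequences(self):
        arch = ("RRM", "CCHC")
        cfg = SimulationConfig(seed=19, phd_gain_rate=0, phd_loss_rate=0,
                               esterase_gain_rate=0,
                               root_architectures={"CR1": arch, "L2": arch,
                                                   "Jockey": arch})
        elements, _ = generate_dataset(cfg)
        tree = build_orf1_tree(elements, "full_orf1", n_boot=0, seed=19)
        assert len(tree.leaf_ids) == len(elements)
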