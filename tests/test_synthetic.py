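import math

import numpy as np
import pytest

from lineorf1.architecture import Architecture, classify_orf1
from lineorf1.phylo import pairwise_identity
from lineorf1.synthetic import (HtEvent, SimulationConfig, evolve_architecture,
                                evolve_protein, generate_dataset,
                                propose_ht_event, replay_events,
                                simulate_lineage_tree, simulate_yule_tree)


class TestYule:
    def test_two_taxa_make_a_cherry(self):
        tree = simulate_yule_tree(2, seed=0)
        assert len(tree.leaf_ids) == 2
        assert tree.bipartitions() == frozenset()

    def test_same_seed_reproduces_the_newick(self):
        assert simulate_yule_tree(15, seed=9).to_newick() == \
            simulate_yule_tree(15, seed=9).to_newick()

    def test_lineage_growth_matches_the_pure_birth_expectation(self):
        # started from two lineages: E[N(t)] = 2 e^{rate t}
        rate, t_obs, reps = 1.0, 1.25, 400
        counts = []
        for seed in range(reps):
            tree = simulate_yule_tree(64, yule_rate=rate, seed=seed)
            depths = {}
            n_at_t = 0
            for node in tree.dendropy_tree.preorder_node_iter():
                if node.parent_node is None:
                    depths[node] = 0.0
                    continue
                depths[node] = depths[node.parent_node] + node.edge.length
                if depths[node] >= t_obs > depths[node.parent_node]:
                    n_at_t += 1
            counts.append(n_at_t)
        expected = 2 * math.exp(rate * t_obs)
        assert abs(np.mean(counts) - expected) / expected < 0.10


class TestEvolveProtein:
    def test_zero_rate_copies_the_root_everywhere(self):
        tree = simulate_yule_tree(8, seed=1)
        leaves = evolve_protein(tree, "MKVLLAGHE" * 10, 0.0, seed=1)
        assert set(leaves.values()) == {"MKVLLAGHE" * 10}

    def test_single_branch_divergence_matches_the_markov_closed_form(self):
        # P(site differs after time t) = (19/20) (1 - e^{-(20/19) r t})
        from lineorf1.io_formats import AA_LETTERS
        from lineorf1.phylo import PhyloTree
        import dendropy

        rng = np.random.default_rng(2)
        root = "".join(AA_LETTERS[i] for i in rng.integers(0, 20, 10000))
        t, rate = 2.0, 0.1
        nwk = f"(x:{t},y:0.0);"
        tree = PhyloTree(dendropy.Tree.get(data=nwk, schema="newick"))
        leaves = evolve_protein(tree, root, rate, seed=2)
        observed = sum(a != b for a, b in zip(leaves["x"], root)) / len(root)
        expected = (19 / 20) * (1 - math.exp(-(20 / 19) * rate * t))
        assert abs(observed - expected) < 3 * math.sqrt(expected * (1 - expected) / 10000) + 0.003

    def test_sisters_resemble_each_other_more_than_non_sisters(self):
        closer = 0
        for seed in range(20):
            tree = simulate_yule_tree(6, seed=seed)
            leaves = evolve_protein(tree, "ACDEFGHIKLMNPQRSTVWY" * 15, 0.1,
                                    seed=seed)
            # find one cherry
            cherry = None
            for node in tree.dendropy_tree.postorder_internal_node_iter():
                kids = node.child_nodes()
                if len(kids) == 2 and all(k.is_leaf() for k in kids):
                    cherry = [k.taxon.label for k in kids]
                    break
            if cherry is None:
                continue
            a, b = cherry
            other = next(lf for lf in leaves if lf not in cherry)
            sister_id = pairwise_identity(leaves[a], leaves[b])
            outer_id = pairwise_identity(leaves[a], leaves[other])
            closer += sister_id >= outer_id
        assert closer >= 16  # sisters win in the large majority of replicates


class TestEvolveArchitecture:
    def test_zero_rates_keep_the_root_architectures(self):
        cfg = SimulationConfig(seed=5, phd_gain_rate=0, phd_loss_rate=0,
                               esterase_gain_rate=0)
        tree, lineages = simulate_lineage_tree(cfg)
        truth = evolve_architecture(tree, cfg, lineages)
        archs = cfg.architectures()
        for leaf, got in truth.true_architectures.items():
            assert got == archs[truth.true_lineages[leaf]]
        assert truth.event_log == []

    def test_high_gain_rate_creates_phd_bearing_variants(self):
        cfg = SimulationConfig(seed=5, phd_gain_rate=3.0, phd_loss_rate=0,
                               esterase_gain_rate=0)
        tree, lineages = simulate_lineage_tree(cfg)
        truth = evolve_architecture(tree, cfg, lineages)
        with_phd = [leaf for leaf, a in truth.true_architectures.items()
                    if "PHD" in a]
        assert len(with_phd) > len(truth.true_architectures) // 2
        for leaf in with_phd:
            label = classify_orf1(
                Architecture(truth.true_architectures[leaf], 0.5)).label
            assert label in {"IC", "IIB", "IIC", "IIIA", "IIIB"}

    def test_explicit_transfer_copies_the_donor_architecture_only(self):
        cfg0 = SimulationConfig(seed=13)
        tree, _ = simulate_lineage_tree(cfg0)
        event = propose_ht_event(tree, "CR1", "L2")
        cfg = SimulationConfig(seed=13, ht_events=(event,),
                               phd_gain_rate=0, phd_loss_rate=0,
                               esterase_gain_rate=0)
        elements, truth = generate_dataset(cfg)
        base = SimulationConfig(seed=13, phd_gain_rate=0, phd_loss_rate=0,
                                esterase_gain_rate=0)
        baseline, _ = generate_dataset(base)
        base_by = {e.id: e for e in baseline}
        donor_arch = cfg.architectures()["L2"]
        for e in elements:
            if e.id in event.recipient_leaves:
                assert truth.true_architectures[e.id] == donor_arch
            # ORF2 untouched by the transfer
            assert e.ape_seq == base_by[e.id].ape_seq
            assert e.rt_seq == base_by[e.id].rt_seq

    def test_recipient_not_in_tree_rejected(self):
        cfg = SimulationConfig(
            seed=1, ht_events=(HtEvent(("nope-01", "nope-02"), "L2"),)
        )
        with pytest.raises(ValueError, match="not in tree"):
            generate_dataset(cfg)

    def test_event_log_replay_reproduces_leaf_architectures(self):
        cfg = SimulationConfig(seed=37, phd_gain_rate=0.3, phd_loss_rate=0.3,
                               esterase_gain_rate=0.1)
        elements, truth = generate_dataset(cfg)
        replayed = replay_events(truth.true_tree, cfg, truth.event_log)
        assert replayed == truth.true_architectures
        assert truth.event_log  # rates high enough that something happened


class TestGenerateDataset:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=8)
        generate_dataset(cfg, outdir=tmp_path / "a")
        generate_dataset(cfg, outdir=tmp_path / "b")
        for name in ("orf1.fasta", "ape.fasta", "rt.fasta", "true_tree.nwk",
                     "true_lineages.tsv", "true_architectures.tsv",
                     "events.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_no_transfer_control_yields_no_candidates(self, default_dataset):
        from lineorf1.congruence import build_orf1_tree, detect_embeddings
        from lineorf1.phylo import Alignment, distance_matrix, neighbor_joining

        elements, truth = default_dataset
        orf1 = build_orf1_tree(elements, "rrm_cchc_block", n_boot=0, seed=11)
        shared = sorted(set(orf1.leaf_ids))
        by = {e.id: e for e in elements}
        orf2 = neighbor_joining(distance_matrix(Alignment(
            tuple(shared), tuple(by[i].ape_seq + by[i].rt_seq for i in shared))))
        labels = {i: truth.true_lineages[i] for i in shared}
        assert detect_embeddings(orf2, orf1, labels) == []

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=2, n_lineages=3)
        with pytest.raises(ValueError):
            SimulationConfig(subst_rate=-0.1)
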