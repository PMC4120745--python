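"""Detect a horizontally acquired ORF1 from ORF1/ORF2 tree incongruence.

Simulates 20 elements in three lineages and injects one whole-ORF1
transfer from the L2 lineage (type IB donor, carrying the 2xRRM + 3xCCHC
block) into a clade of CR1 recipients. The ORF2 (APE+RT) tree keeps the
recipients inside their CR1 lineage, but their ORF1s nest inside the L2
clade of the RRM+CCHC-block tree — the diagnostic embedding pattern. The
permutation p-value quantifies how unusually clustered the recipients'
ORF1s are; it is an invented statistic, not part of the original visual
inference.
"""
from lineorf1.congruence import build_orf1_tree, detect_embeddings
from lineorf1.domain_scan import annotate_orf1
from lineorf1.phylo import Alignment, distance_matrix, neighbor_joining
from lineorf1.profiles import default_library
from lineorf1.synthetic import (SimulationConfig, generate_dataset,
                                propose_ht_event, simulate_lineage_tree)

seed = 23
tree, _ = simulate_lineage_tree(SimulationConfig(seed=seed))
event = propose_ht_event(tree, recipient_lineage="CR1", donor_lineage="L2")
print(f"injected transfer: L2 ORF1 -> CR1 clade {sorted(event.recipient_leaves)}")

elements, truth = generate_dataset(SimulationConfig(seed=seed, ht_events=(event,)))
library = default_library()
annotations = {e.id: annotate_orf1(e.orf1_seq, library, seed=seed)
               for e in elements}

orf1_tree = build_orf1_tree(elements, "rrm_cchc_block", n_boot=0, seed=seed,
                            annotations=annotations)
shared = sorted(orf1_tree.leaf_ids)
by = {e.id: e for e in elements}
orf2_tree = neighbor_joining(distance_matrix(Alignment(
    tuple(shared), tuple(by[i].ape_seq + by[i].rt_seq for i in shared))))

labels = {i: truth.true_lineages[i] for i in shared}
candidates = detect_embeddings(orf2_tree, orf1_tree, labels,
                               n_perm=999, seed=seed)
print(f"elements carrying the RRM+CCHC block: {len(shared)}")
for c in candidates:
    print(f"candidate: {c.focal_lineage} ORF1s embedded in {c.host_lineage}")
    print(f"  recipients: {','.join(sorted(c.focal_leaves))}")
    print(f"  embedding positions: {c.n_embedding_positions}")
    print(f"  delta Fitch (ORF1 vs ORF2 label changes): {c.delta_fitch}")
    print(f"  permutation p: {c.permutation_p}")
recovered = candidates and candidates[0].focal_leaves == frozenset(event.recipient_leaves)
print(f"ground-truth recipient set recovered exactly: {bool(recovered)}")
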