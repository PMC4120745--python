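"""Horizontal ORF1 acquisition from ORF1/ORF2 tree incongruence.

The ORF2 (APE+RT) tree defines lineages; a lineage that is monophyletic
there but whose ORF1 sequences nest inside another lineage's clade of the
ORF1 tree is reported as a transfer candidate, echoing the diagnostic
pattern of a foreign subgroup embedded within a host subgroup's ORF1
phylogeny. The accompanying permutation test quantifies how unusually
clustered the focal leaves are on the ORF1 tree; it is an invented
quantification of what is otherwise a visual inference, and reports label
it as such.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .domain_scan import annotate_orf1
from .io_formats import Element
from .phylo import (Alignment, PhyloTree, bootstrap_support, canonical_split,
                    distance_matrix, fitch_parsimony, neighbor_joining)

log = logging.getLogger(__name__)

DEFAULT_FOREIGN_MAJORITY = 0.5


@dataclass(frozen=True)
class TransferCandidate:
    """A lineage monophyletic on the ORF2 tree but embedded in a
    foreign-lineage context on the ORF1 tree."""

    focal_leaves: frozenset
    focal_lineage: str
    host_lineage: str
    n_embedding_positions: int
    delta_fitch: int
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        if self.focal_lineage == self.host_lineage:
            raise ValueError("focal and host lineages must differ")
        if self.n_embedding_positions < 1:
            raise ValueError("n_embedding_positions must be >= 1")


def _smallest_containing_side(tree: PhyloTree, focal: frozenset) -> frozenset:
    """Smallest proper bipartition side strictly containing ``focal``.

    Rooting-free: every edge of the unrooted tree contributes both of its
    sides. Falls back to the full leaf set when no proper side qualifies.
    """
    all_leaves = frozenset(tree.leaf_ids)
    best = all_leaves
    for leaves in tree._leafsets().values():
        for side in (leaves, all_leaves - leaves):
            if not focal < side < all_leaves:
                continue
            if len(side) < len(best) or (
                len(side) == len(best)
                and tuple(sorted(side)) < tuple(sorted(best))
            ):
                best = side
    return best


def detect_embeddings(orf2_tree: PhyloTree, orf1_tree: PhyloTree,
                      labels: Mapping[str, str], *,
                      foreign_majority: float = DEFAULT_FOREIGN_MAJORITY,
                      n_perm: int = 0, seed: int = 0) -> list[TransferCandidate]:
    """Find lineages whose ORF1s sit inside a foreign lineage's clade.

    For each lineage monophyletic in the ORF2 tree, the smallest ORF1-tree
    bipartition side strictly containing all focal leaves supplies the
    surrounding context: a candidate is emitted when more than
    ``foreign_majority`` of the context's other leaves carry one single
    different label H, those context leaves are a *proper subset* of
    lineage H (the focal ORF1s sit strictly inside the host's diversity,
    not merely sister to the whole of it), H is monophyletic in the ORF2
    tree, and the focal leaves are the minority partner. All statistics are
    computed on unrooted bipartitions, so no rooting artifact can create or
    hide a candidate; identical trees yield no candidates (there the
    context is always an entire sister clade, never part of one).
    ``n_embedding_positions`` is the number of maximal focal-only clades
    (the binary Fitch score of focal-versus-rest).

    With ``n_perm`` > 0 each candidate carries a permutation p-value.
    """
    leaves2, leaves1 = set(orf2_tree.leaf_ids), set(orf1_tree.leaf_ids)
    if leaves2 != leaves1:
        raise ValueError(
            "leaf-set mismatch between trees: "
            f"only-in-ORF2={sorted(leaves2 - leaves1)} "
            f"only-in-ORF1={sorted(leaves1 - leaves2)}"
        )
    missing = sorted(leaves2 - set(labels))
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")

    delta = fitch_parsimony(orf1_tree, labels) - fitch_parsimony(orf2_tree, labels)
    candidates: list[TransferCandidate] = []
    lineages = sorted({labels[lf] for lf in leaves2})
    members = {lin: frozenset(lf for lf in leaves2 if labels[lf] == lin)
               for lin in lineages}
    for lineage in lineages:
        focal = members[lineage]
        if len(focal) < 2 or len(focal) == len(leaves2):
            continue
        if not orf2_tree.is_monophyletic(focal):
            continue
        side = _smallest_containing_side(orf1_tree, focal)
        others = side - focal
        if not others:
            continue
        tally = Counter(labels[lf] for lf in others)
        host, host_n = tally.most_common(1)[0]
        if host == lineage or host_n / len(others) <= foreign_majority:
            continue
        host_all = members[host]
        if len(focal) >= len(host_all):
            continue  # the embedded partner is the minority by definition
        if not orf2_tree.is_monophyletic(host_all):
            continue
        if not others < host_all:
            continue  # context is a whole sister clade, not part of the host
        binary = {lf: ("f" if lf in focal else "r") for lf in leaves2}
        positions = fitch_parsimony(orf1_tree, binary)
        p_value = None
        if n_perm > 0:
            p_value = permutation_test(orf1_tree, labels, lineage,
                                       n_perm=n_perm, seed=seed)
        candidates.append(
            TransferCandidate(
                focal_leaves=focal,
                focal_lineage=lineage,
                host_lineage=host,
                n_embedding_positions=positions,
                delta_fitch=delta,
                permutation_p=p_value,
            )
        )
    return candidates


def permutation_test(orf1_tree: PhyloTree, labels: Mapping[str, str],
                     focal_lineage: str, n_perm: int = 999,
                     seed: int = 0) -> float:
    """Permutation p-value for clustering of a lineage on the ORF1 tree.

    Statistic: Fitch score of the binary focal-versus-rest labeling. The
    p-value is (1 + #{permutations with statistic <= observed}) /
    (n_perm + 1) over uniform reshuffles of the leaf labels.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    leaf_ids = list(orf1_tree.leaf_ids)
    binary = {lf: ("focal" if labels[lf] == focal_lineage else "rest")
              for lf in leaf_ids}
    if "focal" not in binary.values():
        raise ValueError(f"focal lineage {focal_lineage!r} absent from labels")
    observed = fitch_parsimony(orf1_tree, binary)
    values = [binary[lf] for lf in leaf_ids]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        shuffled = {lf: values[perm[i]] for i, lf in enumerate(leaf_ids)}
        hits += fitch_parsimony(orf1_tree, shuffled) <= observed
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# ORF1-region trees
# ---------------------------------------------------------------------------

def _rrm_cchc_block(element: Element, hits) -> str | None:
    """Span from the first accepted RRM through the last accepted CCHC."""
    accepted = [h for h in hits if h.accepted]
    rrms = [h for h in accepted if h.domain == "RRM"]
    cchcs = [h for h in accepted if h.domain == "CCHC"]
    if not rrms or not cchcs:
        return None
    start = min(h.start for h in rrms)
    end = max(h.end for h in cchcs)
    if end <= start:
        return None
    return element.orf1_seq[start:end]


def build_orf1_tree(elements: Sequence[Element], region: str = "rrm_cchc_block",
                    model: str = "kimura_aa", n_boot: int = 1000,
                    seed: int = 0, *, annotations: Mapping[str, list] | None = None,
                    library=None, accept_threshold: float = 85.0) -> PhyloTree:
    """Neighbor-joining tree of an extracted ORF1 region.

    ``region`` is ``full_orf1`` or ``rrm_cchc_block`` (the span covering the
    RRM and CCHC domains, annotated on the fly unless ``annotations`` are
    supplied). Elements lacking the region, or whose extracted block length
    disagrees with the majority (the no-indel, positionally homologous
    alignment convention), are excluded with a logged warning. Bootstrap
    supports are attached when ``n_boot`` >= 1.
    """
    if region not in ("full_orf1", "rrm_cchc_block"):
        raise ValueError(f"unknown region {region!r}")
    extracted: dict[str, str] = {}
    for el in elements:
        if region == "full_orf1":
            block = el.orf1_seq or None
        else:
            if annotations is not None:
                hits = annotations.get(el.id, [])
            else:
                if library is None:
                    from .profiles import default_library
                    library = default_library()
                hits = (annotate_orf1(el.orf1_seq, library, accept_threshold,
                                      seed=seed)
                        if el.orf1_seq else [])
            block = _rrm_cchc_block(el, hits)
        if not block:
            log.warning("element %s lacks the %s region; excluded", el.id, region)
            continue
        extracted[el.id] = block

    lengths = Counter(len(s) for s in extracted.values())
    if not lengths:
        raise ValueError(f"no element carries the {region} region")
    modal_len = max(lengths.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    for eid in sorted(extracted):
        if len(extracted[eid]) != modal_len:
            log.warning(
                "element %s: %s length %d != modal %d; excluded from alignment",
                eid, region, len(extracted[eid]), modal_len,
            )
            del extracted[eid]
    ids = tuple(sorted(extracted))
    if len(ids) < 3:
        raise ValueError(f"fewer than 3 elements carry the {region} region")
    aln = Alignment(ids, tuple(extracted[i] for i in ids))
    if n_boot >= 1:
        return bootstrap_support(aln, model, n_reps=n_boot, seed=seed)
    return neighbor_joining(distance_matrix(aln, model))
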