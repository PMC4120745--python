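"""Distance phylogenetics on the concatenated APE+RT alignment.

Pairwise-deletion identities, correction models (p, Poisson, Kimura
amino-acid), Saitou-Nei neighbor joining with fixed tie-breaking, bootstrap
bipartition supports, Fitch/Hartigan small parsimony, and support-guided
subgroup delineation. Trees are unrooted; midpoint rooting is used for
display and nesting queries only.

The Kimura correction d = -ln(1 - p - 0.2 p^2) is the default surrogate for
maximum-likelihood JTT distances: closed-form, monotone in p, and adequate
for topology at the divergences handled here.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import NewickParseError

DISTANCE_MODELS = ("p", "poisson", "kimura_aa")
DEFAULT_CEILING = 10.0

# p at which 1 - p - 0.2 p^2 hits zero (Kimura saturation)
_KIMURA_SAT = (math.sqrt(1.8) - 1.0) / 0.4


def canonical_split(side, all_leaves: frozenset) -> frozenset:
    """Orientation-free key for a bipartition: the side holding min(leaves)."""
    side = frozenset(side)
    ref = min(all_leaves)
    return side if ref in side else frozenset(all_leaves - side)


class PhyloTree:
    """An unrooted weighted tree with percent supports per internal bipartition.

    Thin wrapper over a :class:`dendropy.Tree`; supports are stored keyed by
    canonical bipartition so they survive any rerooting.
    """

    def __init__(self, tree: dendropy.Tree,
                 supports: Mapping[frozenset, float] | None = None):
        self._tree = tree
        self.supports: dict[frozenset, float] = dict(supports or {})

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(sorted(lf.taxon.label for lf in self._tree.leaf_node_iter()))

    def __len__(self) -> int:
        return len(self.leaf_ids)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several tokenizer errors
            raise NewickParseError(f"newick parse failed: {exc}") from exc
        out = cls(tree)
        all_leaves = frozenset(out.leaf_ids)
        for node, leaves in out._leafsets().items():
            if node.is_leaf() or node.label is None:
                continue
            try:
                value = float(node.label)
            except ValueError:
                continue
            if 1 < len(leaves) < len(all_leaves):
                out.supports[canonical_split(leaves, all_leaves)] = value
        return out

    def to_newick(self) -> str:
        all_leaves = frozenset(self.leaf_ids)
        leafsets = self._leafsets()

        def fmt(node) -> str:
            if node.is_leaf():
                body = node.taxon.label
            else:
                body = "(" + ",".join(fmt(c) for c in node.child_nodes()) + ")"
                leaves = leafsets[node]
                if 1 < len(leaves) < len(all_leaves):
                    sup = self.supports.get(canonical_split(leaves, all_leaves))
                    if sup is not None:
                        body += str(int(round(sup)))
            length = node.edge.length
            if length is not None and node.parent_node is not None:
                body += f":{length:.12g}"
            return body

        return fmt(self._tree.seed_node) + ";"

    # -- topology queries ----------------------------------------------------

    def _leafsets(self) -> dict:
        sets: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                sets[node] = frozenset([node.taxon.label])
            else:
                sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
        return sets

    def bipartitions(self) -> frozenset:
        """Canonical nontrivial bipartitions (internal edges only)."""
        all_leaves = frozenset(self.leaf_ids)
        out = set()
        for node, leaves in self._leafsets().items():
            if node.parent_node is None:
                continue
            if 1 < len(leaves) < len(all_leaves) - 1:
                out.add(canonical_split(leaves, all_leaves))
        return frozenset(out)

    def support_for(self, leaves) -> float | None:
        """Bootstrap support of the bipartition separating ``leaves`` from
        the rest, or ``None`` if that split is absent/trivial."""
        return self.supports.get(
            canonical_split(frozenset(leaves), frozenset(self.leaf_ids))
        )

    def is_monophyletic(self, leaves) -> bool:
        """Whether a leaf set forms one side of a bipartition (unrooted)."""
        leaves = frozenset(leaves)
        n = len(self.leaf_ids)
        if not leaves <= set(self.leaf_ids):
            raise ValueError("leaf set not contained in the tree")
        if len(leaves) in (1, n - 1, n):
            return True
        return canonical_split(leaves, frozenset(self.leaf_ids)) in self.bipartitions()

    def midpoint_rooted(self) -> "PhyloTree":
        clone = self._tree.clone(depth=1)
        lengths = [e.length or 0.0 for e in clone.edges()]
        if sum(lengths) > 0:
            clone.reroot_at_midpoint(update_bipartitions=False)
        rooted = PhyloTree(clone, self.supports)
        if rooted.leaf_ids != self.leaf_ids:  # degenerate rooting: keep as-is
            rooted = PhyloTree(self._tree.clone(depth=1), self.supports)
        return rooted

    def restricted(self, leaves) -> "PhyloTree":
        """Copy of the tree pruned to a leaf subset (supports dropped,
        since they are keyed to the full leaf set)."""
        keep = set(leaves)
        missing = keep - set(self.leaf_ids)
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")
        clone = self._tree.extract_tree_with_taxa_labels(labels=keep)
        clone.is_rooted = self._tree.is_rooted
        return PhyloTree(clone)


# ---------------------------------------------------------------------------
# Alignments and distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows; ``region_map`` labels column blocks
    (e.g. APE then RT in a concatenated alignment)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    region_map: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate alignment ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def region(self, label: str) -> "Alignment":
        if not self.region_map or label not in self.region_map:
            raise KeyError(f"no region {label!r}")
        s, e = self.region_map[label]
        return Alignment(self.ids, tuple(r[s:e] for r in self.rows))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")


def pairwise_identity(a: str, b: str) -> float | None:
    """Percent identity under pairwise deletion; ``None`` if no compared
    columns remain (all-gap overlap)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch {len(a)} vs {len(b)}")
    compared = matches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        matches += x == y
    if compared == 0:
        return None
    return 100.0 * matches / compared


def _encode_alignment(aln: Alignment) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate("ACDEFGHIKLMNPQRSTVWYX"):
        table[ord(ch)] = i
    mat = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8)
    codes = table[mat].reshape(len(aln.rows), aln.n_columns)
    return codes


def _p_from_codes(codes: np.ndarray, cols: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    sub = codes if cols is None else codes[:, cols]
    valid = (sub[:, None, :] >= 0) & (sub[None, :, :] >= 0)
    eq = (sub[:, None, :] == sub[None, :, :]) & valid
    n_valid = valid.sum(axis=2)
    n_match = eq.sum(axis=2)
    with np.errstate(invalid="ignore"):
        p = 1.0 - n_match / n_valid
    return p, n_valid


def _correct(p: np.ndarray, model: str, ceiling: float
             ) -> tuple[np.ndarray, np.ndarray]:
    if model == "p":
        return p.copy(), np.zeros_like(p, dtype=bool)
    if model == "poisson":
        sat = p >= 1.0
        arg = np.where(sat, 0.5, 1.0 - p)
        return np.where(sat, ceiling, -np.log(arg)), sat
    if model == "kimura_aa":
        arg = 1.0 - p - 0.2 * p * p
        sat = arg <= 0.0
        return np.where(sat, ceiling, -np.log(np.where(sat, 0.5, arg))), sat
    raise ValueError(f"unknown distance model {model!r} (use {DISTANCE_MODELS})")


def distance_matrix(aln: Alignment, model: str = "kimura_aa",
                    ceiling: float = DEFAULT_CEILING) -> DistanceMatrix:
    """Pairwise corrected distances; saturated pairs are set to the ceiling
    and flagged."""
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 rows")
    codes = _encode_alignment(aln)
    p, n_valid = _p_from_codes(codes)
    bad = np.argwhere((n_valid == 0) & ~np.eye(len(aln.ids), dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"pairwise identity undefined for ({aln.ids[i]}, {aln.ids[j]}): "
            "no shared ungapped columns"
        )
    d, sat = _correct(p, model, ceiling)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(sat, False)
    d = (d + d.T) / 2.0
    return DistanceMatrix(tuple(aln.ids), d, sat)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration with the standard Q-criterion.

    Ties on Q are broken by the smallest lexicographic pair of cluster
    representatives (a cluster is represented by its smallest leaf id);
    negative branch-length estimates are clamped to zero. Exact on additive
    matrices. The result is unrooted with a trifurcating seed node.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.values
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in dm.ids:
        node = dendropy.Node(taxon=tns.new_taxon(label))
        nodes.append(node)
        reps.append(label)
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # q[i,j] and q[j,i] can differ by a rounding ulp; normalize orientation
        pairs = {(min(a, b), max(a, b)) for a, b in np.argwhere(q <= qmin)}
        best = min(
            (tuple(sorted((reps[idx[a]], reps[idx[b]]))), a, b)
            for a, b in pairs
        )
        a, b = best[1], best[2]
        i, j = int(idx[a]), int(idx[b])
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = sub[a, b] - li
        li = float(li) if li > 0 else 0.0
        lj = float(lj) if lj > 0 else 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        d_new = 0.5 * (D[i, idx] + D[j, idx] - D[i, j])
        D[nxt, idx] = d_new
        D[idx, nxt] = d_new
        D[nxt, nxt] = 0.0
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    center = dendropy.Node()
    for node, length in (
        (nodes[i], 0.5 * (dij + dik - djk)),
        (nodes[j], 0.5 * (dij + djk - dik)),
        (nodes[k], 0.5 * (dik + djk - dij)),
    ):
        center.add_child(node)
        node.edge.length = float(length) if length > 0 else 0.0
    tree = dendropy.Tree(seed_node=center, taxon_namespace=tns)
    tree.is_rooted = False
    return PhyloTree(tree)


def bootstrap_support(aln: Alignment, model: str = "kimura_aa",
                      n_reps: int = 500, seed: int = 0,
                      ceiling: float = DEFAULT_CEILING) -> PhyloTree:
    """Neighbor-joining tree with column-resampling bootstrap supports.

    Columns are resampled with replacement to the original length in each
    replicate; the support of an internal bipartition of the full-data tree
    is the percentage of replicate trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = neighbor_joining(distance_matrix(aln, model, ceiling))
    target = base.bipartitions()
    counts = {split: 0 for split in target}
    codes = _encode_alignment(aln)
    rng = np.random.default_rng(seed)
    ids = tuple(aln.ids)
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        p, n_valid = _p_from_codes(codes, cols)
        p = np.where(n_valid == 0, 1.0, p)  # degenerate resample: saturate
        d, _ = _correct(p, model, ceiling)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        rep_tree = neighbor_joining(DistanceMatrix(ids, d))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    base.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return base


# ---------------------------------------------------------------------------
# Small parsimony
# ---------------------------------------------------------------------------

def fitch_parsimony(tree: PhyloTree, labels: Mapping[str, str]) -> int:
    """Minimum label changes on the tree (Fitch/Hartigan bottom-up count).

    Exact on binary trees and on the trifurcating seed produced by rooting
    an unrooted tree anywhere; the count is independent of that rooting.
    """
    missing = [lf for lf in tree.leaf_ids if lf not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")
    score = 0
    state_sets: dict = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            state_sets[node] = frozenset([labels[node.taxon.label]])
            continue
        tallies: dict[str, int] = {}
        children = node.child_nodes()
        for child in children:
            for state in state_sets[child]:
                tallies[state] = tallies.get(state, 0) + 1
        top = max(tallies.values())
        state_sets[node] = frozenset(s for s, c in tallies.items() if c == top)
        score += len(children) - top
    return score


# ---------------------------------------------------------------------------
# Subgroup delineation
# ---------------------------------------------------------------------------

def delineate_subgroups(tree: PhyloTree, types: Mapping[str, object],
                        support_floor: float,
                        merge_same_type: bool = False) -> list[frozenset]:
    """Partition leaves into maximal well-supported, type-uniform clades.

    A clade qualifies when its bipartition support reaches ``support_floor``
    and all its leaves share one (major, subtype) label; leaves covered by
    no qualifying clade become singletons. With ``merge_same_type``,
    same-type groups (monophyletic or not) are pooled, mirroring curation
    practice of grouping non-monophyletic subgroups by ORF1 structure.
    """
    rooted = tree.midpoint_rooted()
    all_leaves = frozenset(tree.leaf_ids)
    leafsets = rooted._leafsets()

    def type_key(leaf: str):
        t = types[leaf]
        return (t.major, t.subtype)

    groups: list[frozenset] = []

    def walk(node) -> None:
        leaves = leafsets[node]
        if len(leaves) == 1:
            groups.append(leaves)
            return
        uniform = len({type_key(lf) for lf in leaves}) == 1
        sup = None
        if 1 < len(leaves) < len(all_leaves):
            sup = tree.supports.get(canonical_split(leaves, all_leaves))
        if uniform and sup is not None and sup >= support_floor:
            groups.append(leaves)
            return
        for child in node.child_nodes():
            walk(child)

    walk(rooted.dendropy_tree.seed_node)

    if merge_same_type:
        merged: dict = {}
        for group in groups:
            merged.setdefault(type_key(min(group)), set()).update(group)
        groups = [frozenset(g) for g in merged.values()]
    return sorted(groups, key=lambda g: (-len(g), min(g)))
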