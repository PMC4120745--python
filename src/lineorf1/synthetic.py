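"""Synthetic datasets with tree-like ORF2 and modular ORF1 evolution.

The generator emulates the statistical structure the pipeline assumes: a
Yule tree per lineage joined by deep stems (so lineages are monophyletic by
construction), Poisson amino-acid substitution along branches for the APE,
RT and ORF1 regions, modular ORF1 events (PHD gain at the N-terminus or a
downstream slot, PHD loss, esterase gain), and explicit whole-ORF1
horizontal-transfer events that replace a recipient clade's ORF1 with the
donor lineage's contemporaneous state. Domain sequences are seeded from the
same profile consensus strings the scanner uses, so annotation is exact by
construction at low divergence. There is no indel process: columns are
positionally homologous, keeping downstream alignments trivial.

Every event is recorded in a replayable log, and every source of
randomness derives from the config seed through per-branch substreams, so
identical configs give byte-identical outputs.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import AA_LETTERS, Element, write_fasta
from .phylo import PhyloTree
from .profiles import DomainProfile, default_library

DEFAULT_LINEAGES = ("CR1", "L2", "Jockey")

#: default per-lineage ORF1 root architectures: the transfer-donor lineage
#: carries the 2xRRM + 3xCCHC block (type IB), the recipient background is
#: PHD+RRM (type IIIB), and the outgroup lineage a single-RRM type IA.
DEFAULT_ROOT_ARCHITECTURES: dict[str, tuple[str, ...]] = {
    "L2": ("RRM", "RRM", "CCHC", "CCHC", "CCHC"),
    "CR1": ("PHD", "RRM"),
    "Jockey": ("RRM", "CCHC", "CCHC", "CCHC"),
}


@dataclass(frozen=True)
class HtEvent:
    """One whole-ORF1 horizontal transfer into a recipient leaf clade."""

    recipient_leaves: tuple[str, ...]
    donor_lineage: str


@dataclass(frozen=True)
class SimulationConfig:
    n_taxa: int = 20
    n_lineages: int = 3
    yule_rate: float = 1.0
    subst_rate: float = 0.05
    root_architectures: Mapping[str, tuple[str, ...]] | None = None
    phd_gain_rate: float = 0.05
    phd_loss_rate: float = 0.05
    esterase_gain_rate: float = 0.02
    ht_events: tuple[HtEvent, ...] = ()
    seed: int = 0
    stem_length: float = 1.0
    ape_len: int = 180
    rt_len: int = 300
    linker_len: int = 12
    flank_len: int = 20

    def __post_init__(self) -> None:
        if not self.n_taxa >= self.n_lineages >= 1:
            raise ValueError("need n_taxa >= n_lineages >= 1")
        for name in ("yule_rate", "subst_rate", "phd_gain_rate",
                     "phd_loss_rate", "esterase_gain_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def lineage_names(self) -> tuple[str, ...]:
        if self.n_lineages <= len(DEFAULT_LINEAGES):
            return DEFAULT_LINEAGES[: self.n_lineages]
        return DEFAULT_LINEAGES + tuple(
            f"LIN{i}" for i in range(4, self.n_lineages + 1)
        )

    def architectures(self) -> dict[str, tuple[str, ...]]:
        if self.root_architectures is not None:
            return {k: tuple(v) for k, v in self.root_architectures.items()}
        out = {}
        for i, name in enumerate(self.lineage_names):
            default = DEFAULT_ROOT_ARCHITECTURES.get(name)
            out[name] = default if default is not None else ("RRM", "CCHC")
        return out


@dataclass
class GroundTruth:
    """Replayable record of everything the simulator did."""

    true_tree: PhyloTree
    event_log: list[tuple[str, str, dict]]
    true_architectures: dict[str, tuple[str, ...]]
    true_lineages: dict[str, str]


def lineage_of_leaf(leaf_id: str) -> str:
    return leaf_id.rsplit("-", 1)[0]


def _branch_rng(seed: int, branch_key: str, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed & 0x7FFFFFFF,
         zlib.crc32(branch_key.encode()) & 0x7FFFFFFF,
         zlib.crc32(stream.encode()) & 0x7FFFFFFF]
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_LETTERS[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_taxa: int, yule_rate: float = 1.0, seed: int = 0,
                       prefix: str = "t") -> PhyloTree:
    """Pure-birth tree conditioned on ``n_taxa`` tips.

    Starts from the root split (two lineages at time zero); after the last
    split one further exponential wait separates it from the present, so
    pendant edges are positive even for two taxa. Branch lengths are in
    time units; the expected lineage count at time t is 2 e^{rate t}.
    """
    if n_taxa < 2:
        raise ValueError("need n_taxa >= 2")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(prefix.encode())])
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    births: dict = {}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        births[child] = 0.0
        active.append(child)
    k = 2
    while k < n_taxa:
        t += rng.exponential(1.0 / (yule_rate * k))
        idx = int(rng.integers(0, k))
        node = active.pop(idx)
        node.edge.length = t - births[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            births[child] = t
            active.append(child)
        k += 1
    t_end = t + rng.exponential(1.0 / (yule_rate * n_taxa))
    # deterministic tip naming: left-to-right order of the final topology
    for node in active:
        node.edge.length = t_end - births[node]
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"{prefix}-{i:02d}")
    tree.is_rooted = True
    return PhyloTree(tree)


def simulate_lineage_tree(config: SimulationConfig) -> tuple[PhyloTree, dict[str, str]]:
    """Composite tree: one Yule subtree per lineage on deep root stems.

    Subtree stems are stretched so all leaves are contemporaneous
    (ultrametric). Returns the tree plus the leaf -> lineage map.
    """
    names = config.lineage_names
    base, extra = divmod(config.n_taxa, config.n_lineages)
    sizes = [base + (1 if i < extra else 0) for i in range(config.n_lineages)]
    subtrees: list[PhyloTree] = []
    for name, size in zip(names, sizes):
        if size < 2:
            raise ValueError(
                f"lineage {name}: needs >= 2 taxa (got {size}); raise n_taxa"
            )
        subtrees.append(
            simulate_yule_tree(size, config.yule_rate,
                               seed=config.seed, prefix=name)
        )
    if config.n_lineages == 1:
        tree = subtrees[0]
    else:
        heights = [
            max(_node_depths(sub).values()) for sub in subtrees
        ]
        h_max = max(heights)
        root = dendropy.Node()
        for sub, height in zip(subtrees, heights):
            sub_root = sub.dendropy_tree.seed_node
            root.add_child(sub_root)
            sub_root.edge.length = config.stem_length + (h_max - height)
        joined = dendropy.Tree(seed_node=root)
        joined.migrate_taxon_namespace(dendropy.TaxonNamespace(), unify_taxa_by_label=True)
        joined.is_rooted = True
        tree = PhyloTree(joined)
    lineages = {leaf: lineage_of_leaf(leaf) for leaf in tree.leaf_ids}
    return tree, lineages


def _node_keys(tree: PhyloTree) -> dict:
    """Stable per-node keys: the sorted descendant leaf ids."""
    keys = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            keys[node] = node.taxon.label
        else:
            keys[node] = ",".join(sorted(
                lf.taxon.label for lf in node.leaf_iter()
            ))
    return keys


def _node_depths(tree: PhyloTree) -> dict:
    depths = {tree.dendropy_tree.seed_node: 0.0}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate(seq_codes: np.ndarray, n_events: int, rng: np.random.Generator) -> None:
    if n_events == 0 or seq_codes.size == 0:
        return
    positions = rng.integers(0, seq_codes.size, size=n_events)
    draws = rng.integers(0, 19, size=n_events)
    for pos, draw in zip(positions, draws):
        cur = seq_codes[pos]
        seq_codes[pos] = draw if draw < cur else draw + 1


def evolve_protein(tree: PhyloTree, root_seq: str, subst_rate: float,
                   seed: int = 0, stream: str = "protein") -> dict[str, str]:
    """Evolve one region down the tree; per-site Poisson substitutions,
    replacements drawn uniformly from the 19 other residues, no indels."""
    if not root_seq:
        raise ValueError("empty root sequence")
    keys = _node_keys(tree)
    index = {a: i for i, a in enumerate(AA_LETTERS)}
    out: dict[str, str] = {}

    def walk(node, codes: np.ndarray) -> None:
        for child in node.child_nodes():
            child_codes = codes.copy()
            blen = child.edge.length or 0.0
            rng = _branch_rng(seed, keys[child], stream)
            _mutate(child_codes, int(rng.poisson(subst_rate * blen * codes.size)), rng)
            if child.is_leaf():
                out[keys[child]] = "".join(AA_LETTERS[c] for c in child_codes)
            else:
                walk(child, child_codes)

    root_codes = np.array([index[ch] for ch in root_seq], dtype=np.int64)
    walk(tree.dendropy_tree.seed_node, root_codes)
    return out


# ---------------------------------------------------------------------------
# ORF1 modular evolution
# ---------------------------------------------------------------------------

class _Orf1State:
    """Segments (label, residue-code array); 'linker' marks non-domain runs."""

    __slots__ = ("segments",)

    def __init__(self, segments: list[tuple[str, np.ndarray]]):
        self.segments = segments

    def copy(self) -> "_Orf1State":
        return _Orf1State([(lab, arr.copy()) for lab, arr in self.segments])

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.segments if lab != "linker")

    def sequence(self) -> str:
        return "".join(
            "".join(AA_LETTERS[c] for c in arr) for _, arr in self.segments
        )

    def total_len(self) -> int:
        return sum(arr.size for _, arr in self.segments)

    def mutate(self, n_events: int, rng: np.random.Generator) -> None:
        total = self.total_len()
        if total == 0 or n_events == 0:
            return
        starts = np.cumsum([0] + [arr.size for _, arr in self.segments])
        positions = rng.integers(0, total, size=n_events)
        draws = rng.integers(0, 19, size=n_events)
        for pos, draw in zip(positions, draws):
            seg = int(np.searchsorted(starts, pos, side="right")) - 1
            off = pos - starts[seg]
            arr = self.segments[seg][1]
            cur = arr[off]
            arr[off] = draw if draw < cur else draw + 1


def _encode(seq: str) -> np.ndarray:
    index = {a: i for i, a in enumerate(AA_LETTERS)}
    return np.array([index[ch] for ch in seq], dtype=np.int64)


def _root_orf1_state(arch: Sequence[str], config: SimulationConfig,
                     library_by_name: Mapping[str, DomainProfile],
                     rng: np.random.Generator) -> _Orf1State:
    segments: list[tuple[str, np.ndarray]] = [
        ("linker", _encode(_random_seq(rng, config.flank_len)))
    ]
    for label in arch:
        segments.append((label, _encode(library_by_name[label].consensus)))
        segments.append(("linker", _encode(_random_seq(rng, config.linker_len))))
    # widen the trailing linker into a flank
    segments.append(("linker", _encode(_random_seq(rng, config.flank_len))))
    return _Orf1State(segments)


def _apply_arch_events(state: _Orf1State, blen: float, rng: np.random.Generator,
                       config: SimulationConfig,
                       library_by_name: Mapping[str, DomainProfile],
                       branch_key: str, log: list) -> None:
    def fresh(label: str) -> list[tuple[str, np.ndarray]]:
        return [
            (label, _encode(library_by_name[label].consensus)),
            ("linker", _encode(_random_seq(rng, config.linker_len))),
        ]

    for _ in range(rng.poisson(config.phd_gain_rate * blen)):
        domain_slots = [i for i, (lab, _) in enumerate(state.segments)
                        if lab != "linker"]
        at_nterm = not domain_slots or rng.integers(0, 2) == 0
        if at_nterm:
            pos, where = 1, "n_terminus"
        else:
            after = int(domain_slots[int(rng.integers(0, len(domain_slots)))])
            pos, where = after + 2, f"after_segment_{after}"
        state.segments[pos:pos] = fresh("PHD")
        log.append((branch_key, "phd_gain", {"position": where}))
    for _ in range(rng.poisson(config.phd_loss_rate * blen)):
        phd_slots = [i for i, (lab, _) in enumerate(state.segments) if lab == "PHD"]
        if not phd_slots:
            continue
        victim = int(phd_slots[int(rng.integers(0, len(phd_slots)))])
        del state.segments[victim : victim + 2]  # domain + its linker
        log.append((branch_key, "phd_loss", {"slot": victim}))
    for _ in range(rng.poisson(config.esterase_gain_rate * blen)):
        state.segments[1:1] = fresh("Esterase")
        log.append((branch_key, "esterase_gain", {"position": "n_terminus"}))


def _evolve_orf1(tree: PhyloTree, lineages: Mapping[str, str],
                 config: SimulationConfig
                 ) -> tuple[dict[str, str], dict[str, tuple[str, ...]], list]:
    """Returns (leaf ORF1 sequences, leaf architectures, event log)."""
    library_by_name = {p.name: p for p in default_library()}
    archs = config.architectures()
    keys = _node_keys(tree)
    depths = _node_depths(tree)
    root = tree.dendropy_tree.seed_node
    lineage_roots: dict[str, dendropy.Node] = {}
    if config.n_lineages == 1:
        lineage_roots[config.lineage_names[0]] = root
    else:
        for child in root.child_nodes():
            lineage_roots[lineage_of_leaf(next(child.leaf_iter()).taxon.label)] = child

    # horizontal transfers indexed by recipient MRCA node
    leaf_nodes = {lf.taxon.label: lf
                  for lf in tree.dendropy_tree.leaf_node_iter()}
    ht_by_mrca: dict = {}
    for event in config.ht_events:
        missing = [lf for lf in event.recipient_leaves if lf not in leaf_nodes]
        if missing:
            raise ValueError(f"HT recipients not in tree: {missing}")
        mrca = tree.dendropy_tree.mrca(
            taxa=[leaf_nodes[lf].taxon for lf in event.recipient_leaves]
        )
        ht_by_mrca[mrca] = event

    log: list[tuple[str, str, dict]] = []
    orf1: dict[str, str] = {}
    leaf_archs: dict[str, tuple[str, ...]] = {}

    def donor_state_at(event: HtEvent, tau: float) -> _Orf1State:
        droot = lineage_roots.get(event.donor_lineage)
        if droot is None:
            raise ValueError(f"unknown donor lineage {event.donor_lineage!r}")
        # walk the donor path towards its reference leaf, replaying evolution
        path = [droot]
        while not path[-1].is_leaf():
            nxt = min(
                (c for c in path[-1].child_nodes()),
                key=lambda c: min(lf.taxon.label for lf in c.leaf_iter()),
            )
            path.append(nxt)
        rng0 = _branch_rng(config.seed, f"lineage:{event.donor_lineage}", "orf1root")
        state = _root_orf1_state(archs[event.donor_lineage], config,
                                 library_by_name, rng0)
        scratch: list = []
        last = droot.parent_node if droot.parent_node is not None else droot
        for node in path:
            if depths[node] > tau and node is not droot:
                break
            blen = node.edge.length or 0.0
            rng = _branch_rng(config.seed, keys[node], "orf1")
            _apply_arch_events(state, blen, rng, config, library_by_name,
                               keys[node], scratch)
            state.mutate(int(rng.poisson(config.subst_rate * blen * state.total_len())), rng)
            last = node
        residue = max(tau - depths[last], 0.0)
        rng = _branch_rng(config.seed, keys[last], "orf1-ht-partial")
        state.mutate(int(rng.poisson(config.subst_rate * residue * state.total_len())), rng)
        return state

    def walk(node, state: _Orf1State | None) -> None:
        for child in node.child_nodes():
            if config.n_lineages > 1 and child.parent_node is root:
                lineage = lineage_of_leaf(next(child.leaf_iter()).taxon.label)
                rng0 = _branch_rng(config.seed, f"lineage:{lineage}", "orf1root")
                child_state = _root_orf1_state(archs[lineage], config,
                                               library_by_name, rng0)
            else:
                child_state = state.copy()
            blen = child.edge.length or 0.0
            rng = _branch_rng(config.seed, keys[child], "orf1")
            _apply_arch_events(child_state, blen, rng, config, library_by_name,
                               keys[child], log)
            child_state.mutate(
                int(rng.poisson(config.subst_rate * blen * child_state.total_len())),
                rng,
            )
            if child in ht_by_mrca:
                event = ht_by_mrca[child]
                child_state = donor_state_at(event, depths[child])
                log.append((
                    keys[child], "ht",
                    {"donor_lineage": event.donor_lineage,
                     "recipients": sorted(event.recipient_leaves),
                     "architecture": list(child_state.domains)},
                ))
            if child.is_leaf():
                orf1[keys[child]] = child_state.sequence()
                leaf_archs[keys[child]] = child_state.domains
            else:
                walk(child, child_state)

    if config.n_lineages == 1:
        lineage = config.lineage_names[0]
        rng0 = _branch_rng(config.seed, f"lineage:{lineage}", "orf1root")
        walk(root, _root_orf1_state(archs[lineage], config, library_by_name, rng0))
    else:
        walk(root, None)
    return orf1, leaf_archs, log


def evolve_architecture(tree: PhyloTree, config: SimulationConfig,
                        lineages: Mapping[str, str] | None = None) -> GroundTruth:
    """Run modular ORF1 evolution and return the replayable ground truth."""
    if lineages is None:
        lineages = {leaf: lineage_of_leaf(leaf) for leaf in tree.leaf_ids}
    _, leaf_archs, log = _evolve_orf1(tree, lineages, config)
    return GroundTruth(
        true_tree=tree,
        event_log=log,
        true_architectures=leaf_archs,
        true_lineages=dict(lineages),
    )


def replay_events(tree: PhyloTree, config: SimulationConfig,
                  event_log: Sequence[tuple[str, str, dict]]
                  ) -> dict[str, tuple[str, ...]]:
    """Replay the event log at the architecture level (no sequences).

    Applying the logged events along the true tree reproduces the leaf
    architectures exactly; this is the simulator's correctness invariant.
    """
    archs = config.architectures()
    keys = _node_keys(tree)
    by_branch: dict[str, list[tuple[str, dict]]] = {}
    for branch_key, kind, payload in event_log:
        by_branch.setdefault(branch_key, []).append((kind, payload))
    root = tree.dendropy_tree.seed_node
    out: dict[str, tuple[str, ...]] = {}

    def apply_events(domains: list[str], branch_key: str) -> list[str]:
        for kind, payload in by_branch.get(branch_key, []):
            if kind == "phd_gain":
                where = payload["position"]
                if where == "n_terminus":
                    domains.insert(0, "PHD")
                else:
                    seg_index = int(where.rsplit("_", 1)[1])
                    # segment index -> domain ordinal: segments alternate
                    # linker/domain, so domain ordinal = (seg_index - 1) // 2
                    domains.insert((seg_index - 1) // 2 + 1, "PHD")
            elif kind == "phd_loss":
                ordinal = (int(payload["slot"]) - 1) // 2
                del domains[ordinal]
            elif kind == "esterase_gain":
                domains.insert(0, "Esterase")
            elif kind == "ht":
                domains[:] = list(payload["architecture"])
        return domains

    def walk(node, domains: list[str] | None) -> None:
        for child in node.child_nodes():
            if config.n_lineages > 1 and child.parent_node is root:
                lineage = lineage_of_leaf(next(child.leaf_iter()).taxon.label)
                child_domains = list(archs[lineage])
            else:
                child_domains = list(domains)
            child_domains = apply_events(child_domains, keys[child])
            if child.is_leaf():
                out[keys[child]] = tuple(child_domains)
            else:
                walk(child, child_domains)

    if config.n_lineages == 1:
        walk(root, list(archs[config.lineage_names[0]]))
    else:
        walk(root, None)
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def propose_ht_event(tree: PhyloTree, recipient_lineage: str,
                     donor_lineage: str, size_range: tuple[int, int] = (3, 5)
                     ) -> HtEvent:
    """Pick a recipient clade of the requested size inside a lineage.

    Chooses the internal clade whose size is closest to the middle of
    ``size_range`` (ties: smallest leaf-key), so the choice is a
    deterministic function of the tree.
    """
    lo, hi = size_range
    target = (lo + hi) / 2
    candidates: list[tuple[float, str, tuple[str, ...]]] = []
    for node in tree.dendropy_tree.postorder_internal_node_iter():
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        if not all(lineage_of_leaf(lf) == recipient_lineage for lf in leaves):
            continue
        if len(leaves) == len([lf for lf in tree.leaf_ids
                               if lineage_of_leaf(lf) == recipient_lineage]):
            continue  # never transfer into the whole lineage
        candidates.append((abs(len(leaves) - target), leaves[0], tuple(leaves)))
    in_range = [c for c in candidates if lo <= len(c[2]) <= hi]
    pool = in_range or candidates
    if not pool:
        raise ValueError(f"no suitable recipient clade in {recipient_lineage!r}")
    _, _, leaves = min(pool)
    return HtEvent(recipient_leaves=leaves, donor_lineage=donor_lineage)


def generate_dataset(config: SimulationConfig, outdir: str | Path | None = None
                     ) -> tuple[list[Element], GroundTruth]:
    """Simulate a full dataset (elements + ground truth), optionally writing
    ORF1/APE/RT FASTA, the true tree, truth TSVs and a JSON event log."""
    tree, lineages = simulate_lineage_tree(config)
    rng_root = np.random.default_rng([config.seed & 0x7FFFFFFF, zlib.crc32(b"orf2root")])
    ape_root = _random_seq(rng_root, config.ape_len)
    rt_root = _random_seq(rng_root, config.rt_len)
    ape = evolve_protein(tree, ape_root, config.subst_rate, config.seed, stream="ape")
    rt = evolve_protein(tree, rt_root, config.subst_rate, config.seed, stream="rt")
    orf1, leaf_archs, log = _evolve_orf1(tree, lineages, config)
    truth = GroundTruth(tree, log, leaf_archs, dict(lineages))
    elements = [
        Element(id=leaf, orf1_seq=orf1[leaf], ape_seq=ape[leaf],
                rt_seq=rt[leaf], lineage=lineages[leaf])
        for leaf in tree.leaf_ids
    ]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "orf1.fasta", [(e.id, e.orf1_seq) for e in elements])
        write_fasta(outdir / "ape.fasta", [(e.id, e.ape_seq) for e in elements])
        write_fasta(outdir / "rt.fasta", [(e.id, e.rt_seq) for e in elements])
        (outdir / "true_tree.nwk").write_text(tree.to_newick() + "\n")
        with open(outdir / "true_lineages.tsv", "w") as fh:
            fh.write("element\tlineage\n")
            for e in elements:
                fh.write(f"{e.id}\t{e.lineage}\n")
        with open(outdir / "true_architectures.tsv", "w") as fh:
            fh.write("element\tarchitecture\n")
            for e in elements:
                fh.write(f"{e.id}\t{'-'.join(leaf_archs[e.id]) or 'none'}\n")
        with open(outdir / "events.json", "w") as fh:
            json.dump(
                [{"branch": b, "kind": k, "payload": p} for b, k, p in log],
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
    return elements, truth
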