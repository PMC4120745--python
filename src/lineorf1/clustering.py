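"""All-vs-all RRM similarity clustering with a 2-D force layout.

Extracted RRM units (the inter-RNP2/RNP1 core, the only region shared by
all RRMs; tagged U/D for upstream/downstream copies) are compared pairwise
by Smith-Waterman local alignment; the edge weight is a z-score of the
score against a shuffle null, replacing database E-values with a
deterministic, aligner-free statistic. Clusters are thresholded connected
components rather than a visual read-out of the layout; the layout itself
is for display only.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .profiles import DomainProfile

log = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_ATTRACTION_FLOOR = 3.0
DEFAULT_N_SHUFFLES = 200


@dataclass(frozen=True)
class SimilarityGraph:
    """Undirected weighted graph over domain-instance ids."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a > b:
                raise ValueError(f"edge key ({a}, {b}) not sorted")
            if not (a in known and b in known):
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"bad weight {w} on ({a}, {b})")

    def weight(self, a: str, b: str) -> float:
        return self.edges.get((min(a, b), max(a, b)), 0.0)


def extract_rrm_units(annotations: Mapping[str, Sequence],
                      seqs: Mapping[str, str],
                      library: Sequence[DomainProfile]
                      ) -> list[tuple[str, str]]:
    """Extract the RNP2->RNP1 core of every accepted RRM hit.

    Elements with two RRMs yield records tagged ``U`` (upstream) and ``D``
    (downstream) in coordinate order; single-RRM elements yield one
    untagged record. Extraction projects the profile's RNP spans onto hit
    coordinates: the unit runs from the end of RNP2 to the start of RNP1.
    Elements whose matching profile lacks RNP spans are skipped with a
    logged warning.
    """
    spans = {p.name: (p.rnp2_span, p.rnp1_span) for p in library}
    units: list[tuple[str, str]] = []
    for eid in sorted(annotations):
        hits = sorted(
            (h for h in annotations[eid] if h.accepted and h.domain == "RRM"),
            key=lambda h: h.start,
        )
        if not hits:
            continue
        rnp2, rnp1 = spans.get("RRM", (None, None))
        if rnp2 is None or rnp1 is None:
            log.warning("element %s: RRM profile lacks RNP spans; skipped", eid)
            continue
        tags = [""] if len(hits) == 1 else ["U", "D"]
        for tag, hit in zip(tags, hits[:2]):
            core = seqs[eid][hit.start + rnp2[1] : hit.start + rnp1[0]]
            name = f"{eid}_{tag}" if tag else eid
            units.append((name, core))
    return units


def _sw_aligner(gap_open: float, gap_extend: float,
                matrix_name: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def all_vs_all_similarity(units: Sequence[tuple[str, str]],
                          gap_open: float = DEFAULT_GAP_OPEN,
                          gap_extend: float = DEFAULT_GAP_EXTEND,
                          n_shuffles: int = DEFAULT_N_SHUFFLES,
                          seed: int = 0,
                          score_matrix: str = "BLOSUM62") -> SimilarityGraph:
    """Pairwise Smith-Waterman z-score graph.

    attraction(a, b) = max(0, (score - null_mean) / null_sd) where the null
    is the score of ``n_shuffles`` seed-fixed shuffles of the
    lexicographically smaller id's sequence against the other member (a
    fixed shuffle direction makes the weight exactly symmetric).
    Zero-attraction edges are omitted.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 records")
    names = [u[0] for u in units]
    if len(set(names)) != len(names):
        raise ValueError("duplicate unit ids")
    by_name = dict(units)
    aligner = _sw_aligner(gap_open, gap_extend, score_matrix)
    edges: dict[tuple[str, str], float] = {}
    ordered = sorted(names)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            sa, sb = by_name[a], by_name[b]
            if not sa or not sb:
                continue
            score = float(aligner.score(sa, sb))
            pair_key = zlib.crc32(f"{a}|{b}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng([seed & 0x7FFFFFFF, pair_key])
            letters = np.frombuffer(sa.encode(), dtype=np.uint8)
            null = np.empty(n_shuffles)
            for k in range(n_shuffles):
                shuffled = letters[rng.permutation(letters.size)].tobytes().decode()
                null[k] = aligner.score(shuffled, sb)
            sd = max(float(null.std()), 1e-9)
            z = (score - float(null.mean())) / sd
            if z > 0:
                edges[(a, b)] = z
    return SimilarityGraph(tuple(ordered), edges)


def force_layout(graph: SimilarityGraph, iterations: int = 200,
                 seed: int = 0, attraction: float = 0.02,
                 repulsion: float = 0.05, damping: float = 0.9
                 ) -> dict[str, tuple[float, float]]:
    """Deterministic damped force-directed 2-D embedding (display only).

    Edge attraction is proportional to weight; every node pair repels with
    an inverse-square force. A single node keeps its initial position.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    nodes = list(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    pos = rng.normal(0.0, 1.0, size=(n, 2))
    if n == 1:
        return {nodes[0]: (float(pos[0, 0]), float(pos[0, 1]))}
    w = np.zeros((n, n))
    for (a, b), weight in graph.edges.items():
        w[index[a], index[b]] = w[index[b], index[a]] = weight
    vel = np.zeros_like(pos)
    w_scale = w.max() or 1.0
    for _ in range(iterations):
        diff = pos[None, :, :] - pos[:, None, :]
        dist2 = (diff ** 2).sum(axis=2) + 1e-6
        attract = attraction * ((w / w_scale)[:, :, None] * diff).sum(axis=1)
        repel = -repulsion * (diff / dist2[:, :, None]).sum(axis=1)
        vel = damping * vel + attract + repel
        # cap per-node displacement: keeps the damped system stable
        step_norm = np.linalg.norm(vel, axis=1, keepdims=True)
        pos += vel * np.minimum(1.0, 0.5 / np.maximum(step_norm, 1e-12))
    return {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in index.items()}


def extract_clusters(graph: SimilarityGraph,
                     attraction_floor: float = DEFAULT_ATTRACTION_FLOOR
                     ) -> dict[str, int]:
    """Connected components of the subgraph with weight >= floor.

    Cluster ids are assigned by decreasing size, ties by smallest member
    label; singleton components are allowed. Raising the floor only ever
    refines the partition.
    """
    parent = {v: v for v in graph.nodes}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for (a, b), weight in sorted(graph.edges.items()):
        if weight >= attraction_floor:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    components: dict[str, set[str]] = {}
    for v in graph.nodes:
        components.setdefault(find(v), set()).add(v)
    ordered = sorted(components.values(), key=lambda c: (-len(c), min(c)))
    return {v: i for i, comp in enumerate(ordered) for v in sorted(comp)}


def save_layout_plot(layout: Mapping[str, tuple[float, float]],
                     clusters: Mapping[str, int], path: str) -> None:
    """Optional scatter plot of the layout, colored by cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    xs = [layout[v][0] for v in sorted(layout)]
    ys = [layout[v][1] for v in sorted(layout)]
    cs = [clusters.get(v, 0) for v in sorted(layout)]
    ax.scatter(xs, ys, c=cs, cmap="tab10", s=30)
    for v in sorted(layout):
        ax.annotate(v, layout[v], fontsize=6)
    ax.set_title("RRM unit similarity layout")
    fig.savefig(path, dpi=150)
    plt.close(fig)
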