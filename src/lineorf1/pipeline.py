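"""End-to-end orchestration: annotate -> classify -> trees -> clusters ->
congruence -> report, plus the reference-table summary statistics.

Every stochastic step derives from the run seed, all iteration orders are
sorted, and every output file carries the tool version and a config hash in
a comment header, so a rerun with the same inputs and seed is byte
identical.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from statistics import mean
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .architecture import (Architecture, ORF1Type, architecture_from_hits,
                           architecture_signature, classify_orf1,
                           classify_table1, distinct_structures,
                           table1_architectures)
from .clustering import (all_vs_all_similarity, extract_clusters,
                         extract_rrm_units, force_layout)
from .congruence import build_orf1_tree, detect_embeddings
from .domain_scan import NullModel, annotate_orf1, calibrate_probability
from .io_formats import Element, Table1Row, read_fasta
from .phylo import (Alignment, bootstrap_support, delineate_subgroups,
                    distance_matrix, neighbor_joining, pairwise_identity)
from .profiles import default_library, read_profile_library

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    orf1_fasta: str | None = None
    ape_fasta: str | None = None
    rt_fasta: str | None = None
    lineage_tsv: str | None = None
    profile_library: str | None = None
    accept_threshold: float = 85.0
    distance_model: str = "kimura_aa"
    n_boot_orf2: int = 500
    n_boot_orf1: int = 1000
    support_floor: float = 70.0
    attraction_floor: float = 3.0
    n_perm: int = 999
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.accept_threshold <= 100:
            raise ValueError("accept_threshold outside [0, 100]")
        if not 0 <= self.support_floor <= 101:
            raise ValueError("support_floor outside [0, 101]")

    def content_hash(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = repr(sorted(fields.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    annotations: dict[str, list]
    architectures: dict[str, Architecture]
    types: dict[str, ORF1Type]
    orf2_alignment: Alignment
    orf2_tree: object
    orf1_tree: object | None
    subgroups: list[frozenset]
    subgroup_of: dict[str, str]
    clusters: dict[str, int]
    layout: dict[str, tuple[float, float]]
    transfers: list
    summary: list[Table1Row]
    output_files: dict[str, Path] = field(default_factory=dict)


def load_elements(config: RunConfig) -> list[Element]:
    """Assemble elements from the configured FASTA + lineage-map files."""
    for name in ("orf1_fasta", "ape_fasta", "rt_fasta", "lineage_tsv"):
        if getattr(config, name) is None:
            raise ValueError(f"run config missing {name}")
    orf1 = dict(read_fasta(config.orf1_fasta))
    ape = dict(read_fasta(config.ape_fasta))
    rt = dict(read_fasta(config.rt_fasta))
    lineages: dict[str, str] = {}
    with open(config.lineage_tsv) as fh:
        for line in fh:
            if line.startswith(("#", "element\t")) or not line.strip():
                continue
            eid, lineage = line.rstrip("\n").split("\t")[:2]
            lineages[eid] = lineage
    ids = sorted(ape)
    if sorted(rt) != ids:
        raise ValueError("APE and RT FASTA files carry different element ids")
    return [
        Element(id=eid, orf1_seq=orf1.get(eid, ""), ape_seq=ape[eid],
                rt_seq=rt[eid], lineage=lineages.get(eid, "unknown"))
        for eid in ids
    ]


def _concatenated_alignment(elements: Sequence[Element]) -> Alignment:
    ape_lens = {len(e.ape_seq) for e in elements}
    rt_lens = {len(e.rt_seq) for e in elements}
    if len(ape_lens) != 1 or len(rt_lens) != 1:
        raise ValueError(
            "stage ORF2-alignment: APE/RT rows are not positionally homologous "
            f"(APE lengths {sorted(ape_lens)}, RT lengths {sorted(rt_lens)})"
        )
    la = ape_lens.pop()
    ordered = sorted(elements, key=lambda e: e.id)
    return Alignment(
        ids=tuple(e.id for e in ordered),
        rows=tuple(e.ape_seq + e.rt_seq for e in ordered),
        region_map={"APE": (0, la), "RT": (la, la + rt_lens.pop())},
    )


def run_pipeline(config: RunConfig,
                 elements: Sequence[Element] | None = None) -> PipelineResult:
    """Run the full analysis; see module docstring for determinism rules."""
    if elements is None:
        elements = load_elements(config)
    elements = sorted(elements, key=lambda e: e.id)
    if config.profile_library:
        library = read_profile_library(config.profile_library)
    else:
        library = default_library()
    log.info("stage=input elements=%d profiles=%d seed=%d",
             len(elements), len(library), config.seed)

    annotations = {
        e.id: (annotate_orf1(e.orf1_seq, library, config.accept_threshold,
                             seed=config.seed)
               if e.orf1_seq else [])
        for e in elements
    }
    log.info("stage=annotate hits=%d", sum(map(len, annotations.values())))

    architectures = {
        e.id: architecture_from_hits(annotations[e.id], len(e.orf1_seq))
        for e in elements
    }
    types = {eid: classify_orf1(arch) for eid, arch in architectures.items()}
    log.info("stage=classify distinct=%d",
             len({t.label for t in types.values()}))

    aln = _concatenated_alignment(elements)
    if config.n_boot_orf2 >= 1:
        orf2_tree = bootstrap_support(aln, config.distance_model,
                                      n_reps=config.n_boot_orf2,
                                      seed=config.seed)
    else:
        orf2_tree = neighbor_joining(distance_matrix(aln, config.distance_model))
    log.info("stage=orf2-tree taxa=%d boot=%d", len(aln.ids), config.n_boot_orf2)

    subgroups = delineate_subgroups(orf2_tree, types, config.support_floor)
    lineage_by_id = {e.id: e.lineage for e in elements}
    subgroup_of: dict[str, str] = {}
    per_lineage_counter: dict[str, int] = {}
    for group in subgroups:
        lin_tally: dict[str, int] = {}
        for leaf in group:
            lin_tally[lineage_by_id[leaf]] = lin_tally.get(lineage_by_id[leaf], 0) + 1
        lineage = max(sorted(lin_tally), key=lambda k: lin_tally[k])
        per_lineage_counter[lineage] = per_lineage_counter.get(lineage, 0) + 1
        name = f"{lineage}_{per_lineage_counter[lineage]}"
        for leaf in sorted(group):
            subgroup_of[leaf] = name
    log.info("stage=subgroups n=%d", len(subgroups))

    seqs = {e.id: e.orf1_seq for e in elements}
    units = extract_rrm_units(annotations, seqs, library)
    clusters: dict[str, int] = {}
    layout: dict[str, tuple[float, float]] = {}
    if len(units) >= 2:
        graph = all_vs_all_similarity(units, seed=config.seed)
        clusters = extract_clusters(graph, config.attraction_floor)
        layout = force_layout(graph, seed=config.seed)
    log.info("stage=clusters units=%d clusters=%d",
             len(units), len(set(clusters.values())))

    orf1_tree = None
    transfers: list = []
    try:
        orf1_tree = build_orf1_tree(elements, "rrm_cchc_block",
                                    config.distance_model,
                                    n_boot=config.n_boot_orf1,
                                    seed=config.seed,
                                    annotations=annotations)
    except ValueError as exc:
        log.info("stage=orf1-tree skipped: %s", exc)
    if orf1_tree is not None:
        shared = set(orf1_tree.leaf_ids)
        orf2_restricted = orf2_tree.restricted(shared)
        labels = {eid: lineage_by_id[eid] for eid in shared}
        if len({labels[eid] for eid in shared}) > 1:
            transfers = detect_embeddings(orf2_restricted, orf1_tree, labels,
                                          n_perm=config.n_perm,
                                          seed=config.seed)
    log.info("stage=congruence candidates=%d", len(transfers))

    summary = summarize_table1_style(
        elements, annotations, types, subgroup_of, aln, library,
        seed=config.seed,
    )

    result = PipelineResult(
        annotations=annotations, architectures=architectures, types=types,
        orf2_alignment=aln, orf2_tree=orf2_tree, orf1_tree=orf1_tree,
        subgroups=subgroups, subgroup_of=subgroup_of, clusters=clusters,
        layout=layout, transfers=transfers, summary=summary,
    )
    if config.outdir:
        _write_outputs(config, result)
    return result


# ---------------------------------------------------------------------------
# Reference-table-style summary
# ---------------------------------------------------------------------------

def _mean_pairwise_identity(rows: Sequence[str]) -> float | None:
    if len(rows) < 2:
        return None
    vals = [
        pairwise_identity(rows[i], rows[j])
        for i in range(len(rows)) for j in range(i + 1, len(rows))
    ]
    vals = [v for v in vals if v is not None]
    return round(mean(vals), 1) if vals else None


def summarize_table1_style(elements: Sequence[Element],
                           annotations: Mapping[str, Sequence],
                           types: Mapping[str, ORF1Type],
                           subgroup_of: Mapping[str, str],
                           orf2_alignment: Alignment,
                           library, seed: int = 0) -> list[Table1Row]:
    """Per-subgroup summary mirroring the reference table's columns.

    For each subgroup: element count, mean pairwise RT identity (missing,
    never zero, below 2 members), the uniform type/subtype, and per accepted
    domain the minimum observed length, mean pairwise identity of the domain
    alignment, the calibration probability of the subgroup consensus hit,
    and the modal copy number.
    """
    by_id = {e.id: e for e in elements}
    rt_rows = dict(zip(orf2_alignment.ids,
                       (r[slice(*orf2_alignment.region_map["RT"])]
                        for r in orf2_alignment.rows)))
    profile_by_name = {p.name: p for p in library}
    groups: dict[str, list[str]] = {}
    for eid in sorted(subgroup_of):
        groups.setdefault(subgroup_of[eid], []).append(eid)

    out: list[Table1Row] = []
    for name in sorted(groups):
        members = groups[name]
        lineage = name.rsplit("_", 1)[0]
        rt_identity = _mean_pairwise_identity([rt_rows[m] for m in members])
        type_label = types[members[0]].label
        # domain labels in N->C order of the first member's architecture
        ordered_labels: list[str] = []
        for hit in sorted(annotations[members[0]], key=lambda h: h.start):
            if hit.accepted and hit.domain not in ordered_labels:
                ordered_labels.append(hit.domain)
        if not ordered_labels:
            out.append(Table1Row(name, lineage, len(members),
                                 rt_identity, type_label, "none"))
            continue
        for label in ordered_labels:
            spans: list[str] = []
            copies: list[int] = []
            for m in members:
                hits = [h for h in annotations[m]
                        if h.accepted and h.domain == label]
                copies.append(len(hits))
                for h in hits[:1]:
                    spans.append(by_id[m].orf1_seq[h.start:h.end])
            min_len = min((len(s) for s in spans), default=None)
            aa_identity = _mean_pairwise_identity(spans)
            probability = None
            if spans:
                consensus = _column_consensus(spans)
                profile = profile_by_name.get(label)
                if profile is not None:
                    from .domain_scan import window_scores, encode_sequence
                    scores = window_scores(encode_sequence(consensus), profile)
                    if scores.size:
                        probability = round(calibrate_probability(
                            float(scores.max()), profile,
                            NullModel(seq_length=len(consensus)), seed=seed,
                        ), 1)
            modal_copies = max(sorted(set(copies)), key=copies.count)
            out.append(Table1Row(
                name, lineage, len(members), rt_identity, type_label,
                label, min_len, aa_identity, None, probability,
                modal_copies if label in ("RRM", "CCHC") else None,
            ))
    return out


def _column_consensus(rows: Sequence[str]) -> str:
    width = min(len(r) for r in rows)
    cons = []
    for i in range(width):
        col = [r[i] for r in rows]
        cons.append(max(sorted(set(col)), key=col.count))
    return "".join(cons)


# ---------------------------------------------------------------------------
# Reference-table statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureStatistics:
    aa_identity_min: float
    aa_identity_max: float
    n_low_probability: int
    n_major_types: int
    distinct_structures_by_lineage: dict[str, int]


def fixture_statistics(rows: Sequence[Table1Row],
                       prob_threshold: float = 85.0,
                       lineages: Sequence[str] = ("L2", "CR1")
                       ) -> FixtureStatistics:
    """Headline statistics of the reference table.

    Extrema of the per-domain amino-acid identity column; the number of
    domain rows whose probability falls strictly below the threshold (rows
    with missing probability excluded); the number of distinct major types
    and of distinct (major, subtype) structures over the lineage filter,
    the latter via the architecture grammar with context overrides.
    """
    identities = [r.aa_identity_pct for r in rows if r.aa_identity_pct is not None]
    probabilities = [r.probability_pct for r in rows if r.probability_pct is not None]
    assignments = classify_table1(rows)
    lineage_map = {r.subgroup_id: r.lineage for r in rows}
    majors = {
        assignments[sg].major
        for sg in assignments if lineage_map[sg] in lineages
    }
    return FixtureStatistics(
        aa_identity_min=min(identities),
        aa_identity_max=max(identities),
        n_low_probability=sum(p < prob_threshold for p in probabilities),
        n_major_types=len(majors),
        distinct_structures_by_lineage={
            lin: distinct_structures(assignments, lineage_map, lin)
            for lin in lineages
        },
    )


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def _header(config: RunConfig) -> str:
    return f"# lineorf1 v{__version__} config={config.content_hash()} seed={config.seed}\n"


def _write_outputs(config: RunConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(config)

    def tsv(name: str, header_cols: Sequence[str], rows, extra_comment: str = ""):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(head)
            if extra_comment:
                fh.write(f"# {extra_comment}\n")
            fh.write("\t".join(header_cols) + "\n")
            for row in rows:
                fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
        result.output_files[name] = path

    tsv("annotations.tsv",
        ["element", "domain", "start", "end", "score", "probability", "accepted"],
        [(eid, h.domain, h.start + 1, h.end, f"{h.score:.3f}",
          "" if h.probability is None else f"{h.probability:.1f}",
          int(h.accepted))
         for eid in sorted(result.annotations)
         for h in result.annotations[eid]],
        extra_comment="coordinates are 1-based inclusive")
    tsv("classification.tsv",
        ["element", "subgroup", "signature", "major", "subtype", "coverage",
         "context_override"],
        [(eid, result.subgroup_of.get(eid, ""),
          architecture_signature(result.architectures[eid]),
          result.types[eid].major, result.types[eid].subtype or "",
          f"{result.architectures[eid].coverage:.3f}",
          int(result.types[eid].context_override))
         for eid in sorted(result.types)])
    for name, tree in (("orf2_tree.nwk", result.orf2_tree),
                       ("orf1_tree.nwk", result.orf1_tree)):
        if tree is None:
            continue
        path = outdir / name
        path.write_text(f"[lineorf1 v{__version__} config={config.content_hash()}]\n"
                        + tree.to_newick() + "\n")
        result.output_files[name] = path
    tsv("subgroups.tsv", ["element", "subgroup"],
        [(eid, result.subgroup_of[eid]) for eid in sorted(result.subgroup_of)])
    tsv("clusters.tsv", ["unit", "cluster"],
        [(u, result.clusters[u]) for u in sorted(result.clusters)])
    tsv("layout.tsv", ["unit", "x", "y"],
        [(u, f"{result.layout[u][0]:.4f}", f"{result.layout[u][1]:.4f}")
         for u in sorted(result.layout)])
    tsv("transfers.tsv",
        ["focal_lineage", "host_lineage", "n_embedding_positions",
         "delta_fitch", "permutation_p", "focal_leaves"],
        [(t.focal_lineage, t.host_lineage, t.n_embedding_positions,
          t.delta_fitch,
          "" if t.permutation_p is None else f"{t.permutation_p:.4f}",
          ",".join(sorted(t.focal_leaves)))
         for t in result.transfers],
        extra_comment=("permutation_p is an invented quantification of "
                       "tree incongruence, not part of the original "
                       "visual inference"))
    tsv("summary.tsv",
        ["subgroup", "lineage", "n_seqs", "rt_identity_pct", "type_subtype",
         "domain", "length_aa", "aa_identity_pct", "probability_pct",
         "n_copies"],
        [(r.subgroup_id, r.lineage, r.n_seqs, r.rt_identity_pct,
          r.type_subtype, r.domain_label, r.length_aa, r.aa_identity_pct,
          r.probability_pct, r.n_copies)
         for r in result.summary])
    dm = distance_matrix(result.orf2_alignment, config.distance_model)
    path = outdir / "orf2_distances.tsv"
    with open(path, "w") as fh:
        fh.write(head)
        fh.write("\t".join(("id",) + dm.ids) + "\n")
        for i, eid in enumerate(dm.ids):
            fh.write("\t".join([eid] + [f"{v:.6f}" for v in dm.values[i]]) + "\n")
    result.output_files["orf2_distances.tsv"] = path
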