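"""ORF1 architecture typing: the five-type / three-subtype grammar.

An *architecture* is the ordered list of accepted domain labels on one ORF1
plus the fraction of the ORF covered by those hits. The grammar assigns
exactly one (type, subtype) per architecture, with precedence

    V (coverage < 10%)  >  IV (esterase)  >  II (Tnp22)  >
    I (RRM immediately upstream of CCHC)  >  III (PHD)  >  V (otherwise)

so that PHD-bearing type I/II variants (IC, IIB, IIC) are not captured by
type III. Subtypes:

* I:   C with a PHD; B with >= 2 RRMs and >= 3 CCHCs and no PHD; else A.
       (CCHC multiplicity alone never separates A from B.)
* II:  C with a PHD upstream of the Tnp22; B with a PHD downstream; else A.
* III: B with an RRM downstream of the PHD; else A.
* IV:  B with a zinc finger or leucine zipper upstream of the esterase; else A.
* V:   no subtype.

One architecture (the L2_8 reference subgroup) is architecturally identical
to a type IB but is recorded as IC on phylogenetic context; such exceptions
are handled by an explicit, auditable per-subgroup override rather than by
widening the grammar.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import Table1Row

MAJOR_TYPES = ("I", "II", "III", "IV", "V")
SUBTYPES = ("A", "B", "C")

#: subgroups whose subtype is fixed by lineage context, not pure architecture
CONTEXT_OVERRIDES: dict[str, str] = {"L2_8": "C"}

#: coverage is not part of the reference table; these nominal values encode
#: the table's own coverage-based typing (CR1_2: < 10% of the ORF annotated)
TABLE1_COVERAGE: dict[str, float] = {"CR1_2": 0.05}
_TABLE1_DEFAULT_COVERAGE = 0.5

LOW_COVERAGE_CUTOFF = 0.10


@dataclass(frozen=True)
class Architecture:
    """Ordered accepted domain labels plus ORF coverage in [0, 1]."""

    ordered_domains: tuple[str, ...]
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")

    @property
    def counts(self) -> Counter:
        return Counter(self.ordered_domains)


@dataclass(frozen=True)
class ORF1Type:
    """A (major, subtype) assignment; ``context_override`` marks subtypes
    set by lineage context rather than pure architecture (type I only)."""

    major: str
    subtype: str | None = None
    context_override: bool = False

    def __post_init__(self) -> None:
        if self.major not in MAJOR_TYPES:
            raise ValueError(f"unknown major type {self.major!r}")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.major == "V" and self.subtype is not None:
            raise ValueError("type V carries no subtype")
        if self.context_override and self.major != "I":
            raise ValueError("context overrides apply to type I only")

    @property
    def label(self) -> str:
        return self.major + (self.subtype or "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def classify_orf1(arch: Architecture, *, context_subtype: str | None = None) -> ORF1Type:
    """Assign the unique (type, subtype) of an architecture.

    Total and deterministic: exactly one precedence branch fires.
    ``context_subtype`` applies a lineage-context subtype override and is
    honoured only when the grammar assigns major type I.
    """
    doms = arch.ordered_domains
    counts = arch.counts

    if arch.coverage < LOW_COVERAGE_CUTOFF:
        return ORF1Type("V")

    if "Esterase" in counts:
        first_est = doms.index("Esterase")
        flanked = any(d in ("zf", "lz") for d in doms[:first_est])
        return ORF1Type("IV", "B" if flanked else "A")

    if "Tnp22" in counts:
        first_tnp = doms.index("Tnp22")
        if "PHD" in doms[:first_tnp]:
            return ORF1Type("II", "C")
        if "PHD" in doms[first_tnp + 1 :]:
            return ORF1Type("II", "B")
        return ORF1Type("II", "A")

    if any(a == "RRM" and b == "CCHC" for a, b in zip(doms, doms[1:])):
        if context_subtype is not None:
            return ORF1Type("I", context_subtype, context_override=True)
        if "PHD" in counts:
            return ORF1Type("I", "C")
        if counts["RRM"] >= 2 and counts["CCHC"] >= 3:
            return ORF1Type("I", "B")
        return ORF1Type("I", "A")

    if "PHD" in counts:
        first_phd = doms.index("PHD")
        if "RRM" in doms[first_phd + 1 :]:
            return ORF1Type("III", "B")
        return ORF1Type("III", "A")

    return ORF1Type("V")


def architecture_signature(arch: Architecture) -> str:
    """Canonical text rendering, e.g. ``PHD-RRMx2-CCHCx3``; ``none`` if empty."""
    if not arch.ordered_domains:
        return "none"
    parts: list[str] = []
    run_label, run_len = arch.ordered_domains[0], 1
    for label in arch.ordered_domains[1:]:
        if label == run_label:
            run_len += 1
        else:
            parts.append(run_label if run_len == 1 else f"{run_label}x{run_len}")
            run_label, run_len = label, 1
    parts.append(run_label if run_len == 1 else f"{run_label}x{run_len}")
    return "-".join(parts)


def architecture_from_hits(hits: Sequence, seq_len: int) -> Architecture:
    """Build an architecture from accepted annotation hits on one ORF1."""
    accepted = sorted((h for h in hits if h.accepted), key=lambda h: h.start)
    if seq_len <= 0:
        return Architecture((), 0.0)
    covered = sum(h.end - h.start for h in accepted)
    return Architecture(
        tuple(h.domain for h in accepted), min(1.0, covered / seq_len)
    )


def distinct_structures(assignments: Mapping[str, ORF1Type],
                        lineage_map: Mapping[str, str],
                        lineage: str | None = None) -> int:
    """Number of distinct (major, subtype) labels among subgroups of a lineage.

    ``lineage=None`` counts over all subgroups. Raises on a lineage label
    absent from the map.
    """
    present = set(lineage_map.values())
    if lineage is not None and lineage not in present:
        raise ValueError(f"unknown lineage label {lineage!r} (have {sorted(present)})")
    labels = {
        (t.major, t.subtype)
        for subgroup, t in assignments.items()
        if lineage is None or lineage_map[subgroup] == lineage
    }
    return len(labels)


# ---------------------------------------------------------------------------
# Reference-table helpers
# ---------------------------------------------------------------------------

def table1_architectures(rows: Sequence[Table1Row]) -> dict[str, Architecture]:
    """Per-subgroup architectures implied by the reference table.

    Domains appear in the table in N->C order; RRM/CCHC copy numbers expand
    into repeated labels (blank copy number reads as one copy). Coverage is
    nominal (see ``TABLE1_COVERAGE``).
    """
    ordered: dict[str, list[str]] = {}
    for row in rows:
        doms = ordered.setdefault(row.subgroup_id, [])
        if row.domain_label == "none":
            continue
        doms.extend([row.domain_label] * (row.n_copies or 1))
    return {
        sg: Architecture(
            tuple(doms),
            TABLE1_COVERAGE.get(sg, _TABLE1_DEFAULT_COVERAGE) if doms else 0.0,
        )
        for sg, doms in ordered.items()
    }


def classify_table1(rows: Sequence[Table1Row],
                    overrides: Mapping[str, str] | None = None) -> dict[str, ORF1Type]:
    """Classify every reference-table subgroup, applying context overrides."""
    if overrides is None:
        overrides = CONTEXT_OVERRIDES
    archs = table1_architectures(rows)
    return {
        sg: classify_orf1(arch, context_subtype=overrides.get(sg))
        for sg, arch in sorted(archs.items())
    }
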