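"""Readers and writers for the formats the pipeline touches.

FASTA record lists, newick trees with integer bootstrap supports on internal
nodes, and the packaged per-subgroup domain reference table used as the
classifier regression fixture.

Conventions: amino-acid sequences use the 20 standard one-letter codes plus
``X``; ``-`` is the only gap character and is legal only in aligned contexts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
KNOWN_LINEAGES = ("CR1", "L2", "Jockey")

_RESIDUES = frozenset(AA_LETTERS + "X")
_RESIDUES_GAPPED = frozenset(AA_LETTERS + "X-")

DOMAIN_LABELS = ("PHD", "RRM", "CCHC", "Tnp22", "Esterase", "CC", "lz", "zf", "none")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input; the message names the offending line."""


class NewickParseError(ValueError):
    """Raised on malformed newick input."""


class FixtureError(RuntimeError):
    """Raised when the packaged reference table is missing or corrupt."""


@dataclass(frozen=True)
class Element:
    """One transposable-element record.

    ``orf1_seq`` may be empty (elements lacking an identified ORF1 start);
    ``ape_seq``/``rt_seq`` are the two ORF2 enzymatic domains used for the
    reference phylogeny. ``lineage`` is normally one of ``CR1``/``L2``/
    ``Jockey`` but unknown labels are allowed.
    """

    id: str
    orf1_seq: str = ""
    ape_seq: str = ""
    rt_seq: str = ""
    lineage: str = "unknown"
    subgroup: str | None = None
    species: str | None = None
    phylum: str | None = None

    def __post_init__(self) -> None:
        for name in ("orf1_seq", "ape_seq", "rt_seq"):
            seq = getattr(self, name)
            bad = set(seq) - _RESIDUES_GAPPED
            if bad:
                raise ValueError(
                    f"element {self.id!r}: illegal residue(s) {sorted(bad)} in {name}"
                )


@dataclass(frozen=True)
class Table1Row:
    """One (subgroup, domain) row of the packaged reference table.

    Missing cells (blank probability, blank copy number, ...) are ``None``,
    never zero.
    """

    subgroup_id: str
    lineage: str
    n_seqs: int
    rt_identity_pct: float | None
    type_subtype: str
    domain_label: str
    length_aa: int | None = None
    aa_identity_pct: float | None = None
    top_hit: str | None = None
    probability_pct: float | None = None
    n_copies: int | None = None

    def __post_init__(self) -> None:
        for name in ("rt_identity_pct", "aa_identity_pct", "probability_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.subgroup_id}: {name}={v} outside [0, 100]")
        if self.domain_label not in DOMAIN_LABELS:
            raise ValueError(
                f"{self.subgroup_id}: unknown domain label {self.domain_label!r}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Record order is preserved, sequence whitespace is stripped and letters
    are uppercased. Raises :class:`FastaFormatError` naming the line on a
    malformed header, an illegal residue character, or a duplicate id.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        bad = set(seq) - _RESIDUES_GAPPED
        if bad:
            raise FastaFormatError(
                f"{path}: record {header!r} (ending before line {line_no}): "
                f"illegal residue(s) {sorted(bad)}"
            )
        records.append((header, seq))
        header, chunks = None, []

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaFormatError(f"{path}: line {line_no}: empty FASTA header")
                if name in seen:
                    raise FastaFormatError(
                        f"{path}: line {line_no}: duplicate record id {name!r}"
                    )
                seen.add(name)
                header = name
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: line {line_no}: sequence data before first '>' header"
                    )
                chunks.append(line.upper())
        flush(line_no + 1)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write records as wrapped FASTA. Ids must be unique."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for name, seq in records:
            if name in seen:
                raise ValueError(f"duplicate record id {name!r}")
            seen.add(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")


# ---------------------------------------------------------------------------
# Newick (thin delegates; the tree type lives in lineorf1.phylo)
# ---------------------------------------------------------------------------

def read_newick(text: str):
    """Parse a newick string into a :class:`lineorf1.phylo.PhyloTree`.

    Internal node labels are interpreted as integer-percent bootstrap
    supports (the MEGA convention). Raises :class:`NewickParseError` on
    malformed input, with position information where available.
    """
    from .phylo import PhyloTree

    return PhyloTree.from_newick(text)


def write_newick(tree) -> str:
    """Serialize a :class:`lineorf1.phylo.PhyloTree` back to newick."""
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Reference table fixture
# ---------------------------------------------------------------------------

_EXPECTED_SUBGROUPS = {
    "L2": [f"L2_{i}" for i in range(1, 11)],
    "Jockey": ["Jockey_1", "Jockey_2"],
    "CR1": [f"CR1_{i}" for i in range(1, 9)],
}
_EXPECTED_TOTAL = 448


def _opt(value: str, cast):
    value = value.strip()
    return cast(value) if value else None


def load_table1_fixture() -> list[Table1Row]:
    """Load the packaged reference table (one row per subgroup/domain pair).

    Validates subgroup composition (10 L2 + 2 Jockey + 8 CR1 = 20 subgroups)
    and the element total of 448; see ``data/README.md`` for how that total
    relates to the upstream curation counts.
    """
    try:
        src = resources.files("lineorf1.data").joinpath("table1.tsv")
        df = pd.read_csv(src.open(), sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - any failure here is fatal config
        raise FixtureError(f"packaged reference table unreadable: {exc}") from exc

    rows: list[Table1Row] = []
    for rec in df.itertuples(index=False):
        rows.append(
            Table1Row(
                subgroup_id=rec.subgroup,
                lineage=rec.lineage,
                n_seqs=int(rec.n_seqs),
                rt_identity_pct=float(rec.rt_identity_pct),
                type_subtype=rec.type_subtype.strip(),
                domain_label=rec.domain.strip(),
                length_aa=_opt(rec.length_aa, int),
                aa_identity_pct=_opt(rec.aa_identity_pct, float),
                top_hit=_opt(rec.top_hit, str),
                probability_pct=_opt(rec.probability_pct, float),
                n_copies=_opt(rec.n_copies, int),
            )
        )

    by_lineage: dict[str, list[str]] = {}
    n_by_subgroup: dict[str, int] = {}
    for row in rows:
        if row.subgroup_id not in n_by_subgroup:
            by_lineage.setdefault(row.lineage, []).append(row.subgroup_id)
        prev = n_by_subgroup.setdefault(row.subgroup_id, row.n_seqs)
        if prev != row.n_seqs:
            raise FixtureError(f"inconsistent n_seqs for {row.subgroup_id}")

    for lineage, expected in _EXPECTED_SUBGROUPS.items():
        if by_lineage.get(lineage, []) != expected:
            raise FixtureError(
                f"{lineage} subgroups {by_lineage.get(lineage)} != expected {expected}"
            )
    total = sum(n_by_subgroup.values())
    if total != _EXPECTED_TOTAL:
        raise FixtureError(f"fixture element total {total} != {_EXPECTED_TOTAL}")

    keys = [(r.subgroup_id, r.domain_label) for r in rows]
    if len(set(keys)) != len(keys):
        raise FixtureError("duplicate (subgroup, domain) row in fixture")
    return rows
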