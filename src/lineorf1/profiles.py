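"""Position-specific scoring profiles for ORF1 domains.

The library models the seven domain families annotated on Jockey-superfamily
ORF1s: PHD (plant homeodomain, a C4HC3 zinc finger), RRM (RNA recognition
motif, with its internal RNP2 and RNP1 consensus boxes), CCHC (gag-like
Cys2HisCys zinc knuckle), Tnp22 (the composite coiled-coil + RRM + CTD module
of the L1 ORF1 protein, treated as a single profile as in its RCSB/Pfam
entries), Esterase, zf (C2H2 zinc finger) and lz (leucine zipper).

Each profile is a log-odds table over the 20 amino acids versus a uniform
background. The default library is generated deterministically from fixed
consensus sequences with biologically anchored motif residues; the same
consensus strings seed the synthetic-data generator, so profile hits on
simulated data are exact by construction at low divergence.

Profiles serialize to a plain-text format: a tab-separated header line
(name, length, and for RRM the RNP2/RNP1 spans as four extra integers),
then ``length`` rows of 20 tab-separated log-odds values in the column
order ``ACDEFGHIKLMNPQRSTVWY``.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import AA_LETTERS

AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}

# weight of the consensus residue, of conservative alternates, of the rest
_W_CONS = 2.5
_W_ALT = 1.0
_W_OTHER = -1.2

# conservative-replacement groups used for the two alternate residues
_SIMILAR = {
    "A": "SG", "C": "SA", "D": "EN", "E": "DQ", "F": "YW", "G": "AS",
    "H": "NY", "I": "LV", "K": "RQ", "L": "IV", "M": "LI", "N": "DH",
    "P": "AG", "Q": "EK", "R": "KQ", "S": "TA", "T": "SA", "V": "IL",
    "W": "FY", "Y": "FW",
}


@dataclass(frozen=True)
class DomainProfile:
    """An ungapped per-position scoring profile for one domain family.

    ``weights`` is a ``(length, 20)`` log-odds table; ``rnp2_span`` and
    ``rnp1_span`` (RRM only) are 0-based half-open intervals in profile
    coordinates, with RNP2 before RNP1 as in the domain itself.
    """

    name: str
    length: int
    weights: np.ndarray
    rnp2_span: tuple[int, int] | None = None
    rnp1_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length < 8:
            raise ValueError(f"profile {self.name}: length {self.length} < 8")
        if self.weights.shape != (self.length, 20):
            raise ValueError(f"profile {self.name}: weights shape {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"profile {self.name}: non-finite weights")
        spans = (self.rnp2_span, self.rnp1_span)
        if any(s is not None for s in spans):
            if any(s is None for s in spans):
                raise ValueError(f"profile {self.name}: RNP spans must come in pairs")
            (s2, e2), (s1, e1) = self.rnp2_span, self.rnp1_span
            if not (0 <= s2 < e2 <= s1 < e1 <= self.length):
                raise ValueError(
                    f"profile {self.name}: RNP spans {spans} invalid "
                    "(need rnp2 before rnp1, both within the profile)"
                )

    @property
    def consensus(self) -> str:
        """Highest-scoring residue at each position."""
        return "".join(AA_LETTERS[i] for i in np.argmax(self.weights, axis=1))

    @property
    def consensus_score(self) -> float:
        """Score of the consensus sequence against the profile."""
        return float(self.weights.max(axis=1).sum())

    def weights_key(self) -> int:
        """Stable content hash used for calibration caching."""
        return zlib.crc32(self.weights.tobytes()) & 0x7FFFFFFF


def _build(name: str, length: int, anchors: dict[int, str], seed: int,
           rnp2: tuple[int, int] | None = None,
           rnp1: tuple[int, int] | None = None) -> DomainProfile:
    rng = np.random.default_rng(seed)
    cons = rng.integers(0, 20, size=length)
    for pos, letter in anchors.items():
        cons[pos] = AA_INDEX[letter]
    weights = np.full((length, 20), _W_OTHER, dtype=float)
    for i, c in enumerate(cons):
        letter = AA_LETTERS[c]
        for alt in _SIMILAR[letter]:
            weights[i, AA_INDEX[alt]] = _W_ALT
        weights[i, c] = _W_CONS
    # tiny deterministic jitter so window-score ties are broken reproducibly
    weights += rng.normal(0.0, 0.03, size=weights.shape)
    weights[np.arange(length), cons] += 0.5  # keep the consensus the argmax
    return DomainProfile(name, length, weights, rnp2, rnp1)


def default_library() -> list[DomainProfile]:
    """The seven-domain default library, rebuilt deterministically."""
    phd_anchors = {2: "C", 5: "C", 18: "C", 21: "C", 28: "H", 31: "C", 44: "C", 47: "C"}
    cchc_anchors = {2: "C", 5: "C", 10: "H", 15: "C"}
    # RNP2 ([ILV]-[FY]-[ILV]-X-N-L) and RNP1 (K-G-F-G-F-V-X-F) boxes
    rrm_anchors = {8: "I", 9: "F", 10: "V", 12: "N", 13: "L",
                   52: "K", 53: "G", 54: "F", 55: "G", 56: "F", 57: "V", 59: "F"}
    est_anchors = {40: "G", 41: "D", 42: "S", 43: "L"}  # GDSL catalytic block
    zf_anchors = {3: "C", 6: "C", 19: "H", 23: "H"}
    lz_anchors = {0: "L", 7: "L", 14: "L", 21: "L"}
    return [
        _build("PHD", 50, phd_anchors, seed=101),
        _build("RRM", 75, rrm_anchors, seed=102, rnp2=(8, 14), rnp1=(52, 60)),
        _build("CCHC", 18, cchc_anchors, seed=103),
        _build("Tnp22", 160, {}, seed=104),
        _build("Esterase", 175, est_anchors, seed=105),
        _build("zf", 28, zf_anchors, seed=106),
        _build("lz", 28, lz_anchors, seed=107),
    ]


def write_profile(path: str | Path, profile: DomainProfile) -> None:
    header = [profile.name, str(profile.length)]
    if profile.rnp2_span is not None:
        header += [str(v) for v in (*profile.rnp2_span, *profile.rnp1_span)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in profile.weights:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_profile(path: str | Path) -> DomainProfile:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        name, length = header[0], int(header[1])
        rnp2 = rnp1 = None
        if len(header) == 6:
            rnp2 = (int(header[2]), int(header[3]))
            rnp1 = (int(header[4]), int(header[5]))
        elif len(header) != 2:
            raise ValueError(f"{path}: malformed profile header {header}")
        weights = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return DomainProfile(name, length, weights, rnp2, rnp1)


def read_profile_library(directory: str | Path) -> list[DomainProfile]:
    """Load every ``*.profile.tsv`` file in a directory, sorted by name."""
    paths = sorted(Path(directory).glob("*.profile.tsv"))
    if not paths:
        raise FileNotFoundError(f"no *.profile.tsv files in {directory}")
    return [read_profile(p) for p in paths]


def write_profile_library(directory: str | Path, library: list[DomainProfile]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for prof in library:
        write_profile(directory / f"{prof.name}.profile.tsv", prof)
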