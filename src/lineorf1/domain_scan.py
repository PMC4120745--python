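"""Profile-based annotation of ORF1 domains.

Ungapped PSSM scanning replaces database HMM-HMM search: every window of
profile length is scored against the log-odds table, non-overlapping score
maxima are reported, and each hit's probability is the empirical percentile
of its score among the maxima of null scans of shuffled-composition
sequences. The published decision rule is preserved: a hit is *accepted*
when its probability reaches the acceptance threshold (default 85%), and
overlapping hits from different profiles are resolved in favour of the
higher-probability hit.

Coiled-coil segments are detected separately with a heptad-register
hydrophobicity contrast score, since coiled coils have periodicity rather
than positional sequence conservation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import AA_LETTERS
from .profiles import AA_INDEX, DomainProfile

DEFAULT_ACCEPT_THRESHOLD = 85.0
# candidate-window floor as a fraction of the profile's consensus score;
# random windows score far below zero, so 0.25 x consensus keeps specificity
# (~6 sigma above any background window even for the shortest profile) while
# tolerating ~40% divergence from the consensus
DEFAULT_MIN_SCORE_FRAC = 0.25
DEFAULT_NULL_N = 1000

_X_CODE = 20  # unknown residue: scored as the per-position mean weight


@dataclass(frozen=True)
class DomainHit:
    """A located profile match on an ORF1 sequence (0-based, half-open)."""

    domain: str
    start: int
    end: int
    score: float
    probability: float | None = None
    accepted: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"hit {self.domain}: bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NullModel:
    """Parameters of the shuffle null used to calibrate hit probabilities.

    ``seq_length`` is the length of the scanned sequence: each of the ``n``
    null draws is a random sequence of that length from the background
    residue frequencies (uniform 1/20 unless overridden), and the null
    statistic is its maximum window score.
    """

    seq_length: int
    n: int = DEFAULT_NULL_N
    background: tuple[float, ...] | None = None


def encode_sequence(seq: str) -> np.ndarray:
    """Encode residues as integers 0..19, with X as a neutral code."""
    codes = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch == "X":
            codes[i] = _X_CODE
        else:
            try:
                codes[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"illegal residue {ch!r} at position {i}") from None
    return codes


def _extended_weights(profile: DomainProfile) -> np.ndarray:
    # column 20 scores X as the row mean (composition-neutral)
    return np.hstack([profile.weights, profile.weights.mean(axis=1, keepdims=True)])


def window_scores(codes: np.ndarray, profile: DomainProfile) -> np.ndarray:
    """Score every window of profile length; empty array if seq too short."""
    n_win = codes.size - profile.length + 1
    if n_win <= 0:
        return np.empty(0, dtype=float)
    w = _extended_weights(profile)
    scores = np.zeros(n_win, dtype=float)
    for i in range(profile.length):
        scores += w[i, codes[i : i + n_win]]
    return scores


_NULL_CACHE: dict[tuple, np.ndarray] = {}


def null_max_distribution(profile: DomainProfile, null_model: NullModel,
                          seed: int) -> np.ndarray:
    """Sorted max-window scores of ``n`` background sequences (cached)."""
    if null_model.n < 100:
        raise ValueError(f"null model n={null_model.n} < 100: calibration unstable")
    key = (profile.name, profile.weights_key(), null_model.seq_length,
           null_model.n, null_model.background, seed)
    hit = _NULL_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng([seed & 0x7FFFFFFF, profile.weights_key(),
                                 null_model.seq_length])
    length = max(null_model.seq_length, profile.length)
    if null_model.background is None:
        draws = rng.integers(0, 20, size=(null_model.n, length))
    else:
        bg = np.asarray(null_model.background, dtype=float)
        bg = bg / bg.sum()
        draws = rng.choice(20, size=(null_model.n, length), p=bg)
    n_win = length - profile.length + 1
    w = profile.weights
    scores = np.zeros((null_model.n, n_win), dtype=float)
    for i in range(profile.length):
        scores += w[i, draws[:, i : i + n_win]]
    out = np.sort(scores.max(axis=1))
    _NULL_CACHE[key] = out
    return out


def calibrate_probability(score: float, profile: DomainProfile,
                          null_model: NullModel, seed: int = 0) -> float:
    """Empirical-percentile probability of ``score`` under the shuffle null.

    0 if the score is below every null maximum, 100 if above every one;
    monotone non-decreasing in the score for a fixed profile and seed.
    """
    null = null_max_distribution(profile, null_model, seed)
    return 100.0 * float(np.searchsorted(null, score, side="left")) / null.size


def scan_profile(seq: str, profile: DomainProfile, *,
                 min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
                 null_n: int = DEFAULT_NULL_N, seed: int = 0,
                 background: tuple[float, ...] | None = None,
                 calibrate: bool = True) -> list[DomainHit]:
    """Ungapped local scan of one profile along one sequence.

    All windows of profile length are scored; non-overlapping maxima above
    the score floor (``min_score_frac`` x the profile's consensus score) are
    reported in coordinate order. A profile longer than the sequence yields
    an empty result.
    """
    if not seq:
        raise ValueError("scan_profile: empty sequence")
    codes = encode_sequence(seq)
    scores = window_scores(codes, profile)
    if scores.size == 0:
        return []
    floor = min_score_frac * profile.consensus_score
    order = np.argsort(-scores, kind="stable")
    taken: list[tuple[int, int]] = []
    hits: list[DomainHit] = []
    for idx in order:
        s = float(scores[idx])
        if s < floor:
            break
        start, end = int(idx), int(idx) + profile.length
        if any(start < e and b < end for b, e in taken):
            continue
        taken.append((start, end))
        hits.append(DomainHit(profile.name, start, end, s))
    if calibrate and hits:
        model = NullModel(seq_length=len(seq), n=null_n, background=background)
        hits = [
            replace(h, probability=calibrate_probability(h.score, profile, model, seed))
            for h in hits
        ]
    return sorted(hits, key=lambda h: h.start)


# ---------------------------------------------------------------------------
# Coiled-coil detection
# ---------------------------------------------------------------------------

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def detect_coiled_coil(seq: str, window: int = 21,
                       threshold: float = 5.5) -> list[tuple[int, int, float]]:
    """Heptad-repeat coiled-coil segments.

    Per window, the score is the mean hydropathy at the a/d register
    positions minus the mean elsewhere, maximized over the 7 possible
    registers; windows above ``threshold`` are merged into segments,
    reported as (start, end, best window score).
    """
    if window < 14 or window % 7 != 0:
        raise ValueError("window must be >= 14 and a multiple of 7")
    n = len(seq)
    if n < window:
        return []
    hydro = np.array([_KD[ch] for ch in seq], dtype=float)
    n_win = n - window + 1
    offsets = np.arange(window)
    best = np.full(n_win, -np.inf)
    starts = np.arange(n_win)
    for register in range(7):
        ad = ((offsets + register) % 7 == 0) | ((offsets + register) % 7 == 3)
        k_ad, k_other = int(ad.sum()), int((~ad).sum())
        idx = starts[:, None] + offsets[None, :]
        vals = hydro[idx]
        contrast = vals[:, ad].sum(axis=1) / k_ad - vals[:, ~ad].sum(axis=1) / k_other
        best = np.maximum(best, contrast)
    segments: list[tuple[int, int, float]] = []
    for w in np.flatnonzero(best > threshold):
        start, end, score = int(w), int(w) + window, float(best[w])
        if segments and start <= segments[-1][1]:
            p_start, p_end, p_score = segments[-1]
            segments[-1] = (p_start, max(p_end, end), max(p_score, score))
        else:
            segments.append((start, end, score))
    return segments


# ---------------------------------------------------------------------------
# Full ORF1 annotation
# ---------------------------------------------------------------------------

def annotate_orf1(seq: str, library: Sequence[DomainProfile],
                  accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD, *,
                  min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
                  null_n: int = DEFAULT_NULL_N, seed: int = 0,
                  background: tuple[float, ...] | None = None) -> list[DomainHit]:
    """Annotate one ORF1: pooled profile hits with overlaps resolved.

    Overlapping hits keep the higher probability (ties: longer hit, then
    earlier start, then domain name). Hits below ``accept_threshold`` are
    retained but flagged not-accepted; the output is sorted by start and the
    accepted hits are pairwise non-overlapping.
    """
    if not library:
        raise ValueError("annotate_orf1: empty profile library")
    if not seq:
        return []
    pooled: list[DomainHit] = []
    for profile in sorted(library, key=lambda p: p.name):
        pooled.extend(
            scan_profile(seq, profile, min_score_frac=min_score_frac,
                         null_n=null_n, seed=seed, background=background)
        )
    pooled.sort(key=lambda h: (-(h.probability or 0.0), -h.length, h.start, h.domain))
    kept: list[DomainHit] = []
    for hit in pooled:
        if any(hit.start < k.end and k.start < hit.end for k in kept):
            continue
        kept.append(hit)
    kept = [
        replace(h, accepted=(h.probability is not None and h.probability >= accept_threshold))
        for h in kept
    ]
    return sorted(kept, key=lambda h: h.start)
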