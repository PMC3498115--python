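"""Profile scanning and motif detection.

Scanning is gapless: a segment profile is slid over the sequence and scored at
every offset; local matches above a normalized-score floor are reported with
overlaps resolved in favour of the higher score (ties -> leftmost). Normalized
score is raw score divided by the maximum attainable column sum, so a perfect
consensus match scores 1.0. Score tiers stand in for BLAST E-value strata
(strict / investigated / multidomain searches): strong >= 0.80, weak >= 0.55,
anything else above the floor is a bare candidate.

Multidomain proteins carry p25alpha *fragments* of ~70-140 aa whose N-terminal
part is always present; :func:`scan_fragments` therefore scores every prefix of
the full-domain profile in that length range and keeps, per locus, the longest
prefix among the best-scoring ones, re-measuring the fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._aa import seq_to_indices
from .model import (
    EXTENSION_LENGTH,
    FRAGMENT_BOUNDS,
    P25DomainModel,
    ROSSMANN_RE,
    SegmentProfile,
)

TIER_STRONG = 0.80
TIER_WEAK = 0.55


@dataclass(frozen=True)
class DomainHit:
    """A located profile match; coordinates 0-based half-open."""

    segment: str
    start: int
    end: int
    score: float
    normalized_score: float
    tier: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("hit coordinates must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class MotifHit:
    """One GXGXGXXGR Rossmann-like motif occurrence (9 residues)."""

    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.end - self.start != 9 or len(self.matched) != 9:
            raise ValueError("Rossmann-like motif hits span exactly 9 residues")


def _tier(normalized: float) -> str:
    if normalized >= TIER_STRONG:
        return "strong"
    if normalized >= TIER_WEAK:
        return "weak"
    return "candidate"


def _window_scores(idx: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Raw gapless score at every offset (empty if profile longer than seq)."""
    L = columns.shape[0]
    if idx.size < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return columns[np.arange(L)[None, :], windows].sum(axis=1)


def _select_nonoverlapping(candidates: list[DomainHit]) -> list[DomainHit]:
    """Greedy: higher score first, leftmost on ties; drop overlaps."""
    chosen: list[DomainHit] = []
    for hit in sorted(candidates, key=lambda h: (-h.score, h.start)):
        if not any(hit.overlaps(c) for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def scan_profile(
    seq: str,
    model: P25DomainModel | SegmentProfile,
    segment: str | None = None,
    min_normalized: float = 0.5,
) -> list[DomainHit]:
    """Locate occurrences of one model segment in ``seq``.

    Returns non-overlapping hits sorted by start; a segment longer than the
    sequence yields an empty list.
    """
    profile = model if isinstance(model, SegmentProfile) else model[segment]
    idx = seq_to_indices(seq.upper())
    scores = _window_scores(idx, profile.columns)
    if scores.size == 0:
        return []
    maxscore = profile.max_score
    normalized = scores / maxscore
    candidates = [
        DomainHit(
            profile.name, int(o), int(o) + len(profile), float(scores[o]),
            float(normalized[o]), _tier(float(normalized[o])),
        )
        for o in np.nonzero(normalized >= min_normalized)[0]
    ]
    return _select_nonoverlapping(candidates)


def scan_fragments(
    seq: str,
    model: P25DomainModel,
    min_len: int = FRAGMENT_BOUNDS[0],
    max_len: int = FRAGMENT_BOUNDS[1],
    min_normalized: float = 0.5,
) -> list[DomainHit]:
    """Locate p25alpha fragments: prefixes of the full-domain profile.

    At each offset every prefix length in [min_len, max_len] is scored; the
    best (highest normalized score, then longest) is that offset's candidate.
    Overlaps are resolved as in :func:`scan_profile`.
    """
    profile = model.long_domain_profile
    max_len = min(max_len, len(profile))
    idx = seq_to_indices(seq.upper())
    n = idx.size
    if n < min_len:
        return []
    colmax = profile.columns[:, :20].max(axis=1).cumsum()
    candidates: list[DomainHit] = []
    for o in range(n - min_len + 1):
        hi = min(max_len, n - o)
        pos_scores = profile.columns[np.arange(hi), idx[o : o + hi]]
        cum = pos_scores.cumsum()
        norm = cum[min_len - 1 : hi] / colmax[min_len - 1 : hi]
        best_rel = int(np.flatnonzero(norm == norm.max())[-1])  # longest on ties
        best_norm = float(norm[best_rel])
        if best_norm >= min_normalized:
            length = min_len + best_rel
            candidates.append(
                DomainHit(
                    "fragment", o, o + length, float(cum[length - 1]),
                    best_norm, _tier(best_norm),
                )
            )
    chosen: list[DomainHit] = []
    for hit in sorted(candidates, key=lambda h: (-h.normalized_score, -len(h), h.start)):
        if not any(hit.overlaps(c) for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def find_rossmann_motifs(seq: str) -> list[MotifHit]:
    """All (possibly overlapping) GXGXGXXGR matches, left to right."""
    seq = seq.upper()
    return [
        MotifHit(m.start(), m.start() + 9, m.group(1))
        for m in ROSSMANN_RE.finditer(seq)
    ]


def detect_extension(
    seq: str,
    motif: MotifHit,
    model: P25DomainModel,
    min_normalized: float = 0.5,
) -> DomainHit | None:
    """Score the 14-residue window right after a Rossmann-like motif.

    Returns the extension region iff 14 residues remain downstream and the
    window reaches the normalized-score floor against the extension profile.
    """
    profile = model["extension"]
    start = motif.end
    end = start + EXTENSION_LENGTH
    if end > len(seq):
        return None
    idx = seq_to_indices(seq[start:end].upper())
    score = float(profile.columns[np.arange(EXTENSION_LENGTH), idx].sum())
    normalized = score / profile.max_score
    if normalized < min_normalized:
        return None
    return DomainHit("extension", start, end, score, normalized, _tier(normalized))
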