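"""Segmented p25alpha domain model.

The p25alpha domain (Pfam05517/IPR008907) is modelled as ordered segments:

====================  ======  ====================================================
segment               length  role
====================  ======  ====================================================
``ntail``             ~50 aa  N-terminal tail of long-type TPPP1-like proteins
``core``              119 aa  N-terminal/middle part shared by all domain forms
``partial_core``      31 aa   conserved C-terminal block ("partial p25alpha
                              domain"), carries the GXGXGXXGR Rossmann-like motif
``extension``         14 aa   conserved stretch immediately after the motif,
                              present only when the motif is
====================  ======  ====================================================

``core`` + ``partial_core`` = the full (long) domain, constrained to
140-160 aa. Each segment is a per-position log-odds profile built from a seed
alignment; the packaged default model is a *designed synthetic consensus*
(data/synthetic_domain.json) that satisfies every length constraint and, by
composition, the order/disorder contrast the survey predicts. It is not copied
from any database sequence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from ._aa import ALPHABET, AA_INDEX

ROSSMANN_RE = re.compile(r"(?=(G.G.G..GR))")

LONG_DOMAIN_BOUNDS = (140, 160)
PARTIAL_CORE_LENGTHS = (31, 32)
EXTENSION_LENGTH = 14
FRAGMENT_BOUNDS = (70, 140)  # multidomain p25alpha fragments
NTAIL_APPROX = 50

SEGMENT_NAMES = ("ntail", "core", "partial_core", "extension")


@dataclass(frozen=True)
class SegmentProfile:
    """Per-position score columns for one model segment."""

    name: str
    consensus: str
    columns: np.ndarray  # (length, 21); last column = X, scores 0

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def max_score(self) -> float:
        return float(self.columns[:, :20].max(axis=1).sum())


class P25DomainModel:
    """Validated container for the segmented domain profiles."""

    def __init__(self, segments: Mapping[str, SegmentProfile], rossmann_offset: int):
        self.segments = dict(segments)
        self.rossmann_offset = rossmann_offset
        self.validate()

    def __getitem__(self, name: str) -> SegmentProfile:
        return self.segments[name]

    @property
    def long_domain_profile(self) -> SegmentProfile:
        """core + partial_core concatenated: the full long domain."""
        core, part = self.segments["core"], self.segments["partial_core"]
        return SegmentProfile(
            "long_domain",
            core.consensus + part.consensus,
            np.vstack([core.columns, part.columns]),
        )

    def validate(self) -> None:
        for name in ("core", "partial_core", "extension"):
            if name not in self.segments:
                raise ValueError(f"model missing required segment {name!r}")
        n_core = len(self.segments["core"])
        n_part = len(self.segments["partial_core"])
        lo, hi = LONG_DOMAIN_BOUNDS
        if not lo <= n_core + n_part <= hi:
            raise ValueError(
                f"core+partial_core length {n_core + n_part} outside the long-domain "
                f"bound [{lo},{hi}]"
            )
        if n_part not in PARTIAL_CORE_LENGTHS:
            raise ValueError(
                f"partial_core length {n_part} outside the partial-domain "
                f"bound {{{PARTIAL_CORE_LENGTHS[0]},{PARTIAL_CORE_LENGTHS[1]}}}"
            )
        if len(self.segments["extension"]) != EXTENSION_LENGTH:
            raise ValueError(
                f"extension length {len(self.segments['extension'])} != "
                f"{EXTENSION_LENGTH}"
            )
        part = self.segments["partial_core"].consensus
        motifs = [m.start() for m in ROSSMANN_RE.finditer(part)]
        if len(motifs) != 1:
            raise ValueError(
                f"partial_core must contain exactly one GXGXGXXGR motif, found "
                f"{len(motifs)}"
            )
        if motifs[0] != self.rossmann_offset:
            raise ValueError(
                f"rossmann_offset {self.rossmann_offset} != motif position {motifs[0]}"
            )


def build_model(
    seed_alignments: Mapping[str, Sequence[str]],
    pseudocount: float = 0.1,
    rossmann_offset: int | None = None,
) -> P25DomainModel:
    """Build per-segment log-odds profiles from seed alignments.

    score(pos, a) = log((count(pos, a) + c) / (n + 20c)) - log(1/20)
    with uniform background 1/20 and pseudocount c > 0. The consensus is the
    per-column argmax. All domain-geometry invariants are validated at build.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    segments = {}
    for name, aln in seed_alignments.items():
        if not aln:
            raise ValueError(f"segment {name!r}: empty seed alignment")
        length = len(aln[0])
        if any(len(s) != length for s in aln):
            raise ValueError(f"segment {name!r}: ragged alignment")
        counts = np.zeros((length, 20))
        for s in aln:
            for pos, a in enumerate(s.upper()):
                if a in AA_INDEX:
                    counts[pos, AA_INDEX[a]] += 1
        n = len(aln)
        logodds = np.log((counts + pseudocount) / (n + 20 * pseudocount)) - np.log(1 / 20)
        columns = np.hstack([logodds, np.zeros((length, 1))])  # X column
        consensus = "".join(ALPHABET[i] for i in logodds.argmax(axis=1))
        segments[name] = SegmentProfile(name, consensus, columns)
    if rossmann_offset is None:
        part = segments.get("partial_core")
        m = ROSSMANN_RE.search(part.consensus) if part else None
        rossmann_offset = m.start() if m else 0
    return P25DomainModel(segments, rossmann_offset)


def _load_packaged() -> dict:
    ref = resources.files("tppplike.data") / "synthetic_domain.json"
    with resources.as_file(ref) as p:
        return json.loads(p.read_text())


def default_model(pseudocount: float = 0.1) -> P25DomainModel:
    """The packaged synthetic default model (single-sequence seed alignments)."""
    data = _load_packaged()
    return build_model(
        {name: [seq] for name, seq in data["segments"].items()},
        pseudocount=pseudocount,
        rossmann_offset=data["rossmann_offset"],
    )


def synthetic_parts() -> dict:
    """Raw packaged synthetic consensus parts (segments, variants, markers)."""
    return _load_packaged()
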