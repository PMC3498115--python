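"""Subfamily classification and pairwise sequence helpers.

A protein is assigned to one of six architecture subfamilies from its
domain/motif hit set plus caller-supplied foreign-domain annotations:

* ``long_type``    — one complete p25alpha domain (core + partial core,
  140-160 aa), optionally preceded by an ~50 aa N-terminal tail; no other
  domains.
* ``short_type``   — the domain lacks the conserved 31-32 aa C-terminal
  (partial) block; typical of protists and algae.
* ``truncated``    — same architecture as short but derived from the long
  form; arthropod-specific. Sequence alone cannot separate the two, so the
  call requires high affinity to the long-core profile *and* a metazoan
  taxon; otherwise short_type is the default and the ambiguity is recorded.
* ``partial_only`` — 1-4 copies of the partial block, each with or without
  the Rossmann-like motif and its 14 aa extension.
* ``multidomain``  — p25alpha fragment(s) of ~70-140 aa plus foreign domains,
  or >= 2 fragments in one protein.
* ``apicortin``    — partial block combined with a DCX (doublecortin) domain.

Foreign domains (DCX, EFh, IQ, ...) come from annotations, never from ab
initio detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._aa import SIMILARITY_GROUPS
from .io import ProteinRecord, TaxonAssignment, load_taxonomy
from .model import LONG_DOMAIN_BOUNDS, P25DomainModel
from .scan import (
    DomainHit,
    MotifHit,
    detect_extension,
    find_rossmann_motifs,
    scan_fragments,
    scan_profile,
)

logger = logging.getLogger(__name__)

LABELS = (
    "long_type", "short_type", "truncated", "partial_only",
    "multidomain", "apicortin", "none",
)


@dataclass(frozen=True)
class ForeignDomainAnnotation:
    """A non-p25alpha domain located on the sequence (annotation, not scan)."""

    name: str
    start: int
    end: int
    source: str = "provided"  # or synthetic_marker

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("annotation coordinates must satisfy 0 <= start < end")


@dataclass
class ClassifyConfig:
    """Thresholds for architecture classification (documented defaults)."""

    min_normalized: float = 0.5
    truncated_affinity: float = 0.85
    gap_tolerance: int = 10
    min_tail: int = 40
    long_span: tuple[int, int] = LONG_DOMAIN_BOUNDS
    fragment_bounds: tuple[int, int] = (70, 140)
    #: slack when testing whether a fragment hit is the core hit itself
    fragment_margin: int = 25


@dataclass
class ArchitectureCall:
    """Subfamily label plus copy counts and evidence for one protein."""

    label: str
    n_p25_copies: int = 0
    n_partial_copies: int = 0
    has_rossmann: list[bool] = field(default_factory=list)
    has_extension: bool = False
    has_ntail: bool = False
    other_domains: list[str] = field(default_factory=list)
    evidence: list = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "apicortin" and (
            self.n_partial_copies < 1 or "DCX" not in self.other_domains
        ):
            raise ValueError("apicortin requires >=1 partial copy and a DCX domain")


@lru_cache(maxsize=1)
def _default_taxonomy() -> Mapping[str, TaxonAssignment]:
    return load_taxonomy()


def _is_metazoan(taxon: str | None, taxonomy: Mapping[str, TaxonAssignment] | None) -> bool:
    if taxon is None:
        return False
    taxonomy = taxonomy if taxonomy is not None else _default_taxonomy()
    assignment = taxonomy.get(taxon)
    return assignment is not None and "Metazoa" in assignment.path


def count_domain_copies(hits: Sequence[DomainHit]) -> int:
    """Number of disjoint domain hits; overlapping input is a contract breach."""
    for i, a in enumerate(hits):
        for b in hits[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"overlapping hits {a} / {b}: upstream scan broke its contract")
    return len(hits)


def detect_nterminal_tail(seq: str, first_hit: DomainHit, min_tail: int = 40) -> bool:
    """True iff at least ``min_tail`` residues precede the first domain hit."""
    if first_hit.end > len(seq):
        raise ValueError("hit extends beyond sequence")
    return first_hit.start >= min_tail


def classify_architecture(
    seq: str | ProteinRecord,
    model: P25DomainModel,
    foreign: Iterable[ForeignDomainAnnotation] = (),
    taxon: str | None = None,
    taxonomy: Mapping[str, TaxonAssignment] | None = None,
    config: ClassifyConfig | None = None,
) -> ArchitectureCall:
    """Classify one protein into its architecture subfamily (total function)."""
    if isinstance(seq, ProteinRecord):
        if taxon is None:
            taxon = seq.species or None
        seq = seq.sequence
    cfg = config or ClassifyConfig()
    foreign = list(foreign)
    foreign_names = [f.name for f in foreign]

    core_hits = scan_profile(seq, model, "core", cfg.min_normalized)
    partial_hits = scan_profile(seq, model, "partial_core", cfg.min_normalized)
    motifs = find_rossmann_motifs(seq)
    evidence: list = core_hits + partial_hits + motifs

    def copy_flags(hits: list[DomainHit]) -> tuple[list[bool], bool]:
        flags, any_ext = [], False
        for h in hits:
            inside = [m for m in motifs if h.start <= m.start and m.end <= h.end]
            flags.append(bool(inside))
            for m in inside:
                if detect_extension(seq, m, model, cfg.min_normalized):
                    any_ext = True
        return flags, any_ext

    # (2) apicortin: partial p25alpha block combined with a DCX domain
    if partial_hits and "DCX" in foreign_names:
        if core_hits:
            msg = "DCX precedence: core-like hit ignored for apicortin call"
            logger.warning(msg)
        flags, has_ext = copy_flags(partial_hits)
        return ArchitectureCall(
            "apicortin",
            n_p25_copies=0,
            n_partial_copies=len(partial_hits),
            has_rossmann=flags,
            has_extension=has_ext,
            other_domains=foreign_names,
            evidence=evidence,
        )

    # (3) long-type: contiguous core + partial core spanning a full domain
    if not foreign:
        lo, hi = cfg.long_span
        for c in core_hits:
            for p in partial_hits:
                gap = p.start - c.end
                span = p.end - c.start
                if abs(gap) <= cfg.gap_tolerance and lo <= span <= hi:
                    flags, has_ext = copy_flags([p])
                    return ArchitectureCall(
                        "long_type",
                        n_p25_copies=1,
                        n_partial_copies=0,
                        has_rossmann=flags,
                        has_extension=has_ext,
                        has_ntail=detect_nterminal_tail(seq, c, cfg.min_tail),
                        evidence=evidence,
                    )

    fragments = scan_fragments(
        seq, model, cfg.fragment_bounds[0], cfg.fragment_bounds[1], cfg.min_normalized
    )

    # (4) one core-like domain, no partial block, no foreign domains:
    # short-type by default, truncated on long-core affinity + metazoan taxon.
    # Guard: every fragment hit must be the core region itself (within a small
    # margin); a fragment elsewhere means a multidomain architecture (next rule).
    def _is_core_itself(f: DomainHit) -> bool:
        hit = core_hits[0]
        return (
            f.start >= hit.start - cfg.fragment_margin
            and f.end <= hit.end + cfg.fragment_margin
        )

    if (
        len(core_hits) == 1
        and not partial_hits
        and not foreign
        and all(_is_core_itself(f) for f in fragments)
    ):
        hit = core_hits[0]
        notes = []
        if hit.normalized_score >= cfg.truncated_affinity and _is_metazoan(taxon, taxonomy):
            label = "truncated"
        else:
            label = "short_type"
            if hit.normalized_score >= cfg.truncated_affinity:
                notes.append(
                    "long-core affinity met but taxon not metazoan/unknown; "
                    "defaulting to short_type"
                )
        return ArchitectureCall(
            label, n_p25_copies=1, evidence=evidence, notes=notes,
            has_ntail=detect_nterminal_tail(seq, hit, cfg.min_tail),
        )

    # (5) multidomain: 70-140 aa fragment(s) with foreign domains, or >=2 fragments
    if (fragments and foreign) or len(fragments) >= 2:
        return ArchitectureCall(
            "multidomain",
            n_p25_copies=len(fragments),
            other_domains=foreign_names,
            evidence=evidence + fragments,
        )

    # (6) only partial copies
    if partial_hits and not core_hits:
        flags, has_ext = copy_flags(partial_hits)
        return ArchitectureCall(
            "partial_only",
            n_partial_copies=len(partial_hits),
            has_rossmann=flags,
            has_extension=has_ext,
            other_domains=foreign_names,
            evidence=evidence,
        )

    # (7) nothing qualifying
    return ArchitectureCall("none", other_domains=foreign_names, evidence=evidence)


def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def pairwise_align_stats(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    similarity_groups: Sequence[str] = SIMILARITY_GROUPS,
) -> tuple[float, float]:
    """Percent identity and similarity from a global affine-gap alignment.

    Identity = identical aligned pairs / alignment columns excluding terminal
    gaps, x100. Similarity additionally credits substitutions within the
    conventional strong residue groups (ILVM, FYW, KRH, DE, ST, NQ, AG).
    """
    s1 = a.sequence if isinstance(a, ProteinRecord) else a.upper()
    s2 = b.sequence if isinstance(b, ProteinRecord) else b.upper()
    aln = _aligner(gap_open, gap_extend).align(s1, s2)[0]
    row1, row2 = str(aln[0]), str(aln[1])
    group_of = {aa: g for g in similarity_groups for aa in g}

    def span(row: str) -> tuple[int, int]:
        return len(row) - len(row.lstrip("-")), len(row.rstrip("-"))

    lo = max(span(row1)[0], span(row2)[0])
    hi = min(span(row1)[1], span(row2)[1])
    ncols = hi - lo
    ident = sim = 0
    for x, y in zip(row1[lo:hi], row2[lo:hi]):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            sim += 1
        elif group_of.get(x) is not None and group_of.get(x) == group_of.get(y):
            sim += 1
    return 100.0 * ident / ncols, 100.0 * sim / ncols


def alignment_score(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Global BLOSUM62 affine-gap alignment score (default RBH scorer)."""
    s1 = a.sequence if isinstance(a, ProteinRecord) else a.upper()
    s2 = b.sequence if isinstance(b, ProteinRecord) else b.upper()
    return float(_aligner(11.0, 1.0).score(s1, s2))


def reciprocal_best_hits(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    scorer: Callable[[ProteinRecord, ProteinRecord], float] = alignment_score,
) -> list[tuple[str, str]]:
    """1:1 ortholog candidates: pairs that are each other's best-scoring match.

    Argmax ties are broken toward the lexicographically smaller id and logged.
    """
    if not set_a or not set_b:
        raise ValueError("both record sets must be non-empty")

    def best(query, others) -> str:
        scored = sorted(
            ((-scorer(query, o), o.id) for o in others), key=lambda t: (t[0], t[1])
        )
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            logger.warning(
                "RBH tie for %s: %s vs %s, keeping %s",
                query.id, scored[0][1], scored[1][1], scored[0][1],
            )
        return scored[0][1]

    best_ab = {a.id: best(a, set_b) for a in set_a}
    best_ba = {b.id: best(b, set_a) for b in set_b}
    return [(aid, bid) for aid, bid in best_ab.items() if best_ba.get(bid) == aid]
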