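"""Labelled synthetic protein generator.

Each subfamily architecture is assembled from the packaged synthetic consensus
parts with the geometry the survey states (quasi-aligned, realistic lengths):

* long_type     — [~50 aa N-tail] + 119 aa core + 31 aa partial core + 14 aa
                  extension (full domain 150 aa, inside 140-160)
* short_type    — the core only, as a fixed 20%-diverged variant (the short
                  form is a distinct outparalog, not a noisy long core)
* truncated     — the core only, as a fixed 5%-diverged variant (derived from
                  the long form; long-core affinity stays high)
* partial_only  — 1-4 partial-core copies, each +/- Rossmann motif and, when
                  the motif is present, the 14 aa extension; disordered linkers
* multidomain   — 1-2 p25alpha fragments (prefixes of the full domain,
                  70-140 aa) plus foreign-domain marker blocks
* apicortin     — one partial core (+extension) combined with a DCX marker

Point substitutions are applied at ``substitution_rate`` everywhere except
Rossmann-motif positions; indels at ``indel_rate`` are confined to linkers and
tails. Both guarantees keep the emitted truth labels valid by construction.
Foreign domains are composition-distinct marker blocks with coordinates
returned as annotations (classification consumes annotations, never ab initio
detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._aa import ALPHABET
from .architecture import ArchitectureCall, ForeignDomainAnnotation
from .io import ProteinRecord, write_fasta
from .model import synthetic_parts

CLASS_LABELS = (
    "long_type", "short_type", "truncated", "partial_only", "multidomain", "apicortin",
)

#: default species per class, all present in the packaged taxonomy
DEFAULT_TAXA = {
    "long_type": "Homo sapiens",
    "short_type": "Tetrahymena thermophila",
    "truncated": "Drosophila melanogaster",
    "partial_only": "Giardia lamblia",
    "multidomain": "Micromonas pusilla",
    "apicortin": "Toxoplasma gondii",
}

#: linker/tail residue pool: disordered composition, no R (cannot spawn a
#: spurious Rossmann-like motif) — a documented generator guarantee
LINKER_POOL = "EKSGDQPNTA"


@dataclass
class SynthSpec:
    """Recipe for one batch of labelled synthetic proteins."""

    class_label: str
    n: int = 10
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    n_partial_copies: int | None = None  # partial_only; sampled from 1-4 if None
    rossmann_flags: tuple[bool, ...] | None = None  # per partial copy
    include_ntail: bool = True
    taxon: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0 <= self.indel_rate <= 0.05:
            raise ValueError("indel_rate must be in [0, 0.05]")
        if self.n_partial_copies is not None and not 1 <= self.n_partial_copies <= 4:
            raise ValueError("n_partial_copies must be in 1..4")
        if self.taxon is None:
            self.taxon = DEFAULT_TAXA[self.class_label]


class SyntheticProtein(NamedTuple):
    record: ProteinRecord
    truth: ArchitectureCall
    foreign: list[ForeignDomainAnnotation]


@dataclass
class _Part:
    text: str
    kind: str  # 'linker' | segment name | 'marker'
    name: str = ""
    protect: tuple[int, int] | None = None  # relative protected range (motif)


def _linker(rng: np.random.Generator, lo: int, hi: int) -> _Part:
    length = int(rng.integers(lo, hi + 1))
    return _Part("".join(rng.choice(list(LINKER_POOL), size=length)), "linker")


def _motifless_partial(partial: str, offset: int, rng: np.random.Generator) -> str:
    """Partial-core copy with the Rossmann motif overwritten (no G/R left)."""
    filler = "".join(rng.choice(list("EKSDQ"), size=9))
    return partial[:offset] + filler + partial[offset + 9 :]


def _assemble(parts: Sequence[_Part], spec: SynthSpec, rng: np.random.Generator):
    # indels confined to linkers, applied before offsets are fixed
    realized: list[_Part] = []
    for p in parts:
        text = p.text
        if p.kind == "linker" and spec.indel_rate > 0:
            chars = []
            for c in text:
                r = rng.random()
                if r < spec.indel_rate / 2:
                    continue  # deletion
                chars.append(c)
                if r > 1 - spec.indel_rate / 2:
                    chars.append(str(rng.choice(list(LINKER_POOL))))
            text = "".join(chars) or text[:1]
        realized.append(_Part(text, p.kind, p.name, p.protect))

    seq_chars: list[str] = []
    protected: set[int] = set()
    annotations: list[ForeignDomainAnnotation] = []
    offset = 0
    for p in realized:
        if p.kind == "marker":
            annotations.append(
                ForeignDomainAnnotation(p.name, offset, offset + len(p.text), "synthetic_marker")
            )
        if p.protect is not None:
            protected.update(range(offset + p.protect[0], offset + p.protect[1]))
        seq_chars.extend(p.text)
        offset += len(p.text)

    if spec.substitution_rate > 0:
        hit = rng.random(len(seq_chars)) < spec.substitution_rate
        for i in np.flatnonzero(hit):
            if int(i) in protected:
                continue
            old = seq_chars[i]
            choices = [a for a in ALPHABET if a != old]
            seq_chars[i] = str(rng.choice(choices))
    return "".join(seq_chars), annotations


def generate_class_sequence(
    spec: SynthSpec,
    parts_data: dict | None = None,
    rng: np.random.Generator | None = None,
    record_id: str | None = None,
) -> SyntheticProtein:
    """Emit one synthetic protein with its ground-truth architecture call."""
    data = parts_data or synthetic_parts()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    seg = data["segments"]
    var = data["variants"]
    markers = data["markers"]
    moff = data["rossmann_offset"]
    label = spec.class_label
    parts: list[_Part] = []
    truth_kwargs: dict = {}

    if label == "long_type":
        if spec.include_ntail:
            parts.append(_Part(seg["ntail"], "ntail"))
        parts += [
            _Part(seg["core"], "core"),
            _Part(seg["partial_core"], "partial_core", protect=(moff, moff + 9)),
            _Part(seg["extension"], "extension"),
        ]
        truth_kwargs = dict(
            n_p25_copies=1, has_rossmann=[True], has_extension=True,
            has_ntail=spec.include_ntail,
        )
    elif label == "short_type":
        parts.append(_Part(var["short_core"], "core"))
        truth_kwargs = dict(n_p25_copies=1)
    elif label == "truncated":
        parts.append(_Part(var["truncated_core"], "core"))
        truth_kwargs = dict(n_p25_copies=1)
    elif label == "partial_only":
        k = spec.n_partial_copies or int(rng.integers(1, 5))
        flags = spec.rossmann_flags or (True,) * k
        if len(flags) != k:
            raise ValueError("rossmann_flags length must equal n_partial_copies")
        parts.append(_linker(rng, 3, 10))
        for flag in flags:
            if flag:
                parts.append(
                    _Part(seg["partial_core"], "partial_core", protect=(moff, moff + 9))
                )
                parts.append(_Part(seg["extension"], "extension"))
            else:
                parts.append(
                    _Part(_motifless_partial(seg["partial_core"], moff, rng), "partial_core")
                )
            parts.append(_linker(rng, 5, 20))
        truth_kwargs = dict(
            n_partial_copies=k, has_rossmann=list(flags), has_extension=any(flags),
        )
    elif label == "multidomain":
        long_consensus = seg["core"] + seg["partial_core"]
        n_frag = int(rng.integers(1, 3))
        with_marker = n_frag == 1 or bool(rng.integers(0, 2))
        # DCX is reserved for apicortins: partial p25alpha + DCX defines that
        # class, so multidomain proteins draw from the other marker blocks
        pool = sorted(set(markers) - {"DCX"})
        marker_names = (
            [str(x) for x in rng.choice(pool, size=1 + int(rng.integers(0, 2)), replace=False)]
            if with_marker
            else []
        )
        parts.append(_linker(rng, 5, 15))
        for _ in range(n_frag):
            frag_len = int(rng.integers(70, 141))
            parts.append(_Part(long_consensus[:frag_len], "fragment"))
            parts.append(_linker(rng, 10, 25))
        for name in marker_names:
            parts.append(_Part(markers[name], "marker", name=name))
            parts.append(_linker(rng, 5, 15))
        truth_kwargs = dict(n_p25_copies=n_frag, other_domains=marker_names)
    elif label == "apicortin":
        if spec.n_partial_copies == 0:
            raise ValueError("apicortin requires at least one partial copy")
        parts += [
            _linker(rng, 20, 40),
            _Part(seg["partial_core"], "partial_core", protect=(moff, moff + 9)),
            _Part(seg["extension"], "extension"),
            _linker(rng, 10, 20),
            _Part(markers["DCX"], "marker", name="DCX"),
            _linker(rng, 3, 8),
        ]
        truth_kwargs = dict(
            n_partial_copies=1, has_rossmann=[True], has_extension=True,
            other_domains=["DCX"],
        )

    sequence, annotations = _assemble(parts, spec, rng)
    record = ProteinRecord(
        id=record_id or f"{label}_{rng.integers(0, 10**9):09d}",
        sequence=sequence,
        species=spec.taxon,
    )
    truth = ArchitectureCall(label, **truth_kwargs)
    return SyntheticProtein(record, truth, annotations)


def default_specs(
    n: int = 10, substitution_rate: float = 0.0, indel_rate: float = 0.0
) -> list[SynthSpec]:
    """One spec per subfamily class at the given noise level."""
    return [
        SynthSpec(label, n=n, substitution_rate=substitution_rate, indel_rate=indel_rate)
        for label in CLASS_LABELS
    ]


def generate_batch(
    specs: Iterable[SynthSpec], seed: int = 0, parts_data: dict | None = None
) -> list[SyntheticProtein]:
    """Generate all records for the given specs; reproducible from seed."""
    data = parts_data or synthetic_parts()
    rng = np.random.default_rng(seed)
    out: list[SyntheticProtein] = []
    for spec in specs:
        for j in range(spec.n):
            out.append(
                generate_class_sequence(
                    spec, data, rng, record_id=f"{spec.class_label}_{j:03d}"
                )
            )
    return out


def _fmt_foreign(annos: list[ForeignDomainAnnotation]) -> str:
    return ";".join(f"{a.name}:{a.start}-{a.end}" for a in annos) or "-"


def parse_foreign(cell: str) -> list[ForeignDomainAnnotation]:
    """Inverse of the truth-table 'foreign' column format."""
    if cell in ("-", "", None):
        return []
    out = []
    for tok in str(cell).split(";"):
        name, span = tok.split(":")
        start, end = span.split("-")
        out.append(ForeignDomainAnnotation(name, int(start), int(end), "synthetic_marker"))
    return out


def generate_dataset(
    specs: Iterable[SynthSpec],
    out_dir: str | Path,
    seed: int = 0,
    parts_data: dict | None = None,
) -> tuple[Path, Path]:
    """Write a FASTA + truth TSV pair; byte-reproducible from the seed."""
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    batch = generate_batch(specs, seed=seed, parts_data=parts_data)
    fasta_path = write_fasta([s.record for s in batch], out_dir / "synthetic.fasta")
    truth_path = out_dir / "truth.tsv"
    header = [
        "id", "class_label", "species", "n_p25_copies", "n_partial_copies",
        "has_rossmann", "has_extension", "has_ntail", "other_domains", "foreign",
    ]
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for rec, truth, annos in batch:
            fh.write(
                "\t".join(
                    [
                        rec.id,
                        truth.label,
                        rec.species,
                        str(truth.n_p25_copies),
                        str(truth.n_partial_copies),
                        ";".join("1" if f else "0" for f in truth.has_rossmann) or "-",
                        "1" if truth.has_extension else "0",
                        "1" if truth.has_ntail else "0",
                        ";".join(truth.other_domains) or "-",
                        _fmt_foreign(annos),
                    ]
                )
                + "\n"
            )
    return fasta_path, truth_path
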