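"""Sequence and fixture I/O.

FASTA headers carry record metadata as ``key=value`` tokens after the id
(spaces separate tokens, underscores stand in for spaces inside values), e.g.::

    >TPPP1_HUMAN species=Homo_sapiens db=RefSeq est=0

The reader is deliberately strict: it reports the line number of the first
syntactic problem, rejects duplicate ids, and maps non-standard residue codes
(B, Z, U, J, O, ``*``) to X with a warning.

Fixture tables transcribe the survey's printed lists of truncated TPPPs
(T2), multidomain proteins (T3) and partial-domain proteins (T4); sequences
are not shipped, only metadata, so these drive tabulation, not scanning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from ._aa import NONSTANDARD, VALID_RESIDUES

SOURCE_DBS = {"RefSeq", "GenBank", "JGI", "Broad", "UniProt", "GiardiaDB", "other"}
TABLE_FILES = {
    "T2_truncated": "table2_truncated.tsv",
    "T3_multidomain": "table3_multidomain.tsv",
    "T4_partial": "table4_partial.tsv",
}
#: subfamily each fixture table tabulates under
TABLE_SUBFAMILY = {
    "T2_truncated": "truncated",
    "T3_multidomain": "multidomain",
    "T4_partial": "partial_only",
}


class FastaParseError(ValueError):
    """Malformed FASTA; the message names the offending line."""


@dataclass
class ProteinRecord:
    """One protein (or translated EST) sequence with database metadata."""

    id: str
    sequence: str
    species: str = ""
    source_db: str = "other"
    is_est: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}; "
                "alphabet is the 20 amino acids plus X"
            )
        if self.source_db not in SOURCE_DBS:
            self.source_db = "other"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FixtureRow:
    """One printed row of a packaged survey table (metadata only)."""

    table_id: str
    species: str
    accession: str
    phylum_path: tuple[str, ...]
    n_p25_domains: int
    rossmann_flags: list[bool] = field(default_factory=list)
    other_domains: list[str] = field(default_factory=list)
    source: str = "other"
    is_est: bool = False
    questionable: bool = False

    def __post_init__(self) -> None:
        if self.n_p25_domains < 0:
            raise ValueError("n_p25_domains must be >= 0")
        if self.table_id == "T2_truncated":
            if self.n_p25_domains != 1 or self.other_domains:
                raise ValueError(
                    f"{self.accession}: truncated-table rows carry exactly one "
                    "p25alpha domain and no other domains"
                )
        if self.table_id == "T4_partial" and self.rossmann_flags:
            if len(self.rossmann_flags) != self.n_p25_domains:
                raise ValueError(
                    f"{self.accession}: {len(self.rossmann_flags)} Rossmann flags "
                    f"for {self.n_p25_domains} partial-domain copies"
                )

    @property
    def subfamily(self) -> str:
        return TABLE_SUBFAMILY[self.table_id]


class TaxonAssignment(NamedTuple):
    supergroup: str
    megagroup: str
    path: tuple[str, ...]


UNASSIGNED = TaxonAssignment("unassigned", "unassigned", ())


def _sanitize(seq: str, record_id: str) -> str:
    mapped = [NONSTANDARD.get(a, a) for a in seq]
    if mapped != list(seq):
        warnings.warn(
            f"record {record_id!r}: non-standard residue(s) mapped to X",
            stacklevel=3,
        )
    return "".join(mapped)


def _parse_header(line: str) -> dict:
    tokens = line[1:].split()
    meta: dict = {"id": tokens[0] if tokens else ""}
    for tok in tokens[1:]:
        if "=" not in tok:
            continue
        key, value = tok.split("=", 1)
        if key == "species":
            meta["species"] = value.replace("_", " ")
        elif key == "db":
            meta["source_db"] = value
        elif key == "est":
            meta["is_est"] = value in ("1", "true", "True", "yes")
    return meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Raises :class:`FastaParseError` naming the line for syntactic problems
    and for duplicate ids; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    meta: dict | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if meta is None:
            return
        seq = _sanitize("".join(chunks), meta["id"])
        if not seq:
            raise FastaParseError(
                f"{path}:{header_line}: entry {meta['id']!r} has no sequence"
            )
        records.append(ProteinRecord(sequence=seq, **meta))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                meta = _parse_header(line)
                if not meta["id"]:
                    raise FastaParseError(f"{path}:{lineno}: header with empty id")
                if meta["id"] in seen:
                    raise FastaParseError(
                        f"{path}:{lineno}: duplicate id {meta['id']!r} "
                        f"(first seen on line {seen[meta['id']]})"
                    )
                seen[meta["id"]] = lineno
                header_line = lineno
                chunks = []
            elif meta is None:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            else:
                chunks.append(line)
    flush()
    if not records:
        warnings.warn(f"{path}: empty FASTA, no records read", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as FASTA (60-char wrap); metadata in header tokens."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            tokens = [rec.id]
            if rec.species:
                tokens.append(f"species={rec.species.replace(' ', '_')}")
            if rec.source_db != "other":
                tokens.append(f"db={rec.source_db}")
            if rec.is_est:
                tokens.append("est=1")
            fh.write(">" + " ".join(tokens) + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


def _split(cell: str) -> list[str]:
    return [] if cell in ("-", "", None) else str(cell).split(";")


def load_fixture_table(table_id: str) -> list[FixtureRow]:
    """Load a packaged survey table (T2_truncated, T3_multidomain, T4_partial)."""
    if table_id not in TABLE_FILES:
        raise KeyError(f"unknown fixture table {table_id!r}; one of {sorted(TABLE_FILES)}")
    ref = resources.files("tppplike.data") / TABLE_FILES[table_id]
    if not ref.is_file():  # pragma: no cover - packaging error
        raise FileNotFoundError(f"packaged fixture {TABLE_FILES[table_id]} missing")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str).fillna("-")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            FixtureRow(
                table_id=table_id,
                species=r["species"],
                accession=r["accession"],
                phylum_path=tuple(_split(r["phylum_path"])),
                n_p25_domains=int(r["n_p25_domains"]),
                rossmann_flags=[f == "yes" for f in _split(r["rossmann_flags"])],
                other_domains=_split(r["other_domains"]),
                source=r["source"],
                is_est=r["is_est"] == "1",
                questionable=r["questionable"] == "1",
            )
        )
    return rows


def load_taxonomy() -> dict[str, TaxonAssignment]:
    """Species -> (supergroup, megagroup, sub-taxa path) for packaged taxa.

    The mapping is total over fixture species; lookups of unknown species are
    handled by :func:`tppplike.phyletics.assign_taxon`, never silently dropped.
    """
    ref = resources.files("tppplike.data") / "taxonomy.tsv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return {
        r["species"]: TaxonAssignment(
            r["supergroup"], r["megagroup"], tuple(r["path"].split(";"))
        )
        for _, r in df.iterrows()
    }
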