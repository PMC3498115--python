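"""Phyletic distribution tabulation.

Eukaryote taxa are organised Adl-style into six supergroups (Opisthokonta,
Amoebozoa, Apusozoa, Archaeplastida, Chromalveolata, Rhizaria, Excavata)
grouped into three megagroups: unikonts (Opisthokonta + Amoebozoa, plus the
opisthokont sister Apusozoa), the photosynthetic megagroup (Archaeplastida +
Chromalveolata + Rhizaria) and Excavata. Classified proteins are tallied per
(taxon row, subfamily) with translated-EST sub-counts, rendered in the
conventional "total (est)" style.

Rows flagged questionable (footnoted accessions) stay in the headline counts
-- that is the printed tables' own arithmetic -- but are surfaced separately
via :attr:`DistributionTable.footnotes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .architecture import ArchitectureCall
from .io import FixtureRow, ProteinRecord, TaxonAssignment, UNASSIGNED

SUBFAMILIES = (
    "long_type", "truncated", "short_type", "multidomain", "partial_only", "apicortin",
)
MEGAGROUP_ORDER = ("unikonts", "photosynthetic", "Excavata", "unassigned")
SUPERGROUP_ORDER = (
    "Opisthokonta", "Amoebozoa", "Apusozoa", "Archaeplastida",
    "Chromalveolata", "Rhizaria", "Excavata", "unassigned",
)


def assign_taxon(
    record: ProteinRecord | FixtureRow | str,
    taxonomy: Mapping[str, TaxonAssignment],
) -> TaxonAssignment:
    """Deterministic species lookup; unknown species map to 'unassigned'."""
    species = record if isinstance(record, str) else record.species
    assignment = taxonomy.get(species)
    if assignment is not None:
        return assignment
    if isinstance(record, FixtureRow) and record.phylum_path:
        # fixture rows carry their printed phylogenetic-group path as fallback
        return TaxonAssignment("unassigned", "unassigned", record.phylum_path)
    return UNASSIGNED


@dataclass
class DistributionTable:
    """Supergroup x subfamily counts with EST sub-counts (survey-table shape)."""

    items: pd.DataFrame  # one row per classified item

    def count(
        self,
        subfamily: str | None = None,
        taxon: str | None = None,
        est_only: bool = False,
    ) -> int:
        """Count items, optionally restricted to one subfamily and/or taxon.

        ``taxon`` matches the megagroup, the supergroup, or any element of the
        sub-taxa path.
        """
        df = self.items
        if subfamily is not None:
            df = df[df["subfamily"] == subfamily]
        if taxon is not None:
            mask = (
                (df["megagroup"] == taxon)
                | (df["supergroup"] == taxon)
                | df["path"].map(lambda p: taxon in p)
            )
            df = df[mask]
        if est_only:
            df = df[df["is_est"]]
        return int(len(df))

    @property
    def footnotes(self) -> pd.DataFrame:
        return self.items[self.items["questionable"]]

    @property
    def diagnostics(self) -> pd.DataFrame:
        """Items that classified to 'none' (excluded from the main table)."""
        return self.items[self.items["subfamily"] == "none"]

    def _pivot(self, df: pd.DataFrame, est: bool) -> pd.DataFrame:
        sub = df[df["is_est"]] if est else df
        out = pd.crosstab(
            [sub["megagroup"], sub["supergroup"], sub["subtaxon"]], sub["subfamily"]
        )
        return out.reindex(columns=list(SUBFAMILIES), fill_value=0)

    def table(self) -> pd.DataFrame:
        """Hierarchical counts: rows (megagroup, supergroup, sub-taxon),
        columns (subfamily, total|est)."""
        cols = pd.MultiIndex.from_tuples(
            [(s, k) for s in SUBFAMILIES for k in ("total", "est")]
        )
        if self.items.empty:
            idx = pd.MultiIndex.from_tuples(
                [], names=["megagroup", "supergroup", "subtaxon"]
            )
            return pd.DataFrame(index=idx, columns=cols).fillna(0).astype(int)
        df = self.items[self.items["subfamily"] != "none"]
        if df.empty:
            idx = pd.MultiIndex.from_tuples(
                [], names=["megagroup", "supergroup", "subtaxon"]
            )
            return pd.DataFrame(index=idx, columns=cols).fillna(0).astype(int)
        total = self._pivot(df, est=False)
        est = self._pivot(df, est=True).reindex(total.index, fill_value=0)
        out = pd.concat({"total": total, "est": est}, axis=1)
        out = out.swaplevel(axis=1).sort_index(axis=1)
        return out.reindex(columns=cols, fill_value=0)

    def supergroup_table(self) -> pd.DataFrame:
        """Marginal per-supergroup totals (sum over sub-taxa)."""
        return self.table().groupby(level=[0, 1]).sum()

    def grand_totals(self) -> pd.Series:
        return self.table().sum(axis=0)

    def render(self) -> str:
        """Text table in the survey's "total (est)" convention."""
        tab = self.table()
        lines = ["taxon\t" + "\t".join(SUBFAMILIES)]

        def fmt_row(label: str, row) -> str:
            cells = []
            for fam in SUBFAMILIES:
                t, e = int(row[(fam, "total")]), int(row[(fam, "est")])
                cells.append("" if t == 0 else (f"{t} ({e})" if e else str(t)))
            return label + "\t" + "\t".join(cells)

        gt = self.grand_totals()
        lines.append(fmt_row("Total", gt))
        for mega in MEGAGROUP_ORDER:
            if mega not in tab.index.get_level_values(0):
                continue
            block = tab.loc[mega]
            for sg in SUPERGROUP_ORDER:
                if sg not in block.index.get_level_values(0):
                    continue
                sgblock = block.loc[sg]
                lines.append(fmt_row(f"{sg}", sgblock.sum(axis=0)))
                for sub, row in sgblock.iterrows():
                    lines.append(fmt_row(f"  {sub}", row))
        if len(self.footnotes):
            lines.append("")
            lines.append("Footnotes (questionable assignments, kept in counts):")
            for _, r in self.footnotes.iterrows():
                lines.append(f"  {r['species']} {r['id']} [{r['subfamily']}]")
        return "\n".join(lines)


def tabulate_distribution(
    calls: Iterable[tuple[ProteinRecord | FixtureRow, ArchitectureCall | str]],
    taxonomy: Mapping[str, TaxonAssignment],
) -> DistributionTable:
    """Tally classified proteins/fixture rows into the distribution table.

    Each item pairs a record (or fixture row) with its subfamily label, given
    either as an :class:`ArchitectureCall` or as a plain label string. Items
    labelled 'none' are kept for diagnostics but excluded from the table.
    """
    rows = []
    for record, call in calls:
        label = call.label if isinstance(call, ArchitectureCall) else str(call)
        sg, mega, path = assign_taxon(record, taxonomy)
        rows.append(
            {
                "id": getattr(record, "id", getattr(record, "accession", "")),
                "species": record.species,
                "subfamily": label,
                "supergroup": sg,
                "megagroup": mega,
                "subtaxon": path[0] if path else "unassigned",
                "path": path,
                "is_est": bool(getattr(record, "is_est", False)),
                "questionable": bool(getattr(record, "questionable", False)),
            }
        )
    columns = [
        "id", "species", "subfamily", "supergroup", "megagroup",
        "subtaxon", "path", "is_est", "questionable",
    ]
    return DistributionTable(pd.DataFrame(rows, columns=columns))
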