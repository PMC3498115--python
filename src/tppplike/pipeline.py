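"""End-to-end survey pipeline and run configuration.

`run_pipeline` chains the stages — scan, classify, tabulate, disorder,
optional NJ tree — over a FASTA file and writes a deterministic report
bundle (TSV tables, a rendered distribution in "total (est)" style, newick).
Every threshold used is logged. The per-stage functions mirror the stages
1:1 for programmatic use.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .architecture import (
    ArchitectureCall,
    ClassifyConfig,
    ForeignDomainAnnotation,
    classify_architecture,
)
from .disorder import disorder_scores
from .io import ProteinRecord, TaxonAssignment, load_taxonomy, read_fasta
from .model import P25DomainModel, default_model
from .phylo import distance_matrix, nj_tree
from .phyletics import tabulate_distribution
from .scan import scan_fragments, scan_profile
from .synth import parse_foreign

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of a pipeline run; YAML round-trippable."""

    min_normalized: float = 0.5
    truncated_affinity: float = 0.85
    gap_tolerance: int = 10
    min_tail: int = 40
    disorder_window: int = 21
    disorder_threshold: float = 0.5
    build_tree: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_normalized <= 1:
            raise ValueError("min_normalized must be in [0, 1]")
        if self.disorder_window % 2 == 0:
            raise ValueError("disorder_window must be odd")

    def classify_config(self) -> ClassifyConfig:
        return ClassifyConfig(
            min_normalized=self.min_normalized,
            truncated_affinity=self.truncated_affinity,
            gap_tolerance=self.gap_tolerance,
            min_tail=self.min_tail,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportBundle:
    out_dir: Path
    calls: dict[str, ArchitectureCall] = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def scan_table(records: list[ProteinRecord], model: P25DomainModel, cfg: RunConfig) -> pd.DataFrame:
    """Domain/fragment hits for every record (the `scan` stage)."""
    rows = []
    for rec in records:
        for segment in ("core", "partial_core"):
            for h in scan_profile(rec.sequence, model, segment, cfg.min_normalized):
                rows.append((rec.id, h.segment, h.start, h.end, round(h.normalized_score, 4), h.tier))
        for h in scan_fragments(rec.sequence, model, min_normalized=cfg.min_normalized):
            rows.append((rec.id, h.segment, h.start, h.end, round(h.normalized_score, 4), h.tier))
    return pd.DataFrame(rows, columns=["id", "segment", "start", "end", "normalized_score", "tier"])


def classify_records(
    records: list[ProteinRecord],
    model: P25DomainModel,
    cfg: RunConfig,
    annotations: Mapping[str, list[ForeignDomainAnnotation]] | None = None,
    taxonomy: Mapping[str, TaxonAssignment] | None = None,
) -> dict[str, ArchitectureCall]:
    annotations = annotations or {}
    return {
        rec.id: classify_architecture(
            rec, model, annotations.get(rec.id, ()), taxonomy=taxonomy,
            config=cfg.classify_config(),
        )
        for rec in records
    }


def load_annotations(path: str | Path) -> dict[str, list[ForeignDomainAnnotation]]:
    """Read a foreign-domain annotation TSV (id, foreign columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    return {r["id"]: parse_foreign(r["foreign"]) for _, r in df.iterrows() if "foreign" in r}


def run_pipeline(
    fasta: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    model: P25DomainModel | None = None,
    annotations_path: str | Path | None = None,
    taxonomy: Mapping[str, TaxonAssignment] | None = None,
) -> ReportBundle:
    """Run every stage over a FASTA file and write the report bundle."""
    cfg = config or RunConfig()
    model = model or default_model()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: %s", asdict(cfg))
    bundle = ReportBundle(out_dir=out_dir)

    records = read_fasta(fasta)
    if not records:
        logger.warning("empty FASTA %s: writing empty report", fasta)
        (out_dir / "calls.tsv").write_text("id\tlabel\n")
        bundle.paths["calls"] = out_dir / "calls.tsv"
        return bundle

    taxonomy = taxonomy if taxonomy is not None else load_taxonomy()
    annotations = load_annotations(annotations_path) if annotations_path else {}

    hits = scan_table(records, model, cfg)
    hits.to_csv(out_dir / "hits.tsv", sep="\t", index=False)
    bundle.paths["hits"] = out_dir / "hits.tsv"

    calls = classify_records(records, model, cfg, annotations, taxonomy)
    bundle.calls = calls
    call_rows = [
        {
            "id": rid,
            "label": c.label,
            "n_p25_copies": c.n_p25_copies,
            "n_partial_copies": c.n_partial_copies,
            "has_rossmann": ";".join("1" if f else "0" for f in c.has_rossmann) or "-",
            "has_extension": int(c.has_extension),
            "has_ntail": int(c.has_ntail),
            "other_domains": ";".join(c.other_domains) or "-",
        }
        for rid, c in calls.items()
    ]
    pd.DataFrame(call_rows).to_csv(out_dir / "calls.tsv", sep="\t", index=False)
    bundle.paths["calls"] = out_dir / "calls.tsv"

    by_id = {r.id: r for r in records}
    table = tabulate_distribution(
        [(by_id[rid], call) for rid, call in calls.items()], taxonomy
    )
    table.table().to_csv(out_dir / "distribution.tsv", sep="\t")
    (out_dir / "distribution.txt").write_text(table.render() + "\n")
    bundle.paths["distribution"] = out_dir / "distribution.tsv"

    dis_rows = [
        {
            "id": rec.id,
            "length": len(rec),
            "disordered_fraction": round(
                disorder_scores(rec.sequence, cfg.disorder_window).disordered_fraction, 4
            ),
        }
        for rec in records
    ]
    pd.DataFrame(dis_rows).to_csv(out_dir / "disorder.tsv", sep="\t", index=False)
    bundle.paths["disorder"] = out_dir / "disorder.tsv"

    if cfg.build_tree and len(records) >= 3:
        tree = nj_tree(distance_matrix(records))
        tree.write(str(out_dir / "tree.nwk"))
        bundle.paths["tree"] = out_dir / "tree.nwk"

    return bundle
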