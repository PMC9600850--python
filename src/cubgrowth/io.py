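"""Readers and writers: CDS FASTA, coverage tables, training tables, model
JSON documents, and run configuration."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codonstats import CubgrowthWarning, GeneRecord, clean_sequence
from .models import GrowthModel

__all__ = [
    "CoverageTable",
    "RunConfig",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_coverage_tsv",
    "apply_coverage",
    "read_training_table",
    "save_model",
    "load_model",
    "save_model_set",
    "load_model_set",
    "load_default_models",
]


@dataclass
class CoverageTable:
    """Per-gene coverage used as relative abundance weights."""

    coverage: dict[str, float]

    def __post_init__(self) -> None:
        for gid, cov in self.coverage.items():
            if cov < 0:
                raise ValueError(f"negative coverage for gene {gid!r}")

    @property
    def median(self) -> float:
        return float(pd.Series(self.coverage).median())


@dataclass
class RunConfig:
    """Serializable record of one CLI run's options."""

    mode: str = "mmv2"
    fragments: bool = False
    weighted: bool = False
    temperature: float | None = None
    n_shuffles: int = 100
    background_k: int = 100
    seed: int = 0
    cds_path: str | None = None
    coverage_path: str | None = None
    model_path: str | None = None
    he_pattern: str = "ribosomal protein"
    he_ids_path: str | None = None
    output_format: str = "json"
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# FASTA


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Read coding sequences from FASTA.

    IDs are the first whitespace token; the full header is kept as the
    description; sequences are upper-cased and the trimming policy is applied
    (trailing partial codons and terminal stop codons dropped).
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = clean_sequence(str(rec.seq), gene_id=rec.id)
        genes.append(GeneRecord(id=rec.id, sequence=seq, description=rec.description))
    if not genes:
        raise ValueError(f"no FASTA records found in {path}")
    return genes


def write_cds_fasta(genes: list[GeneRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=g.description or g.id)
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# tables


def read_coverage_tsv(path: str | Path) -> CoverageTable:
    """Parse a 2+ column TSV of (gene_id, coverage); header auto-detected."""
    cov: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            gid, raw = parts[0].strip(), parts[1].strip()
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: cannot parse coverage value {raw!r}"
                ) from None
            if gid in cov:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage {value}")
            cov[gid] = value
    if not cov:
        raise ValueError(f"no coverage rows found in {path}")
    return CoverageTable(coverage=cov)


def apply_coverage(genes: list[GeneRecord], table: CoverageTable) -> list[GeneRecord]:
    """Set gene weights from a coverage table.

    Genes absent from the table get the table median, with a warning.
    """
    med = table.median
    missing = [g.id for g in genes if g.id not in table.coverage]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) missing from the coverage table; "
            f"assigned the median coverage {med:.4g}",
            CubgrowthWarning,
            stacklevel=2,
        )
    for g in genes:
        g.weight = table.coverage.get(g.id, med)
    return genes


def read_training_table(path: str | Path, mode: str = "mmbc") -> pd.DataFrame:
    """Read a training CSV (species, phylum, doubling_time_h, feature columns,
    optional ogt_c) and validate the columns the mode needs."""
    table = pd.read_csv(path)
    needed = {"doubling_time_h", "cub_he", "icub_all", "icub_he", "gc"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"training table lacks columns: {sorted(missing)}")
    if (table["doubling_time_h"] <= 0).any():
        raise ValueError("training table contains non-positive doubling times")
    return table


# --------------------------------------------------------------------------
# models


def save_model(model: GrowthModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def load_model(path: str | Path) -> GrowthModel:
    return GrowthModel.from_dict(json.loads(Path(path).read_text()))


def save_model_set(models: dict[str, GrowthModel], path: str | Path) -> None:
    doc = {name: m.to_dict() for name, m in models.items()}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model_set(path: str | Path) -> dict[str, GrowthModel]:
    """Load a model JSON holding either one model or a {mode: model} set."""
    doc = json.loads(Path(path).read_text())
    if "coefficients" in doc:
        model = GrowthModel.from_dict(doc)
        return {model.mode: model}
    return {name: GrowthModel.from_dict(d) for name, d in doc.items()}


def load_default_models(with_temperature: bool = False) -> dict[str, GrowthModel]:
    """Load the shipped default coefficient set.

    These coefficients are fitted on the package's synthetic genome generator
    (clearly labeled SYNTHETIC in their metadata) and are intended for testing
    and demonstration; supply your own training table for real predictions.
    """
    from importlib import resources

    name = "models_synthetic_temp.json" if with_temperature else "models_synthetic.json"
    with resources.files("cubgrowth.data").joinpath(name).open() as fh:
        doc = json.load(fh)
    return {mode: GrowthModel.from_dict(d) for mode, d in doc.items()}
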