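"""File I/O: long-format TSV tables, wrapped FASTA, YAML config, reports.

Every format round-trips losslessly; malformed inputs fail fast with
named-location diagnostics (duplicate ids, ragged rows, non-numeric cells).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import CandidateCall, ExpressionMatrix, GenotypeInfo, QpcrTable, ScreenConfig, WHEAT_DESIGN

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_qpcr_tsv",
    "write_qpcr_tsv",
    "read_fasta",
    "write_fasta",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "load_config_yaml",
]


def _read_numeric_tsv(path: str | Path, columns: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    if frame.isna().any().any():
        row = int(frame.index[frame.isna().any(axis=1)][0])
        raise ValueError(f"{path.name}: missing/ragged value at data row {row + 1}")
    for col in numeric:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            row = int(frame.index[converted.isna()][0])
            raise ValueError(
                f"{path.name}: non-numeric {col!r} value {frame[col].iloc[row]!r} "
                f"at data row {row + 1}"
            )
        frame[col] = converted
    return frame


def read_expression_tsv(
    path: str | Path, genotypes: tuple[GenotypeInfo, ...] = WHEAT_DESIGN
) -> ExpressionMatrix:
    """Read a long-format FPKM table (gene_id, genotype, replicate, fpkm)."""
    frame = _read_numeric_tsv(path, ["gene_id", "genotype", "replicate", "fpkm"], ["fpkm"])
    frame["replicate"] = pd.to_numeric(frame["replicate"], errors="raise").astype(int)
    return ExpressionMatrix(frame, genotypes)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qpcr_tsv(
    path: str | Path,
    reference_gene: str = "ARF",
    key_genes: tuple[str, str] = ("GBSSI", "SBEIIb"),
    genotypes: tuple[GenotypeInfo, ...] = WHEAT_DESIGN,
) -> QpcrTable:
    """Read a long-format Ct table (gene_id, genotype, stage, replicate, ct)."""
    frame = _read_numeric_tsv(path, ["gene_id", "genotype", "stage", "replicate", "ct"], ["ct"])
    frame["stage"] = pd.to_numeric(frame["stage"], errors="raise").astype(int)
    frame["replicate"] = pd.to_numeric(frame["replicate"], errors="raise").astype(int)
    stages = tuple(sorted(frame["stage"].unique()))
    return QpcrTable(frame, reference_gene, key_genes, genotypes, stages)


def write_qpcr_tsv(table: QpcrTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered id -> sequence mapping; rejects duplicate ids.

    Tolerates wrapped lines and CRLF line endings (Biopython parser).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{Path(path).name}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns."""
    recs = [SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in sequences.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)


_CAND_COLUMNS = ["gene_id", "source", "rule", "direction", "fc_p1", "fc_p2", "fc_p3"]


def write_candidates_tsv(calls: Iterable[CandidateCall], path: str | Path) -> None:
    """Candidate calls TSV with per-pair supporting folds where defined."""
    rows = []
    for call in calls:
        row = {
            "gene_id": call.gene,
            "source": call.source,
            "rule": call.rule,
            "direction": call.direction,
        }
        for pair in ("p1", "p2", "p3"):
            row[f"fc_{pair}"] = call.support.get(f"fc_{pair}", "")
        # non-transcriptome support values are carried in extra columns
        for key, value in call.support.items():
            if not key.startswith("fc_"):
                row[key] = value
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not len(frame):
        frame = pd.DataFrame(columns=_CAND_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_candidates_tsv(path: str | Path) -> list[CandidateCall]:
    frame = pd.read_csv(path, sep="\t")
    calls = []
    for _, row in frame.iterrows():
        support = {}
        for col in frame.columns:
            if col in ("gene_id", "source", "rule", "direction"):
                continue
            value = row[col]
            if pd.notna(value) and value != "":
                support[col] = float(value)
        calls.append(CandidateCall(row["gene_id"], row["source"], row["rule"], row["direction"], support))
    return calls


def load_config_yaml(path: str | Path) -> ScreenConfig:
    """Load a ScreenConfig from YAML; unknown keys are rejected."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(ScreenConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "late_stages" in payload:
        payload["late_stages"] = tuple(payload["late_stages"])
    return ScreenConfig(**payload)
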