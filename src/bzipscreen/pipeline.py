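"""End-to-end orchestration: generate or read data, run all screens, integrate.

The integrated candidate total follows the study's arithmetic: unique genes
from the transcriptome rules plus the qPCR negative (QN) rule. Correlation
(CORR) calls corroborate genes already in the list and qPCR positive (QP)
flags are reported separately; neither adds to the total. A gene called
positive by one source and negative by another is surfaced as conflicting
and excluded from the total rather than silently resolved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as bio_io
from .correlation import correlation_candidates, correlation_table
from .datatypes import CandidateCall, ExpressionMatrix, QpcrTable, ScreenConfig
from .qpcr import delta_ct, qpcr_candidates, stage_fold_table
from .screen import run_expression_screen
from .synthetic import (
    generate_expression,
    generate_qpcr,
    qpcr_replica_preset,
    replica_preset,
)

logger = logging.getLogger(__name__)

__all__ = ["IntegratedReport", "integrate", "run_pipeline"]


@dataclass
class IntegratedReport:
    """Merged candidate lists with per-source and per-direction totals."""

    candidates: list[dict] = field(default_factory=list)  # per-gene union rows
    conflicts: list[str] = field(default_factory=list)
    totals: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "candidates": self.candidates,
                    "conflicts": self.conflicts,
                    "totals": self.totals,
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.candidates)
        if not len(frame):
            frame = pd.DataFrame(columns=["gene_id", "sources", "rules", "direction", "in_total"])
        frame.to_csv(path, sep="\t", index=False)


def integrate(
    transcriptome_calls: Sequence[CandidateCall],
    qpcr_calls: Sequence[CandidateCall] = (),
    correlation_calls: Sequence[CandidateCall] = (),
    config: Optional[ScreenConfig] = None,
) -> IntegratedReport:
    """Merge candidate calls from the three screens by gene id.

    The grand total counts unique genes carrying a transcriptome rule or
    the qPCR QN rule; QP flags and CORR corroborations annotate only.
    """
    merged: dict[str, dict] = {}
    for call in list(transcriptome_calls) + list(qpcr_calls) + list(correlation_calls):
        entry = merged.setdefault(
            call.gene, {"gene_id": call.gene, "sources": [], "rules": [], "directions": set()}
        )
        if call.source not in entry["sources"]:
            entry["sources"].append(call.source)
        entry["rules"].append(call.rule)
        entry["directions"].add(call.direction)

    counted_rules = {"U1", "U2", "C12", "C123", "QN"}
    rows, conflicts = [], []
    for gene in sorted(merged):
        entry = merged[gene]
        conflicting = len(entry["directions"]) > 1
        in_total = bool(counted_rules & set(entry["rules"])) and not conflicting
        if conflicting:
            conflicts.append(gene)
            logger.warning("gene %s has conflicting call directions; excluded from totals", gene)
        rows.append(
            {
                "gene_id": gene,
                "sources": ",".join(entry["sources"]),
                "rules": ",".join(entry["rules"]),
                "direction": "conflicting" if conflicting else next(iter(entry["directions"])),
                "in_total": in_total,
            }
        )

    def count(source: str, rules: set[str] | None = None) -> int:
        return sum(
            1
            for c in {"transcriptome": transcriptome_calls, "qpcr": qpcr_calls, "correlation": correlation_calls}[source]
            if rules is None or c.rule in rules
        )

    grand = sum(1 for r in rows if r["in_total"])
    by_direction = {"positive": 0, "negative": 0}
    for r in rows:
        if r["in_total"]:
            by_direction[r["direction"]] += 1
    totals = {
        "transcriptome": count("transcriptome"),
        "qpcr_negative": count("qpcr", {"QN"}),
        "qpcr_positive_flags": count("qpcr", {"QP"}),
        "correlation": count("correlation"),
        "grand_total": grand,
        "by_direction": by_direction,
        "conflicting": len(conflicts),
    }
    report = IntegratedReport(candidates=rows, conflicts=conflicts, totals=totals)
    if config is not None:
        report.config = asdict(config)
    return report


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    config: Optional[ScreenConfig] = None,
    expression: Optional[ExpressionMatrix] = None,
    qpcr: Optional[QpcrTable] = None,
) -> IntegratedReport:
    """Run the full analysis and write every intermediate under ``out_dir``.

    When ``expression`` / ``qpcr`` are omitted, the study-replica presets
    are generated at the given seed: the qPCR target genes are then drawn
    from the synthetic expression gene set, disjoint from the planted
    transcriptome candidates (as in the study, where the qPCR negatives
    were distinct from the transcriptome candidates).

    Deterministic given the seed; writes expression/qPCR tables, manifest
    JSONs (generated mode), presence and DE Venn memberships, fold tables,
    dCt profiles, correlation records, per-screen candidate TSVs and the
    integrated report (JSON + TSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or ScreenConfig()

    generated = expression is None
    if expression is None:
        matrix, manifest = generate_expression(replica_preset(seed=seed))
        manifest.to_json(out / "expression_manifest.json")
        expression = matrix
    bio_io.write_expression_tsv(expression, out / "expression.tsv")

    result = run_expression_screen(expression, config)

    if qpcr is None:
        if generated:
            rng = np.random.default_rng(seed + 1)
            candidate_ids = {c.gene for c in result["calls"]}
            pool = sorted(set(expression.genes) - candidate_ids)
            target_ids = tuple(sorted(rng.choice(pool, size=52, replace=False)))
        else:
            target_ids = None
        table, qmanifest = generate_qpcr(qpcr_replica_preset(seed=seed, target_ids=target_ids))
        qmanifest.to_json(out / "qpcr_manifest.json")
        qpcr = table
    bio_io.write_qpcr_tsv(qpcr, out / "qpcr.tsv")

    # expression-screen intermediates
    result["means"].to_csv(out / "mean_fpkm.tsv", sep="\t", float_format="%.10g")
    venn_rows = []
    for label, venn in (("presence", result["presence_venn"]), ("de", result["de_venn"])):
        for region, genes in venn.regions.items():
            for gene in sorted(genes):
                venn_rows.append({"venn": label, "region": region, "gene_id": gene})
    pd.DataFrame(venn_rows, columns=["venn", "region", "gene_id"]).to_csv(
        out / "venn_membership.tsv", sep="\t", index=False
    )
    fold_rows = [
        {
            "gene_id": r.gene,
            "pair": r.pair,
            "log2_fold": "" if r.log2_fold is None else r.log2_fold,
            "excluded_reason": r.excluded_reason or "",
        }
        for pair in ("p1", "p2", "p3")
        for r in result["folds"][pair]
    ]
    pd.DataFrame(fold_rows).to_csv(out / "fold_changes.tsv", sep="\t", index=False, float_format="%.10g")
    bio_io.write_candidates_tsv(result["calls"], out / "candidates_transcriptome.tsv")
    (out / "expression_summary.json").write_text(
        json.dumps(result["summary"], indent=1, sort_keys=True) + "\n"
    )

    # qPCR + correlation screens
    profiles = delta_ct(qpcr)
    profiles.to_csv(out / "delta_ct.tsv", sep="\t", float_format="%.10g")
    stage_fold_table(profiles, qpcr.stages).to_csv(
        out / "stage_folds.tsv", sep="\t", float_format="%.10g"
    )
    qcalls = qpcr_candidates(
        profiles, config, stages=qpcr.stages, exclude=qpcr.key_genes
    )
    bio_io.write_candidates_tsv(qcalls, out / "candidates_qpcr.tsv")

    records = correlation_table(profiles, qpcr.key_genes, config)
    pd.DataFrame(
        [
            {
                "gene_id": r.gene,
                "r_gbssi": r.r_gbssi,
                "r_sbeiib": r.r_sbeiib,
                "n_points": r.n_points,
                "sign_class": r.sign_class,
                "candidate": r.candidate,
            }
            for r in records
        ]
    ).to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.10g")
    ccalls = correlation_candidates(records, config)
    bio_io.write_candidates_tsv(ccalls, out / "candidates_correlation.tsv")

    report = integrate(result["calls"], qcalls, ccalls, config)
    report.input_checksums = {
        name: _checksum(out / name) for name in ("expression.tsv", "qpcr.tsv")
    }
    report.to_json(out / "report.json")
    report.to_tsv(out / "report.tsv")
    logger.info(
        "pipeline complete: %d transcriptome + %d qPCR-negative candidates, grand total %d",
        report.totals["transcriptome"],
        report.totals["qpcr_negative"],
        report.totals["grand_total"],
    )
    return report
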