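"""Ground-truth manifests for the synthetic generators.

Every generator records the planted class of each gene or sequence in a
manifest, which is the authoritative truth for recovery scoring and
round-trips losslessly through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

SCHEMA_VERSION = 1

__all__ = ["GeneTruth", "QpcrGeneTruth", "SequenceTruth", "GroundTruthManifest"]


@dataclass(frozen=True)
class GeneTruth:
    """Planted expression classes of one synthetic gene."""

    gene_id: str
    presence_region: str  # HLP|HL|HP|LP|H|L|P|silent
    de_region: Optional[str] = None  # p1|p2|p3|p12|p13|p23|p123
    log2fc: dict = field(default_factory=dict)  # planted pair -> log2 effect
    candidate_rule: Optional[str] = None
    candidate_direction: Optional[str] = None


@dataclass(frozen=True)
class QpcrGeneTruth:
    """Planted qPCR classes of one target gene."""

    gene_id: str
    qpcr_class: str  # qn_corr | qn | qp | background
    sign_gbssi: str  # '+' or '-': planted sign of r against GBSSI
    sign_sbeiib: str
    corr_candidate: bool = False


@dataclass(frozen=True)
class SequenceTruth:
    """Authoritative motif counts of one synthetic promoter.

    Counts come from a brute-force scan of the final sequence, so they
    include any occurrences the random background created beyond the
    planted ones.
    """

    sequence_id: str
    planted: dict = field(default_factory=dict)  # motif -> planted count
    counts: dict = field(default_factory=dict)  # motif -> true count after background


@dataclass
class GroundTruthManifest:
    kind: str  # expression | qpcr | promoters | proteins
    seed: int
    config: dict = field(default_factory=dict)
    genes: list = field(default_factory=list)
    sequences: list = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "kind": self.kind,
            "seed": self.seed,
            "config": self.config,
            "genes": [asdict(g) for g in self.genes],
            "sequences": [asdict(s) for s in self.sequences],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        if payload["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported manifest schema {payload['schema_version']}")
        gene_cls = {"expression": GeneTruth, "qpcr": QpcrGeneTruth}.get(payload["kind"])
        genes = [gene_cls(**g) for g in payload["genes"]] if gene_cls else payload["genes"]
        sequences = [SequenceTruth(**s) for s in payload["sequences"]]
        return cls(
            kind=payload["kind"],
            seed=payload["seed"],
            config=payload["config"],
            genes=genes,
            sequences=sequences,
        )
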