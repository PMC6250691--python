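"""Core domain containers shared by the screening modules.

The study design is three wheat genotypes — a high-amylose EMS mutant, a
low-amylose EMS mutant and their shared parent variety — profiled either by
RNA-seq (FPKM per gene, genotype and biological replicate) or by qRT-PCR
(Ct per gene, genotype, seed-development stage and technical replicate,
normalized to the ARF reference gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

ROLE_HIGH = "high_mutant"
ROLE_LOW = "low_mutant"
ROLE_PARENT = "parent"
ROLES = (ROLE_HIGH, ROLE_LOW, ROLE_PARENT)

#: Pair labels of the three pairwise genotype contrasts, in design order:
#: p1 = high vs low mutant, p2 = high mutant vs parent, p3 = low mutant vs parent.
PAIR_ROLES: Mapping[str, tuple[str, str]] = {
    "p1": (ROLE_HIGH, ROLE_LOW),
    "p2": (ROLE_HIGH, ROLE_PARENT),
    "p3": (ROLE_LOW, ROLE_PARENT),
}
PAIRS = ("p1", "p2", "p3")


@dataclass(frozen=True)
class GenotypeInfo:
    """One genotype of the study design.

    ``amylose_pct`` is descriptive metadata only (the screens never use it).
    """

    name: str
    role: str
    amylose_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown genotype role {self.role!r}; expected one of {ROLES}")
        if self.amylose_pct == self.amylose_pct and not 0.0 <= self.amylose_pct <= 100.0:
            raise ValueError(f"amylose_pct must be in [0, 100], got {self.amylose_pct}")


#: The wheat EMS-mutant study design: 'TAC 75' (~65% amylose), 'TAC 6' (~7%)
#: and their parent bread-wheat variety 'C 306' (~26%).
WHEAT_DESIGN: tuple[GenotypeInfo, ...] = (
    GenotypeInfo("TAC 75", ROLE_HIGH, 65.0),
    GenotypeInfo("TAC 6", ROLE_LOW, 7.0),
    GenotypeInfo("C 306", ROLE_PARENT, 26.0),
)


def design_by_role(genotypes: Sequence[GenotypeInfo]) -> dict[str, GenotypeInfo]:
    """Map role -> genotype, requiring exactly one genotype per role."""
    by_role: dict[str, GenotypeInfo] = {}
    for g in genotypes:
        if g.role in by_role:
            raise ValueError(f"duplicate genotype role {g.role!r}")
        by_role[g.role] = g
    missing = [r for r in ROLES if r not in by_role]
    if missing:
        raise ValueError(f"design is missing roles: {missing}")
    return by_role


@dataclass
class ExpressionMatrix:
    """FPKM values per (gene, genotype, replicate), long format.

    ``data`` columns: gene_id, genotype, replicate, fpkm. Every
    (gene, genotype, replicate) cell must be present and non-negative.
    """

    data: pd.DataFrame
    genotypes: tuple[GenotypeInfo, ...] = WHEAT_DESIGN

    def __post_init__(self) -> None:
        required = ["gene_id", "genotype", "replicate", "fpkm"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"expression table is missing columns: {missing}")
        design_by_role(self.genotypes)
        names = {g.name for g in self.genotypes}
        unknown = set(self.data["genotype"]) - names
        if unknown:
            raise ValueError(f"expression table references unknown genotypes: {sorted(unknown)}")
        if (self.data["fpkm"] < 0).any():
            bad = self.data.loc[self.data["fpkm"] < 0].iloc[0]
            raise ValueError(
                f"negative FPKM for gene {bad['gene_id']!r}, genotype {bad['genotype']!r}"
            )
        dup = self.data.duplicated(["gene_id", "genotype", "replicate"])
        if dup.any():
            bad = self.data.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate cell (gene {bad['gene_id']!r}, genotype {bad['genotype']!r}, "
                f"replicate {bad['replicate']})"
            )
        # every gene must carry the full genotype x replicate grid
        counts = self.data.groupby("gene_id", sort=False).size()
        expected = counts.iloc[0] if len(counts) else 0
        ragged = counts[counts != expected]
        if len(ragged):
            raise ValueError(
                f"gene {ragged.index[0]!r} has {int(ragged.iloc[0])} cells, expected {int(expected)}"
            )

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene_id"]))


@dataclass
class QpcrTable:
    """Ct cycle values per (gene, genotype, stage, replicate), long format.

    ``data`` columns: gene_id, genotype, stage, replicate, ct. The reference
    gene (internal control, ARF in the wheat study) must have a Ct value for
    every (genotype, stage, replicate); the two key starch genes are the
    correlation anchors GBSSI and SBEIIb.
    """

    data: pd.DataFrame
    reference_gene: str = "ARF"
    key_genes: tuple[str, str] = ("GBSSI", "SBEIIb")
    genotypes: tuple[GenotypeInfo, ...] = WHEAT_DESIGN
    stages: tuple[int, ...] = (21, 28, 35)

    def __post_init__(self) -> None:
        required = ["gene_id", "genotype", "stage", "replicate", "ct"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"qPCR table is missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            bad = self.data.loc[self.data["ct"] <= 0].iloc[0]
            raise ValueError(f"non-positive Ct for gene {bad['gene_id']!r}")
        ref = self.data[self.data["gene_id"] == self.reference_gene]
        have = set(zip(ref["genotype"], ref["stage"]))
        for g in self.genotypes:
            for s in self.stages:
                if (g.name, s) not in have:
                    raise ValueError(
                        f"reference gene {self.reference_gene!r} has no Ct for "
                        f"(genotype {g.name!r}, stage {s})"
                    )

    @property
    def target_genes(self) -> list[str]:
        """Genes screened, excluding the reference and the key starch genes."""
        special = {self.reference_gene, *self.key_genes}
        return [g for g in dict.fromkeys(self.data["gene_id"]) if g not in special]


@dataclass(frozen=True)
class FoldChangeRecord:
    """log2 fold-change of one gene in one genotype pair, or an exclusion.

    Genes whose mean FPKM falls below the presence threshold in either
    genotype of the pair are excluded rather than given an infinite or
    unstable ratio (the zero-exclusion rule).
    """

    gene: str
    pair: str
    log2_fold: Optional[float]
    excluded_reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.log2_fold is not None


@dataclass(frozen=True)
class CandidateCall:
    """One gene flagged by one screening rule.

    rule ∈ {U1, U2, C12, C123} (transcriptome), {QN, QP} (qPCR),
    {CORR} (correlation). direction is 'positive' for putative positive
    regulators of high amylose (higher expression in the high-amylose
    mutant) and 'negative' otherwise.
    """

    gene: str
    source: str
    rule: str
    direction: str
    support: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be positive/negative, got {self.direction!r}")


REGIONS3 = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class VennPartition3:
    """Disjoint decomposition of three sets into the seven Venn regions.

    Region labels name the sets an element belongs to: 'A' is unique to the
    first set, 'AB' is in the first and second only, 'ABC' is the center.
    """

    regions: dict[str, frozenset]

    def __getitem__(self, region: str) -> frozenset:
        return self.regions[region]

    @property
    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for s in self.regions.values():
            out |= s
        return out

    def sizes(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS3}


@dataclass(frozen=True)
class ScreenConfig:
    """Every threshold of the screening cascade.

    presence_min_fpkm: a gene counts as expressed in a genotype when its
        mean FPKM is at least this value (inclusive).
    de_fold: fold threshold of the differential-expression sets (2 = the
        conventional 2-fold screen).
    candidate_fold: the stringent fold threshold of the candidate rules.
    qpcr_negative_log2: log2 relative-expression ceiling of the qPCR
        negative rule (−1 = at least 2-fold lower at every stage).
    qpcr_positive_log2: log2 floor of the late-stage positive flag
        (+2 = at least 4-fold higher at 28 and 35 DAA).
    moderate_r: |r| cutoff of the moderate-correlation candidate rule.
    tolerance: absolute slack applied to every inclusive comparison on the
        log2 / r scale so exact planted ratios pass deterministically.
    """

    presence_min_fpkm: float = 0.02
    de_fold: float = 2.0
    candidate_fold: float = 5.0
    qpcr_negative_log2: float = -1.0
    qpcr_positive_log2: float = 2.0
    late_stages: tuple[int, ...] = (28, 35)
    moderate_r: float = 0.3
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.presence_min_fpkm < 0:
            raise ValueError("presence_min_fpkm must be non-negative")
        if not self.de_fold > 1 or not self.candidate_fold > 1:
            raise ValueError("fold thresholds must exceed 1")
        if self.candidate_fold < self.de_fold:
            raise ValueError("candidate_fold must be at least de_fold")
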