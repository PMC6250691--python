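"""Synthetic FPKM matrix generator with planted, manifest-recorded truth.

Because the wheat mutant-line transcriptome underlying the screening
cascade was never deposited, this generator emulates its statistical shape:
genes are allocated to presence-Venn regions (which genotypes express
them), differential-expression (DE) Venn regions over the three genotype
pairs, and candidate classes, with exact planted log2 effects, so that the
downstream screen run at zero replicate noise recovers every planted class
exactly.

The construction honors the log-ratio identity
``log2FC(p1) = log2FC(p2) - log2FC(p3)`` that binds the three pairwise
folds of any gene expressed in all three genotypes: a gene observed in all
three genotypes can only show a |log2FC| >= 1 unique to one pair when the
other two folds, each < 1, differ by that amount — which caps unique-pair
effects below 4-fold. Planted unique-pair effects of >= 5-fold are
therefore realized by the exclusion mechanism: the third genotype's FPKM is
set to zero (below the presence threshold), which removes the other two
pairs from consideration, exactly as the screen's zero-exclusion rule
prescribes. Weaker (2- to <4-fold) unique-pair genes use cancelling
sub-threshold effects in the other two pairs instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ..datatypes import PAIRS, ExpressionMatrix, GenotypeInfo, WHEAT_DESIGN, design_by_role
from .manifest import GeneTruth, GroundTruthManifest

__all__ = ["CandidatePlan", "ExpressionSimConfig", "generate_expression", "replica_preset"]

#: Presence-Venn region codes: which genotypes express the gene.
#: H = high mutant, L = low mutant, P = parent.
PRESENCE_REGIONS = ("HLP", "HL", "HP", "LP", "H", "L", "P")

#: DE-Venn region codes over the three pairwise contrasts.
DE_REGIONS = ("p1", "p2", "p3", "p12", "p13", "p23", "p123")


@dataclass(frozen=True)
class CandidatePlan:
    """Planted candidate allocation: ``count`` genes of ``rule``/``direction``.

    ``log2fc`` is the planted effect magnitude in the rule's defining
    pair(s); it must be at least log2(candidate_fold).
    """

    rule: str  # U1 | U2 | C12 | C123
    direction: str  # positive | negative
    count: int
    log2fc: float = 2.5


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Full design of one synthetic expression matrix.

    presence_occupancy maps presence-region codes (plus 'silent') to gene
    counts and must sum to n_genes. de_occupancy maps DE-region codes to
    counts; DE genes are carved out of the presence regions where their
    required pairs are evaluable (p-regions needing all three folds live in
    'HLP'; exclusion-based unique-pair candidates live in the two-genotype
    regions). candidates lists the planted candidate classes, which are
    drawn from (and must fit inside) the matching DE occupancies.
    """

    n_genes: int = 370
    presence_occupancy: dict = field(
        default_factory=lambda: {
            "HLP": 177, "HL": 20, "HP": 27, "LP": 13, "H": 12, "L": 31, "P": 9, "silent": 81,
        }
    )
    de_occupancy: dict = field(
        default_factory=lambda: {
            "p1": 18, "p2": 8, "p3": 15, "p12": 9, "p13": 23, "p23": 35, "p123": 39,
        }
    )
    candidates: tuple[CandidatePlan, ...] = (
        CandidatePlan("U1", "positive", 2),
        CandidatePlan("U1", "negative", 3),
        CandidatePlan("U2", "negative", 1),
        CandidatePlan("C12", "negative", 7),
        CandidatePlan("C123", "positive", 3),
        CandidatePlan("C123", "negative", 3),
    )
    presence_min_fpkm: float = 0.02
    baseline_log_mean: float = 2.0  # natural-log scale
    baseline_log_sd: float = 1.0
    baseline_min_fpkm: float = 0.5
    unique_high_max_fpkm: float = 0.5  # genes expressed only in the high mutant stay below this
    replicate_noise_sd: float = 0.0
    n_replicates: int = 2
    genotypes: tuple[GenotypeInfo, ...] = WHEAT_DESIGN
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.presence_occupancy.values()) or any(
            v < 0 for v in self.de_occupancy.values()
        ):
            raise ValueError("occupancies must be non-negative")
        total = sum(self.presence_occupancy.values())
        if total != self.n_genes:
            raise ValueError(
                f"presence occupancies sum to {total}, expected n_genes = {self.n_genes}"
            )
        design_by_role(self.genotypes)
        # candidate classes must fit inside their DE regions and, for the
        # exclusion-realized unique rules, inside the two-genotype presence regions
        need = {"U1": 0, "U2": 0, "C12": 0, "C123": 0}
        for plan in self.candidates:
            if plan.rule not in need:
                raise ValueError(f"unknown candidate rule {plan.rule!r}")
            if plan.log2fc < math.log2(5) - 1e-9:
                raise ValueError(
                    f"candidate class {plan.rule}/{plan.direction}: planted |log2fc| "
                    f"{plan.log2fc} is below the 5-fold rule threshold"
                )
            need[plan.rule] += plan.count
        region_of_rule = {"U1": "p1", "U2": "p2", "C12": "p12", "C123": "p123"}
        for rule, region in region_of_rule.items():
            if need[rule] > self.de_occupancy[region]:
                raise ValueError(
                    f"candidate class {rule}: {need[rule]} genes exceed the "
                    f"{region} DE occupancy {self.de_occupancy[region]}"
                )
        if need["U1"] > self.presence_occupancy["HL"]:
            raise ValueError(
                "U1 candidates need the exclusion mechanism (parent FPKM below threshold) "
                f"but only {self.presence_occupancy['HL']} genes occupy the HL presence region"
            )
        if need["U2"] > self.presence_occupancy["HP"]:
            raise ValueError(
                "U2 candidates need the exclusion mechanism (low-mutant FPKM below threshold) "
                f"but only {self.presence_occupancy['HP']} genes occupy the HP presence region"
            )
        # every DE gene whose region requires all three folds must fit in HLP,
        # as must the weak (non-excluded) unique-pair genes
        n_center = (
            sum(self.de_occupancy[r] for r in ("p3", "p13", "p23", "p123"))
            + (self.de_occupancy["p1"] - need["U1"])
            + (self.de_occupancy["p2"] - need["U2"])
            + self.de_occupancy["p12"]
        )
        if n_center > self.presence_occupancy["HLP"]:
            raise ValueError(
                f"DE plan needs {n_center} genes evaluable in all three pairs but the "
                f"all-three presence region holds only {self.presence_occupancy['HLP']}"
            )


def replica_preset(seed: int = 0) -> ExpressionSimConfig:
    """Deterministic preset replicating the wheat study's printed set sizes.

    370 genes; 81 silent; presence Venn with 177 genes expressed in all
    three genotypes, 12 unique to the high-amylose mutant and per-genotype
    totals 236/241/226 (union 289); DE Venn summing to 147 with 89 and 91
    genes differential in the high-vs-low and high-vs-parent pairs; and 19
    planted candidates (5 positive, 14 negative) across the four rules.
    Replicate noise is zero so the screen recovers the plan exactly.
    """
    return ExpressionSimConfig(seed=seed)


# per-class planted (f2, f3) effect templates for genes expressed in all three
# genotypes; f1 = f2 - f3 follows from the log-ratio identity.
_CENTER_TEMPLATES = {
    "p1": (0.9, -0.6),   # f1 = 1.5: DE unique to p1, below 4-fold
    "p2": (1.5, 0.6),    # f2 DE only
    "p3": (0.6, 1.5),    # f3 DE only
    "p12": (1.5, 0.3),   # f1 = 1.2, f2 = 1.5 DE, both below the 5-fold rule
    "p13": (0.5, 2.0),   # f1 = -1.5, f3 DE
    "p23": (1.5, 1.2),   # f1 = 0.3, f2 and f3 DE
    "p123": (2.5, 1.2),  # f1 = 1.3: all DE, short of the C123 pattern
}


def _candidate_effects(plan: CandidatePlan) -> dict[str, float]:
    s = 1.0 if plan.direction == "positive" else -1.0
    e = plan.log2fc
    if plan.rule == "U1":
        return {"p1": s * e}
    if plan.rule == "U2":
        return {"p2": s * e}
    if plan.rule == "C12":
        return {"p2": s * e, "p3": 0.0}  # f1 = f2 = s*e
    # C123: mutant effects bracket the parent; f1 = f2 - f3 = 2 s e
    return {"p2": s * e, "p3": -s * e}


def generate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, GroundTruthManifest]:
    """Generate an FPKM matrix whose screen output equals the planted plan.

    With ``replicate_noise_sd = 0`` the matrix means equal the planted
    values exactly and the screening cascade reproduces the configured
    presence regions, DE regions and candidate calls. Replicate values are
    mean x exp(N(0, replicate_noise_sd)) (multiplicative log-normal noise,
    preserving FPKM non-negativity).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    gene_ids = [f"bZIP{i + 1:0{width}d}" for i in range(n)]
    order = rng.permutation(n)  # scatter classes across gene ids

    # build the per-gene plan: (presence_region, de_region|None, candidate|None)
    slots: list[tuple[str, Optional[str], Optional[CandidatePlan]]] = []
    for plan in config.candidates:
        region = {"U1": "p1", "U2": "p2", "C12": "p12", "C123": "p123"}[plan.rule]
        slots.extend(
            [("HL" if plan.rule == "U1" else "HP" if plan.rule == "U2" else "HLP",
              region, plan)] * plan.count
        )
    used_de = {r: 0 for r in DE_REGIONS}
    for _, region, _plan in slots:
        used_de[region] += 1
    used_presence = {"HL": 0, "HP": 0, "HLP": 0}
    for pres, _, _ in slots:
        used_presence[pres] += 1
    for region in DE_REGIONS:  # weak, non-candidate DE genes live in HLP
        for _ in range(config.de_occupancy[region] - used_de[region]):
            slots.append(("HLP", region, None))
            used_presence["HLP"] += 1
    for pres in PRESENCE_REGIONS:  # remaining non-DE genes
        remaining = config.presence_occupancy[pres] - used_presence.get(pres, 0)
        slots.extend([(pres, None, None)] * remaining)
    slots.extend([("silent", None, None)] * config.presence_occupancy["silent"])
    assert len(slots) == n

    floor = config.presence_min_fpkm
    rows = []
    truths: list[GeneTruth] = []
    by_role = design_by_role(config.genotypes)
    role_names = {r: g.name for r, g in by_role.items()}

    def baseline() -> float:
        return max(float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)),
                   config.baseline_min_fpkm)

    for slot_idx, gene_idx in enumerate(order):
        gene = gene_ids[gene_idx]
        pres, de_region, plan = slots[slot_idx]
        effects: dict[str, Optional[float]] = {"p1": None, "p2": None, "p3": None}
        if pres == "silent":
            fpkm = {r: float(rng.uniform(0.0, floor * 0.95)) for r in role_names}
        elif pres == "H":
            # expressed only in the high mutant, at low level (below 0.5 FPKM)
            hi = float(rng.uniform(floor * 1.05, config.unique_high_max_fpkm * 0.98))
            fpkm = {"high_mutant": hi, "low_mutant": 0.0, "parent": 0.0}
        elif pres == "L":
            fpkm = {"high_mutant": 0.0, "low_mutant": baseline(), "parent": 0.0}
        elif pres == "P":
            fpkm = {"high_mutant": 0.0, "low_mutant": 0.0, "parent": baseline()}
        elif pres == "HL":
            b = baseline()
            if plan is not None:
                f1 = _candidate_effects(plan)["p1"]
            else:
                f1 = float(rng.uniform(-0.9, 0.9))
            effects["p1"] = f1
            fpkm = {"high_mutant": b * 2.0 ** f1, "low_mutant": b, "parent": 0.0}
        elif pres == "HP":
            b = baseline()
            if plan is not None:
                f2 = _candidate_effects(plan)["p2"]
            else:
                f2 = float(rng.uniform(-0.9, 0.9))
            effects["p2"] = f2
            fpkm = {"high_mutant": b * 2.0 ** f2, "low_mutant": 0.0, "parent": b}
        elif pres == "LP":
            b = baseline()
            f3 = float(rng.uniform(-0.9, 0.9))
            effects["p3"] = f3
            fpkm = {"high_mutant": 0.0, "low_mutant": b * 2.0 ** f3, "parent": b}
        else:  # HLP: expressed in all three genotypes
            b = baseline()
            if plan is not None:
                tmpl = _candidate_effects(plan)
                f2, f3 = tmpl["p2"], tmpl["p3"]
            elif de_region is not None:
                t2, t3 = _CENTER_TEMPLATES[de_region]
                s = 1.0 if rng.random() < 0.5 else -1.0
                f2, f3 = s * t2, s * t3
            else:
                f2 = float(rng.uniform(-0.45, 0.45))
                f3 = float(rng.uniform(-0.45, 0.45))
            effects.update({"p1": f2 - f3, "p2": f2, "p3": f3})
            fpkm = {"high_mutant": b * 2.0 ** f2, "low_mutant": b * 2.0 ** f3, "parent": b}

        for role, mean in fpkm.items():
            noise = (
                np.exp(rng.normal(0.0, config.replicate_noise_sd, config.n_replicates))
                if config.replicate_noise_sd > 0
                else np.ones(config.n_replicates)
            )
            for rep in range(config.n_replicates):
                rows.append(
                    {
                        "gene_id": gene,
                        "genotype": role_names[role],
                        "replicate": rep + 1,
                        "fpkm": float(mean * noise[rep]),
                    }
                )
        truths.append(
            GeneTruth(
                gene_id=gene,
                presence_region=pres,
                de_region=de_region,
                log2fc={k: v for k, v in effects.items() if v is not None},
                candidate_rule=plan.rule if plan else None,
                candidate_direction=plan.direction if plan else None,
            )
        )

    truths.sort(key=lambda t: t.gene_id)
    frame = pd.DataFrame(rows).sort_values(
        ["gene_id", "genotype", "replicate"], kind="stable"
    ).reset_index(drop=True)
    matrix = ExpressionMatrix(frame, config.genotypes)
    manifest = GroundTruthManifest(
        kind="expression",
        seed=config.seed,
        config={
            "n_genes": config.n_genes,
            "presence_occupancy": dict(config.presence_occupancy),
            "de_occupancy": dict(config.de_occupancy),
            "replicate_noise_sd": config.replicate_noise_sd,
            "n_replicates": config.n_replicates,
            "presence_min_fpkm": config.presence_min_fpkm,
        },
        genes=truths,
    )
    return matrix, manifest
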