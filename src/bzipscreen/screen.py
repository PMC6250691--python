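"""Transcriptome screening cascade for candidate bZIP regulators.

The cascade mirrors the threshold-based analysis applied to the wheat
high/low-amylose mutant transcriptomes:

1. replicate means per (gene, genotype);
2. presence calls at FPKM >= 0.02 and their three-set Venn decomposition;
3. pairwise log2 fold-changes on means, with pairs excluded whenever either
   genotype falls below the presence threshold (the zero-exclusion rule);
4. 2-fold differential-expression (DE) sets per pair and their Venn;
5. four region-based candidate rules at the stringent 5-fold threshold,
   yielding directional candidate calls.

No variance model or p-values are involved: the procedure is deliberately
threshold-based, operating on means of (typically two) biological replicates.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datatypes import (
    PAIR_ROLES,
    PAIRS,
    CandidateCall,
    ExpressionMatrix,
    FoldChangeRecord,
    ScreenConfig,
    VennPartition3,
    design_by_role,
)

__all__ = [
    "mean_expression",
    "presence_sets",
    "venn3",
    "pairwise_log2fc",
    "de_sets",
    "classify_candidates",
    "summarize",
    "run_expression_screen",
]


def mean_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean FPKM over replicates, genes x genotype roles.

    Returns a DataFrame indexed by gene_id with one column per genotype
    role (high_mutant, low_mutant, parent). No other transformation is
    applied; every downstream threshold operates on these means.
    """
    by_role = design_by_role(matrix.genotypes)
    name_to_role = {g.name: g.role for g in matrix.genotypes}
    means = (
        matrix.data.groupby(["gene_id", "genotype"], sort=False)["fpkm"]
        .mean()
        .unstack("genotype")
    )
    means = means.rename(columns=name_to_role)
    means = means.reindex(columns=["high_mutant", "low_mutant", "parent"]).loc[matrix.genes]
    if means.isna().any().any():
        gene = means.index[means.isna().any(axis=1)][0]
        col = means.columns[means.isna().any(axis=0)][0]
        raise ValueError(f"missing expression cell (gene {gene!r}, genotype {col!r})")
    return means


def presence_sets(means: pd.DataFrame, config: ScreenConfig) -> dict[str, frozenset]:
    """Genes called expressed per genotype role (mean FPKM >= threshold, inclusive)."""
    out = {}
    for role in means.columns:
        mask = means[role] >= config.presence_min_fpkm - config.tolerance
        out[role] = frozenset(means.index[mask])
    return out


def venn3(set_a: Iterable, set_b: Iterable, set_c: Iterable) -> VennPartition3:
    """Exact three-set Venn partition into seven disjoint regions."""
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    return VennPartition3(
        regions={
            "A": a - b - c,
            "B": b - a - c,
            "C": c - a - b,
            "AB": (a & b) - c,
            "AC": (a & c) - b,
            "BC": (b & c) - a,
            "ABC": a & b & c,
        }
    )


def pairwise_log2fc(
    means: pd.DataFrame, pair: str, config: ScreenConfig
) -> list[FoldChangeRecord]:
    """log2 fold-change per gene for one genotype pair.

    The fold is log2(mean_first / mean_second) and is only defined when both
    means pass the presence threshold; otherwise the record carries an
    exclusion reason (a generalization of discarding pairs with zero FPKM,
    since absence of expression makes the ratio uninterpretable).
    """
    first_role, second_role = PAIR_ROLES[pair]
    floor = config.presence_min_fpkm - config.tolerance
    records = []
    for gene, num, den in zip(means.index, means[first_role], means[second_role]):
        if num < 0 or den < 0:
            raise ValueError(f"negative FPKM for gene {gene!r} in pair {pair}")
        if num < floor and den < floor:
            records.append(FoldChangeRecord(gene, pair, None, "both below presence threshold"))
        elif num < floor:
            records.append(FoldChangeRecord(gene, pair, None, "numerator below presence threshold"))
        elif den < floor:
            records.append(FoldChangeRecord(gene, pair, None, "comparator below presence threshold"))
        else:
            records.append(FoldChangeRecord(gene, pair, math.log2(num / den)))
    return records


def de_sets(
    folds: Mapping[str, Sequence[FoldChangeRecord]], config: ScreenConfig
) -> tuple[dict[str, frozenset], VennPartition3]:
    """2-fold DE gene set per pair, plus the Venn over the three pairs."""
    cut = math.log2(config.de_fold) - config.tolerance
    sets = {
        pair: frozenset(r.gene for r in folds[pair] if r.defined and abs(r.log2_fold) >= cut)
        for pair in PAIRS
    }
    return sets, venn3(sets["p1"], sets["p2"], sets["p3"])


def _fold_lookup(folds: Mapping[str, Sequence[FoldChangeRecord]]) -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    for pair in PAIRS:
        for rec in folds[pair]:
            if rec.defined:
                table.setdefault(rec.gene, {})[pair] = rec.log2_fold
    return table


def classify_candidates(
    de_venn: VennPartition3,
    folds: Mapping[str, Sequence[FoldChangeRecord]],
    config: ScreenConfig,
) -> list[CandidateCall]:
    """Apply the four region-based candidate rules at the stringent fold.

    With F = log2(candidate_fold), the DE-Venn regions over pairs
    (p1 = high vs low, p2 = high vs parent, p3 = low vs parent) yield:

    * U1 — unique to p1: |log2FC_p1| >= F;
    * U2 — unique to p2: |log2FC_p2| >= F;
    * C12 — p1∩p2 only: same sign and |log2FC| >= F in both p1 and p2;
    * C123 — all three pairs: |log2FC| >= F with the same sign in p1 and
      p2, and |log2FC_p3| >= F with the opposite sign (the mutant effects
      bracket the parent).

    Regions involving p3 without p1∩p2 support yield no calls — p3 contrasts
    the two mutants' directions but does not involve the high-amylose line.
    Direction is the sign of the high-amylose-line fold.
    """
    f_cut = math.log2(config.candidate_fold) - config.tolerance
    table = _fold_lookup(folds)
    calls: list[CandidateCall] = []

    def direction(value: float) -> str:
        return "positive" if value > 0 else "negative"

    for gene in sorted(de_venn["A"]):  # unique to p1
        f1 = table[gene].get("p1")
        if f1 is not None and abs(f1) >= f_cut:
            calls.append(CandidateCall(gene, "transcriptome", "U1", direction(f1), {"fc_p1": f1}))
    for gene in sorted(de_venn["B"]):  # unique to p2
        f2 = table[gene].get("p2")
        if f2 is not None and abs(f2) >= f_cut:
            calls.append(CandidateCall(gene, "transcriptome", "U2", direction(f2), {"fc_p2": f2}))
    for gene in sorted(de_venn["AB"]):  # p1 and p2 only
        f1, f2 = table[gene].get("p1"), table[gene].get("p2")
        if (
            f1 is not None
            and f2 is not None
            and abs(f1) >= f_cut
            and abs(f2) >= f_cut
            and f1 * f2 > 0
        ):
            calls.append(
                CandidateCall(gene, "transcriptome", "C12", direction(f1), {"fc_p1": f1, "fc_p2": f2})
            )
    for gene in sorted(de_venn["ABC"]):  # all three pairs
        fc = table[gene]
        f1, f2, f3 = fc.get("p1"), fc.get("p2"), fc.get("p3")
        if None in (f1, f2, f3):
            continue
        if (
            abs(f1) >= f_cut
            and abs(f2) >= f_cut
            and f1 * f2 > 0
            and abs(f3) >= f_cut
            and f3 * f1 < 0
        ):
            calls.append(
                CandidateCall(
                    gene,
                    "transcriptome",
                    "C123",
                    direction(f1),
                    {"fc_p1": f1, "fc_p2": f2, "fc_p3": f3},
                )
            )
    return calls


def summarize(
    presence: Mapping[str, frozenset],
    presence_venn: VennPartition3,
    de: Mapping[str, frozenset],
    de_venn: VennPartition3,
    calls: Sequence[CandidateCall],
    n_genes: int,
) -> dict:
    """Printed-style count summary of the whole cascade."""
    by_rule: dict[str, int] = {}
    by_direction = {"positive": 0, "negative": 0}
    for call in calls:
        by_rule[call.rule] = by_rule.get(call.rule, 0) + 1
        by_direction[call.direction] += 1
    return {
        "n_genes": n_genes,
        "expressed_per_genotype": {role: len(s) for role, s in presence.items()},
        "expressed_any": len(presence_venn.union),
        "silent": n_genes - len(presence_venn.union),
        "presence_regions": presence_venn.sizes(),
        "de_per_pair": {pair: len(s) for pair, s in de.items()},
        "de_total": len(de_venn.union),
        "de_regions": de_venn.sizes(),
        "candidates_total": len(calls),
        "candidates_by_rule": by_rule,
        "candidates_by_direction": by_direction,
    }


def run_expression_screen(matrix: ExpressionMatrix, config: ScreenConfig | None = None) -> dict:
    """Run the full cascade; returns every intermediate plus the summary.

    Keys: means, presence, presence_venn, folds, de, de_venn, calls, summary.
    """
    config = config or ScreenConfig()
    means = mean_expression(matrix)
    presence = presence_sets(means, config)
    presence_venn = venn3(presence["high_mutant"], presence["low_mutant"], presence["parent"])
    folds = {pair: pairwise_log2fc(means, pair, config) for pair in PAIRS}
    de, de_venn = de_sets(folds, config)
    calls = classify_candidates(de_venn, folds, config)
    summary = summarize(presence, presence_venn, de, de_venn, calls, len(means))
    return {
        "means": means,
        "presence": presence,
        "presence_venn": presence_venn,
        "folds": folds,
        "de": de,
        "de_venn": de_venn,
        "calls": calls,
        "summary": summary,
    }
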