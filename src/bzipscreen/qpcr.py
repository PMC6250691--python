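"""Relative-expression (2^-ddCt) screen over the qRT-PCR stage series.

Ct values are normalized to the internal reference gene (ARF in the wheat
study): dCt = mean Ct(gene) - mean Ct(reference) per (genotype, stage).
Between two genotypes, ddCt = dCt(first) - dCt(second) and relative
expression is 2^-ddCt, so log2 relative expression = -ddCt. Amplification
efficiency is fixed at perfect doubling (the classic ddCt method, no
efficiency correction).

Two rules over pairs p1 (high vs low mutant) and p2 (high mutant vs parent):

* QN — negative candidate: at least 2-fold lower expression in the
  high-amylose line in both pairs at all three stages (21, 28, 35 DAA);
* QP — positive flag: at least 4-fold higher in both pairs at the two late
  stages (28 and 35 DAA), when amylose deposition peaks. QP genes are
  reported separately and are not part of the candidate total.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .datatypes import PAIR_ROLES, CandidateCall, QpcrTable, ScreenConfig, design_by_role

__all__ = ["delta_ct", "relative_expression", "stage_fold_table", "qpcr_candidates"]

QPCR_PAIRS = ("p1", "p2")


def delta_ct(table: QpcrTable) -> pd.DataFrame:
    """dCt profiles: genes x (genotype role, stage) MultiIndex columns.

    Replicate Ct values are averaged arithmetically for the gene and the
    reference separately before subtraction. Column order is genotype roles
    in design order (high_mutant, low_mutant, parent) crossed with stages
    ascending — the documented flattening order used everywhere downstream.
    """
    name_to_role = {g.name: g.role for g in table.genotypes}
    means = (
        table.data.groupby(["gene_id", "genotype", "stage"], sort=False)["ct"].mean().unstack(
            ["genotype", "stage"]
        )
    )
    means.columns = pd.MultiIndex.from_tuples(
        [(name_to_role[g], s) for g, s in means.columns], names=["role", "stage"]
    )
    order = pd.MultiIndex.from_product(
        [["high_mutant", "low_mutant", "parent"], sorted(table.stages)],
        names=["role", "stage"],
    )
    means = means.reindex(columns=order)
    ref = means.loc[table.reference_gene]
    if ref.isna().any():
        role, stage = ref.index[ref.isna()][0]
        raise ValueError(
            f"reference gene {table.reference_gene!r} missing Ct at (role {role!r}, stage {stage})"
        )
    profiles = means.drop(index=table.reference_gene).sub(ref, axis=1)
    return profiles


def relative_expression(
    profiles: pd.DataFrame, pair: str, stage: int
) -> pd.DataFrame:
    """Per-gene relative expression for one pair at one stage.

    Columns: ddct, log2_rel (= -ddCt), fold (= 2^-ddCt), excluded (bool,
    True where either genotype's dCt is undefined).
    """
    first_role, second_role = PAIR_ROLES[pair]
    ddct = profiles[(first_role, stage)] - profiles[(second_role, stage)]
    out = pd.DataFrame(index=profiles.index)
    out["ddct"] = ddct
    out["log2_rel"] = -ddct
    out["fold"] = 2.0 ** (-ddct)
    out["excluded"] = ddct.isna()
    return out


def stage_fold_table(profiles: pd.DataFrame, stages: Sequence[int]) -> pd.DataFrame:
    """log2 relative expression, genes x (pair, stage) for pairs p1 and p2."""
    cols = {}
    for pair in QPCR_PAIRS:
        for stage in stages:
            cols[(pair, stage)] = relative_expression(profiles, pair, stage)["log2_rel"]
    out = pd.DataFrame(cols, index=profiles.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["pair", "stage"])
    return out


def qpcr_candidates(
    profiles: pd.DataFrame,
    config: ScreenConfig | None = None,
    stages: Sequence[int] = (21, 28, 35),
    exclude: Sequence[str] = (),
) -> list[CandidateCall]:
    """Apply the QN and QP rules to the dCt profiles.

    ``exclude`` removes the key starch genes themselves from candidacy.
    Returns QN calls (rule 'QN', direction negative) and QP flags (rule
    'QP', direction positive); integration counts only QN in totals.
    """
    config = config or ScreenConfig()
    tol = config.tolerance
    folds = stage_fold_table(profiles, stages)
    late = [s for s in stages if s in config.late_stages]
    calls: list[CandidateCall] = []
    for gene in folds.index:
        if gene in exclude:
            continue
        row = folds.loc[gene]
        if row.isna().any():
            continue
        neg = all(
            row[(pair, stage)] <= config.qpcr_negative_log2 + tol
            for pair in QPCR_PAIRS
            for stage in stages
        )
        pos = all(
            row[(pair, stage)] >= config.qpcr_positive_log2 - tol
            for pair in QPCR_PAIRS
            for stage in late
        )
        support = {f"log2_{pair}_{stage}": float(row[(pair, stage)]) for pair in QPCR_PAIRS for stage in stages}
        if neg:
            calls.append(CandidateCall(gene, "qpcr", "QN", "negative", support))
        elif pos:
            calls.append(CandidateCall(gene, "qpcr", "QP", "positive", support))
    return calls
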