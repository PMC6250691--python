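"""Pearson co-expression screen against the key starch genes.

Each screened gene's normalized dCt profile (all genotype x stage grid
points, flattened genotypes-in-design-order x stages-ascending) is
correlated against the GBSSI and SBEIIb dCt profiles. Correlations are
computed on dCt values directly — the convention of the source data, with
the caveat that dCt is inversely related to expression level, so a positive
r on the dCt scale is also a positive co-expression relationship (both
profiles move together on the expression scale).

Candidate rule (CORR): moderate negative correlation with GBSSI and
moderate positive with SBEIIb (|r| >= 0.3, inclusive) — the signature of a
putative negative regulator tracking low GBSSI / high SBEIIb expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CandidateCall, ScreenConfig

__all__ = ["pearson_r", "CorrelationRecord", "correlation_table", "correlation_candidates"]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard product-moment correlation coefficient.

    Requires equal lengths >= 3 and non-constant vectors (a constant vector
    has no defined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationRecord:
    gene: str
    r_gbssi: float
    r_sbeiib: float
    n_points: int
    sign_class: str  # '++', '+-', '-+', '--' as (sign vs GBSSI, sign vs SBEIIb)
    candidate: bool


def _sign(r: float) -> str:
    return "+" if r > 0 else "-"


def correlation_table(
    profiles: pd.DataFrame,
    key_genes: tuple[str, str] = ("GBSSI", "SBEIIb"),
    config: ScreenConfig | None = None,
) -> list[CorrelationRecord]:
    """Correlate every screened gene's dCt profile against both key genes.

    Genes with incomplete profiles, or constant profiles (undefined r), are
    skipped with a warning rather than failing the whole screen.
    """
    import warnings

    config = config or ScreenConfig()
    gb_name, sb_name = key_genes
    for k in key_genes:
        if k not in profiles.index:
            raise ValueError(f"key gene {k!r} has no dCt profile")
    gb = profiles.loc[gb_name].to_numpy(dtype=float)
    sb = profiles.loc[sb_name].to_numpy(dtype=float)
    records: list[CorrelationRecord] = []
    tol = config.tolerance
    for gene in profiles.index:
        if gene in key_genes:
            continue
        x = profiles.loc[gene].to_numpy(dtype=float)
        if np.isnan(x).any():
            warnings.warn(f"gene {gene!r} skipped: incomplete dCt profile")
            continue
        try:
            r_gb = pearson_r(x, gb)
            r_sb = pearson_r(x, sb)
        except ValueError as exc:
            warnings.warn(f"gene {gene!r} skipped: {exc}")
            continue
        candidate = r_gb <= -config.moderate_r + tol and r_sb >= config.moderate_r - tol
        records.append(
            CorrelationRecord(gene, r_gb, r_sb, x.size, _sign(r_gb) + _sign(r_sb), candidate)
        )
    return records


def correlation_candidates(
    records: Sequence[CorrelationRecord], config: ScreenConfig | None = None
) -> list[CandidateCall]:
    """CORR rule: r_GBSSI <= -moderate_r and r_SBEIIb >= +moderate_r.

    Direction is negative: these genes track low GBSSI expression in the
    high-amylose background, the signature of a putative negative regulator.
    """
    config = config or ScreenConfig()
    tol = config.tolerance
    calls = []
    for rec in records:
        if rec.r_gbssi <= -config.moderate_r + tol and rec.r_sbeiib >= config.moderate_r - tol:
            calls.append(
                CandidateCall(
                    rec.gene,
                    "correlation",
                    "CORR",
                    "negative",
                    {"r_gbssi": rec.r_gbssi, "r_sbeiib": rec.r_sbeiib},
                )
            )
    return calls
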