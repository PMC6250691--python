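"""Synthetic qRT-PCR Ct generator with planted candidate and correlation classes.

The generator emulates the three-stage (21/28/35 DAA) Ct profiles of the
52 screened genes plus the two key starch genes (GBSSI, SBEIIb) and the
ARF reference. Planted classes:

* ``qn`` / ``qn_corr`` — negative qPCR candidates: dCt elevated by a fixed
  number of cycles in the high-amylose genotype at every stage (>= 2-fold
  lower expression in both screened pairs). The ``qn_corr`` subset
  additionally carries a stage-trend component strong enough to clear the
  moderate-correlation rule against SBEIIb, making them the
  correlation-overlap candidates.
* ``qp`` — late-stage positive flags: dCt lowered by >= 2 cycles in the
  high-amylose genotype at 28 and 35 DAA only (>= 4-fold higher expression).
* ``background`` — every other gene's dCt profile is a linear combination
  alpha*g + beta*s of the GBSSI and SBEIIb dCt profiles, which are
  constructed centered and mutually orthogonal (g is a pure genotype
  contrast, s a pure stage trend, of equal norm). With zero Ct noise the
  Pearson sign class of each gene is therefore exactly
  (sign alpha, sign beta), and |r| is set by the alpha:beta ratio — weak
  enough on the GBSSI axis that background genes never cross the moderate
  cutoff, and weak enough in cycles that none triggers the fold rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..datatypes import GenotypeInfo, QpcrTable, WHEAT_DESIGN, design_by_role
from .manifest import GroundTruthManifest, QpcrGeneTruth

__all__ = ["QpcrSimConfig", "generate_qpcr", "qpcr_replica_preset"]


@dataclass(frozen=True)
class QpcrSimConfig:
    """Design of one synthetic Ct table.

    The correlation occupancy is stated the way a screen would report it:
    ``n_pos_gbssi`` / ``n_pos_sbeiib`` genes positively correlated with each
    key gene and ``n_pos_both`` with both, out of ``n_targets``. Planted
    candidate classes (``n_negative`` QN genes, of which ``n_corr_overlap``
    also clear the correlation rule, and ``n_positive_flags`` QP genes) are
    accounted inside those margins: QN genes correlate (-, +) and QP genes
    (+, -).
    """

    n_targets: int = 52
    n_pos_gbssi: int = 31
    n_pos_sbeiib: int = 34
    n_pos_both: int = 14
    n_negative: int = 5
    n_corr_overlap: int = 3
    n_positive_flags: int = 2
    stages: tuple[int, ...] = (21, 28, 35)
    n_replicates: int = 3
    ref_ct: float = 20.0
    base_delta_ct: float = 5.0  # cycles between a typical target and the reference
    genotype_amplitude: float = 2.0  # cycles: GBSSI genotype contrast (+-a)
    stage_amplitude: float = 2.0  # cycles: SBEIIb stage trend (-c, 0, +c)
    qn_shift: float = 2.0  # cycles added in the high mutant (4-fold lower)
    qp_shift: float = 2.0  # cycles subtracted at late stages (4-fold higher)
    ct_noise_sd: float = 0.0
    target_ids: Optional[tuple[str, ...]] = None
    genotypes: tuple[GenotypeInfo, ...] = WHEAT_DESIGN
    seed: int = 0

    def background_classes(self) -> dict[str, int]:
        """Derive background sign-class counts from the stated margins."""
        pp = self.n_pos_both
        pm = self.n_pos_gbssi - self.n_pos_both - self.n_positive_flags
        mp = self.n_pos_sbeiib - self.n_pos_both - self.n_negative
        mm = self.n_targets - self.n_negative - self.n_positive_flags - pp - pm - mp
        return {"pp": pp, "pm": pm, "mp": mp, "mm": mm}

    def validate(self) -> None:
        if self.n_pos_gbssi + self.n_pos_sbeiib - self.n_pos_both > self.n_targets:
            raise ValueError(
                "inconsistent correlation occupancy: "
                f"{self.n_pos_gbssi} + {self.n_pos_sbeiib} - {self.n_pos_both} "
                f"> {self.n_targets}"
            )
        if self.n_corr_overlap > self.n_negative:
            raise ValueError("n_corr_overlap cannot exceed n_negative")
        bad = {k: v for k, v in self.background_classes().items() if v < 0}
        if bad:
            raise ValueError(f"correlation occupancy leaves negative background classes: {bad}")
        if len(self.stages) != 3:
            raise ValueError("exactly three developmental stages are expected")
        if self.target_ids is not None and len(self.target_ids) != self.n_targets:
            raise ValueError(
                f"{len(self.target_ids)} target ids supplied for n_targets = {self.n_targets}"
            )


def qpcr_replica_preset(seed: int = 0, target_ids: Optional[Sequence[str]] = None) -> QpcrSimConfig:
    """Preset replicating the wheat study's qPCR arithmetic.

    52 screened genes; 5 planted negative candidates (3 of them clearing
    the moderate-correlation overlap rule), 2 late-stage positive flags,
    and a correlation occupancy of 31 positive with GBSSI, 34 with SBEIIb,
    14 with both. Ct noise is zero.
    """
    ids = tuple(target_ids) if target_ids is not None else None
    return QpcrSimConfig(seed=seed, target_ids=ids)


def _grid_profiles(config: QpcrSimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(g, s, u): GBSSI contrast, SBEIIb stage trend, high-genotype indicator.

    Vectors live on the flattened (role in design order) x (stage ascending)
    grid of 9 points. g and s are centered, orthogonal and of equal norm.
    """
    a, c = config.genotype_amplitude, config.stage_amplitude
    # roles: high, low, parent; stages ascending
    g = np.array([-a] * 3 + [a] * 3 + [0.0] * 3)
    s = np.array([-c, 0.0, c] * 3)
    u = np.array([1.0] * 3 + [0.0] * 6)
    return g, s, u


def generate_qpcr(config: QpcrSimConfig) -> tuple[QpcrTable, GroundTruthManifest]:
    """Generate a Ct table whose screens reproduce the planted classes.

    With ``ct_noise_sd = 0`` the qPCR screen reports exactly the planted
    QN/QP genes and the correlation screen reports exactly the planted sign
    classes and overlap candidates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_targets
    if config.target_ids is not None:
        ids = list(config.target_ids)
    else:
        ids = [f"qZIP{i + 1:02d}" for i in range(n)]

    g, s, u = _grid_profiles(config)
    v_late = np.array([0.0, -config.qp_shift, -config.qp_shift] + [0.0] * 6)

    classes = config.background_classes()
    # planted (class label, dCt deviation profile, sign pair)
    plan: list[tuple[str, np.ndarray, str, str, bool]] = []
    for _ in range(config.n_corr_overlap):
        plan.append(("qn_corr", config.qn_shift * u + 1.0 * s, "-", "+", True))
    for _ in range(config.n_negative - config.n_corr_overlap):
        plan.append(("qn", config.qn_shift * u + 0.15 * s, "-", "+", False))
    for _ in range(config.n_positive_flags):
        plan.append(("qp", v_late.copy(), "+", "-", False))
    weights = {"pp": (0.2, 0.3), "pm": (0.2, -0.3), "mp": (-0.1, 0.45), "mm": (-0.1, -0.45)}
    signs = {"pp": ("+", "+"), "pm": ("+", "-"), "mp": ("-", "+"), "mm": ("-", "-")}
    for cls in ("pp", "pm", "mp", "mm"):
        alpha, beta = weights[cls]
        sg, sb = signs[cls]
        for _ in range(classes[cls]):
            plan.append(("background", alpha * g + beta * s, sg, sb, False))
    assert len(plan) == n
    order = rng.permutation(n)

    roles = ["high_mutant", "low_mutant", "parent"]
    by_role = design_by_role(config.genotypes)
    grid = [(by_role[r].name, stage) for r in roles for stage in sorted(config.stages)]

    rows: list[dict] = []
    truths: list[QpcrGeneTruth] = []

    def emit(gene_id: str, dct: np.ndarray) -> None:
        for (genotype, stage), value in zip(grid, dct):
            ct = config.ref_ct + value
            noise = (
                rng.normal(0.0, config.ct_noise_sd, config.n_replicates)
                if config.ct_noise_sd > 0
                else np.zeros(config.n_replicates)
            )
            for rep in range(config.n_replicates):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "genotype": genotype,
                        "stage": stage,
                        "replicate": rep + 1,
                        "ct": float(ct + noise[rep]),
                    }
                )

    # key genes and reference: GBSSI carries g, SBEIIb carries s
    emit("GBSSI", config.base_delta_ct + g)
    emit("SBEIIb", config.base_delta_ct + s)
    emit("ARF", np.zeros(9))

    for slot, gene_idx in zip(plan, order):
        cls, deviation, sg, sb, corr = slot
        gene_id = ids[gene_idx]
        emit(gene_id, config.base_delta_ct + deviation)
        truths.append(
            QpcrGeneTruth(
                gene_id=gene_id,
                qpcr_class=cls,
                sign_gbssi=sg,
                sign_sbeiib=sb,
                corr_candidate=corr,
            )
        )

    truths.sort(key=lambda t: t.gene_id)
    frame = pd.DataFrame(rows)
    table = QpcrTable(
        frame, reference_gene="ARF", key_genes=("GBSSI", "SBEIIb"),
        genotypes=config.genotypes, stages=tuple(sorted(config.stages)),
    )
    manifest = GroundTruthManifest(
        kind="qpcr",
        seed=config.seed,
        config={
            "n_targets": n,
            "n_pos_gbssi": config.n_pos_gbssi,
            "n_pos_sbeiib": config.n_pos_sbeiib,
            "n_pos_both": config.n_pos_both,
            "n_negative": config.n_negative,
            "n_corr_overlap": config.n_corr_overlap,
            "n_positive_flags": config.n_positive_flags,
            "ct_noise_sd": config.ct_noise_sd,
        },
        genes=truths,
    )
    return table, manifest
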