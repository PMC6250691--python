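"""Unit and property tests of the 2^-ddCt qPCR screen."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bzipscreen.datatypes import QpcrTable, ScreenConfig, WHEAT_DESIGN
from bzipscreen.qpcr import delta_ct, qpcr_candidates, relative_expression, stage_fold_table
from bzipscreen.synthetic import QpcrSimConfig, generate_qpcr, qpcr_replica_preset

CONFIG = ScreenConfig()
GENOTYPES = ("TAC 75", "TAC 6", "C 306")


def _table(gene_ct: dict[str, dict[tuple[str, int], float]], ref_ct: float = 20.0) -> QpcrTable:
    """Build a Ct table from gene -> {(genotype, stage): ct}; ARF constant."""
    rows = []
    for gene, cells in gene_ct.items():
        for (genotype, stage), ct in cells.items():
            rows.append(
                {"gene_id": gene, "genotype": genotype, "stage": stage, "replicate": 1, "ct": ct}
            )
    for genotype in GENOTYPES:
        for stage in (21, 28, 35):
            rows.append(
                {"gene_id": "ARF", "genotype": genotype, "stage": stage, "replicate": 1, "ct": ref_ct}
            )
    return QpcrTable(pd.DataFrame(rows))


def _full(gene: str, value: float) -> dict:
    return {(g, s): value for g in GENOTYPES for s in (21, 28, 35)}


class TestDeltaCt:
    def test_subtracts_reference(self):
        profiles = delta_ct(_table({"g": _full("g", 25.0)}))
        assert (profiles.loc["g"] == 5.0).all()

    def test_equal_to_reference_gives_zero(self):
        profiles = delta_ct(_table({"g": _full("g", 20.0)}))
        assert (profiles.loc["g"] == 0.0).all()

    def test_replicates_averaged(self):
        rows = []
        for rep, ct in ((1, 24.9), (2, 25.1)):
            for g in GENOTYPES:
                for s in (21, 28, 35):
                    rows.append({"gene_id": "g", "genotype": g, "stage": s, "replicate": rep, "ct": ct})
        for rep in (1, 2):
            for g in GENOTYPES:
                for s in (21, 28, 35):
                    rows.append({"gene_id": "ARF", "genotype": g, "stage": s, "replicate": rep, "ct": 20.0})
        profiles = delta_ct(QpcrTable(pd.DataFrame(rows)))
        assert profiles.loc["g"].to_numpy() == pytest.approx(5.0)

    def test_missing_reference_is_named(self):
        rows = [
            {"gene_id": "ARF", "genotype": g, "stage": s, "replicate": 1, "ct": 20.0}
            for g in GENOTYPES
            for s in (21, 28)  # stage 35 missing
        ]
        with pytest.raises(ValueError, match="35"):
            QpcrTable(pd.DataFrame(rows))


class TestRelativeExpression:
    def test_no_difference_is_fold_one(self):
        profiles = delta_ct(_table({"g": _full("g", 25.0)}))
        rel = relative_expression(profiles, "p1", 28)
        assert rel.loc["g", "fold"] == 1.0

    def test_two_cycle_advantage_is_fourfold(self):
        cells = _full("g", 25.0)
        for s in (21, 28, 35):
            cells[("TAC 75", s)] = 23.0  # ddCt = -2 in p1 and p2
        profiles = delta_ct(_table({"g": cells}))
        rel = relative_expression(profiles, "p1", 28)
        assert rel.loc["g", "fold"] == pytest.approx(4.0)
        assert rel.loc["g", "log2_rel"] == pytest.approx(2.0)

    def test_reference_shift_invariance(self):
        """Adding a constant to every Ct of one (genotype, stage) leaves ddCt unchanged."""
        base = {"g": _full("g", 25.0)}
        shifted = {"g": dict(base["g"])}
        rows_base = delta_ct(_table(base))
        # shift gene AND reference Ct at (TAC 75, 28) by +3
        rows = []
        for gene, cells in shifted.items():
            for (genotype, stage), ct in cells.items():
                bump = 3.0 if (genotype, stage) == ("TAC 75", 28) else 0.0
                rows.append({"gene_id": gene, "genotype": genotype, "stage": stage, "replicate": 1, "ct": ct + bump})
        for genotype in GENOTYPES:
            for stage in (21, 28, 35):
                bump = 3.0 if (genotype, stage) == ("TAC 75", 28) else 0.0
                rows.append({"gene_id": "ARF", "genotype": genotype, "stage": stage, "replicate": 1, "ct": 20.0 + bump})
        rows_shifted = delta_ct(QpcrTable(pd.DataFrame(rows)))
        pd.testing.assert_frame_equal(rows_base, rows_shifted)


class TestQpcrRules:
    def test_flat_data_yields_no_calls(self):
        profiles = delta_ct(_table({"g": _full("g", 25.0)}))
        assert qpcr_candidates(profiles, CONFIG) == []

    def test_exact_fourfold_late_positive_is_flagged(self):
        cells = _full("g", 25.0)
        for s in (28, 35):
            cells[("TAC 75", s)] = 23.0
        profiles = delta_ct(_table({"g": cells}))
        (call,) = qpcr_candidates(profiles, CONFIG)
        assert (call.rule, call.direction) == ("QP", "positive")

    def test_negative_rule_needs_all_three_stages(self):
        cells = _full("g", 25.0)
        for s in (21, 28):  # only two of three stages lower
            cells[("TAC 75", s)] = 27.0
        profiles = delta_ct(_table({"g": cells}))
        assert qpcr_candidates(profiles, CONFIG) == []
        cells[("TAC 75", 35)] = 27.0
        (call,) = qpcr_candidates(delta_ct(_table({"g": cells})), CONFIG)
        assert (call.rule, call.direction) == ("QN", "negative")

    def test_preset_recovers_planted_classes(self, qpcr_preset):
        table, manifest, profiles = qpcr_preset
        calls = qpcr_candidates(profiles, CONFIG, stages=table.stages, exclude=table.key_genes)
        called_qn = {c.gene for c in calls if c.rule == "QN"}
        called_qp = {c.gene for c in calls if c.rule == "QP"}
        planted_qn = {t.gene_id for t in manifest.genes if t.qpcr_class in ("qn", "qn_corr")}
        planted_qp = {t.gene_id for t in manifest.genes if t.qpcr_class == "qp"}
        assert called_qn == planted_qn and len(called_qn) == 5
        assert called_qp == planted_qp and len(called_qp) == 2

    def test_qn_sign_coherence(self, qpcr_preset):
        table, _, profiles = qpcr_preset
        folds = stage_fold_table(profiles, table.stages)
        calls = qpcr_candidates(profiles, CONFIG, stages=table.stages, exclude=table.key_genes)
        for call in calls:
            if call.rule == "QN":
                assert folds.loc[call.gene].mean() < 0


def test_qn_recovery_under_ct_noise():
    """With Ct noise sd 0.2, planted negatives are recovered in >= 90% of runs."""
    recovered = total = 0
    for seed in range(100):
        cfg = dataclasses.replace(qpcr_replica_preset(seed=seed), ct_noise_sd=0.2)
        table, manifest, = generate_qpcr(cfg)
        profiles = delta_ct(table)
        calls = qpcr_candidates(profiles, CONFIG, stages=table.stages, exclude=table.key_genes)
        called = {c.gene for c in calls if c.rule == "QN"}
        planted = {t.gene_id for t in manifest.genes if t.qpcr_class in ("qn", "qn_corr")}
        recovered += len(called & planted)
        total += len(planted)
    assert recovered / total >= 0.90


def test_inconsistent_occupancy_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        QpcrSimConfig(n_pos_gbssi=40, n_pos_sbeiib=30, n_pos_both=10).validate()
    with pytest.raises(ValueError, match="negative background"):
        QpcrSimConfig(n_pos_gbssi=15, n_pos_sbeiib=34, n_pos_both=14).validate()
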