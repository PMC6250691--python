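"""Unit and property tests of the transcriptome screening cascade."""

import dataclasses
import math
import random

import numpy as np
import pandas as pd
import pytest

from bzipscreen.datatypes import ExpressionMatrix, ScreenConfig, WHEAT_DESIGN
from bzipscreen.screen import (
    classify_candidates,
    de_sets,
    mean_expression,
    pairwise_log2fc,
    presence_sets,
    run_expression_screen,
    venn3,
)

CONFIG = ScreenConfig()


def _matrix(values: dict[str, tuple[float, float, float]], reps=(1, 2)) -> ExpressionMatrix:
    """Build a matrix from gene -> (high, low, parent) mean FPKM."""
    rows = []
    for gene, (hi, lo, pa) in values.items():
        for genotype, mean in (("TAC 75", hi), ("TAC 6", lo), ("C 306", pa)):
            for rep in reps:
                rows.append({"gene_id": gene, "genotype": genotype, "replicate": rep, "fpkm": mean})
    return ExpressionMatrix(pd.DataFrame(rows), WHEAT_DESIGN)


def _means(values):
    return mean_expression(_matrix(values))


class TestMeanExpression:
    def test_arithmetic_mean_of_replicates(self):
        rows = []
        for rep, fpkm in ((1, 1.0), (2, 3.0)):
            rows.append({"gene_id": "g", "genotype": "TAC 75", "replicate": rep, "fpkm": fpkm})
        for genotype in ("TAC 6", "C 306"):
            for rep in (1, 2):
                rows.append({"gene_id": "g", "genotype": genotype, "replicate": rep, "fpkm": 5.0})
        means = mean_expression(ExpressionMatrix(pd.DataFrame(rows)))
        assert means.loc["g", "high_mutant"] == 2.0
        assert means.loc["g", "low_mutant"] == 5.0

    def test_single_replicate_is_identity(self):
        means = _means({"g": (7.0, 1.0, 2.0)})
        assert means.loc["g", "high_mutant"] == 7.0

    def test_missing_cell_is_named(self):
        rows = [
            {"gene_id": "g", "genotype": g, "replicate": 1, "fpkm": 1.0}
            for g in ("TAC 75", "TAC 6")
        ]
        with pytest.raises(ValueError):
            mean_expression(ExpressionMatrix(pd.DataFrame(rows)))

    def test_preset_means_equal_planted_values(self, expr_preset):
        matrix, manifest, result = expr_preset
        means = result["means"]
        # planted candidate folds are recovered bit-for-bit at zero noise
        for truth in manifest.genes:
            if truth.candidate_rule == "C12":
                hi = means.loc[truth.gene_id, "high_mutant"]
                pa = means.loc[truth.gene_id, "parent"]
                assert math.log2(hi / pa) == pytest.approx(truth.log2fc["p2"], abs=1e-12)


class TestPresence:
    def test_threshold_is_inclusive(self):
        means = _means({"at": (0.02, 0.019, 1.0)})
        sets = presence_sets(means, CONFIG)
        assert "at" in sets["high_mutant"]
        assert "at" not in sets["low_mutant"]
        assert "at" in sets["parent"]

    def test_lowering_threshold_never_shrinks_sets(self, expr_preset):
        _, _, result = expr_preset
        means = result["means"]
        loose = presence_sets(means, dataclasses.replace(CONFIG, presence_min_fpkm=0.001))
        for role, genes in result["presence"].items():
            assert genes <= loose[role]


class TestVenn3:
    def test_identical_sets_all_center(self):
        v = venn3({"g1"}, {"g1"}, {"g1"})
        assert v["ABC"] == frozenset({"g1"})
        assert all(not v[r] for r in ("A", "B", "C", "AB", "AC", "BC"))

    def test_disjoint_singletons(self):
        v = venn3({"a"}, {"b"}, {"c"})
        assert (v["A"], v["B"], v["C"]) == ({"a"}, {"b"}, {"c"})

    def test_oracle_equivalence_on_random_triples(self):
        rng = random.Random(0)
        universe = list(range(30))
        for _ in range(200):
            a, b, c = (frozenset(rng.sample(universe, rng.randint(0, 30))) for _ in range(3))
            v = venn3(a, b, c)
            # oracle: classify each element by its membership vector
            for x in a | b | c:
                key = "".join(lbl for lbl, s in (("A", a), ("B", b), ("C", c)) if x in s)
                assert x in v[key]
            assert sum(len(v[r]) for r in v.regions) == len(a | b | c)


class TestFoldChanges:
    def test_simple_ratio(self):
        (rec,) = pairwise_log2fc(_means({"g": (4.0, 1.0, 1.0)}), "p1", CONFIG)
        assert rec.log2_fold == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        (rec,) = pairwise_log2fc(_means({"g": (0.02, 0.02, 1.0)}), "p1", CONFIG)
        assert rec.log2_fold == 0.0

    def test_zero_comparator_is_excluded(self):
        (rec,) = pairwise_log2fc(_means({"g": (10.0, 0.0, 1.0)}), "p1", CONFIG)
        assert not rec.defined
        assert rec.excluded_reason == "comparator below presence threshold"

    def test_zero_numerator_is_excluded(self):
        (rec,) = pairwise_log2fc(_means({"g": (0.0, 10.0, 1.0)}), "p1", CONFIG)
        assert rec.excluded_reason == "numerator below presence threshold"

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            hi, lo = rng.uniform(0.02, 100, size=2)
            fwd = pairwise_log2fc(_means({"g": (hi, lo, 1.0)}), "p1", CONFIG)[0].log2_fold
            rev = pairwise_log2fc(_means({"g": (lo, hi, 1.0)}), "p1", CONFIG)[0].log2_fold
            assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_log_ratio_identity_on_screen_output(self, expr_preset):
        _, _, result = expr_preset
        folds = {
            pair: {r.gene: r.log2_fold for r in result["folds"][pair] if r.defined}
            for pair in ("p1", "p2", "p3")
        }
        shared = set(folds["p1"]) & set(folds["p2"]) & set(folds["p3"])
        assert shared
        for gene in shared:
            assert abs(folds["p1"][gene] - (folds["p2"][gene] - folds["p3"][gene])) < 1e-9


class TestCandidateRules:
    def test_de_threshold_excludes_just_below(self):
        means = _means({"g": (2.0 ** 0.999, 1.0, 1.0)})
        folds = {p: pairwise_log2fc(means, p, CONFIG) for p in ("p1", "p2", "p3")}
        sets, _ = de_sets(folds, CONFIG)
        assert "g" not in sets["p1"]

    def test_unique_pair1_eightfold_is_positive_call(self):
        means = _means({"g": (8.0, 1.0, 0.0)})
        folds = {p: pairwise_log2fc(means, p, CONFIG) for p in ("p1", "p2", "p3")}
        _, venn = de_sets(folds, CONFIG)
        (call,) = classify_candidates(venn, folds, CONFIG)
        assert (call.rule, call.direction) == ("U1", "positive")

    def test_c123_requires_opposite_parent_contrast(self):
        # mutant effects bracket the parent: candidate
        # "hit": mutant effects bracket the parent; "miss" is DE in all three
        # pairs but its high-vs-parent fold is only 2-fold, short of the rule
        means = _means({"hit": (32.0, 1.0, 5.65685424949238), "miss": (32.0, 1.0, 16.0)})
        folds = {p: pairwise_log2fc(means, p, CONFIG) for p in ("p1", "p2", "p3")}
        _, venn = de_sets(folds, CONFIG)
        calls = classify_candidates(venn, folds, CONFIG)
        assert [c.gene for c in calls] == ["hit"]
        assert calls[0].rule == "C123"

    def test_no_calls_on_empty_de_sets(self):
        means = _means({"g": (1.0, 1.0, 1.0)})
        folds = {p: pairwise_log2fc(means, p, CONFIG) for p in ("p1", "p2", "p3")}
        _, venn = de_sets(folds, CONFIG)
        assert classify_candidates(venn, folds, CONFIG) == []

    def test_call_support_satisfies_rule_inequalities(self, expr_preset):
        _, _, result = expr_preset
        cut = math.log2(CONFIG.candidate_fold) - CONFIG.tolerance
        pos = {c.gene for c in result["calls"] if c.direction == "positive"}
        neg = {c.gene for c in result["calls"] if c.direction == "negative"}
        assert not pos & neg
        for call in result["calls"]:
            for value in call.support.values():
                assert abs(value) >= cut

    def test_raising_candidate_fold_never_adds_calls(self, expr_preset):
        _, _, result = expr_preset
        stricter = dataclasses.replace(CONFIG, candidate_fold=8.0)
        calls = classify_candidates(result["de_venn"], result["folds"], stricter)
        assert {c.gene for c in calls} <= {c.gene for c in result["calls"]}


def test_summary_counts_are_internally_consistent(expr_preset):
    _, _, result = expr_preset
    s = result["summary"]
    assert sum(s["presence_regions"].values()) == s["expressed_any"]
    assert s["expressed_any"] + s["silent"] == s["n_genes"]
    assert sum(s["de_regions"].values()) == s["de_total"]
    assert sum(s["candidates_by_rule"].values()) == s["candidates_total"]
    assert sum(s["candidates_by_direction"].values()) == s["candidates_total"]
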