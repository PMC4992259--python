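import numpy as np
import pandas as pd
import pytest

from laborbasin.classification import (
    ClassifierUsageError,
    IntervalPair,
    RectanglePair,
    SampleSizeError,
    SweepConfig,
    classify_sample,
    construct_model_classifier,
    construct_null_1gene,
    construct_null_2gene,
    enumerate_partitions,
    evaluate,
    nonparametric_ci,
    sample_probabilities,
    sweep,
)
from laborbasin.expression import Predictor, SURROGATE_GENES
from laborbasin.labor_probability import BasinGridSpec
from itertools import combinations


class TestPartitions:
    def test_full_cohort_count(self, normalized_cohort):
        parts = enumerate_partitions(normalized_cohort)
        assert len(parts) == 17_640  # C(10,5) * C(8,4)
        first = parts[0]
        assert len(first.train_il) == 5
        assert len(first.train_nil) == 4
        assert len(first.test) == 9

    def test_toy_counts(self, toy_cohort):
        parts = enumerate_partitions(toy_cohort)
        assert len(parts) == 36  # C(4,2)^2, brute-force cross-check below
        seen = {(p.train_il, p.train_nil) for p in parts}
        il = sorted(toy_cohort.ids_in_group("IL"))
        nil = sorted(toy_cohort.ids_in_group("NIL"))
        expected = {
            (a, b) for a in combinations(il, 2) for b in combinations(nil, 2)
        }
        assert seen == expected

    def test_partition_is_disjoint_cover(self, toy_cohort):
        for p in enumerate_partitions(toy_cohort):
            ids = set(p.train_il) | set(p.train_nil) | set(p.test)
            assert len(ids) == 8
            assert not (set(p.train_il) | set(p.train_nil)) & set(p.test)


class TestConfidenceIntervals:
    @pytest.mark.parametrize("method", ["bootstrap-median", "range"])
    def test_degenerate_sample(self, method):
        assert nonparametric_ci([0.4] * 5, method=method, seed=0) == (0.4, 0.4)

    def test_range_of_two(self):
        assert nonparametric_ci([0.0, 1.0], method="range") == (0.0, 1.0)

    def test_bootstrap_contains_median_and_is_reproducible(self):
        values = [0.1, 0.2, 0.3, 0.4, 0.5]
        lo, hi = nonparametric_ci(values, method="bootstrap-median", n_boot=10_000, seed=1234)
        assert lo <= 0.3 <= hi
        # pinned regression endpoints: at n=5 the bootstrap-median percentile
        # interval reaches the sample extremes
        assert (lo, hi) == (0.1, 0.5)
        assert nonparametric_ci(values, method="bootstrap-median", n_boot=10_000, seed=1234) == (lo, hi)

    def test_single_value_rejected(self):
        with pytest.raises(SampleSizeError):
            nonparametric_ci([0.5])


class TestRegions:
    def test_separation_is_strict_disjointness(self):
        assert IntervalPair((0.0, 0.3), (0.5, 0.9)).separated
        assert not IntervalPair((0.0, 0.5), (0.5, 0.9)).separated  # shared endpoint
        assert not IntervalPair((0.0, 0.6), (0.5, 0.9)).separated

    def test_rectangles_separate_iff_some_axis_does(self):
        sep_axis1 = RectanglePair(
            il_region=((0.0, 0.3), (0.0, 1.0)), nil_region=((0.5, 0.9), (0.2, 0.8))
        )
        assert sep_axis1.separated
        overlap_both = RectanglePair(
            il_region=((0.0, 0.6), (0.0, 0.6)), nil_region=((0.5, 0.9), (0.5, 0.9))
        )
        assert not overlap_both.separated

    def test_classify_sample_three_way(self):
        regions = IntervalPair((0.7, 0.9), (0.1, 0.3))
        assert classify_sample(0.8, regions) == "IL"
        assert classify_sample(0.2, regions) == "NIL"
        assert classify_sample(0.5, regions) == "no-call"   # between
        assert classify_sample(0.05, regions) == "no-call"  # below both
        assert classify_sample(0.95, regions) == "no-call"  # above both

    def test_classify_point_in_rectangles(self):
        regions = RectanglePair(
            il_region=((0.6, 1.0), (0.6, 1.0)), nil_region=((0.0, 0.4), (0.0, 0.4))
        )
        assert classify_sample((0.8, 0.7), regions) == "IL"
        assert classify_sample((0.1, 0.2), regions) == "NIL"
        assert classify_sample((0.8, 0.2), regions) == "no-call"

    def test_unconstructed_classifier_unusable(self):
        with pytest.raises(ClassifierUsageError):
            classify_sample(0.5, IntervalPair((0.0, 0.6), (0.5, 0.9)))


class TestEvaluate:
    def test_perfect_calls(self):
        truth = {f"s{j}": "IL" for j in range(9)}
        calls = dict(truth)
        assert evaluate(calls, truth) == (1.0, 1.0)

    def test_partial_calls(self):
        truth = {f"s{j}": ("IL" if j < 5 else "NIL") for j in range(9)}
        calls = {sid: "no-call" for sid in truth}
        calls["s0"] = "IL"
        calls["s1"] = "IL"
        calls["s5"] = "IL"  # wrong
        precision, recall = evaluate(calls, truth)
        assert precision == pytest.approx(2 / 3)
        assert recall == pytest.approx(1 / 3)

    def test_zero_classified_convention(self):
        truth = {f"s{j}": "IL" for j in range(9)}
        calls = {sid: "no-call" for sid in truth}
        assert evaluate(calls, truth) == (0.0, 0.0)


class TestScalarConstruction:
    def test_separated_by_construction(self, toy_cohort):
        part = enumerate_partitions(toy_cohort)[0]
        probs = {sid: (0.9 if sid.startswith("T_IL") else 0.1) for sid in toy_cohort.sample_ids}
        pair = construct_model_classifier(part, Predictor("FKBP5", "IL1B"), probs)
        assert pair.separated

    def test_identical_groups_never_separate(self, toy_cohort):
        part = enumerate_partitions(toy_cohort)[0]
        probs = {sid: 0.5 for sid in toy_cohort.sample_ids}
        pair = construct_model_classifier(part, Predictor("FKBP5", "IL1B"), probs)
        assert not pair.separated

    def test_two_gene_uses_per_gene_intervals(self, toy_cohort):
        part = enumerate_partitions(toy_cohort)[0]
        rect = construct_null_2gene(part, ("IL6", "FKBP5"), toy_cohort, master_seed=3)
        iv1 = construct_null_1gene(part, "IL6", toy_cohort, master_seed=3)
        iv2 = construct_null_1gene(part, "FKBP5", toy_cohort, master_seed=3)
        assert rect.il_region == (iv1.il_interval, iv2.il_interval)
        assert rect.separated == (iv1.separated or iv2.separated)


class TestSweep:
    def test_counting_identities(self, normalized_cohort):
        # 21 configurations per partition: 6 model + 5 single-gene + 10 two-gene
        assert 6 + 5 + len(list(combinations(SURROGATE_GENES, 2))) == 21
        assert 17_640 * 6 == 105_840
        assert 17_640 * 15 == 264_600
        assert 105_840 + 264_600 == 370_440

    def test_toy_sweep_matches_scalar_path(self, toy_cohort):
        """The vectorized sweep must agree row-for-row with the one-at-a-time
        classifier constructors on a brute-force enumerable cohort."""
        grid = BasinGridSpec(resolution=41)
        config = SweepConfig(master_seed=9, grid=grid, n_boot=2000)
        result = sweep(toy_cohort, config)
        assert result.n_partitions == 36
        assert len(result.outcomes) == 36 * 21

        probs = sample_probabilities(toy_cohort, grid)
        truth = toy_cohort.groups.to_dict()
        parts = enumerate_partitions(toy_cohort)
        outcome_index = result.outcomes.set_index(["partition_id", "kind", "predictor"])

        rng = np.random.default_rng(0)
        for pid in rng.choice(36, size=8, replace=False):
            part = parts[pid]
            for predictor in [Predictor("FKBP5", "IL1B"), Predictor("FOXO1A", "IL6")]:
                pair = construct_model_classifier(
                    part, predictor, probs[predictor.name].to_dict(),
                    n_boot=2000, master_seed=9,
                )
                row = outcome_index.loc[(pid, "model", predictor.name)]
                assert bool(row["constructed"]) == pair.separated
                if pair.separated:
                    calls = {
                        sid: classify_sample(probs[predictor.name][sid], pair)
                        for sid in part.test
                    }
                    precision, recall = evaluate(calls, truth)
                    assert row["precision"] == pytest.approx(precision)
                    assert row["recall"] == pytest.approx(recall)
            for gene in ("IL1B", "FOXO1A"):
                pair = construct_null_1gene(part, gene, toy_cohort, n_boot=2000, master_seed=9)
                row = outcome_index.loc[(pid, "null-1gene", gene)]
                assert bool(row["constructed"]) == pair.separated
            for pair_genes in [("FOXO1A", "IL6"), ("IL1B", "IL8")]:
                rect = construct_null_2gene(
                    part, pair_genes, toy_cohort, n_boot=2000, master_seed=9
                )
                row = outcome_index.loc[(pid, "null-2gene", "-".join(pair_genes))]
                assert bool(row["constructed"]) == rect.separated
                if rect.separated:
                    g1, g2 = pair_genes
                    e1 = toy_cohort.expression(g1)
                    e2 = toy_cohort.expression(g2)
                    calls = {
                        sid: classify_sample((e1[sid], e2[sid]), rect)
                        for sid in part.test
                    }
                    precision, recall = evaluate(calls, truth)
                    assert row["precision"] == pytest.approx(precision)
                    assert row["recall"] == pytest.approx(recall)

    def test_sweep_is_deterministic(self, toy_cohort):
        config = SweepConfig(master_seed=4, grid=BasinGridSpec(41), n_boot=1000)
        a = sweep(toy_cohort, config)
        b = sweep(toy_cohort, config)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        pd.testing.assert_frame_equal(a.model_summary, b.model_summary)

    def test_subsample_is_seeded_subset(self, toy_cohort):
        config = SweepConfig(master_seed=4, grid=BasinGridSpec(41), n_boot=1000, subsample=10)
        a = sweep(toy_cohort, config)
        assert a.n_partitions == 10
        full = sweep(toy_cohort, SweepConfig(master_seed=4, grid=BasinGridSpec(41), n_boot=1000))
        merged = a.outcomes.merge(
            full.outcomes, on=["partition_id", "kind", "predictor"], suffixes=("_a", "_b")
        )
        assert len(merged) == len(a.outcomes)
        assert (merged["constructed_a"] == merged["constructed_b"]).all()

    def test_recall_counts_no_calls_exactly(self, toy_cohort):
        result = sweep(toy_cohort, SweepConfig(master_seed=2, grid=BasinGridSpec(41), n_boot=1000))
        built = result.outcomes[result.outcomes["constructed"]]
        assert ((built["precision"] >= 0) & (built["precision"] <= 1)).all()
        assert ((built["recall"] >= 0) & (built["recall"] <= 1)).all()
        # recall is a multiple of 1/4 on the 4-sample toy test sets
        assert np.allclose((built["recall"] * 4) % 1, 0.0)
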