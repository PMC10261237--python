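import math

import numpy as np
import pytest

from mpxval.cutoffs import (
    DEFAULT_CUTOFF_GRID,
    AucEstimate,
    CutoffPerformance,
    PairedSample,
    binarize_reference,
    delong_auc,
    optimal_cutoff,
    parse_binary_result,
    performance_at_cutoff,
    read_paired_samples,
    roc_points,
    sweep_cutoffs,
)
from mpxval.errors import DegenerateClassesError, DuplicateCutoffWarning, SchemaError

from conftest import make_pairs


class TestPairedSample:
    def test_rejects_negative_reference(self):
        with pytest.raises(ValueError):
            PairedSample("a", -0.1, True)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            PairedSample("a", math.nan, False)


class TestBinarizeReference:
    def test_strict_inequality_convention(self):
        labels = binarize_reference([0.05, 0.6, 2.0], 0.6)
        assert labels.tolist() == [False, False, True]

    def test_cutoff_below_minimum_all_positive(self):
        assert binarize_reference([0.2, 0.5, 3.0], 0.01).all()

    def test_cutoff_at_max_only_strict_exceeders(self):
        values = [0.1, 0.5, 0.5, 0.9, 0.9]
        labels = binarize_reference(values, max(values))
        # brute-force comparison
        assert labels.tolist() == [v > max(values) for v in values]
        assert labels.sum() == 0


class TestPerformanceAtCutoff:
    # hand-enumerated 4-sample example
    PAIRS = make_pairs([2.0, 0.9, 0.3, 0.0], [True, True, False, False])

    def test_perfect_at_0p6(self):
        perf = performance_at_cutoff(self.PAIRS, 0.6)
        assert (perf.tp, perf.fn, perf.tn, perf.fp) == (2, 0, 2, 0)
        assert perf.sensitivity == 1.0
        assert perf.specificity == 1.0
        assert perf.accuracy == 1.0

    def test_mixed_at_1p5(self):
        perf = performance_at_cutoff(self.PAIRS, 1.5)
        assert (perf.tp, perf.fn, perf.tn, perf.fp) == (1, 0, 2, 1)
        assert perf.sensitivity == 1.0
        assert perf.specificity == pytest.approx(2 / 3)
        assert perf.accuracy == pytest.approx(3 / 4)

    def test_undefined_specificity_not_coerced(self):
        pairs = make_pairs([1.0, 2.0], [True, True])
        perf = performance_at_cutoff(pairs, 0.5)
        assert perf.sensitivity == 1.0
        assert perf.specificity is None
        assert perf.youden_j is None

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            performance_at_cutoff([], 0.5)

    def test_value_at_cutoff_is_condition_negative(self):
        pairs = make_pairs([0.6], [True])
        perf = performance_at_cutoff(pairs, 0.6)
        assert perf.fp == 1 and perf.tp == 0


class TestSweepCutoffs:
    def test_default_grid_has_ten_rows(self, default_cohort):
        sweep = sweep_cutoffs(list(default_cohort.samples))
        assert len(sweep) == 10
        assert [r.cutoff for r in sweep] == pytest.approx(list(DEFAULT_CUTOFF_GRID))

    def test_singleton_grid_matches_direct_call(self, default_cohort):
        pairs = list(default_cohort.samples)
        (row,) = sweep_cutoffs(pairs, [0.4])
        assert row == performance_at_cutoff(pairs, 0.4)

    def test_duplicates_collapsed_with_warning(self, default_cohort):
        pairs = list(default_cohort.samples)
        with pytest.warns(DuplicateCutoffWarning):
            sweep = sweep_cutoffs(pairs, [0.3, 0.1, 0.3])
        assert [r.cutoff for r in sweep] == sorted({0.1, 0.3})

    def test_empty_grid_raises(self, default_cohort):
        with pytest.raises(ValueError):
            sweep_cutoffs(list(default_cohort.samples), [])


class TestRocPoints:
    def test_perfect_classifier_geometry(self):
        ref = [0.01, 0.2, 0.7, 1.5, 8.0]
        t_star = 0.5
        pairs = make_pairs(ref, [v > t_star for v in ref])
        pts = {(round(s, 12), round(f, 12)) for _, s, f in roc_points(pairs).points}
        assert (0.0, 0.0) in pts
        assert (1.0, 0.0) in pts  # (sens, 1-spec) = (1, 0)
        assert (1.0, 1.0) in pts

    def test_at_most_n_plus_one_matrices(self, rng):
        ref = rng.uniform(0, 10, 25)
        pairs = make_pairs(ref, rng.random(25) < 0.5)
        curve = roc_points(pairs)
        assert len(set(curve.points)) <= 26 + 1  # n distinct values + sentinel

    def test_coin_flip_curve_hugs_diagonal(self, rng):
        n = 4000
        ref = rng.uniform(0, 10, n)
        pairs = make_pairs(ref, rng.random(n) < 0.5)
        # restrict to central cutoffs so both classes hold >= 1000 samples;
        # binomial sampling error is then well below the tolerance
        for cutoff, sens, fpr in roc_points(pairs).points:
            if 2.5 <= cutoff <= 7.5:
                assert abs(sens - fpr) < 0.08

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            roc_points([])


class TestDelongAuc:
    def test_perfect_separation(self):
        pairs = make_pairs([5, 6, 7, 1, 2], [True, True, True, False, False])
        assert delong_auc(pairs).auc == 1.0

    def test_pure_ties_give_half(self):
        pairs = make_pairs([3.0] * 6, [True, True, True, False, False, False])
        est = delong_auc(pairs)
        assert est.auc == 0.5

    def test_worked_example_with_tie(self, oracle_auc):
        # positives (2, 5, 9) vs negatives (1, 5): exhaustive count = 4.5/6
        pairs = make_pairs([2, 5, 9, 1, 5], [True, True, True, False, False])
        expected = oracle_auc([2, 5, 9], [1, 5])
        assert expected == 4.5 / 6
        assert delong_auc(pairs).auc == pytest.approx(expected, abs=1e-12)

    def test_one_class_absent_raises(self):
        with pytest.raises(DegenerateClassesError):
            delong_auc(make_pairs([1, 2, 3], [True, True, True]))

    def test_ci_brackets_point_estimate(self, default_cohort):
        est = delong_auc(list(default_cohort.samples))
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0

    def test_logit_ci_inside_unit_interval(self, default_cohort):
        est = delong_auc(list(default_cohort.samples), ci_method="logit")
        assert 0.0 < est.ci_low <= est.auc <= est.ci_high < 1.0

    def test_higher_level_widens_ci(self, default_cohort):
        pairs = list(default_cohort.samples)
        e90 = delong_auc(pairs, level=0.90)
        e99 = delong_auc(pairs, level=0.99)
        assert e99.ci_high - e99.ci_low > e90.ci_high - e90.ci_low

    def test_invalid_level_raises(self, default_cohort):
        with pytest.raises(ValueError):
            delong_auc(list(default_cohort.samples), level=1.5)


def _row(cutoff, sens, spec, acc=0.5):
    return CutoffPerformance(cutoff, 1, 1, 1, 1, sens, spec, acc)


class TestOptimalCutoff:
    def test_argmax_of_youden(self):
        rows = [_row(0.1, 0.6, 0.6), _row(0.2, 0.94, 0.94), _row(0.3, 0.75, 0.75)]
        cutoff, best = optimal_cutoff(rows)
        assert cutoff == 0.2 and best is rows[1]

    def test_tie_breaks_to_lower_cutoff(self):
        rows = [_row(0.4, 0.9, 0.9), _row(0.2, 0.9, 0.9)]
        cutoff, _ = optimal_cutoff(rows)
        assert cutoff == 0.2

    def test_undefined_rows_skipped(self):
        rows = [_row(0.1, None, 1.0), _row(0.5, 0.8, 0.8)]
        assert optimal_cutoff(rows)[0] == 0.5

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            optimal_cutoff([_row(0.1, None, 1.0), _row(0.2, 1.0, None)])

    def test_accuracy_criterion(self):
        rows = [_row(0.1, 0.9, 0.9, acc=0.7), _row(0.2, 0.5, 0.5, acc=0.95)]
        assert optimal_cutoff(rows, criterion="accuracy")[0] == 0.2

    def test_step_detector_parameter_recovery_single(self):
        from mpxval.synthetic import default_table4_config, sample_cohort

        theta = 0.4
        cfg = default_table4_config(5000, seed=11, detection_mid=theta, detection_slope=0.0)
        sweep = sweep_cutoffs(list(sample_cohort(cfg).samples))
        assert optimal_cutoff(sweep)[0] == pytest.approx(theta)


class TestIO:
    @pytest.mark.parametrize(
        "token,expected",
        [("1", True), ("0", False), ("pos", True), ("NEG", False),
         ("positive", True), ("negative", False), (1, True), (0, False)],
    )
    def test_parse_binary_result(self, token, expected):
        assert parse_binary_result(token) is expected

    def test_parse_garbage_raises(self):
        with pytest.raises(SchemaError):
            parse_binary_result("maybe")

    def test_round_trip_csv(self, tmp_path, default_cohort):
        from mpxval.synthetic import write_cohort_csv

        path = tmp_path / "cohort.csv"
        write_cohort_csv(default_cohort, path)
        pairs = read_paired_samples(path)
        assert len(pairs) == 219
        orig = list(default_cohort.samples)
        assert [p.index_result for p in pairs] == [p.index_result for p in orig]
        np.testing.assert_allclose(
            [p.reference_value for p in pairs],
            [p.reference_value for p in orig],
            rtol=1e-9,
        )

    def test_missing_column_names_file(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,value\na,1\n")
        with pytest.raises(SchemaError, match="qrt_percent_is"):
            read_paired_samples(path)
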