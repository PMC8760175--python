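import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aievote.dataio import ACQ, AIE
from aievote.evaluate import (
    ConfusionCounts,
    CVConfig,
    compute_auc,
    compute_metrics,
    make_folds,
    run_cv,
)
from aievote.synthetic import GeneratorConfig, generate_dataset


def brute_force_auc(scores, labels01):
    """Pair-counting oracle: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = [s for s, y in zip(scores, labels01) if y == 1]
    neg = [s for s, y in zip(scores, labels01) if y == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestMakeFolds:
    def test_reference_scale_fold_sizes(self):
        labels = [AIE] * 134 + [ACQ] * 222
        folds = make_folds(labels, K=10, seed=0)
        sizes = sorted(len(folds.test_indices(f)) for f in range(10))
        assert set(sizes) <= {35, 36} and sum(sizes) == 356

    def test_stratification_of_positives(self):
        # 134 positives over 10 folds -> 13 or 14 per fold
        labels = np.array([AIE] * 134 + [ACQ] * 222)
        folds = make_folds(labels, K=10, seed=3)
        for f in range(10):
            n_pos = (labels[folds.test_indices(f)] == AIE).sum()
            assert n_pos in (13, 14)

    def test_partition_is_disjoint_and_exhaustive(self):
        labels = [AIE] * 40 + [ACQ] * 60
        folds = make_folds(labels, K=5, seed=1)
        all_idx = np.concatenate([folds.test_indices(f) for f in range(5)])
        assert sorted(all_idx) == list(range(100))

    def test_same_seed_reproduces_assignments(self):
        labels = [AIE] * 30 + [ACQ] * 30
        a = make_folds(labels, K=5, seed=9)
        b = make_folds(labels, K=5, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_too_few_class_members_errors(self):
        with pytest.raises(ValueError, match="stratification"):
            make_folds([AIE] * 5 + [ACQ] * 50, K=10, seed=0)


class TestComputeMetrics:
    def test_perfect_two_sample_case(self):
        report = compute_metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert (report.accuracy, report.precision, report.recall, report.f1) == (1, 1, 1, 1)

    def test_reference_error_decomposition(self):
        # 134 positives / 222 negatives with 4 false negatives and 16 false
        # positives; oracle values by direct arithmetic
        c = ConfusionCounts(TP=130, TN=206, FP=16, FN=4)
        report = compute_metrics(c)
        assert report.accuracy == pytest.approx(336 / 356)
        assert report.precision == pytest.approx(130 / 146)
        assert report.recall == pytest.approx(130 / 134)
        expected_f1 = 2 * (130 / 146) * (130 / 134) / ((130 / 146) + (130 / 134))
        assert report.f1 == pytest.approx(expected_f1)
        assert report.fpr == pytest.approx(16 / 222)

    def test_undefined_ratios_reported_as_none_not_zero(self):
        report = compute_metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert report.accuracy == 1.0
        assert report.precision is None and report.recall is None and report.f1 is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)

    @given(st.tuples(*[st.integers(0, 200)] * 4).filter(lambda t: sum(t) > 0))
    def test_accuracy_error_complement_identity(self, counts):
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp, tn, fp, fn)
        assert compute_metrics(c).accuracy == pytest.approx(1 - (fp + fn) / c.total)


class TestComputeAuc:
    def test_perfect_ranking(self):
        assert compute_auc([0.9, 0.8, 0.1], [AIE, AIE, ACQ]) == 1.0

    def test_constant_scores_are_chance(self):
        assert compute_auc([0.5] * 6, [AIE, ACQ, AIE, ACQ, AIE, ACQ]) == 0.5

    def test_three_point_oracles(self):
        # pair-counting oracle: 2 positives x 1 negative -> 2 pairs
        assert compute_auc([0.9, 0.4, 0.6], [AIE, ACQ, AIE]) == 1.0
        assert compute_auc([0.4, 0.9, 0.6], [AIE, ACQ, AIE]) == 0.0
        assert compute_auc([0.4, 0.9, 0.9], [AIE, ACQ, AIE]) == 0.25

    def test_matches_pair_counting_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = np.where(y == 1, AIE, ACQ)
            assert compute_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(40)
        labels = np.where(rng.integers(0, 2, 40) == 1, AIE, ACQ)
        if len(set(labels)) < 2:
            labels[0] = AIE if labels[0] == ACQ else ACQ
        base = compute_auc(scores, labels)
        assert compute_auc(np.exp(5 * scores), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [AIE, AIE])


@pytest.fixture(scope="module")
def report(small_synth, small_blocks):
    config = CVConfig(
        multimodal=False, outer_folds=3, inner_folds=3, seed=2,
        families=("logistic_regression", "knn"), grid_preset="reduced",
    )
    return run_cv(small_synth, config, blocks=small_blocks), small_synth


class TestRunCV:
    def test_layout_covers_all_cells_and_ensemble(self, report):
        rep, _ = report
        assert len(rep.cells) == 2 * 5  # families x single modes
        frame = rep.to_table()
        assert len(frame) == 11  # 10 voter rows + ensemble row

    def test_every_record_tested_exactly_once(self, report):
        rep, ds = report
        for cell in rep.cells.values():
            assert cell.pooled_confusion.total == len(ds)
        assert rep.ensemble.pooled_confusion.total == len(ds)
        assert sum(rep.fold_sizes) == len(ds)

    def test_aggregation_uses_sample_std_over_folds(self, report):
        rep, _ = report
        cell = next(iter(rep.cells.values()))
        accs = [f["test_accuracy"] for f in cell.per_fold]
        assert cell.mean["test_accuracy"] == pytest.approx(np.mean(accs))
        assert cell.std["test_accuracy"] == pytest.approx(np.std(accs, ddof=1))

    def test_deterministic_rerun_bit_identical(self, small_synth, small_blocks):
        config = CVConfig(
            multimodal=False, outer_folds=3, inner_folds=3, seed=4,
            families=("knn",), fingerprint_modes=("morgan",), grid_preset="reduced",
        )
        a = run_cv(small_synth, config, blocks=small_blocks)
        b = run_cv(small_synth, config, blocks=small_blocks)
        assert a.to_json() == b.to_json()

    def test_single_voter_ensemble_equals_that_voter(self, small_synth, small_blocks):
        # a panel whose voters all agree on every record (here: one voter)
        # must yield ensemble label metrics identical to that voter's
        config = CVConfig(
            multimodal=True, outer_folds=3, inner_folds=3, seed=4,
            families=("knn",), fingerprint_modes=("morgan",), grid_preset="reduced",
        )
        rep = run_cv(small_synth, config, blocks=small_blocks)
        assert len(rep.cells) == 1
        cell = next(iter(rep.cells.values()))
        assert rep.ensemble.pooled_confusion == cell.pooled_confusion
        assert rep.ensemble.mean["test_accuracy"] == pytest.approx(
            cell.mean["test_accuracy"]
        )

    def test_unlabeled_or_single_class_dataset_refused(self):
        ds = generate_dataset(GeneratorConfig(n=10, n_positive=0, seed=1))
        with pytest.raises(ValueError, match="both classes"):
            run_cv(ds, CVConfig(outer_folds=2))

    def test_two_fold_toy_protocol(self, small_synth, small_blocks):
        config = CVConfig(
            multimodal=False, outer_folds=2, inner_folds=2, seed=0,
            families=("knn",), fingerprint_modes=("morgan",), grid_preset="reduced",
        )
        rep = run_cv(small_synth, config, blocks=small_blocks)
        assert len(rep.fold_sizes) == 2
        assert sum(rep.fold_sizes) == len(small_synth)

    def test_fold_safe_fusion_runs_and_keeps_widths(self, small_synth, small_blocks):
        config = CVConfig(
            multimodal=True, outer_folds=2, inner_folds=2, seed=0,
            families=("knn",), fingerprint_modes=("morgan",),
            grid_preset="reduced", fold_safe_fusion=True,
        )
        rep = run_cv(small_synth, config, blocks=small_blocks)
        assert rep.manifest["decisions"]["fusion_fit_scope"] == "per-fold"
        assert rep.ensemble.pooled_confusion.total == len(small_synth)
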