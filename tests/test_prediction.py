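import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from topf.dataio import RunConfig
from topf.features import FeatureMatrix
from topf.prediction import (
    concatenate_clips,
    corrected_resampled_ttest,
    fdr_adjust,
    length_sweep,
    make_family_folds,
    permutation_test,
    run_nested_cv,
    score,
    sweep_lengths,
)
from topf.synthdata import GenerativeSpec, generate_clip, generate_cohort


class TestMakeFamilyFolds:
    def test_singleton_families_balanced(self):
        cohort = generate_cohort(100, 100, seed=0)
        scheme = make_family_folds(cohort, 10, seed=1)
        sizes = scheme.assignment.value_counts()
        assert (sizes == 10).all()

    def test_large_family_stays_together(self):
        import pandas as pd
        from topf.synthdata import CohortTable
        rows = [{"subject_id": f"s{i}", "family_id": "big", "sex_label": i % 2}
                for i in range(11)]
        rows += [{"subject_id": f"t{i}", "family_id": f"f{i}", "sex_label": i % 2}
                 for i in range(20)]
        cohort = CohortTable(pd.DataFrame(rows))
        scheme = make_family_folds(cohort, 10, seed=2)
        folds = {scheme.assignment[f"s{i}"] for i in range(11)}
        assert len(folds) == 1

    def test_no_family_split_exhaustive(self):
        # DERIVED: brute-force audit over a random 90-family cohort
        cohort = generate_cohort(178, 90, seed=3)
        scheme = make_family_folds(cohort, 10, seed=4)
        frame = cohort.table.assign(fold=scheme.assignment.values)
        per_family = frame.groupby("family_id")["fold"].nunique()
        assert (per_family == 1).all()

    def test_every_subject_once(self):
        cohort = generate_cohort(57, 23, seed=5)
        scheme = make_family_folds(cohort, 5, seed=6)
        assert scheme.assignment.notna().all()
        assert set(scheme.assignment.index) == set(cohort.subject_ids)

    def test_too_few_families(self):
        cohort = generate_cohort(20, 4, seed=0)
        with pytest.raises(ValueError):
            make_family_folds(cohort, 5, seed=0)

    def test_deterministic(self):
        cohort = generate_cohort(60, 30, seed=1)
        a = make_family_folds(cohort, 10, seed=9).assignment
        b = make_family_folds(cohort, 10, seed=9).assignment
        assert a.equals(b)


class TestScore:
    def test_perfect_predictions(self):
        assert score([1, 0, 1], [1, 0, 1], "classification") == 1.0
        assert score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "regression") == pytest.approx(1.0)

    def test_all_majority_is_chance(self):
        observed = np.array([1] * 6 + [0] * 4)
        predicted = np.ones(10)
        assert score(predicted, observed, "classification") == pytest.approx(0.5)

    def test_hand_evaluated_confusion(self):
        # TP=40, FN=10, TN=30, FP=20 -> (40/50 + 30/50)/2 = 0.70
        observed = np.array([1] * 50 + [0] * 50)
        predicted = np.array([1] * 40 + [0] * 10 + [1] * 20 + [0] * 30)
        assert score(predicted, observed, "classification") == pytest.approx(0.70)

    def test_constant_observed_regression_raises(self):
        with pytest.raises(ValueError):
            score([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], "regression")

    @given(st.integers(min_value=1, max_value=50),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_balanced_classes_reduce_to_plain_accuracy(self, half, seed):
        rng = np.random.default_rng(seed)
        observed = np.array([0] * half + [1] * half)
        predicted = rng.integers(0, 2, size=2 * half)
        ba = score(predicted, observed, "classification")
        assert ba == pytest.approx(np.mean(predicted == observed))


class TestNestedCV:
    def test_planted_signal_recovered(self, cohort60, signal_clip, fast_config):
        result = run_nested_cv(signal_clip, cohort60, fast_config)
        assert result.mean_score() >= 0.75

    def test_null_signal_near_chance(self, cohort60, fast_config):
        spec = GenerativeSpec(n_subjects=60, n_rois=30, n_trs=100,
                              shared_fraction=0.3, effect_size=0.0,
                              noise_sd=1.0, seed=21)
        clip = generate_clip(cohort60, spec)
        result = run_nested_cv(clip, cohort60, fast_config)
        assert 0.3 <= result.mean_score() <= 0.7

    def test_deterministic_rerun(self, cohort60, signal_clip, fast_config):
        a = run_nested_cv(signal_clip, cohort60, fast_config).scores()
        b = run_nested_cv(signal_clip, cohort60, fast_config).scores()
        assert np.array_equal(a, b)

    def test_score_count_and_sizes(self, cohort60, signal_clip, fast_config):
        result = run_nested_cv(signal_clip, cohort60, fast_config)
        assert len(result.records) == fast_config.n_repeats * fast_config.k_outer
        for rec in result.records:
            assert rec.n_train + rec.n_test == 60

    def test_family_integrity_every_repeat(self, cohort60, signal_clip):
        config = RunConfig(task="classification", n_pcs=1, estimator="ridge",
                           k_outer=5, k_inner=3, n_repeats=3, seed=2,
                           grids={"ridge": [{"alpha": 1.0}]})
        result = run_nested_cv(signal_clip, cohort60, config)
        fam = cohort60.table.set_index("subject_id")["family_id"]
        for rec in result.records:
            test_fams = set(fam.loc[rec.test_subjects])
            train_ids = [s for s in cohort60.subject_ids
                         if s not in rec.test_subjects]
            assert test_fams.isdisjoint(set(fam.loc[train_ids]))

    def test_feature_matrix_input(self, cohort60, fast_config):
        rng = np.random.default_rng(0)
        y = cohort60.phenotype("sex_label")
        x = rng.standard_normal((60, 8))
        x[:, 0] += 2.0 * y  # one strongly informative feature
        fm = FeatureMatrix(x, [(f"r{j}", 1) for j in range(8)],
                           cohort60.subject_ids)
        result = run_nested_cv(fm, cohort60, fast_config)
        assert result.mean_score() > 0.8

    def test_monotone_power_in_effect_size(self, cohort60, fast_config):
        means = []
        for effect in (0.0, 0.4, 0.8, 1.2):
            spec = GenerativeSpec(n_subjects=60, n_rois=15, n_trs=100,
                                  shared_fraction=0.3,
                                  predictive_rois=tuple(range(5)),
                                  effect_size=effect, noise_sd=1.0, seed=31)
            clip = generate_clip(cohort60, spec)
            means.append(run_nested_cv(clip, cohort60, fast_config).mean_score())
        # monotone within Monte-Carlo error
        assert means[-1] > means[0]
        assert all(b >= a - 0.08 for a, b in zip(means, means[1:]))


class TestPermutationTest:
    def test_observed_beats_all(self):
        p, obs, perm = permutation_test(lambda y: float(np.all(y == 0)),
                                        np.zeros(6), n_perm=10, seed=0,
                                        observed_score=2.0)
        assert p == 0.0

    def test_observed_equals_all(self):
        p, _, _ = permutation_test(lambda y: 0.5, np.arange(6), n_perm=20, seed=0)
        assert p == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        x = rng.standard_normal(20)
        pipeline = lambda labels: float(np.corrcoef(x, labels)[0, 1])
        a = permutation_test(pipeline, y, n_perm=50, seed=3)
        b = permutation_test(pipeline, y, n_perm=50, seed=3)
        assert a[0] == b[0]
        assert np.array_equal(a[2], b[2])


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_fixed_point(self):
        out = fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_hand_step_up(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(30))
        out = fdr_adjust(p)
        assert (out >= p - 1e-15).all()
        assert (np.diff(out) >= -1e-15).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestCorrectedResampledTTest:
    def test_identical_scores(self):
        t, p = corrected_resampled_ttest([0.7, 0.8], [0.7, 0.8], 90, 10)
        assert t == 0.0
        assert p == 1.0

    def test_hand_evaluated_formula(self):
        # d = (0.1, 0.2, 0.0, 0.1); mean 0.1; unbiased var = 0.02/3
        # t = 0.1 / sqrt((1/4 + 1/9) * 0.02/3)
        a = np.array([0.8, 0.9, 0.7, 0.8])
        b = a - np.array([0.1, 0.2, 0.0, 0.1])
        t, p = corrected_resampled_ttest(a, b, n_train=90, n_test=10)
        expected = 0.1 / np.sqrt((0.25 + 1.0 / 9.0) * (0.02 / 3.0))
        assert t == pytest.approx(expected, abs=1e-12)
        assert t == pytest.approx(2.04, abs=0.01)
        assert p == pytest.approx(2 * stats.t.sf(expected, df=3), abs=1e-12)

    def test_constant_nonzero_difference(self):
        t, p = corrected_resampled_ttest([0.8, 0.8], [0.7, 0.7], 90, 10)
        assert t == np.inf
        assert p == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            corrected_resampled_ttest([0.1, 0.2], [0.1], 9, 1)

    def test_type_one_rate_under_exchangeable_null(self):
        # DERIVED calibration: k=100 folds, test/train = 1/9, 500 reps
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(500):
            common = rng.standard_normal(100)
            a = common + 0.1 * rng.standard_normal(100)
            b = common + 0.1 * rng.standard_normal(100)
            _, p = corrected_resampled_ttest(a, b, n_train=90, n_test=10)
            rejections += p < 0.05
        assert rejections / 500 <= 0.08


class TestLengthUtilities:
    def test_eight_lengths_for_249(self):
        assert len(sweep_lengths(249, 30, 30)) == 8

    def test_lengths_for_132(self):
        assert sweep_lengths(132, 30, 30) == [30, 60, 90, 120]

    def test_step_larger_than_total(self):
        assert sweep_lengths(100, 30, 500) == [30]

    def test_start_exceeds_total(self):
        with pytest.raises(ValueError):
            sweep_lengths(20, 30, 30)

    def test_length_sweep_runs_cv_per_length(self, cohort60, signal_clip,
                                             fast_config):
        sweep = length_sweep(signal_clip, start=50, step=50,
                             cohort=cohort60, config=fast_config)
        assert sorted(sweep) == [50, 100]
        for result in sweep.values():
            assert len(result.records) == 5

    def test_concatenate_order_and_truncation(self, cohort20):
        base = dict(n_subjects=20, n_rois=3, n_trs=132, shared_fraction=0.3)
        a = generate_clip(cohort20, GenerativeSpec(**base, seed=1))
        b = generate_clip(cohort20, GenerativeSpec(**base, seed=2))
        out = concatenate_clips([a, b], [240])
        assert out[0].n_trs == 240
        assert np.array_equal(out[0].data[:, :, :132], a.data)
        assert np.array_equal(out[0].data[:, :, 132:], b.data[:, :, :108])

    def test_concatenate_short_target_uses_first_clip(self, cohort20):
        base = dict(n_subjects=20, n_rois=3, n_trs=132, shared_fraction=0.3)
        a = generate_clip(cohort20, GenerativeSpec(**base, seed=1))
        b = generate_clip(cohort20, GenerativeSpec(**base, seed=2))
        out = concatenate_clips([a, b], [120])
        assert np.array_equal(out[0].data, a.data[:, :, :120])

    def test_concatenate_five_targets(self, cohort20):
        base = dict(n_subjects=20, n_rois=2, n_trs=132, shared_fraction=0.3)
        clips = [generate_clip(cohort20, GenerativeSpec(**base, seed=s))
                 for s in range(5)]
        targets = [120, 240, 360, 480, 600]
        out = concatenate_clips(clips, targets)
        assert [c.n_trs for c in out] == targets

    def test_concatenate_mismatch_raises(self, cohort20, cohort60):
        a = generate_clip(cohort20, GenerativeSpec(
            n_subjects=20, n_rois=2, n_trs=50, shared_fraction=0.3, seed=1))
        b = generate_clip(cohort60, GenerativeSpec(
            n_subjects=60, n_rois=2, n_trs=50, shared_fraction=0.3, seed=1))
        with pytest.raises(ValueError):
            concatenate_clips([a, b], [60])
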