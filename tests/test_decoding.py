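"""Decoding: CV scheme, SVM accuracies, permutation null, group statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from vitalmvpa import (
    BOLDRun,
    NoiseConfig,
    SignalConfig,
    build_pattern_set,
    cross_task_contrasts,
    decode_contrast,
    make_cv_folds,
    permutation_null,
    attach_null,
    simulate_run,
    univariate_roi_check,
    wilcoxon_group,
    within_task_contrasts,
)


class TestCVScheme:
    def test_exact_alternate_run_folds(self):
        cv = make_cv_folds()
        assert len(cv.folds) == 4
        expected = [({1, 3}, {2, 4}), ({2, 4}, {1, 3}), ({2, 3}, {1, 4}), ({1, 4}, {2, 3})]
        assert [(set(a), set(b)) for a, b in cv.folds] == expected
        for train, test in cv.folds:
            assert len(train) == len(test) == 2
            assert train | test == {1, 2, 3, 4}
            assert not train & test


class TestDecodeContrast:
    def test_separable_limit_reaches_perfect_accuracy(self, reduced_rois, session_design):
        sig = SignalConfig(delta=50.0, gain_sd=0.0, pattern_jitter_sd=0.01)
        runs = [
            simulate_run(d, reduced_rois, sig, NoiseConfig.silent(), seed=i)
            for i, d in enumerate(session_design.runs)
        ]
        p = build_pattern_set(runs, session_design.runs, reduced_rois, "left_insula")
        res = decode_contrast(p, cross_task_contrasts()[0])
        assert res.mean_accuracy == 1.0

    def test_null_generator_decodes_at_chance(self, reduced_rois, session_design):
        sig = SignalConfig(delta=0.0, gain_sd=0.0)
        runs = [
            simulate_run(d, reduced_rois, sig, NoiseConfig(), seed=30 + i)
            for i, d in enumerate(session_design.runs)
        ]
        p = build_pattern_set(runs, session_design.runs, reduced_rois, "left_insula")
        accs = [decode_contrast(p, c).mean_accuracy for c in cross_task_contrasts()]
        # single-subject 95% Monte Carlo band around 0.5
        assert 0.35 < np.mean(accs) < 0.65

    def test_within_task_contrast_at_chance_with_default_signal(self, noisy_subject):
        p = noisy_subject["patterns"]["left_insula"]
        accs = [decode_contrast(p, c).mean_accuracy for c in within_task_contrasts()]
        assert 0.35 < np.mean(accs) < 0.65

    def test_weights_have_one_value_per_voxel_per_fold(self, noisy_subject):
        p = noisy_subject["patterns"]["left_insula"]
        res = decode_contrast(p, cross_task_contrasts()[1])
        assert len(res.fold_weights) == 4
        assert all(w.shape == (p.beta.shape[1],) for w in res.fold_weights)

    def test_unbalanced_classes_rejected(self, noisy_subject):
        p = noisy_subject["patterns"]["left_insula"]
        bad = p.labels.copy()
        # turn one rude trial of run 1 into a neutral one: 14 vs 15 balance
        idx = bad[(bad.run_index == 1) & (bad.level == 1)].index[0]
        bad.loc[idx, "level"] = 2
        from vitalmvpa.trial_betas import TrialPatternSet

        broken = TrialPatternSet(beta=p.beta, labels=bad, roi_name=p.roi_name, subject_id="s")
        with pytest.raises(ValueError, match="unbalanced"):
            decode_contrast(broken, cross_task_contrasts()[0])


class TestPermutationNull:
    def test_reproducible_and_bounded(self, noisy_subject):
        p = noisy_subject["patterns"]["ctrl_white_matter"]
        c = cross_task_contrasts()[0]
        a = permutation_null(p, c, n_perm=2, seed=3)
        b = permutation_null(p, c, n_perm=2, seed=3)
        assert np.array_equal(a, b)
        assert a.shape == (2,)
        assert np.all((a >= 0) & (a <= 1))

    def test_empirical_p_value_formula(self, noisy_subject):
        p = noisy_subject["patterns"]["ctrl_white_matter"]
        c = cross_task_contrasts()[0]
        res = decode_contrast(p, c)
        null = permutation_null(p, c, n_perm=19, seed=0)
        res = attach_null(res, null)
        expected = (1 + np.sum(null >= res.mean_accuracy)) / 20
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1

    def test_invalid_n_perm_rejected(self, noisy_subject):
        with pytest.raises(ValueError):
            permutation_null(
                noisy_subject["patterns"]["left_insula"], cross_task_contrasts()[0], n_perm=0
            )


class TestWilcoxon:
    def test_all_above_chance_gives_single_extreme_assignment(self):
        accs = 0.5 + np.linspace(0.01, 0.16, 16)
        assert wilcoxon_group(accs, 0.5) == pytest.approx(1 / 2**16)

    def test_matches_exhaustive_enumeration_for_n6(self, rng):
        for _ in range(5):
            d = rng.standard_normal(6)
            d = d[d != 0]
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            count = sum(
                sum(r for r, s in zip(ranks, signs) if s > 0) >= w_obs - 1e-12
                for signs in itertools.product([-1, 1], repeat=len(d))
            )
            expected = count / 2 ** len(d)
            assert wilcoxon_group(d + 0.5, 0.5) == pytest.approx(expected)

    def test_agrees_with_scipy_exact_without_ties(self, rng):
        d = rng.standard_normal(12)
        expected = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert wilcoxon_group(d + 0.5, 0.5) == pytest.approx(expected)

    def test_symmetric_differences_not_significant(self):
        d = np.array([0.04, -0.04, 0.03, -0.03, 0.02, -0.02])
        assert wilcoxon_group(d + 0.5, 0.5) > 0.4

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_group([0.5, 0.5, 0.5], 0.5)


def _toy_run(mean, run_index, shape=(4, 4, 2), n_vol=8):
    data = np.full(shape + (n_vol,), float(mean))
    return BOLDRun(data=data, run_index=run_index, subject_id="s", seed=0, n_volumes=n_vol)


class TestUnivariateCheck:
    def _designs(self):
        from types import SimpleNamespace

        return [
            SimpleNamespace(run_index=i, task=t)
            for i, t in ((1, "vitality"), (2, "vitality"), (3, "velocity"), (4, "velocity"))
        ]

    def _rois(self, reduced_rois):
        # reuse a tiny mask inside the toy volume
        import dataclasses

        coords = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 1]])
        return dataclasses.replace(
            reduced_rois, shape=(4, 4, 2), masks={"roi": coords}, signal_annotation={}
        )

    def test_matches_hand_computation(self, reduced_rois):
        rois = self._rois(reduced_rois)
        designs = self._designs()
        vit_means = [1.0, 2.0, 3.0]
        vel_means = [0.5, 2.5, 2.0]
        runs = [
            [_toy_run(v, 1), _toy_run(v, 2), _toy_run(w, 3), _toy_run(w, 4)]
            for v, w in zip(vit_means, vel_means)
        ]
        t, p = univariate_roi_check(runs, rois, [designs] * 3, "roi")
        t_exp, p_exp = stats.ttest_rel(vit_means, vel_means)
        assert (t, p) == pytest.approx((t_exp, p_exp))

    def test_planted_global_offset_detected(self, reduced_rois):
        rois = self._rois(reduced_rois)
        designs = self._designs()
        rng = np.random.default_rng(0)
        runs = [
            [
                _toy_run(100.4 + 0.01 * rng.standard_normal(), 1),
                _toy_run(100.4 + 0.01 * rng.standard_normal(), 2),
                _toy_run(100.0 + 0.01 * rng.standard_normal(), 3),
                _toy_run(100.0 + 0.01 * rng.standard_normal(), 4),
            ]
            for _ in range(6)
        ]
        t, p = univariate_roi_check(runs, rois, [designs] * 6, "roi")
        assert p < 0.05 and t > 0

    def test_too_few_subjects_rejected(self, reduced_rois):
        rois = self._rois(reduced_rois)
        with pytest.raises(ValueError):
            univariate_roi_check([[_toy_run(1, 1)]], rois, [self._designs()], "roi")
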