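"""Panel enumeration, F-score thresholding, logistic panel fits and nested CV."""

import math

import numpy as np
import pandas as pd
import pytest

from uropanel import (
    MarkerSpec,
    NestedCvConfig,
    SimulationConfig,
    choose_threshold_fscore,
    enumerate_panels,
    evaluate_panel,
    fit_panel,
    generate_cohort,
    nested_cv_select,
)
from uropanel.panel import PanelError

from test_screen import _two_group_cohort


def brute_force_best_f1(scores, labels):
    """Exhaustive search over every candidate threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    uniq = np.unique(s)
    cand = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best = -1.0
    for t in cand:
        pred = s >= t
        tp = (pred & y).sum()
        fp = (pred & ~y).sum()
        fn = (~pred & y).sum()
        denom = 2 * tp + fp + fn
        f = 2 * tp / denom if denom else 0.0
        best = max(best, f)
    return best


def _f1_at(scores, labels, t):
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    pred = s >= t
    tp = (pred & y).sum()
    fp = (pred & ~y).sum()
    fn = (~pred & y).sum()
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


class TestEnumeratePanels:
    def test_small_counts(self):
        assert len(enumerate_panels(list("abcd"), sizes=(2,))) == 6
        assert enumerate_panels(["b", "a"], sizes=(2,)) == [("a", "b")]

    def test_full_pool_counts_match_binomials(self):
        pool = [f"m{j:02d}" for j in range(23)]
        subsets = enumerate_panels(pool, sizes=(2, 3, 4))
        expected = math.comb(23, 2) + math.comb(23, 3) + math.comb(23, 4)
        assert len(subsets) == expected == 10879
        assert len(set(subsets)) == len(subsets)

    def test_size_exceeding_pool_rejected(self):
        with pytest.raises(PanelError):
            enumerate_panels(["a", "b"], sizes=(3,))


class TestThresholdFscore:
    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 30)
            s = rng.uniform(size=n).round(2)
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                y[0] = 1
            t = choose_threshold_fscore(s, y)
            assert _f1_at(s, y, t) == pytest.approx(brute_force_best_f1(s, y))

    def test_perfect_separation_reaches_f1_of_one(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        t = choose_threshold_fscore(s, y)
        assert 0.2 < t < 0.8
        assert _f1_at(s, y, t) == 1.0

    def test_all_positive_labels_threshold_zero(self):
        assert choose_threshold_fscore([0.2, 0.7, 0.9], [1, 1, 1]) == 0.0

    def test_identical_scores_warns_and_returns_half(self):
        with pytest.warns(UserWarning, match="identical"):
            assert choose_threshold_fscore([0.4] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_tie_break_prefers_higher_specificity(self):
        # F1 = 2/3 both at threshold 0 (everyone positive: tp=2 fp=2) and at
        # 0.7 (tp=1 fp=0 fn=1); the tie resolves to the higher threshold,
        # which has specificity 100% instead of 0%
        s = np.array([0.9, 0.3, 0.5, 0.4])
        y = np.array([1, 1, 0, 0])
        t = choose_threshold_fscore(s, y)
        assert t == pytest.approx(0.7)


class TestFitEvaluatePanel:
    def _separable_cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, 2)) * 0.1
        z[n // 2:, :] += 4.0  # cancer rows hugely shifted on both markers
        return _two_group_cohort(10.0 ** z, ["a", "b"])

    def test_separable_training_data_perfect_metrics(self):
        cohort = self._separable_cohort()
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_panel(cohort, ("a", "b"))
        ev = evaluate_panel(model, cohort)
        allg = ev.subgroups["all"]
        assert allg.sn == 100.0 and allg.sp == 100.0
        assert allg.auc.auc == 1.0

    def test_refit_is_deterministic(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        m1 = fit_panel(cohort, ("HE4", "TTR", "CEA"))
        m2 = fit_panel(cohort, ("HE4", "TTR", "CEA"))
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-10)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)
        assert m1.threshold == m2.threshold

    def test_missing_marker_rejected(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        with pytest.raises(PanelError, match="lacks"):
            fit_panel(cohort, ("HE4", "nonexistent"))

    def test_ppv_npv_match_confusion_arithmetic(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        model = fit_panel(cohort, ("HE4", "TTR", "CEA", "Creatinine"))
        ev = evaluate_panel(model, cohort)
        for sub in ev.subgroups.values():
            if sub.tp + sub.fp:
                assert sub.ppv == pytest.approx(100.0 * sub.tp / (sub.tp + sub.fp))
            if sub.tn + sub.fn:
                assert sub.npv == pytest.approx(100.0 * sub.tn / (sub.tn + sub.fn))
            assert sub.sn == pytest.approx(100.0 * sub.tp / (sub.tp + sub.fn))
            assert sub.sp == pytest.approx(100.0 * sub.tn / (sub.tn + sub.fp))

    def test_sn_at_sp_grid_monotone(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        model = fit_panel(cohort, ("HE4", "TTR"))
        ev = evaluate_panel(model, cohort)
        for sub in ev.subgroups.values():
            sn = sub.sn_at_sp["sn"].to_numpy()
            assert np.all(np.diff(sn) <= 1e-9)

    def test_evaluation_invariant_to_sample_order(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        model = fit_panel(cohort, ("HE4", "TTR"))
        rng = np.random.default_rng(3)
        perm = rng.permutation(cohort.n_samples)
        shuffled = cohort.subset(np.zeros(cohort.n_samples, bool) | True)
        shuffled = type(cohort)(
            cohort.meta.iloc[perm].reset_index(drop=True),
            cohort.x.iloc[perm].reset_index(drop=True),
        )
        a = evaluate_panel(model, cohort).subgroups["all"]
        b = evaluate_panel(model, shuffled).subgroups["all"]
        assert a.auc.auc == pytest.approx(b.auc.auc, abs=1e-12)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)

    def test_menopause_covariate_helps_when_strongly_associated(self):
        # menopausal status is markedly enriched in the cancer class, so
        # adding it to a modest 2-marker panel should usually raise held-out AUC
        wins = 0
        n_runs = 60
        base = [MarkerSpec("A", d=0.7), MarkerSpec("B", d=0.5)]
        for seed in range(n_runs):
            cfg = SimulationConfig(
                markers=base, n_benign=80, n_borderline=0,
                n_cancer_early=0, n_cancer_advanced=80,
                p_post_benign=0.2, p_post_cancer=0.6,  # odds ratio ~ 6
                one_unknown_menopause=False, seed=seed,
            )
            train, _ = generate_cohort(cfg)
            test, _ = generate_cohort(
                SimulationConfig(**{**cfg.__dict__, "seed": 10_000 + seed})
            )
            plain = fit_panel(train, ("A", "B"))
            cov = fit_panel(train, ("A", "B"), include_menopause=True)
            auc_plain = evaluate_panel(plain, test).subgroups["all"].auc.auc
            auc_cov = evaluate_panel(cov, test).subgroups["all"].auc.auc
            wins += auc_cov >= auc_plain
        assert wins / n_runs >= 0.8


class TestNestedCv:
    def _planted_cohort(self, seed=0, d=1.3, n_null=4):
        markers = [MarkerSpec("T1", d=d), MarkerSpec("T2", d=d)]
        markers += [MarkerSpec(f"N{j}") for j in range(n_null)]
        cfg = SimulationConfig(
            markers=markers, n_benign=120, n_borderline=0,
            n_cancer_early=0, n_cancer_advanced=140, seed=seed,
        )
        return generate_cohort(cfg)

    def test_planted_pair_is_modal_winner(self):
        cohort, truth = self._planted_cohort(seed=42)
        cfg = NestedCvConfig(
            outer_reps=40, sizes=(2,), seed=1,
            pool=tuple(sorted(cohort.markers)),
        )
        res = nested_cv_select(cohort, cfg)
        assert res.best_models[2].markers == ("T1", "T2")
        wins = res.selection.set_index("panel").loc["T1+T2", "wins"]
        assert wins / 40 >= 0.8

    def test_noise_marker_adds_nothing_held_out(self):
        cohort, _ = self._planted_cohort(seed=7, n_null=1)
        cfg = NestedCvConfig(
            outer_reps=80, sizes=(2, 3), seed=2,
            pool=("N0", "T1", "T2"),
        )
        res = nested_cv_select(cohort, cfg)
        # forced 3-panel = true pair + noise; held-out gain must be negligible
        assert res.heldout_mean_auc[3] <= res.heldout_mean_auc[2] + 0.01

    def test_heldout_auc_does_not_beat_inner_cv_estimate(self):
        cohort, _ = self._planted_cohort(seed=9)
        cfg = NestedCvConfig(outer_reps=50, sizes=(2,), seed=3,
                             pool=tuple(sorted(cohort.markers)))
        res = nested_cv_select(cohort, cfg)
        best_row = res.selection.sort_values("wins", ascending=False).iloc[0]
        assert res.heldout_mean_auc[2] <= best_row["mean_inner_auc"] + 0.02

    def test_reproducible_with_fixed_seed(self):
        cohort, _ = self._planted_cohort(seed=5)
        cfg = NestedCvConfig(outer_reps=10, sizes=(2,), seed=4,
                             pool=tuple(sorted(cohort.markers)))
        a = nested_cv_select(cohort, cfg)
        b = nested_cv_select(cohort, cfg)
        pd.testing.assert_frame_equal(a.selection, b.selection)
        assert a.heldout_mean_auc == b.heldout_mean_auc

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NestedCvConfig(outer_frac=1.2)
        with pytest.raises(ValueError):
            NestedCvConfig(sizes=(5,))
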