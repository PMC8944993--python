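"""Agreement regression, slope/intercept test, confusion metrics, AUROC, CV."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgann import (AGA, SGA, auroc, auroc_from_outputs, confusion_metrics,
                   evaluate, kfold_cv, regression_performance,
                   slope_intercept_test)
from sgann.evaluation import binarize_outputs, kfold_indices


class TestRegression:
    def test_perfect_agreement(self):
        a = np.linspace(0.5, 1.0, 20)
        r, r2, slope, intercept = regression_performance(a, a)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_relation(self):
        a = np.linspace(0, 1, 30)
        r, r2, slope, intercept = regression_performance(a, 2 * a + 3)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)

    def test_matches_closed_form_loop_oracle(self, rng):
        a = rng.normal(size=40)
        p = rng.normal(size=40)
        n = len(a)
        sx = sum(a); sy = sum(p)
        sxx = sum(x * x for x in a); sxy = sum(x * y for x, y in zip(a, p))
        slope_o = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept_o = (sy - slope_o * sx) / n
        syy = sum(y * y for y in p)
        r_o = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy))
        r, r2, slope, intercept = regression_performance(a, p)
        assert slope == pytest.approx(slope_o, rel=1e-10)
        assert intercept == pytest.approx(intercept_o, rel=1e-10)
        assert r == pytest.approx(r_o, rel=1e-10)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            regression_performance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            regression_performance([1.0, 2.0], [1.0, 2.0])


class TestSlopeInterceptTest:
    def test_identity_passes_with_zero_t(self):
        a = np.linspace(0.4, 1.0, 25)
        noise = np.random.default_rng(1).normal(0, 1e-3, 25)
        res = slope_intercept_test(a, a + noise, confidence=0.998)
        assert res.passed
        assert res.p_slope > 0.002 and res.p_intercept > 0.002
        assert res.df == 23

    def test_shifted_line_fails_on_intercept(self):
        import scipy.stats
        a = np.linspace(0, 1, 50)
        noise = np.random.default_rng(2).normal(0, 1e-6, 50)
        res = slope_intercept_test(a, a + 10 + noise, confidence=0.998)
        assert not res.passed
        crit = scipy.stats.t.ppf(1 - 0.002 / 2, 48)
        assert abs(res.t_intercept) > crit      # intercept t clears alpha=0.002
        assert res.p_intercept < 0.002

    def test_confidence_bounds_checked(self):
        a = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            slope_intercept_test(a, a, confidence=1.5)


class TestConfusion:
    def _outputs(self, calls):
        # an output squarely in each band
        return np.array([0.5 if c == SGA else 0.9 for c in calls])

    def test_perfect_classifier(self):
        labels = [SGA] * 2 + [AGA] * 8
        rep = confusion_metrics(labels, self._outputs(labels))
        assert rep.tp == 2 and rep.fp == 0 and rep.tn == 8 and rep.fn == 0
        assert rep.accuracy == 1.0 and rep.ppv == 1.0

    def test_hand_counted_mixed_table(self):
        labels = [SGA, SGA, AGA, AGA, AGA, AGA, AGA, AGA, AGA, AGA]
        calls = [SGA, AGA, SGA, AGA, AGA, AGA, AGA, AGA, AGA, AGA]
        rep = confusion_metrics(labels, self._outputs(calls))
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (1, 1, 7, 1)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.ppv == pytest.approx(0.5)
        assert rep.npv == pytest.approx(0.875)
        assert rep.f1 == pytest.approx(0.5)

    def test_no_positive_calls_ppv_undefined(self):
        labels = [SGA] * 3 + [AGA] * 7
        rep = confusion_metrics(labels, np.full(10, 0.9))
        assert math.isnan(rep.ppv)
        assert rep.npv == pytest.approx(0.7)

    def test_counts_conserved_random_inputs(self, rng):
        labels = rng.choice([SGA, AGA], size=100)
        outputs = rng.uniform(0.0, 1.0, size=100)
        rep = confusion_metrics(labels, outputs)
        assert rep.tp + rep.fp + rep.tn + rep.fn == 100
        for m in (rep.accuracy,):
            assert 0.0 <= m <= 1.0

    def test_below_band_output_counts_as_sga_call(self):
        assert binarize_outputs([0.2])[0] == SGA
        assert binarize_outputs([0.85])[0] == AGA

    def test_bad_inputs_error(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])
        with pytest.raises(ValueError):
            confusion_metrics(["LGA"], [0.5])


def brute_force_auroc(labels, scores, positive=SGA):
    pos = [s for l, s in zip(labels, scores) if l == positive]
    neg = [s for l, s in zip(labels, scores) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        labels = [SGA] * 3 + [AGA] * 3
        assert auroc(labels, [3, 2, 1, 0, -1, -2]) == 1.0

    def test_all_ties_half(self):
        labels = [SGA] * 4 + [AGA] * 4
        assert auroc(labels, np.ones(8)) == 0.5

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        labels = [SGA] * 6 + [AGA] * 6
        scores = rng.integers(0, 5, size=12).astype(float)  # force ties
        assert auroc(labels, scores) == pytest.approx(
            brute_force_auroc(labels, scores), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.integers(-5, 5)),
                    min_size=2, max_size=20))
    def test_rank_formula_equals_brute_force_property(self, pairs):
        labels = [SGA if b else AGA for b, _ in pairs]
        scores = [float(s) for _, s in pairs]
        if not (0 < sum(b for b, _ in pairs) < len(pairs)):
            return
        assert auroc(labels, scores) == pytest.approx(
            brute_force_auroc(labels, scores), abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score
        labels = rng.choice([SGA, AGA], size=60)
        if len(set(labels)) < 2:
            labels[0], labels[1] = SGA, AGA
        outputs = rng.uniform(size=60)
        ours = auroc_from_outputs(labels, outputs)
        ref = roc_auc_score([1 if l == SGA else 0 for l in labels], -outputs)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([SGA, SGA], [1.0, 2.0])

    def test_orientation_lower_output_favors_sga(self):
        # SGA cases produce lower network outputs -> inverted scores rank them on top
        labels = [SGA, SGA, AGA, AGA]
        outputs = [0.5, 0.55, 0.9, 0.95]
        assert auroc_from_outputs(labels, outputs) == 1.0


class TestKFold:
    def test_folds_partition_rows(self):
        folds = kfold_indices(60, 10, seed=4)
        sizes = np.bincount(folds, minlength=10)
        assert (sizes == 6).all()
        folds = kfold_indices(77, 10, seed=4)
        assert folds.max() == 9 and len(folds) == 77
        assert np.ptp(np.bincount(folds)) <= 1

    def test_leave_one_out(self, rng):
        X = rng.uniform(0.1, 0.9, size=(8, 14))
        t = rng.uniform(0.4, 1.0, size=8)
        from sgann import TrainingConfig
        cv = kfold_cv(X, t, k=8, h=1, config=TrainingConfig(max_epochs=5),
                      seed=1)
        assert cv.k == 8
        assert all(rep.n == 1 for rep in cv.fold_reports)

    def test_k_exceeding_n_errors(self, rng):
        with pytest.raises(ValueError):
            kfold_indices(5, 10)

    def test_oracle_cv_stability(self):
        """On noiseless oracle data the mean fold R^2 sits within 0.05 of
        the full-data R^2 of a model trained on everything."""
        from sgann import (CohortConfig, FEATURE_NAMES, TrainingConfig,
                           fit_normalizer, forward, generate_oracle_cohort,
                           normalize, regression_performance)
        from sgann.network import train_with_restarts
        cohort = generate_oracle_cohort(
            CohortConfig(n_sga=28, n_aga=126, seed=15, mode="oracle",
                         oracle_noise_sd=0.0))
        X = normalize(cohort[FEATURE_NAMES],
                      fit_normalizer(cohort[FEATURE_NAMES]))
        t = cohort.target.to_numpy()
        cfg = TrainingConfig(max_epochs=200)

        def train_fn(Xtr, ttr, h, config):
            p, _, _ = train_with_restarts(Xtr, ttr, h, 5, list(range(5)), config)
            return p

        cv = kfold_cv(X, t, k=10, h=2, config=cfg, seed=3, train_fn=train_fn)
        fold_r2 = np.nanmean([rep.r2 for rep in cv.fold_reports])
        full_p = train_fn(X, t, 2, cfg)
        _, full_r2, _, _ = regression_performance(t, forward(X, full_p))
        assert abs(fold_r2 - full_r2) < 0.05
        agg = cv.aggregate()
        assert "r2" in agg.index


class TestEvaluate:
    def test_full_report_fields(self, rng):
        t = np.concatenate([np.full(10, 0.5), np.full(30, 1.0)])
        out = np.clip(t + rng.normal(0, 0.05, 40), 0, 1)
        labels = np.where(t == 0.5, SGA, AGA)
        rep = evaluate(t, out, labels)
        assert rep.n == 40
        assert 0 <= rep.r2 <= 1
        assert rep.tp + rep.fp + rep.tn + rep.fn == 40
        assert 0 <= rep.auroc <= 1
        assert rep.slope_intercept is not None
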