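"""Metrics: ROC/AUC, averaging, correlations, baselines, sign test."""

import numpy as np
import pandas as pd
import pytest

from volmatch.evaluate import (PairedComparison, average_roc, cross_cohort_eval,
                               femaleness_covariate_correlation, learning_curve,
                               roc_auc, sign_test, tiv_threshold_baseline)


class TestRocAuc:
    def test_perfect_ordering(self):
        rep = roc_auc([-2.0, -1.0, 1.0, 2.0], [0, 0, 1, 1])
        assert rep.auc == 1.0 and rep.accuracy == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        rep = roc_auc(rng.normal(size=2000), rng.integers(0, 2, 2000))
        assert abs(rep.auc - 0.5) < 0.05

    def test_matches_pairwise_oracle(self):
        """AUC equals the concordant-pair fraction (ties counted half)."""
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=50), 1)  # induce some ties
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        rep = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert np.isclose(rep.auc, wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_accuracy_uses_strict_positive_rule(self):
        rep = roc_auc([0.0, 1.0], [0, 1])
        assert rep.accuracy == 1.0  # score 0 classified male


class TestAverageRoc:
    def _reports(self, k, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(k):
            labels = rng.integers(0, 2, 60)
            labels[:2] = [0, 1]
            out.append(roc_auc(rng.normal(size=60) + labels, labels))
        return out

    def test_identical_runs_average_to_single_curve(self):
        rep = self._reports(1)[0]
        grid, mean_tpr, mean_auc = average_roc([rep, rep])
        np.testing.assert_allclose(mean_tpr, np.interp(grid, rep.fpr, rep.tpr))
        assert mean_auc == rep.auc

    def test_mean_auc_is_arithmetic_mean(self):
        reps = self._reports(5)
        _, _, mean_auc = average_roc(reps)
        assert np.isclose(mean_auc, np.mean([r.auc for r in reps]))

    def test_curve_within_envelope(self):
        reps = self._reports(5, seed=2)
        grid, mean_tpr, _ = average_roc(reps)
        tprs = np.array([np.interp(grid, r.fpr, r.tpr) for r in reps])
        assert np.all(mean_tpr <= tprs.max(axis=0) + 1e-12)
        assert np.all(mean_tpr >= tprs.min(axis=0) - 1e-12)


class TestCovariateCorrelation:
    def test_exact_negative_correlation(self):
        frame = pd.DataFrame({
            "sex": ["female"] * 10,
            "tiv_ml": np.linspace(1300, 1500, 10),
            "score": -np.linspace(1300, 1500, 10),
        })
        rep, = femaleness_covariate_correlation(frame)
        assert np.isclose(rep.rho, -1.0)
        assert rep.p_value < 1e-10

    def test_wald_p_matches_slope_t_test(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        frame = pd.DataFrame({"sex": ["male"] * 40, "tiv_ml": x, "score": y})
        rep, = femaleness_covariate_correlation(frame)
        # oracle: t statistic of the regression slope
        from scipy import stats
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - slope * x - intercept
        se = np.sqrt((resid @ resid / 38) / ((x - x.mean()) @ (x - x.mean())))
        t = slope / se
        p = 2 * stats.t.sf(abs(t), 38)
        assert np.isclose(rep.p_value, p, rtol=1e-6)

    def test_zero_variance_flagged(self):
        frame = pd.DataFrame({"sex": ["male"] * 5, "tiv_ml": [1.0] * 5,
                              "score": [0.1, 0.2, 0.3, 0.4, 0.5]})
        rep, = femaleness_covariate_correlation(frame)
        assert rep.degenerate


class TestTivThresholdBaseline:
    def test_disjoint_supports_perfect(self):
        frame = pd.DataFrame({
            "subject_id": list("abcdef"),
            "sex": ["female"] * 3 + ["male"] * 3,
            "tiv_ml": [1300, 1310, 1320, 1500, 1510, 1520.0]})
        thr, acc = tiv_threshold_baseline(frame)
        assert acc == 1.0 and 1320 < thr <= 1500

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame({
            "subject_id": [str(i) for i in range(20)],
            "sex": rng.choice(["male", "female"], 20).tolist(),
            "tiv_ml": rng.uniform(1300, 1700, 20)})
        if len(set(frame.sex)) < 2:
            frame.loc[0, "sex"] = "male"
            frame.loc[1, "sex"] = "female"
        thr, acc = tiv_threshold_baseline(frame)
        tiv = frame.tiv_ml.to_numpy()
        female = (frame.sex == "female").to_numpy()
        best = max(np.mean((tiv < t) == female)
                   for t in np.concatenate([tiv - 1e-9, tiv + 1e-9]))
        assert np.isclose(acc, best)

    def test_tie_broken_to_smaller_threshold(self):
        frame = pd.DataFrame({
            "subject_id": list("abcd"),
            "sex": ["female", "male", "female", "male"],
            "tiv_ml": [1300.0, 1400, 1500, 1600]})
        thr, acc = tiv_threshold_baseline(frame)
        # accuracy 0.75 achievable at several thresholds; smallest returned
        assert np.isclose(acc, 0.75)
        assert thr == 1350.0


class TestCrossCohort:
    def test_reduces_to_within_cohort_on_held_out_folds(self, tiny_cohort):
        from volmatch.cv import run_nested_cv

        cohort, frame, norm = tiny_cohort
        res = run_nested_cv(norm, cohort.labels, frame.subject_id.tolist(),
                            "logreg", "matched", seed=0, epochs=5)
        out = cross_cohort_eval(res, norm, cohort.labels)
        run0 = res.runs[0]
        ids = frame.subject_id.tolist()
        te = [ids.index(s) for s in run0.test_ids]
        sub = roc_auc(out["reports"][0].scores[te], cohort.labels[te])
        assert np.isclose(sub.auc, run0.auc)

    def test_null_cohort_transfers_to_chance(self, tiny_cohort):
        import dataclasses

        import volmatch as vm
        from volmatch.cv import run_nested_cv
        from volmatch.preprocess import normalize_stack

        cohort, frame, norm = tiny_cohort
        res = run_nested_cv(norm, cohort.labels, frame.subject_id.tolist(),
                            "logreg", "matched", seed=0, epochs=10)
        effects = dataclasses.replace(
            cohort.effects, sex_effect=np.zeros(cohort.effects.n_regions))
        null = vm.simulate_cohort(vm.HCP_PROFILE, seed=8, n=100,
                                  atlas=cohort.atlas, effects=effects)
        null_norm = normalize_stack(null.images, cohort.atlas.mask)
        out = cross_cohort_eval(res, null_norm, null.labels)
        assert abs(out["mean_auc"] - 0.5) < 0.12

    def test_shared_mechanism_transfers(self, tiny_cohort):
        import volmatch as vm
        from volmatch.cv import run_nested_cv
        from volmatch.preprocess import normalize_stack

        cohort, frame, norm = tiny_cohort
        res = run_nested_cv(norm, cohort.labels, frame.subject_id.tolist(),
                            "logreg", "matched", seed=0, epochs=10)
        other = vm.simulate_cohort(vm.HCP_PROFILE, seed=9, n=100,
                                   atlas=cohort.atlas, effects=cohort.effects)
        other_norm = normalize_stack(other.images, cohort.atlas.mask)
        out = cross_cohort_eval(res, other_norm, other.labels)
        assert out["mean_auc"] > res.mean_auc - 0.1


class TestLearningCurve:
    def test_bookkeeping_and_trend(self, tiny_cohort):
        cohort, frame, norm = tiny_cohort
        tab = learning_curve(norm, cohort.labels, frame, sizes=[40, 120],
                             repeats=1, seed=0, epochs=6)
        assert (tab.n_runs == 25).all()
        assert tab.mean_auc.iloc[1] >= tab.mean_auc.iloc[0] - 0.05

    def test_oversize_rejected(self, tiny_cohort):
        cohort, frame, norm = tiny_cohort
        with pytest.raises(ValueError):
            learning_curve(norm, cohort.labels, frame, sizes=[10_000])


class TestSignTest:
    def test_symmetric_discordance(self):
        res = sign_test(PairedComparison(50, 4, 4, 2))
        assert res["p_value"] == 1.0

    def test_printed_contingency_table(self):
        """35 vs 3 discordant pairs: p = 2 * sum_{i<=3} C(38,i) / 2^38."""
        from math import comb

        res = sign_test(PairedComparison(59, 35, 3, 3))
        exact = 2 * sum(comb(38, i) for i in range(4)) / 2 ** 38
        assert np.isclose(res["p_value"], exact, rtol=1e-12)
        assert res["p_value"] < 7e-8

    def test_single_discordant_pair(self):
        res = sign_test(PairedComparison(10, 1, 0, 0))
        assert res["p_value"] == 1.0

    def test_no_discordant_pairs_flagged(self):
        res = sign_test(PairedComparison(10, 0, 0, 0))
        assert res["p_value"] == 1.0 and res["degenerate"]


def test_plot_roc_curves_writes_png(tmp_path):
    rng = np.random.default_rng(0)
    reports = []
    for _ in range(3):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        reports.append(roc_auc(rng.normal(size=40) + labels, labels))
    from volmatch.evaluate import plot_roc_curves
    out = tmp_path / "roc.png"
    plot_roc_curves(reports, path=out)
    assert out.stat().st_size > 0
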