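import math

import numpy as np
import pandas as pd
import pytest

from glycosig.io import ClinicalRecord, ExpressionMatrix, clinical_frame
from glycosig.model import (
    CorrelationCentroid,
    FittedModel,
    KernelNaiveBayes,
    make_split,
    predict_response,
    roc_auc,
    survival_compare,
)


def records(n, nr_frac=0.5, cohort="K1"):
    out = []
    for i in range(n):
        out.append(
            ClinicalRecord(
                f"{cohort}s{i:03d}", cohort, "NR" if i < round(n * nr_frac) else "R"
            )
        )
    return out


class TestMakeSplit:
    def test_published_cohort_counts(self):
        # 772 samples at 80% -> 618 train (round half up), 154 validation
        plan = make_split(records(772, nr_frac=0.45), train_frac=0.8, seed=1)
        assert len(plan.train_ids) == 618
        assert len(plan.validation_ids) == 154

    def test_exact_stratification_small_n(self):
        clin = clinical_frame(records(10, nr_frac=0.5))
        plan = make_split(clin, train_frac=0.8, seed=3)
        assert len(plan.train_ids) == 8
        resp = clin.loc[plan.train_ids, "response"]
        assert (resp == "NR").sum() == 4 and (resp == "R").sum() == 4

    def test_seed_determinism(self):
        clin = records(50)
        a = make_split(clin, seed=11)
        b = make_split(clin, seed=11)
        assert a.train_ids == b.train_ids and a.validation_ids == b.validation_ids

    def test_held_out_cohorts_untouched(self):
        clin = records(40, cohort="K1") + records(20, cohort="K2")
        plan = make_split(clin, seed=0, test_cohorts=["K2"])
        assert len(plan.test_ids) == 20
        assert all(s.startswith("K2") for s in plan.test_ids)
        assert len(plan.train_ids) + len(plan.validation_ids) == 40

    def test_disjoint_partitions(self):
        plan = make_split(records(37, nr_frac=0.3), seed=5)
        assert not set(plan.train_ids) & set(plan.validation_ids)
        assert len(plan.train_ids) + len(plan.validation_ids) == 37


class TestKernelNaiveBayes:
    def test_gaussian_mode_symmetric_midpoint(self):
        # classes with empirical means 0 and 2, equal sds and priors:
        # x = 1 is equidistant -> posterior exactly 0.5
        X = np.array([[-1.0], [0.0], [0.0], [1.0], [1.0], [2.0], [2.0], [3.0]])
        y = np.array(["R"] * 4 + ["NR"] * 4)
        nb = KernelNaiveBayes(usekernel=False).fit(X, y)
        p = nb.predict_proba(np.array([[1.0]]))
        assert p[0, list(nb.classes_).index("NR")] == pytest.approx(0.5, abs=1e-12)
        assert nb.predict(np.array([[0.0]]))[0] == "R"

    def test_kernel_mode_matches_hand_kde(self):
        # bimodal NR class; oracle evaluates the Gaussian-kernel posterior
        X = np.array([[0.0], [0.5], [1.0], [5.0], [6.0], [10.0]])
        y = np.array(["R", "R", "R", "NR", "NR", "NR"])
        nb = KernelNaiveBayes(usekernel=True, adjust=1.0, fL=0.0).fit(X, y)

        def kde_like(x, pts):
            pts = np.asarray(pts)
            sd = pts.std(ddof=1)
            bw = 0.9 * sd * len(pts) ** -0.2
            dens = np.exp(-0.5 * ((x - pts) / bw) ** 2) / (bw * math.sqrt(2 * math.pi))
            return dens.mean()

        for x in (0.3, 4.0, 7.5):
            num = kde_like(x, [5.0, 6.0, 10.0]) * 0.5
            den = num + kde_like(x, [0.0, 0.5, 1.0]) * 0.5
            got = nb.predict_proba(np.array([[x]]))[0, list(nb.classes_).index("NR")]
            assert got == pytest.approx(num / den, rel=1e-10)

    def test_fL_smooths_priors(self):
        X = np.array([[0.0], [0.1], [5.0]])
        y = np.array(["R", "R", "NR"])
        nb0 = KernelNaiveBayes(fL=0.0).fit(X, y)
        nb1 = KernelNaiveBayes(fL=1.0).fit(X, y)
        assert np.exp(nb0.log_prior_[list(nb0.classes_).index("NR")]) == pytest.approx(1 / 3)
        assert np.exp(nb1.log_prior_[list(nb1.classes_).index("NR")]) == pytest.approx(2 / 5)


class TestCorrelationCentroid:
    def test_separable_profiles(self, rng):
        c0 = np.array([1.0, 2, 3, 4, 5])
        c1 = c0[::-1].copy()
        X = np.vstack(
            [c0 + rng.normal(0, 0.1, 5) for _ in range(10)]
            + [c1 + rng.normal(0, 0.1, 5) for _ in range(10)]
        )
        y = np.array(["R"] * 10 + ["NR"] * 10)
        cc = CorrelationCentroid().fit(X, y)
        assert (cc.predict(X) == y).all()
        p = cc.predict_proba(X)
        assert p.shape == (20, 2) and np.allclose(p.sum(axis=1), 1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array(["NR", "NR", "R", "R"]))
        assert res.auc == 1.0 and res.ci_high <= 1.0

    def test_all_ties_half(self):
        res = roc_auc(np.ones(6), np.array(["NR"] * 3 + ["R"] * 3))
        assert res.auc == pytest.approx(0.5)

    def test_three_of_four_pairs_concordant(self):
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        labels = np.array(["NR", "NR", "R", "R"])
        assert roc_auc(scores, labels).auc == pytest.approx(0.75)

    def test_complement_symmetry_exact(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.4, "NR", "R")
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-15)

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.normal(size=50), 1)  # force some ties
        labels = np.where(rng.random(50) < 0.5, "NR", "R")
        pos, neg = scores[labels == "NR"], scores[labels != "NR"]
        oracle = np.mean(
            [1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg]
        )
        assert roc_auc(scores, labels).auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array(["R", "R"]))


def efron_loglik(beta, times, events, x):
    """Oracle: Efron partial log-likelihood for one binary covariate."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        died = (times == t) & (events == 1)
        at_risk = times >= t
        d = died.sum()
        sum_died = np.exp(beta * x[died]).sum()
        sum_risk = np.exp(beta * x[at_risk]).sum()
        ll += beta * x[died].sum()
        for j in range(d):
            ll -= math.log(sum_risk - j / d * sum_died)
    return ll


class TestSurvival:
    def _clinical(self, times, events, labels):
        recs = [
            ClinicalRecord(f"s{i}", "K", "NA", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))
        ]
        df = clinical_frame(recs)
        lab = pd.Series(labels, index=df.index)
        return df, lab

    def test_identical_groups_hr_one(self):
        times = np.tile([3.0, 5.0, 8.0, 12.0], 2)
        events = np.tile([1, 1, 0, 1], 2)
        labels = ["R"] * 4 + ["NR"] * 4
        df, lab = self._clinical(times, events, labels)
        comp = survival_compare(df, lab)
        assert comp.hr == pytest.approx(1.0, abs=1e-6)

    def test_six_subject_toy_matches_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 0, 1])
        labels = ["NR", "NR", "R", "NR", "R", "R"]
        df, lab = self._clinical(times, events, labels)
        comp = survival_compare(df, lab)
        x = (np.array(labels) == "NR").astype(float)
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [efron_loglik(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert math.log(comp.hr) == pytest.approx(beta_star, abs=2e-4)

    def test_km_median_invariant_to_sample_order(self, rng):
        times = rng.exponential(10, size=30).round(2)
        events = (rng.random(30) < 0.8).astype(int)
        labels = np.where(rng.random(30) < 0.5, "NR", "R")
        df, lab = self._clinical(times, events, labels)
        ref = survival_compare(df, lab)
        perm = rng.permutation(30)
        df2, lab2 = df.iloc[perm], lab.iloc[perm]
        out = survival_compare(df2, lab2)
        assert out.median_os == ref.median_os
        assert out.hr == pytest.approx(ref.hr, rel=1e-9)

    def test_ci_brackets_hr(self, rng):
        times = rng.exponential(10, size=40)
        events = np.ones(40, dtype=int)
        labels = np.where(rng.random(40) < 0.5, "NR", "R")
        df, lab = self._clinical(times, events, labels)
        comp = survival_compare(df, lab)
        assert comp.ci_low <= comp.hr <= comp.ci_high

    def test_no_events_in_group_warns(self):
        times = [3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 1, 0, 0, 0]
        labels = ["NR"] * 3 + ["R"] * 3
        df, lab = self._clinical(times, events, labels)
        with pytest.warns(UserWarning, match="no events"):
            survival_compare(df, lab)


class TestPredictResponse:
    def _model(self):
        X = np.array([[0.0, 0.0], [0.2, 0.1], [2.0, 2.0], [2.2, 1.9]])
        y = np.array(["R", "R", "NR", "NR"])
        est = KernelNaiveBayes(usekernel=False).fit(X, y)
        return FittedModel(
            algorithm="nb",
            hyperparameters={},
            features=["GA", "GB"],
            feature_means=X.mean(axis=0),
            estimator=est,
            cv_auc=None,
            validation_auc=None,
        )

    def test_labels_follow_score_threshold(self):
        m = ExpressionMatrix(
            np.array([[0.0, 2.0], [0.0, 2.0]]), ["GA", "GB"], ["low", "high"], "adjusted"
        )
        pred = predict_response(self._model(), m)
        assert pred.loc["low", "label"] == "R" and pred.loc["high", "label"] == "NR"
        assert ((pred["score"] >= 0) & (pred["score"] <= 1)).all()

    def test_missing_features_imputed_with_warning(self):
        m = ExpressionMatrix(np.array([[2.0]]), ["GA"], ["s1"], "adjusted")
        with pytest.warns(UserWarning, match="imputed"):
            pred = predict_response(self._model(), m)
        assert pred.shape[0] == 1

    def test_no_overlap_is_error(self):
        m = ExpressionMatrix(np.array([[1.0]]), ["ZZ"], ["s1"], "adjusted")
        with pytest.raises(ValueError, match="no genes"):
            predict_response(self._model(), m)
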