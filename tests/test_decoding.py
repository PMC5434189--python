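"""Feature ranking, naive Bayes, LOSO protocols and permutation testing."""

import numpy as np
import pytest
from scipy.stats import norm

from gradconn.clusters import Cluster
from gradconn.decoding import (classification_metrics, loso_behavior_prediction,
                               loso_classify, nb_fit_predict, permutation_pvalue,
                               permutation_test, rank_features)


def _two_class(n1=8, n0=12, p=6, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
    X = rng.normal(0, 1, (n1 + n0, p))
    X[y == 1, 0] += delta
    return X, y


class TestRankFeatures:
    def test_informative_feature_ranked_first(self):
        X, y = _two_class(delta=10.0, seed=1)
        assert rank_features(X, y, 1)[0] == 0

    def test_all_features_when_n_max(self):
        X, y = _two_class(seed=2)
        assert set(rank_features(X, y, X.shape[1])) == set(range(X.shape[1]))

    def test_tie_broken_toward_lower_index(self):
        X, y = _two_class(p=4, seed=3)
        X[:, 2] = X[:, 1]  # identical |t|
        sel = list(rank_features(X, y, 4))
        assert sel.index(1) < sel.index(2)

    def test_constant_feature_handled_by_variance_floor(self):
        X, y = _two_class(seed=4)
        X[:, 3] = 7.0
        sel = rank_features(X, y, X.shape[1])
        assert len(sel) == X.shape[1]


class TestNaiveBayes:
    def test_separated_classes_confident_posterior(self):
        rng = np.random.default_rng(5)
        X = np.r_[rng.normal(0, 1, 20), rng.normal(10, 1, 20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        label, post = nb_fit_predict(X, y, np.array([0.0]))
        assert label == 0 and post[0] > 0.999

    def test_prior_tie_break_toward_majority(self):
        # symmetric classes around the test point; priors 48:18
        X = np.r_[np.linspace(-2, 0, 48), np.linspace(0, 2, 18)][:, None]
        X[:48] -= 1.0
        X[48:] += 1.0
        y = np.r_[np.zeros(48), np.ones(18)].astype(int)
        label, _ = nb_fit_predict(X, y, np.array([0.0]))
        assert label == 0

    def test_posteriors_match_brute_force_densities(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            X, y = _two_class(p=2, delta=rng.uniform(0, 2), seed=rng.integers(1e6))
            x = rng.normal(0, 1, 2)
            label, post = nb_fit_predict(X, y, x)
            # independent oracle: direct density computation
            like = []
            for c in (0, 1):
                rows = X[y == c]
                mu, var = rows.mean(0), np.maximum(rows.var(0), 1e-9)
                dens = np.prod(norm.pdf(x, mu, np.sqrt(var)))
                like.append(dens * (y == c).mean())
            expect = np.array(like) / sum(like)
            assert np.allclose(post, expect, atol=1e-12)

    def test_matches_sklearn_gaussian_nb(self):
        from sklearn.naive_bayes import GaussianNB

        X, y = _two_class(p=4, delta=1.0, seed=7)
        x = np.array([0.3, -0.2, 0.1, 0.4])
        _, post = nb_fit_predict(X, y, x)
        sk = GaussianNB(var_smoothing=0.0).fit(X, y)
        assert np.allclose(post, sk.predict_proba(x[None])[0], atol=1e-8)

    def test_single_class_raises(self):
        X = np.random.default_rng(8).normal(0, 1, (6, 2))
        with pytest.raises(ValueError):
            nb_fit_predict(X, np.ones(6, int), X[0])


class TestClassificationMetrics:
    def test_study_confusion_counts(self):
        m = classification_metrics(tp=11, fn=7, tn=35, fp=13)
        assert m["accuracy"] == pytest.approx(46 / 66)
        assert m["sensitivity"] == pytest.approx(11 / 18)
        assert m["specificity"] == pytest.approx(35 / 48)
        assert m["dor"] == pytest.approx(11 * 35 / (13 * 7))

    def test_perfect_classification_haldane(self):
        m = classification_metrics(tp=18, fn=0, tn=48, fp=0)
        assert m["accuracy"] == 1.0 and np.isfinite(m["dor"])

    def test_all_predicted_negative(self):
        m = classification_metrics(tp=0, fn=18, tn=48, fp=0)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            classification_metrics(tp=0, fn=0, tn=5, fp=1)


class TestLosoClassify:
    def test_separable_feature_perfect_accuracy(self):
        X, y = _two_class(delta=20.0, seed=9)
        res = loso_classify(X, y, range(1, 5))
        assert np.all(res.accuracy == 1.0)
        assert res.best_n == 1

    def test_accuracy_curve_shape_and_confusion_totals(self):
        X, y = _two_class(delta=1.0, seed=10)
        res = loso_classify(X, y, range(1, 7))
        assert len(res.accuracy) == 6
        c = res.confusion
        assert c["tp"] + c["fn"] == (y == 1).sum()
        assert c["tn"] + c["fp"] == (y == 0).sum()

    def test_matches_brute_force_loo_refit(self):
        """LOSO accuracy equals an independently coded leave-one-out refit (n=8)."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            X, y = _two_class(n1=4, n0=4, p=4, delta=rng.uniform(0, 2),
                              seed=rng.integers(1e6))
            for n in (1, 2, 4):
                res = loso_classify(X, y, [n])
                correct = 0
                for i in range(8):
                    keep = [j for j in range(8) if j != i]
                    Xtr, ytr = X[keep], y[keep]
                    g1, g0 = Xtr[ytr == 1], Xtr[ytr == 0]
                    sp = ((len(g1) - 1) * g1.var(0, ddof=1)
                          + (len(g0) - 1) * g0.var(0, ddof=1)) / (len(ytr) - 2)
                    t = (g1.mean(0) - g0.mean(0)) / np.sqrt(
                        np.maximum(sp, 1e-9) * (1 / len(g1) + 1 / len(g0)))
                    sel = np.argsort(-np.abs(t), kind="stable")[:n]
                    scores = []
                    for c in (0, 1):
                        rows = Xtr[ytr == c][:, sel]
                        mu, var = rows.mean(0), np.maximum(rows.var(0), 1e-9)
                        scores.append(np.log((ytr == c).mean())
                                      + norm.logpdf(X[i, sel], mu, np.sqrt(var)).sum())
                    pred = int(scores[1] > scores[0])
                    correct += pred == y[i]
                assert res.accuracy[0] == pytest.approx(correct / 8)

    def test_held_out_subject_cannot_influence_fold(self):
        """Perturbing only the held-out subject's features leaves the fold's
        selected features and fitted parameters unchanged (training/test
        independence audit)."""
        X, y = _two_class(delta=1.0, seed=12)
        i = 3
        keep = np.ones(len(y), bool)
        keep[i] = False
        sel_before = rank_features(X[keep], y[keep], 3)
        X2 = X.copy()
        X2[i] += 100.0
        sel_after = rank_features(X2[keep], y[keep], 3)
        assert np.array_equal(sel_before, sel_after)
        from gradconn.decoding import _nb_params

        for a, b in zip(_nb_params(X[keep], y[keep]), _nb_params(X2[keep], y[keep])):
            assert np.array_equal(a, b)


class TestPermutation:
    def test_printed_proportion_formula(self):
        null = np.r_[np.full(28, 0.8), np.full(972, 0.5)]
        assert permutation_pvalue(null, 0.7) == pytest.approx(0.028)

    def test_observed_above_every_null_gives_zero(self):
        assert permutation_pvalue(np.full(100, 0.4), 0.9) == 0.0

    def test_permutation_detects_signal(self):
        X, y = _two_class(n1=6, n0=10, delta=4.0, seed=13)
        res = permutation_test(X, y, n_features=1, n_perm=99, seed=0)
        assert res.observed_accuracy == 1.0
        assert res.p < 0.05
        assert len(res.null_accuracies) == 99


class TestLosoBehavior:
    def _setup(self, n1=6, n0=8, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        grid = (6, 6, 4)
        y = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
        n = n1 + n0
        pos_mask = np.zeros(grid, bool)
        pos_mask[0:2, 0:2, 0:2] = True
        neg_mask = np.zeros(grid, bool)
        neg_mask[4:6, 4:6, 2:4] = True
        maps = {}
        for key in ("bilateral", "L", "R"):
            m = rng.normal(0, 0.05, (n,) + grid)
            m[y == 1][:, pos_mask] += 0.0  # fancy indexing copy; do it properly below
            maps[key] = m
        for key in maps:
            maps[key][y == 1, 0:2, 0:2, 0:2] += 0.5
            maps[key][y == 1, 4:6, 4:6, 2:4] -= 0.5
        refs = [
            Cluster(voxels=np.argwhere(pos_mask), size=8, sign=1, peak_stat=5.0,
                    centroid=(0.5, 0.5, 0.5), mask=pos_mask),
            Cluster(voxels=np.argwhere(neg_mask), size=8, sign=-1, peak_stat=-5.0,
                    centroid=(4.5, 4.5, 2.5), mask=neg_mask),
        ]
        feats = np.column_stack([
            maps[s].reshape(n, -1)[:, m.ravel()].mean(axis=1)
            for s in ("L", "R") for m in (pos_mask, neg_mask)
        ])
        beta = np.array([1.0, -0.5, 0.8, -0.3])
        behavior = feats @ beta + rng.normal(0, noise, n)
        return maps, y, behavior, refs

    def test_noiseless_linear_recovery(self):
        maps, y, behavior, refs = self._setup()
        res = loso_behavior_prediction(maps["bilateral"],
                                       {"L": maps["L"], "R": maps["R"]},
                                       y, behavior, refs, nominal_p=0.01)
        assert res.r > 0.99
        assert len(res.predicted) == len(y)

    def test_null_behavior_gives_near_zero_r(self):
        rs = []
        for s in range(15):
            maps, y, behavior, refs = self._setup(seed=s)
            rng = np.random.default_rng(1000 + s)
            res = loso_behavior_prediction(maps["bilateral"],
                                           {"L": maps["L"], "R": maps["R"]},
                                           y, rng.permutation(behavior), refs)
            rs.append(res.r)
        assert abs(np.mean(rs)) < 0.35  # centered near 0 within small-sample error

    def test_degenerate_fold_raises(self):
        maps, y, behavior, refs = self._setup(n1=2, n0=8)
        with pytest.raises(ValueError):
            loso_behavior_prediction(maps["bilateral"],
                                     {"L": maps["L"], "R": maps["R"]},
                                     y, behavior, refs)
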