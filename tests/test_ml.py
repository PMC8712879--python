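"""Classification-pipeline tests: labels, preprocessing, selection, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from crtpredict import cohort as ch
from crtpredict import ml


def toy_table(n=60, n_noise=10, seed=0, signal=True):
    """Small table with one informative feature and Gaussian noise."""
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.4
    cols = {"signal_feat": (y.astype(float) * 2.0 if signal else
                            rng.normal(size=n)) + 0.1 * rng.normal(size=n)}
    for k in range(n_noise):
        cols[f"noise_{k:02d}"] = rng.normal(size=n)
    data = pd.DataFrame(cols)
    meta = pd.DataFrame({
        "kind": "continuous", "provenance": "clinical", "preop_safe": True,
    }, index=pd.Index(data.columns, name="feature"))
    outcomes = pd.DataFrame({
        "dEF_CRT": np.where(y, 17.0, 3.0),
        "dESV_CRT": np.where(y, -47.0, -9.0),
    })
    return ml.CohortTable(data=data, meta=meta, outcomes=outcomes)


class TestLabelResponse:
    @pytest.mark.parametrize("def_, col, val, expect", [
        ("EF10", "dEF_CRT", 17.0, 1),
        ("EF10", "dEF_CRT", 3.0, 0),
        ("EF10", "dEF_CRT", 10.0, 0),   # strict inequality
        ("EF5", "dEF_CRT", 7.0, 1),
        ("EF15", "dEF_CRT", 12.0, 0),
        ("ESV15", "dESV_CRT", -47.0, 1),
        ("ESV15", "dESV_CRT", -10.0, 0),
    ])
    def test_thresholds(self, def_, col, val, expect):
        out = pd.DataFrame({"dEF_CRT": [val], "dESV_CRT": [val]})
        assert ml.label_response(out, def_).iloc[0] == expect

    def test_combined_criterion_is_conjunction(self):
        out = pd.DataFrame({"dEF_CRT": [17, 17, 3], "dESV_CRT": [-47, -5, -47]})
        lab = ml.label_response(out, "EF10+ESV15")
        assert lab.tolist() == [1, 0, 0]

    def test_missing_outcome_drops_patient(self):
        out = pd.DataFrame({"dEF_CRT": [17, np.nan], "dESV_CRT": [-1, -2]})
        lab = ml.label_response(out, "EF10")
        assert len(lab) == 1


class TestPreprocess:
    def test_identical_columns_one_survives(self):
        t = toy_table(seed=1)
        t.data["dup_of_signal"] = t.data["signal_feat"]
        t.meta.loc["dup_of_signal"] = ["continuous", "sim_lbbb", True]
        p = ml.preprocess(t)
        assert ("signal_feat" in p.data.columns) != \
               ("dup_of_signal" in p.data.columns) or \
               "dup_of_signal" not in p.data.columns
        assert "signal_feat" in p.data.columns  # clinical wins the tie

    def test_r_080_pair_both_kept(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=500)
        b = 0.8 * a + 0.6 * rng.normal(size=500)  # r ~ 0.8 < 0.85
        t = toy_table(n=500, seed=2)
        t.data["col_a"], t.data["col_b"] = a, b
        for c in ("col_a", "col_b"):
            t.meta.loc[c] = ["continuous", "clinical", True]
        p = ml.preprocess(t)
        assert {"col_a", "col_b"} <= set(p.data.columns)

    def test_no_surviving_pair_above_threshold(self):
        spec = ch.CohortSpec(n=120, seed=9)
        p = ml.preprocess(ch.generate_feature_table(spec))
        corr = p.data.corr().abs().values
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.85 + 1e-12

    def test_missing_value_columns_dropped_not_imputed(self):
        t = ch.generate_feature_table(ch.CohortSpec(n=80, seed=4))
        p = ml.preprocess(t)
        assert not p.data.isna().any().any()
        assert "IVD" not in p.data.columns


class TestSelectFeatures:
    @pytest.mark.parametrize("selector", ["MDA", "UST", "L1"])
    def test_perfect_separator_ranked_first(self, selector):
        t = toy_table(n=120, seed=3)
        y = ml.label_response(t.outcomes, "EF10").values
        chosen = ml.select_features(t.features(), y, t.meta, selector,
                                    k=3, seed=0)
        assert "signal_feat" in chosen

    def test_categorical_uses_chi_squared(self):
        rng = np.random.default_rng(5)
        n = 200
        y = (rng.random(n) < 0.4).astype(int)
        data = pd.DataFrame({
            "cat_feat": np.where(y, rng.random(n) < 0.8,
                                 rng.random(n) < 0.2).astype(float),
            "cont_feat": rng.normal(size=n),
        })
        meta = pd.DataFrame({"kind": ["categorical", "continuous"],
                             "provenance": "clinical", "preop_safe": True},
                            index=pd.Index(data.columns, name="feature"))
        audit = {}
        chosen = ml.select_features(data, y, meta, "UST", k=1, seed=0,
                                    audit=audit)
        assert audit["cat_feat"] == "chi2"
        assert audit["cont_feat"] == "ttest"
        assert chosen == ["cat_feat"]

    def test_k_exceeding_features_returns_all(self):
        t = toy_table(n=40, n_noise=3, seed=6)
        y = ml.label_response(t.outcomes, "EF10").values
        chosen = ml.select_features(t.features(), y, t.meta, "UST",
                                    k=50, seed=0)
        assert set(chosen) == set(t.data.columns)


class TestEvaluate:
    def test_separable_data_loo_auc_one(self):
        t = toy_table(n=40, seed=7)
        for clf in ("LR", "SVM", "LDA"):
            cfg = ml.MLConfig(classifier=clf, selector="UST", cv="loo",
                              top_k=3, seed=0)
            res = ml.evaluate(t, cfg)
            assert res.auc == pytest.approx(1.0), clf

    def test_auc_matches_concordant_pair_oracle(self):
        y = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0])
        s = np.array([.1, .4, .35, .8, .2, .7, .55, .45, .9, .3])
        conc = half = tot = 0
        for i in range(10):
            for j in range(10):
                if y[i] == 1 and y[j] == 0:
                    tot += 1
                    conc += s[i] > s[j]
                    half += s[i] == s[j]
        assert roc_auc_score(y, s) == pytest.approx((conc + 0.5 * half) / tot)

    def test_five_fold_reports_spread(self):
        t = toy_table(n=60, seed=8)
        cfg = ml.MLConfig(classifier="LR", selector="L1", cv="5fold",
                          n_repeats=3, top_k=3, seed=1)
        res = ml.evaluate(t, cfg)
        assert res.per_fold_auc.shape == (15,)
        assert res.auc_sd is not None and res.auc_sd >= 0
        assert 0.9 < res.auc <= 1.0

    def test_deterministic_for_fixed_seed(self):
        t = ch.generate_feature_table(ch.CohortSpec(n=57, seed=12))
        p = ml.preprocess(t)
        cfg = ml.MLConfig(classifier="RF", selector="UST", cv="5fold",
                          n_repeats=2, seed=3)
        a = ml.evaluate(p, cfg)
        b = ml.evaluate(p, cfg)
        np.testing.assert_array_equal(a.per_fold_auc, b.per_fold_auc)
        assert a.selection_frequency == b.selection_frequency

    def test_confusion_matrix_sums_to_n(self):
        t = toy_table(n=50, seed=9)
        res = ml.evaluate(t, ml.MLConfig(classifier="LR", selector="UST",
                                         cv="loo", top_k=3))
        assert res.confusion.sum() == 50
        assert 0 <= res.auc <= 1
        for f in res.selection_frequency.values():
            assert 0 <= f <= 1

    def test_mda_selector_runs_with_rf(self):
        t = toy_table(n=45, n_noise=5, seed=10)
        cfg = ml.MLConfig(classifier="RF", selector="MDA", cv="5fold",
                          n_repeats=1, top_k=3, seed=0)
        res = ml.evaluate(t, cfg)
        assert res.auc > 0.8

    @given(shift=st.floats(-3, 3, allow_nan=False),
           scale=st.floats(0.1, 5, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_score_transform(self, shift, scale):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 0])
        s = np.linspace(0.05, 0.95, 12)[::-1].copy()
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, scale * s + shift))


class TestLeakageGuard:
    def test_no_test_row_reaches_any_fit(self):
        """Instrumented scaler/selector/classifier record every row they are
        fitted on; none may coincide with the held-out rows of its fold."""
        t = toy_table(n=30, n_noise=4, seed=11)
        y = ml.label_response(t.outcomes, "EF10").values
        X = t.features().reset_index(drop=True)

        fit_rows = []          # one entry per fold: array of fitted rows

        class RecordingScaler(StandardScaler):
            def fit(self, Xf, y=None):
                fit_rows.append(np.asarray(Xf))
                return super().fit(Xf, y)

        sel_indices = []

        def recording_selector(X_tr, y_tr):
            sel_indices.append(set(X_tr.index))
            return ml.select_features(X_tr, y_tr, t.meta, "UST", k=3, seed=0)

        cfg = ml.MLConfig(classifier="LR", selector="UST", cv="loo", top_k=3)
        ml.evaluate(t, cfg, make_scaler=RecordingScaler,
                    make_selector=recording_selector)

        assert len(fit_rows) == len(sel_indices) == len(y)
        # selector never saw its fold's held-out row
        for fold, idx in enumerate(sel_indices):
            assert fold not in idx
            assert len(idx) == len(y) - 1
        # scaler (and hence the classifier fitted after it) never saw the
        # held-out row: continuous draws are unique with probability one, so
        # a matching signal-feature value would prove leakage
        sig = X["signal_feat"].values
        for fold, rows in enumerate(fit_rows):
            assert rows.shape[0] == len(y) - 1
            assert not np.any(np.isclose(rows[:, 0], sig[fold]))


class TestPCAAndClustering:
    def test_full_rank_pca_matches_plain_logistic(self):
        t = toy_table(n=30, n_noise=4, seed=13)
        df = ml.pca_lr(t, n_components_range=[5], criterion="EF10")
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import LeaveOneOut
        y = ml.label_response(t.outcomes, "EF10").values
        X = t.features().values
        scores = np.empty(len(y))
        for tr, te in LeaveOneOut().split(X):
            sc = StandardScaler().fit(X[tr])
            lr = LogisticRegression(max_iter=5000, tol=1e-10, random_state=0)
            lr.fit(sc.transform(X[tr]), y[tr])
            scores[te] = lr.predict_proba(sc.transform(X[te]))[:, 1]
        direct = roc_auc_score(y, scores)
        assert df["auc"].iloc[0] == pytest.approx(direct, abs=1e-6)

    def test_explained_variance_monotone(self):
        t = toy_table(n=40, n_noise=6, seed=14)
        df = ml.pca_lr(t, n_components_range=[2, 3, 4, 5])
        ev = df["explained_variance"].values
        assert np.all(np.diff(ev) >= -1e-12)

    def test_component_scores_orthogonal(self):
        t = toy_table(n=50, n_noise=6, seed=15)
        from sklearn.decomposition import PCA
        Z = StandardScaler().fit_transform(t.features().values)
        pc = PCA(n_components=3).fit_transform(Z)
        gram = pc.T @ pc
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_kmeans_recovers_separated_blobs(self):
        rng = np.random.default_rng(16)
        n = 40
        blob = np.repeat([0, 1], n // 2)
        data = pd.DataFrame({
            "f1": blob * 10.0 + rng.normal(scale=0.3, size=n),
            "f2": -blob * 8.0 + rng.normal(scale=0.3, size=n),
            "f3": rng.normal(size=n),
        })
        meta = pd.DataFrame({"kind": "continuous", "provenance": "clinical",
                             "preop_safe": True},
                            index=pd.Index(data.columns, name="feature"))
        outcomes = pd.DataFrame({"dEF_CRT": np.where(blob, 15.0, 2.0),
                                 "dESV_CRT": np.zeros(n)})
        t = ml.CohortTable(data=data, meta=meta, outcomes=outcomes)
        labels, summary, _ = ml.kmeans_clusters(t, seed=0)
        agreement = max(np.mean(labels == blob), np.mean(labels != blob))
        assert agreement == 1.0
        assert summary["n"].sum() == n

    def test_kmeans_within_cluster_ss_beats_random_assignment(self):
        """Exhaustive oracle at n=8: k-means inertia is minimal over all
        2-colorings of the points."""
        from itertools import product
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(8, 2))
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts)

        def wss(assign):
            total = 0.0
            for c in (0, 1):
                sel = pts[np.array(assign) == c]
                if len(sel):
                    total += ((sel - sel.mean(axis=0)) ** 2).sum()
            return total

        best = min(wss(a) for a in product([0, 1], repeat=8)
                   if 0 < sum(a) < 8)
        assert km.inertia_ == pytest.approx(best, rel=1e-9)

    def test_duplicate_rows_identical_assignment(self):
        t = toy_table(n=20, n_noise=3, seed=18)
        t.data.iloc[5] = t.data.iloc[3]
        labels, _, _ = ml.kmeans_clusters(t, seed=1)
        assert labels[5] == labels[3]
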