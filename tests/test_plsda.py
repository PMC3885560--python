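"""NIPALS PLS-DA: analytic identities, CV, selection, permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from ogttmet.plsda import (auroc, combined_model, fit_plsda, loo_q2,
                           ogtt_time_model, performance_distributions,
                           select_features)
from ogttmet.synthetic import CohortConfig, generate_cohort


def _two_class(rng, n0=15, n1=12, p=50, n_info=10, effect=2.0):
    X = rng.normal(size=(n0 + n1, p))
    y = np.r_[np.zeros(n0), np.ones(n1)]
    info = rng.choice(p, n_info, replace=False)
    X[np.ix_(y == 1, info)] += effect
    return X, y, info


class TestNipals:
    def test_single_feature_rank_one_exact(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        X = (2.0 * y + 1.0).reshape(-1, 1)
        model = fit_plsda(X, y, n_components=1, compute_q2=False)
        yhat = model.predict(X)
        np.testing.assert_allclose(yhat, y, atol=1e-10)

    def test_univariate_pls_equals_ols(self, rng):
        """One predictor, one component: PLS prediction is the OLS line."""
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(0, 0.3, 20)
        model = fit_plsda(x.reshape(-1, 1), y, n_components=1, orient="time",
                          compute_q2=False)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(model.predict(x.reshape(-1, 1)),
                                   slope * x + intercept, atol=1e-10)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        model = fit_plsda(X, y, n_components=5, orient="time", compute_q2=False)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_weight_vectors_unit_norm(self, rng):
        X, y, _ = _two_class(rng)
        model = fit_plsda(X, y, n_components=3, compute_q2=False)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10)

    def test_coefficient_reconstruction_matches_scores(self, rng):
        """B = W (P'W)^-1 q reproduces score-space predictions."""
        X, y, _ = _two_class(rng)
        model = fit_plsda(X, y, n_components=3, compute_q2=False)
        from ogttmet.plsda import _scale_apply
        Xs = _scale_apply(X, model.centers, model.scales)
        via_scores = model.T @ model.q + model.y_mean
        via_coef = Xs @ model.coef + model.y_mean
        np.testing.assert_allclose(via_coef, via_scores, atol=1e-10)

    def test_matches_sklearn_plsregression(self, rng):
        """Independent oracle: sklearn's NIPALS on the same scaled data."""
        from sklearn.cross_decomposition import PLSRegression

        X, y, _ = _two_class(rng, p=30)
        model = fit_plsda(X, y, n_components=3, compute_q2=False)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(model.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_class_orientation(self, rng):
        X, y, _ = _two_class(rng)
        model = fit_plsda(X, y, compute_q2=True)
        assert model.T[y == 1, 0].mean() > model.T[y == 0, 0].mean()

    def test_noise_data_not_predictive(self):
        """Pure-noise designs: LOO Q2 of the one-component model stays at or
        below zero in the vast majority of seeds."""
        bad = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            X = rng.normal(size=(27, 50))
            y = np.r_[np.zeros(15), np.ones(12)]
            rng.shuffle(y)
            q2, _, _, _ = loo_q2(X, y, max_components=3)
            bad += q2[0] > 0
        assert bad <= 4


class TestLooQ2:
    def test_separable_data_high_q2(self, rng):
        X, y, _ = _two_class(rng, effect=3.0, n_info=20)
        q2, best, fold_w, skipped = loo_q2(X, y, max_components=3)
        assert q2[0] > 0.9
        assert skipped == 0
        assert fold_w.shape == (27, 50)

    def test_q2_bounded_above_by_one(self, rng):
        X, y, _ = _two_class(rng)
        q2, *_ = loo_q2(X, y, max_components=4)
        assert (q2 <= 1.0).all()

    def test_permuted_labels_nonpositive_q2(self):
        bad = 0
        for seed in range(20):
            rng = np.random.default_rng(1700 + seed)
            X, y, _ = _two_class(rng, effect=2.0)
            q2, *_ = loo_q2(X, rng.permutation(y), max_components=2)
            bad += q2[0] > 0
        assert bad <= 4


class TestSelectFeatures:
    def test_signal_feature_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(50 + seed)
            X = rng.normal(size=(27, 50))
            y = np.r_[np.zeros(15), np.ones(12)]
            X[y == 1, 0] += 3.0  # single informative feature
            model = fit_plsda(X, y, max_components=2)
            sel = select_features(model)
            chosen = set(sel.loc[sel["selected"], "feature_id"])
            hits += 0 in chosen
        assert hits >= 19

    def test_null_selection_fraction_controlled(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(150 + seed)
            X = rng.normal(size=(27, 80))
            y = np.r_[np.zeros(15), np.ones(12)]
            model = fit_plsda(X, y, max_components=2)
            sel = select_features(model)
            fracs.append(sel["selected"].mean())
        assert np.mean(fracs) <= 0.10

    def test_constant_fold_weights_not_selected(self, rng):
        X, y, _ = _two_class(rng)
        model = fit_plsda(X, y, max_components=2)
        model.fold_weights = np.tile(model.W[:, 0], (27, 1))  # degenerate jackknife
        sel = select_features(model)
        assert not sel["selected"].any()

    def test_sign_groups_partition_features(self, rng):
        X, y, _ = _two_class(rng)
        model = fit_plsda(X, y, max_components=2)
        sel = select_features(model)
        w = model.weights_lv1
        nonzero_w = int((w != 0).sum())
        assert len(sel) == nonzero_w
        for _, row in sel.iterrows():
            expect = "positive" if w[row["feature_id"]] > 0 else "negative"
            assert row["sign_group"] == expect


class TestCombinedModel:
    def _inputs(self, rng):
        n = 24
        y = np.r_[np.zeros(12), np.ones(12)]
        fast = pd.DataFrame(rng.normal(size=(n, 20)),
                            columns=[f"m{i}" for i in range(20)])
        auc = pd.DataFrame(rng.normal(size=(n, 20)),
                           columns=[f"m{i}" for i in range(20)])
        fast.loc[y == 1, ["m0", "m1", "m2"]] += 3.0
        auc.loc[y == 1, ["m3", "m4", "m5"]] += 3.0
        clin = pd.DataFrame({"matsuda": rng.normal(size=n) + 2 * y,
                             "quicki": rng.normal(size=n)})
        return fast, auc, clin, y

    def test_disjoint_strong_selections_survive(self, rng):
        fast, auc, clin, y = self._inputs(rng)
        mf = fit_plsda(fast, y, max_components=2)
        ma = fit_plsda(auc, y, max_components=2)
        sf, sa = select_features(mf), select_features(ma)
        assert {"m0", "m1", "m2"} <= set(sf.loc[sf["selected"], "feature_id"])
        model, table = combined_model(fast, sf, auc, sa, clin, y)
        strong = table[table["feature_id"].isin(
            ["fast:m0", "fast:m1", "fast:m2", "auc:m3", "auc:m4", "auc:m5"])]
        assert strong["in_final"].all()

    def test_both_category_from_set_logic(self, rng):
        fast, auc, clin, y = self._inputs(rng)
        auc.loc[y == 1, "m0"] += 3.0  # m0 now informative in both blocks
        mf = fit_plsda(fast, y, max_components=2)
        ma = fit_plsda(auc, y, max_components=2)
        sf, sa = select_features(mf), select_features(ma)
        if not (("m0" in set(sf.loc[sf["selected"], "feature_id"]))
                and ("m0" in set(sa.loc[sa["selected"], "feature_id"]))):
            pytest.skip("selection did not pick m0 in both blocks for this draw")
        _, table = combined_model(fast, sf, auc, sa, clin, y)
        cats = table.set_index("feature_id")["category"]
        assert cats["fast:m0"] == "both" and cats["auc:m0"] == "both"

    def test_added_back_features_flagged(self, rng):
        fast, auc, clin, y = self._inputs(rng)
        mf = fit_plsda(fast, y, max_components=2)
        ma = fit_plsda(auc, y, max_components=2)
        sf, sa = select_features(mf), select_features(ma)
        _, table = combined_model(fast, sf, auc, sa, clin, y)
        dropped = table[table["added_back"]]
        # every base-selected feature is in the final set, by re-selection or add-back
        assert table.loc[table["category"] != "clinical", "in_final"].all()
        assert (~dropped["reselected"]).all()


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_enumerated_pairs(self):
        # pairs: (.6,.4)+ (.6,.7)- (.3,.4)- (.3,.7)- -> 1/4
        assert auroc([0.6, 0.3, 0.4, 0.7], [1, 1, 0, 0]) == 0.25

    def test_all_tied_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_mannwhitney(self, rng):
        from scipy.stats import mannwhitneyu
        s = rng.normal(size=30)
        lab = (rng.random(30) < 0.4).astype(int)
        u = mannwhitneyu(s[lab == 1], s[lab == 0]).statistic
        assert auroc(s, lab) == pytest.approx(u / ((lab == 1).sum() * (lab == 0).sum()))


class TestPerformanceDistributions:
    def test_bookkeeping_and_null_center(self, rng):
        X, y, _ = _two_class(rng, p=40, effect=2.5, n_info=12)
        rep = performance_distributions(X, y, n_splits=100, seed=5)
        for k in ("Q2", "RMSEP", "AUROC"):
            assert len(rep.observed[k]) == 100
            assert len(rep.null[k]) == 100
            assert 0 < rep.p[k] <= 1
        assert np.median(rep.observed["AUROC"]) >= 0.95
        assert abs(rep.null["AUROC"].mean() - 0.5) < 0.05

    def test_permuted_observed_is_null_like(self):
        """Feeding permuted labels as 'observed' gives non-significant p."""
        high = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X, y, _ = _two_class(rng, p=30, effect=2.0)
            rep = performance_distributions(X, rng.permutation(y), n_splits=30,
                                            seed=seed)
            high += rep.p["AUROC"] > 0.05
        assert high >= 9


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortConfig(n_metabolites=60, n_planted=0, missing_frac=0.0, seed=42)
    return generate_cohort(cfg)


class TestOgttTimeModel:
    def test_archetype_loading_signs(self, cohort):
        model, scores, loadings = ogtt_time_model(cohort.panel)
        info = cohort.metabolite_info.set_index("metabolite_id")
        carb = loadings[info["archetype"] == "carb_raised"]
        lipid = loadings[info["archetype"] == "lipid_suppressed"]
        late = loadings[info["archetype"] == "late_rise_xeno"]
        # with the positive score-time orientation, rising metabolites load
        # positive and suppressed metabolites negative
        assert late.mean() > 0 > lipid.mean()
        assert (np.corrcoef(scores["lv1"], scores["time_min"])[0, 1]) > 0
        _ = carb

    def test_shuffled_time_not_predictive(self, cohort):
        rng = np.random.default_rng(0)
        bad = 0
        for _ in range(10):
            panel = cohort.panel.copy()
            shuffled = panel[["subject_id", "phase", "time_min"]].drop_duplicates()
            perm = rng.permutation(shuffled["time_min"].to_numpy())
            shuffled = shuffled.assign(new_time=perm)
            panel = panel.merge(shuffled, on=["subject_id", "phase", "time_min"])
            panel["time_min"] = panel["new_time"]
            panel = panel.drop(columns="new_time")
            panel = panel.drop_duplicates(["subject_id", "phase", "time_min",
                                           "metabolite_id"])
            model, _, _ = ogtt_time_model(panel)
            bad += np.max(model.q2_path) > 0
        assert bad <= 1

    def test_late_timepoints_cluster(self, cohort):
        """90 and 120 min centroids sit closer together than 0 and 90 min."""
        _, scores, _ = ogtt_time_model(cohort.panel)
        cent = scores.groupby("time_min")[["lv1", "lv2"]].mean()
        d_90_120 = np.linalg.norm(cent.loc[90] - cent.loc[120])
        d_0_90 = np.linalg.norm(cent.loc[0] - cent.loc[90])
        assert d_90_120 < d_0_90
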