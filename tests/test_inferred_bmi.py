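"""Sparse-ensemble fitting, hold-out assembly and model interrogation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from omicsbmi import inferred_bmi as ib
from omicsbmi import synthetic_cohort as sc
from omicsbmi.preprocess import zscore
from omicsbmi.stats_core import out_of_sample_r2, welch_t_test


class TestSplitPlan:
    def test_folds_partition_participants(self, study):
        plan = study.plan
        sizes = plan.fold_assignment.value_counts()
        assert len(sizes) == 10
        assert sizes.max() - sizes.min() <= 1
        union = set()
        for f in range(10):
            ho = set(plan.holdout_index(f))
            assert not (ho & union)
            union |= ho
        assert union == set(study.meta.index)

    def test_too_few_participants_rejected(self, study):
        with pytest.raises(ValueError):
            ib.make_split_plan(study.meta.iloc[:15], k=10)

    def test_random_folds_are_balanced_across_seeds(self, study):
        ok = 0
        for seed in range(100):
            plan = ib.make_split_plan(study.meta, k=10, seed=seed)
            if (plan.balance_report["p_adj"] > 0.05).all():
                ok += 1
        assert ok >= 95

    def test_stratified_mode_balances_the_stratum(self, study):
        plan = ib.make_split_plan(study.meta, k=10, seed=0, stratify_by="sex")
        counts = pd.crosstab(study.meta["sex"], plan.fold_assignment)
        assert (counts.max(axis=1) - counts.min(axis=1) <= 1).all()


class TestLassoEnsemble:
    def test_holdout_r2_near_generative_oracle(self, study):
        pred = study.predictions["metabolomics"]
        oracle = sc.generative_r2(study.truth, study.config, ["metabolomics"])
        assert pred.pooled_r2 == pytest.approx(oracle, abs=0.1)
        assert pred.pooled_r2 >= 0.5

    def test_exactly_one_prediction_per_participant(self, study):
        frame = study.predictions["metabolomics"].frame
        assert frame.index.equals(study.meta.index)
        assert frame["predicted"].notna().all()
        np.testing.assert_allclose(
            frame["delta"],
            (frame["predicted"] - frame["measured"]) / frame["measured"] * 100)

    def test_shuffled_measure_has_no_signal(self, study):
        rng = np.random.default_rng(0)
        r2s = []
        X = study.prepared["chemistries"]
        for _ in range(5):
            shuffled = pd.Series(rng.permutation(study.meta["bmi"].to_numpy()),
                                 index=study.meta.index)
            _, pred = ib.fit_cv_lasso_ensemble(X, shuffled, study.plan)
            r2s.append(pred.pooled_r2)
        assert max(r2s) <= 0.05

    def test_noiseless_single_signal_always_retained(self):
        cfg = sc.GeneratorConfig(
            n_participants=120, seed=4, noise_sd=0.0,
            panel_sizes={"metabolomics": 20, "proteomics": 5, "chemistries": 5},
            n_signal_analytes={"metabolomics": 1, "proteomics": 1,
                               "chemistries": 1},
            n_interaction_pairs=2)
        omics, meta, truth = sc.generate_baseline_cohort(cfg)
        plan = ib.make_split_plan(meta, k=10, seed=4)
        X = omics["metabolomics"].values
        keep = [c for c in X.columns if X[c].std() > 0]
        Xz, _ = zscore(X[keep])
        ens, _ = ib.fit_cv_lasso_ensemble(Xz, meta["bmi"], plan)
        (signal,) = truth.signal_support["metabolomics"]
        intersection, _ = ib.robust_retained_set(ens)
        assert signal in intersection

    def test_fold_isolation(self, study):
        """Changing a hold-out fold's measure values does not change that
        fold's fitted coefficients."""
        X = study.prepared["chemistries"]
        measure = study.meta["bmi"].copy()
        ens_a, _ = ib.fit_cv_lasso_ensemble(X, measure, study.plan)
        corrupted = measure.copy()
        ho = study.plan.holdout_index(0)
        corrupted.loc[ho] = measure.loc[ho].mean()  # valid but wrong values
        ens_b, _ = ib.fit_cv_lasso_ensemble(X, corrupted, study.plan)
        np.testing.assert_allclose(ens_a.coefs.iloc[0], ens_b.coefs.iloc[0])

    def test_serialization_round_trip(self, study):
        ens = study.ensembles["metabolomics"]
        back = ib.SparseEnsemble.from_json(ens.to_json())
        pd.testing.assert_frame_equal(back.coefs, ens.coefs)
        X = study.prepared["metabolomics"]
        np.testing.assert_allclose(back.fold_predict_log(3, X),
                                   ens.fold_predict_log(3, X))


class TestStandardMeasures:
    def test_baseline_comparator_underperforms_omics(self, study):
        pred = ib.fit_standard_measures_model(study.meta, study.plan)
        assert 0.0 < pred.pooled_r2 < study.predictions["metabolomics"].pooled_r2
        # contract: per-fold R2 comparable across models via Welch's t-test
        res = welch_t_test(study.predictions["metabolomics"].fold_r2,
                           pred.fold_r2)
        assert res.p_value < 0.05

    def test_random_regressors_have_no_signal(self, study, rng):
        meta = study.meta.copy()
        for col in ("triglycerides", "hdl", "ldl", "glucose", "insulin"):
            meta[col] = rng.uniform(1, 10, len(meta))
        meta["age"] = rng.uniform(20, 70, len(meta))
        pred = ib.fit_standard_measures_model(meta, study.plan)
        assert pred.pooled_r2 <= 0.05

    def test_missing_regressor_rejected(self, study):
        with pytest.raises(ValueError, match="insulin"):
            ib.fit_standard_measures_model(
                study.meta.drop(columns=["insulin"]), study.plan)


class TestExternalPrediction:
    def test_identical_fold_models_collapse_to_single_model(self, study):
        ens = study.ensembles["metabolomics"]
        clone = dataclasses.replace(
            ens,
            coefs=pd.DataFrame([ens.coefs.iloc[0]] * ens.plan.k).reset_index(drop=True),
            intercepts=pd.Series([ens.intercepts.iloc[0]] * ens.plan.k))
        X = study.prepared["metabolomics"]
        single = np.exp(ens.fold_predict_log(0, X))
        np.testing.assert_allclose(ib.predict_external(clone, X), single)

    def test_transfer_r2_positive_but_below_within_cohort(self, study):
        cfg = study.config
        ext_omics, ext_meta, _ = sc.generate_external_cohort(cfg, 0.7)
        shared = list(ext_omics["metabolomics"].values.columns)
        ens = ib.refit_restricted_panel(
            study.prepared["metabolomics"], study.meta["bmi"], study.plan,
            shared)
        within_r2 = out_of_sample_r2(
            np.log(study.meta["bmi"]),
            np.log(ib.predict_external(ens, study.prepared["metabolomics"][shared])))
        Xz_ext, _ = zscore(ext_omics["metabolomics"].values)
        pred = ib.predict_external(ens, Xz_ext)
        transfer_r2 = out_of_sample_r2(np.log(ext_meta["bmi"]), np.log(pred))
        assert 0.0 < transfer_r2 < within_r2

    def test_panel_mismatch_rejected(self, study):
        ens = study.ensembles["metabolomics"]
        X = study.prepared["metabolomics"].copy()
        X.columns = [f"renamed_{c}" for c in X.columns]
        with pytest.raises(ValueError, match="panel"):
            ib.predict_external(ens, X)


class TestRestrictedRefit:
    def test_full_restriction_reproduces_fit(self, study):
        ens = ib.refit_restricted_panel(
            study.prepared["metabolomics"], study.meta["bmi"], study.plan,
            list(study.prepared["metabolomics"].columns))
        pd.testing.assert_frame_equal(ens.coefs,
                                      study.ensembles["metabolomics"].coefs)

    def test_excluding_all_signal_kills_performance(self, study):
        signal = set(study.truth.signal_support["metabolomics"])
        planted = {a for pair in study.truth.planted_pairs for a in pair[:2]}
        nulls = [c for c in study.prepared["metabolomics"].columns
                 if c not in signal | planted]
        ens, pred = None, None
        ens = ib.refit_restricted_panel(
            study.prepared["metabolomics"], study.meta["bmi"], study.plan,
            nulls)
        _, union = ib.robust_retained_set(ens)
        assert len(union) <= len(nulls)
        preds = ib.predict_external(ens, study.prepared["metabolomics"][nulls])
        assert out_of_sample_r2(np.log(study.meta["bmi"]),
                                np.log(preds)) <= 0.05

    def test_empty_restriction_rejected(self, study):
        with pytest.raises(ValueError, match="empty"):
            ib.refit_restricted_panel(study.prepared["metabolomics"],
                                      study.meta["bmi"], study.plan, [])


class TestFollowupPrediction:
    def test_baseline_scoring_reproduces_holdout_predictions(self, study):
        pred = ib.predict_followup(study.ensembles["metabolomics"],
                                   study.prepared["metabolomics"], study.plan)
        np.testing.assert_allclose(
            pred, study.predictions["metabolomics"].frame["predicted"],
            rtol=1e-10)

    def test_identical_rows_in_different_folds_may_differ(self, study):
        ens = study.ensembles["metabolomics"]
        fa = study.plan.fold_assignment
        p0 = fa.index[fa == 0][0]
        p1 = fa.index[fa == 1][0]
        X = study.prepared["metabolomics"].loc[[p0, p1]].copy()
        X.iloc[1] = X.iloc[0]  # identical analyte rows
        pred = ib.predict_followup(ens, X, study.plan)
        assert pred.iloc[0] != pred.iloc[1]

    def test_unknown_participant_rejected(self, study):
        X = study.prepared["metabolomics"].iloc[:2].copy()
        X.index = ["ghost1", "ghost2"]
        with pytest.raises(ValueError, match="unknown"):
            ib.predict_followup(study.ensembles["metabolomics"], X, study.plan)

    def test_metbmi_declines_under_intervention(self, study):
        cfg = dataclasses.replace(study.config, visit_schedule=(0, 365))
        visits = sc.generate_longitudinal_visits(
            (study.omics, study.meta, study.truth), cfg)
        mean, sd = study.stats["metabolomics"]
        Xz = (visits.analytes["metabolomics"] - mean) / sd
        pred = ib.predict_followup(study.ensembles["metabolomics"], Xz,
                                   study.plan)
        by_day = pred.groupby(level="day").mean()
        assert by_day.loc[365] < by_day.loc[0]


class TestDeltaMeasure:
    @pytest.mark.parametrize("pred,meas,expected", [
        (27.5, 25.0, 10.0), (25.0, 25.0, 0.0), (20.0, 25.0, -20.0)])
    def test_reference_points(self, pred, meas, expected):
        assert ib.delta_measure(pred, meas) == pytest.approx(expected)

    def test_nonpositive_measured_rejected(self):
        with pytest.raises(ValueError):
            ib.delta_measure(25.0, 0.0)


class TestRetainedSets:
    def test_intersection_subset_of_union(self, study):
        for ens in study.ensembles.values():
            inter, union = ib.robust_retained_set(ens)
            assert set(inter) <= set(union)

    def test_shuffled_target_leaves_little_retained(self, study):
        rng = np.random.default_rng(1)
        shuffled = pd.Series(rng.permutation(study.meta["bmi"].to_numpy()),
                             index=study.meta.index)
        ens, _ = ib.fit_cv_lasso_ensemble(study.prepared["metabolomics"],
                                          shuffled, study.plan)
        inter, _ = ib.robust_retained_set(ens)
        assert len(inter) <= 2

    def test_dominant_signal_in_intersection_at_high_effect(self):
        # Strong signals with enough per-analyte noise that each carries
        # independent information (near-duplicate analytes would be
        # legitimately dropped by the penalty).
        cfg = sc.GeneratorConfig(
            n_participants=250, seed=8, effect_scale=1.5, noise_sd=0.8,
            panel_sizes={"metabolomics": 30, "proteomics": 5, "chemistries": 5},
            n_signal_analytes={"metabolomics": 5, "proteomics": 2,
                               "chemistries": 2}, n_interaction_pairs=2)
        omics, meta, truth = sc.generate_baseline_cohort(cfg)
        plan = ib.make_split_plan(meta, k=10, seed=8)
        Xz, _ = zscore(omics["metabolomics"].values)
        ens, _ = ib.fit_cv_lasso_ensemble(Xz, meta["bmi"], plan)
        inter, _ = ib.robust_retained_set(ens)
        assert set(truth.signal_support["metabolomics"]) <= set(inter)


class TestStrongestRemoval:
    def test_zero_iterations_touch_nothing(self, study):
        X = study.prepared["chemistries"]
        before = X.copy()
        trace = ib.iterative_strongest_removal(X, study.meta["bmi"],
                                               study.plan, n_iter=0)
        assert trace.empty
        pd.testing.assert_frame_equal(X, before)

    def test_removing_dominant_analyte_costs_its_unique_contribution(self, study):
        X = study.prepared["chemistries"]
        trace = ib.iterative_strongest_removal(X, study.meta["bmi"],
                                               study.plan, n_iter=3)
        assert trace["removed_analyte"].is_unique
        first = trace["removed_analyte"].iloc[0]
        support = study.truth.signal_support["chemistries"]
        rest = [a for a in support if a != first]
        oracle_full = sc.generative_r2(study.truth, study.config,
                                       ["chemistries"])
        oracle_without = sc.generative_r2(study.truth, study.config,
                                          ["chemistries"], analytes=rest)
        unique = oracle_full - oracle_without
        assert first in support
        drop = trace["pooled_r2"].iloc[0] - trace["pooled_r2"].iloc[1]
        assert drop >= unique - 0.1

    def test_decay_trace_is_mostly_decreasing(self, study):
        trace = ib.iterative_strongest_removal(
            study.prepared["chemistries"], study.meta["bmi"], study.plan,
            n_iter=4)
        assert trace["pooled_r2"].iloc[-1] < trace["pooled_r2"].iloc[0]


class TestUnivariateExplainedVariance:
    def test_reference_points(self, study, rng):
        meta = study.meta
        covs = meta[["sex", "age", "pc1", "pc2", "pc3", "pc4", "pc5"]]
        X = pd.DataFrame({
            "copy_of_log_bmi": np.log(meta["bmi"]),
            "independent": rng.normal(size=len(meta)),
        }, index=meta.index)
        out = ib.univariate_explained_variance(X, meta["bmi"], covs)
        import statsmodels.api as sm
        base = sm.OLS(np.log(meta["bmi"]),
                      sm.add_constant(ib._covariate_design(covs))).fit()
        assert out.loc["copy_of_log_bmi", "explained_variance"] == \
            pytest.approx(1.0 - base.rsquared, abs=1e-8)
        assert out.loc["independent", "explained_variance"] < 0.02

    def test_ranking_matches_planted_effects_on_clean_data(self):
        cfg = sc.GeneratorConfig(
            n_participants=300, seed=6, noise_sd=0.02,
            latent_deviation_sd=0.0,
            panel_sizes={"metabolomics": 10, "proteomics": 5, "chemistries": 5},
            n_signal_analytes={"metabolomics": 4, "proteomics": 2,
                               "chemistries": 2}, n_interaction_pairs=1)
        omics, meta, truth = sc.generate_baseline_cohort(cfg)
        covs = meta[["sex", "age", "pc1", "pc2", "pc3", "pc4", "pc5"]]
        support = truth.signal_support["metabolomics"]
        X = omics["metabolomics"].values[sorted(support)]
        out = ib.univariate_explained_variance(X, meta["bmi"], covs)
        planted = pd.Series({k: abs(v["bmi"]) for k, v in support.items()})
        got = out["explained_variance"].rank()
        assert (got.sort_index().idxmax() == planted.idxmax())

    def test_reference_rows_belong_to_family(self, study):
        covs = study.meta[["sex", "age", "pc1", "pc2", "pc3", "pc4", "pc5"]]
        X = study.prepared["chemistries"]
        out = ib.univariate_explained_variance(
            X, study.meta["bmi"], covs,
            inferred={"metbmi": study.predictions["metabolomics"].frame["predicted"]})
        assert out.loc["metbmi", "is_reference"]
        # an accurate inferred measure explains more than any single analyte
        assert out.loc["metbmi", "explained_variance"] > \
            out.drop("metbmi")["explained_variance"].max()


class TestAlternativeEstimators:
    def test_all_estimators_land_in_the_same_regime(self, study):
        X = study.prepared["chemistries"]
        results = {"lasso": study.predictions["metabolomics"].pooled_r2}
        _, lasso_pred = ib.fit_cv_lasso_ensemble(X, study.meta["bmi"],
                                                 study.plan)
        results["lasso"] = lasso_pred.pooled_r2
        for kind in ("elastic_net", "ridge"):
            _, pred = ib.fit_alternative_estimator(X, study.meta["bmi"],
                                                   study.plan, kind)
            results[kind] = pred.pooled_r2
        rf_ens, rf_pred = ib.fit_alternative_estimator(
            X, study.meta["bmi"], study.plan, "random_forest",
            rf_grid={"n_estimators": [100], "max_features": ["sqrt", 0.5]})
        results["random_forest"] = rf_pred.pooled_r2
        values = np.array(list(results.values()))
        assert values.max() - values.min() <= 0.15
        np.testing.assert_allclose(rf_ens.importances.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_ridge_retains_every_analyte(self, study):
        _, pred = None, None
        ens, pred = ib.fit_alternative_estimator(
            study.prepared["chemistries"], study.meta["bmi"], study.plan,
            "ridge")
        inter, union = ib.robust_retained_set(ens)
        assert inter == union == list(study.prepared["chemistries"].columns)

    def test_unknown_kind_rejected(self, study):
        with pytest.raises(ValueError, match="kind"):
            ib.fit_alternative_estimator(study.prepared["chemistries"],
                                         study.meta["bmi"], study.plan,
                                         "gradient_boosting")
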