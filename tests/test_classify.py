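"""Two-class vesicle discrimination, SHAP selection, embedding."""

import numpy as np
import pytest
import xgboost as xgb

from organellems import classify


@pytest.fixture(scope="module")
def separable():
    """Two classes with disjoint informative features, n = 60 + 60."""
    rng = np.random.default_rng(13)
    n, d = 60, 24
    Xa = rng.gamma(2.0, size=(n, d))
    Xb = rng.gamma(2.0, size=(n, d))
    Xa[:, :4] += 12.0  # class A markers
    Xb[:, 4:8] += 12.0  # class B markers
    X = np.vstack([Xa, Xb])
    y = np.array(["DCV"] * n + ["LV"] * n)
    return X, y


class TestTrainClassifier:
    def test_separable_classes_reach_high_accuracy(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        assert rep.mean_accuracy >= 0.95
        assert len(rep.fold_accuracies) == 3

    def test_shuffled_labels_fall_to_chance(self, separable):
        X, y = separable
        rng = np.random.default_rng(1)
        rep = classify.train_classifier(X, rng.permutation(y), seed=0)
        assert 0.35 <= rep.mean_accuracy <= 0.65

    def test_duplicated_feature_column_changes_nothing(self, separable):
        X, y = separable
        a = classify.train_classifier(X, y, seed=0)
        b = classify.train_classifier(np.hstack([X, X[:, :1]]), y, seed=0)
        assert a.mean_accuracy == pytest.approx(b.mean_accuracy, abs=0.02)

    def test_confusion_rows_sum_to_class_counts(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [60, 60])
        assert rep.confusion.sum() == len(y)

    def test_single_class_rejected(self, separable):
        X, _ = separable
        with pytest.raises(ValueError, match="2 classes"):
            classify.train_classifier(X, np.repeat("DCV", len(X)), seed=0)

    def test_no_leakage_label_feature_detector(self, rng):
        # a feature equal to the label must give perfect held-out accuracy;
        # a shuffled copy of it must not
        n = 90
        y = np.array(["a", "b"] * (n // 2))
        noise = rng.normal(size=(n, 5))
        leak = (y == "b").astype(float)[:, None]
        perfect = classify.train_classifier(np.hstack([noise, leak]), y, seed=0)
        assert perfect.mean_accuracy == 1.0
        shuffled = rng.permutation(leak)
        broken = classify.train_classifier(np.hstack([noise, shuffled]), y, seed=0)
        assert broken.mean_accuracy < 0.75


class TestShapSelect:
    def test_constant_feature_gets_zero_shap(self, separable):
        X, y = separable
        Xc = np.hstack([X, np.full((len(X), 1), 3.0)])
        rep = classify.train_classifier(Xc, y, seed=0)
        imp = classify.shap_select(rep, Xc, y)
        last = imp.iloc[-1]
        assert last["mean_abs_shap"] == 0.0
        assert not last["selected"]

    def test_markers_dominate_importance(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        top = imp.nlargest(3, "mean_abs_shap")["feature"]
        assert set(top) <= set(range(8))  # planted marker columns

    def test_normalization_max_is_one(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        assert imp["normalized_importance"].max() == 1.0
        assert imp["normalized_importance"].between(0, 1).all()

    def test_direction_reflects_class_means(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        assert (imp.loc[imp["feature"] < 4, "higher_in"] == "DCV").all()
        assert (imp.loc[(imp["feature"] >= 4) & (imp["feature"] < 8), "higher_in"] == "LV").all()

    def test_shap_additivity_reproduces_margin(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        model, test = rep.models[0], rep.fold_test_indices[0]
        contrib, base = classify.shap_values(model, X[test])
        margin = model.get_booster().predict(xgb.DMatrix(X[test]), output_margin=True)
        # float32 tree arithmetic bounds the reconstruction error
        assert np.abs(contrib.sum(axis=1) + base - margin).max() < 5e-5


class TestRetrainOnSelected:
    def test_identity_subset_reproduces_report(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        again = classify.retrain_on_selected(X, y, imp, subset=np.arange(X.shape[1]), seed=0)
        assert again.fold_accuracies == rep.fold_accuracies

    def test_marker_subset_keeps_accuracy(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        sub = classify.retrain_on_selected(X, y, imp, subset="selected", seed=0)
        assert sub.mean_accuracy >= rep.mean_accuracy - 0.02

    def test_uninformative_single_feature_near_chance(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        noise_col = 20  # outside the planted marker columns
        rep2 = classify.retrain_on_selected(X, y, imp, subset=np.array([noise_col]), seed=0)
        assert 0.3 <= rep2.mean_accuracy <= 0.7

    def test_empty_subset_rejected(self, separable):
        X, y = separable
        rep = classify.train_classifier(X, y, seed=0)
        imp = classify.shap_select(rep, X, y)
        with pytest.raises(ValueError, match="empty"):
            classify.retrain_on_selected(X, y, imp, subset=np.array([], dtype=int))


class TestEmbedTsne:
    def test_output_shape_and_determinism(self, separable):
        X, y = separable
        a = classify.embed_tsne(X, seed=3)
        b = classify.embed_tsne(X, seed=3)
        assert a.shape == (len(X), 2)
        np.testing.assert_array_equal(a, b)

    def test_separable_classes_have_positive_silhouette(self, separable):
        from sklearn.metrics import silhouette_score

        X, y = separable
        coords = classify.embed_tsne(X, seed=0)
        assert silhouette_score(coords, y) > 0

    def test_perplexity_auto_reduced_with_warning(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.warns(UserWarning, match="perplexity reduced"):
            coords = classify.embed_tsne(X, seed=0)
        assert coords.shape == (8, 2)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            classify.embed_tsne(rng.normal(size=(4, 3)), seed=0)


class TestOnFixtureSpectra:
    def test_lipid_window_classification_of_vesicle_types(self, peak_matrix, spectra_fix):
        _, specs = spectra_fix
        y = np.array([s.class_label for s in specs])
        rep = classify.train_classifier(peak_matrix, y, mz_window=(500.0, 1100.0), seed=0)
        assert rep.mean_accuracy >= 0.95
        restricted = peak_matrix.restrict(500.0, 1100.0)
        imp = classify.shap_select(rep, restricted, y)
        assert imp["selected"].any()
        # every selected feature is a genuinely class-informative m/z
        sel_mz = imp.loc[imp["selected"], "feature_mz"]
        cfg, _ = spectra_fix
        informative = [m for cls in ("DCV", "LV") for m, _ in cfg.peak_set_per_class[cls]]
        informative += [m for cl in cfg.cluster_peaks["DCV"].values() for m, _ in cl]
        for m in sel_mz:
            assert min(abs(m - t) / t for t in informative) * 1e6 < 10.0
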