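import numpy as np
import pandas as pd
import pytest

from snprecall.genotypes import GENOTYPES
from snprecall.models import (ModelSpec, fit_final, grid_search, group_folds,
                              load_model, predict_proba, save_model, train)


def separable_fixture(n_per_class=60, sigma=1e-3, seed=0, n_individuals=4):
    """Three tight clusters in (theta, r) space, trivially separable."""
    rng = np.random.default_rng(seed)
    centers = {"AA": 0.0, "AB": np.pi / 4, "BB": np.pi / 2}
    rows = []
    for g, c in centers.items():
        for i in range(n_per_class):
            rows.append({
                "theta": c + rng.normal(0, sigma),
                "r": 1.0 + rng.normal(0, sigma),
                "label": g,
                "individual_id": f"i{i % n_individuals}",
            })
    df = pd.DataFrame(rows).sample(frac=1.0, random_state=seed).reset_index(drop=True)
    return df[["theta", "r"]], df["label"], df["individual_id"]


@pytest.mark.parametrize("family,params", [
    ("rmlr", {"C": 10.0}),
    ("gbt", {"n_estimators": 20, "max_depth": 3}),
    ("nn", {"epochs": 200}),
])
def test_separable_limit_every_family_is_perfect(family, params):
    X, y, _ = separable_fixture()
    model = train(ModelSpec(family, params, seed=0), X, y)
    # held-out draws from the same clusters, inside the training support
    held_X, held_y, _ = separable_fixture(sigma=5e-4, seed=99)
    post = predict_proba(model, held_X)
    assert (post["call"].to_numpy() == held_y.to_numpy()).all()


@pytest.fixture(scope="module")
def fitted():
    X, y, _ = separable_fixture()
    return train(ModelSpec("gbt", {"n_estimators": 20}, seed=0), X, y), X


class TestPredictProba:
    def test_simplex_contract(self, fitted):
        model, X = fitted
        post = predict_proba(model, X)
        P = post[["p_aa", "p_ab", "p_bb"]].to_numpy()
        assert (P >= 0).all()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_cluster_centers_recovered(self, fitted):
        model, _ = fitted
        centers = pd.DataFrame({"theta": [0.0, np.pi / 4, np.pi / 2],
                                "r": [1.0, 1.0, 1.0]})
        assert predict_proba(model, centers)["call"].tolist() == list(GENOTYPES)

    def test_permutation_alignment(self, fitted):
        model, X = fitted
        perm = X.sample(frac=1.0, random_state=5)
        a = predict_proba(model, X).loc[perm.index, "call"]
        b = predict_proba(model, perm)["call"]
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_feature_mismatch_rejected(self, fitted):
        model, X = fitted
        with pytest.raises(ValueError, match="feature"):
            predict_proba(model, X.rename(columns={"theta": "t"}))


class TestTrainContracts:
    def test_fewer_than_three_classes_rejected(self):
        X, y, _ = separable_fixture()
        keep = y != "BB"
        with pytest.raises(ValueError, match="BB"):
            train(ModelSpec("gbt", {"n_estimators": 5}), X[keep], y[keep])

    def test_invalid_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ModelSpec("rmlr", {"n_estimators": 10})

    def test_deterministic_under_seed(self):
        X, y, _ = separable_fixture(sigma=0.3)
        for family, params in (("rmlr", {"C": 1.0}), ("gbt", {"n_estimators": 10})):
            a = train(ModelSpec(family, params, seed=7), X, y)
            b = train(ModelSpec(family, params, seed=7), X, y)
            pa = predict_proba(a, X)[["p_aa", "p_ab", "p_bb"]].to_numpy()
            pb = predict_proba(b, X)[["p_aa", "p_ab", "p_bb"]].to_numpy()
            assert np.array_equal(pa, pb)

    def test_unit_weights_match_unweighted(self):
        X, y, _ = separable_fixture(sigma=0.2)
        w = {g: 1.0 for g in GENOTYPES}
        a = train(ModelSpec("gbt", {"n_estimators": 10}, seed=3), X, y)
        b = train(ModelSpec("gbt", {"n_estimators": 10}, seed=3), X, y, class_weight=w)
        assert np.array_equal(
            predict_proba(a, X)[["p_aa", "p_ab", "p_bb"]].to_numpy(),
            predict_proba(b, X)[["p_aa", "p_ab", "p_bb"]].to_numpy())

    def test_reference_gbt_settings_memorize_training_stratum(self, sim_data):
        """1000 estimators at depth 100 with 0.8 subsampling fit a low-input
        stratum essentially perfectly."""
        from snprecall.features import FEATURE_COLUMNS, Normalizer, compute_features
        from snprecall.labeling import build_truth, make_examples
        from snprecall.qc import qc_filter
        records, _, manifest = sim_data
        kept, _ = qc_filter(records)
        feats = compute_features(kept)
        truth = build_truth(feats, manifest)
        stratum = feats.loc[feats["dna_input_ng"] == 1.0]
        ex = make_examples(stratum, truth).sample(2000, random_state=0)
        norm = Normalizer.fit(ex, FEATURE_COLUMNS)
        X = norm.transform(ex)
        m = train(ModelSpec("gbt", {"n_estimators": 1000, "max_depth": 100,
                                    "subsample": 0.8}, seed=0),
                  X, ex["truth_genotype"])
        post = predict_proba(m, X)
        acc = (post["call"].to_numpy() == ex["truth_genotype"].to_numpy()).mean()
        assert acc > 0.99

    def test_rmlr_elasticnet_produces_finite_coefficients(self):
        X, y, _ = separable_fixture(sigma=0.2)
        m = train(ModelSpec("rmlr", {"penalty": "elasticnet", "l1_ratio": 0.001,
                                     "C": 1.0}), X, y)
        assert np.isfinite(m.estimator.coef_).all()

    def test_rmlr_coefficients_shrink_with_regularization(self):
        X, y, _ = separable_fixture(sigma=0.3)
        norms = []
        for C in (10.0, 0.1, 0.001):  # decreasing C = stronger regularization
            m = train(ModelSpec("rmlr", {"C": C}), X, y)
            norms.append(np.abs(m.estimator.coef_).sum())
        assert norms[0] > norms[1] > norms[2]


class TestGridSearch:
    def test_group_integrity(self):
        X, y, groups = separable_fixture(sigma=0.3)
        for tr, va in group_folds(groups, n_folds=4):
            assert set(groups.iloc[tr]).isdisjoint(set(groups.iloc[va]))

    def test_leave_one_individual_out(self):
        X, y, groups = separable_fixture(n_individuals=7, sigma=0.3)
        folds = group_folds(groups, n_folds=7)
        assert len(folds) == 7
        for _, va in folds:
            assert len(set(groups.iloc[va])) == 1

    def test_too_many_folds_rejected(self):
        _, _, groups = separable_fixture(n_individuals=3)
        with pytest.raises(ValueError, match="exceeds"):
            group_folds(groups, n_folds=5)

    def test_single_point_grid_returned(self):
        X, y, groups = separable_fixture(sigma=0.3)
        best, scores = grid_search("gbt", {"n_estimators": [10]}, X, y, groups,
                                   n_folds=4, seed=0)
        assert best.params == {"n_estimators": 10}
        assert len(scores) == 4  # one row per fold

    def test_intact_point_beats_crippled_point(self):
        """A grid point with crushing regularization loses to a sane one."""
        X, y, groups = separable_fixture(sigma=0.2)
        best, _ = grid_search("rmlr", {"C": [1e-6, 1.0]}, X, y, groups,
                              n_folds=4, seed=0)
        assert best.params["C"] == 1.0


class TestFitFinalAndPersistence:
    def test_fit_final_applies_weights_on_all_data(self):
        X, y, groups = separable_fixture(sigma=0.3)
        best = ModelSpec("gbt", {"n_estimators": 10}, seed=0)
        w = {"AA": 0.5, "AB": 2.0, "BB": 0.5}
        m = fit_final("gbt", best, X, y, w)
        assert m.metadata["n_examples"] == len(y)

    def test_artifact_roundtrip(self, tmp_path):
        X, y, _ = separable_fixture(sigma=0.2)
        m = train(ModelSpec("gbt", {"n_estimators": 10}, seed=1), X, y)
        save_model(m, tmp_path / "artifact")
        back = load_model(tmp_path / "artifact")
        assert back.spec.family == "gbt"
        assert back.feature_names == ["theta", "r"]
        assert np.array_equal(
            predict_proba(m, X)[["p_aa", "p_ab", "p_bb"]].to_numpy(),
            predict_proba(back, X)[["p_aa", "p_ab", "p_bb"]].to_numpy())
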