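import numpy as np
import pytest

from canopy_yield import ELMRegressor, ModelSpec, fit_elm, fit_model, predict, \
    simulate_feature_table, split_train_validation
from canopy_yield.models import MODEL_NAMES
from canopy_yield.pipeline import select_and_fit

from conftest import make_table


class TestSplit:
    def test_default_ratio_gives_199_116(self, table315):
        tr, va = split_train_validation(table315, seed=0)
        assert (len(tr), len(va)) == (199, 116)

    def test_same_seed_same_split(self, table315):
        a1, b1 = split_train_validation(table315, seed=3)
        a2, b2 = split_train_validation(table315, seed=3)
        assert list(a1.data.index) == list(a2.data.index)
        assert list(b1.data.index) == list(b2.data.index)

    def test_partition_is_disjoint_and_exhaustive(self, table315):
        tr, va = split_train_validation(table315, seed=1)
        ids = set(tr.data.index) | set(va.data.index)
        assert ids == set(table315.data.index)
        assert not set(tr.data.index) & set(va.data.index)

    def test_bad_ratio_rejected(self, table315):
        with pytest.raises(ValueError):
            split_train_validation(table315, ratio=1.5)


class TestELM:
    def make(self, n=40, p=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        return make_table(X, y)

    def test_overparameterized_elm_interpolates(self):
        t = self.make()
        elm = fit_elm(t, n_hidden=80, ridge=0.0, seed=1)
        resid = elm.predict(t.X.to_numpy()) - t.y.to_numpy()
        assert np.sqrt((resid**2).mean()) < 1e-6

    def test_constant_target_predicts_constant(self):
        t = self.make()
        t.data["yield_t_ha"] = 4.2
        elm = fit_elm(t, n_hidden=20, ridge=1e-6, seed=2)
        rng = np.random.default_rng(3)
        pred = elm.predict(rng.normal(size=(10, 3)))
        np.testing.assert_allclose(pred, 4.2, atol=1e-8)

    def test_refit_is_bit_identical(self):
        t = self.make(seed=5)
        b1 = fit_elm(t, n_hidden=30, ridge=1e-3, seed=7).beta_
        b2 = fit_elm(t, n_hidden=30, ridge=1e-3, seed=7).beta_
        assert (b1 == b2).all()

    def test_ridge_shrinks_toward_smoother_fit(self):
        t = self.make(n=30)
        loose = fit_elm(t, n_hidden=60, ridge=0.0, seed=1)
        tight = fit_elm(t, n_hidden=60, ridge=10.0, seed=1)
        assert np.linalg.norm(tight.beta_) < np.linalg.norm(loose.beta_)


class TestGridSearchFits:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_trivially_learnable_target(self, name):
        """y = 3*x1 with vanishing noise: every model must nail it."""
        rng = np.random.default_rng(11)
        X = rng.uniform(-2, 2, size=(120, 3))
        y = 3 * X[:, 0] + rng.normal(0, 1e-4, 120)
        t = make_table(X, y)
        tr, va = split_train_validation(t, ratio=0.7, seed=0)
        rep = fit_model(ModelSpec(name, cv_folds=5, seed=0), tr, va)
        assert rep.val_metrics.r2 > 0.99, name

    def test_plsr_with_all_components_matches_ols(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(0, 0.1, 60)
        t = make_table(X, y)
        rep = fit_model(ModelSpec("PLSR", grid={"n_components": [4]}, seed=0), t)
        from sklearn.linear_model import LinearRegression
        from sklearn.preprocessing import StandardScaler

        Xs = StandardScaler().fit_transform(X)
        ols = LinearRegression().fit(Xs, y).predict(Xs)
        np.testing.assert_allclose(rep.train_pred.to_numpy(), ols, atol=1e-8)


class TestPredict:
    def test_train_rows_reproduce_stored_predictions(self, table315):
        t = table315.subset(["NGRDI", "CON_MEAN"])
        tr, va = split_train_validation(t, seed=0)
        rep = fit_model(ModelSpec("ELM", grid={"n_hidden": [30]}, seed=0), tr, va)
        np.testing.assert_allclose(predict(rep, tr), rep.train_pred.to_numpy())

    def test_row_permutation_permutes_predictions(self, table315):
        t = table315.subset(["NGRDI", "CON_MEAN"])
        tr, va = split_train_validation(t, seed=0)
        rep = fit_model(ModelSpec("KRR", grid={"alpha": [0.1], "gamma": [0.1]},
                                  seed=0), tr)
        perm = va.select_rows(va.data.index[::-1])
        np.testing.assert_allclose(predict(rep, perm), predict(rep, va)[::-1])

    def test_empty_table_gives_empty_vector(self, table315):
        t = table315.subset(["NGRDI"])
        tr, _ = split_train_validation(t, seed=0)
        rep = fit_model(ModelSpec("ELM", grid={"n_hidden": [10]}, seed=0), tr)
        empty = t.select_rows(t.data.index[:0])
        assert predict(rep, empty).shape == (0,)

    def test_column_mismatch_lists_names(self, table315):
        tr, _ = split_train_validation(table315.subset(["NGRDI", "ExG"]), seed=0)
        rep = fit_model(ModelSpec("ELM", grid={"n_hidden": [10]}, seed=0), tr)
        with pytest.raises(ValueError, match="ExG"):
            predict(rep, table315.subset(["NGRDI", "VARI"]))


def test_elm_beats_strictly_linear_models_on_saturating_vi_tables():
    """When the saturating VI response dominates the noise, the ELM's
    nonlinear inversion outperforms the strictly linear regressors in nearly
    every seed (kernel ridge, though grouped with the linear methods by
    convention, is itself a nonlinear learner and is compared at the
    family-ordering level instead)."""
    wins = {"PLSR": 0, "ElasticNet": 0}
    for seed in range(10):
        t = simulate_feature_table(315, noise=(0.05, 0.8), seed=seed)
        elm = select_and_fit(t, selector="RFE", model="ELM",
                             family="vi", seed=seed).val_metrics.r2
        for m in wins:
            lin = select_and_fit(t, selector="RFE", model=m,
                                 family="vi", seed=seed).val_metrics.r2
            wins[m] += elm >= lin
    assert all(w >= 8 for w in wins.values()), wins


def test_selection_cannot_see_validation_rows():
    """A canary feature that is informative only on the validation rows must
    not be picked: screening runs on the training split alone."""
    t = simulate_feature_table(315, seed=0)
    seed = 4
    tr, va = split_train_validation(t, seed=seed)
    canary = np.zeros(len(t))
    rng = np.random.default_rng(0)
    pos = {idx: i for i, idx in enumerate(t.data.index)}
    canary[[pos[i] for i in va.data.index]] = va.y.to_numpy()
    canary[[pos[i] for i in tr.data.index]] = rng.normal(0, 0.01, len(tr))
    data = t.data.copy()
    data["WI"] = canary  # replace a weak vi column with the canary
    t2 = type(t)(data, t.families)
    rep = select_and_fit(t2, selector="P", model="ELM", family="vi", seed=seed)
    assert "WI" not in rep.feature_names
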