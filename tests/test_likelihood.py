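"""Tests for the prey-means MLE and the MUFASA random-effects model."""
import numpy as np
import pytest
from scipy.stats import multivariate_normal

from fasdiet import (
    MLEDietModel, MufasaModel, clr, estimate_diet, mle_diet, mle_loglik,
    mufasa_diet, pseudo_preds, pseudo_preds_norm,
)


class TestMleLoglik:
    def test_matches_independent_gaussian_density(self, small_db, rng):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.4, 0.3, 0.2, 0.1, 0.0])
        x = rng.dirichlet(np.ones(10))
        s2 = 0.05
        ll = mle_loglik(diet, x, means, s2, "isotropic")
        mix = diet @ means.to_numpy()
        expected = multivariate_normal.logpdf(
            clr(x / x.sum()), mean=clr(mix / mix.sum()), cov=s2 * np.eye(10),
            allow_singular=True)
        # same density formula, computed through scipy on the clr coordinates
        assert ll == pytest.approx(float(expected), rel=1e-9)

    def test_exact_mixture_has_zero_residual_term(self, small_db):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
        mix = diet @ means.to_numpy()
        s2 = 0.1
        ll = mle_loglik(diet, mix / mix.sum(), means, s2, "isotropic")
        assert ll == pytest.approx(-0.5 * 10 * np.log(2 * np.pi * s2), rel=1e-9)

    def test_larger_residual_lowers_loglik(self, small_db):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
        mix = diet @ means.to_numpy()
        near = 0.9 * mix / mix.sum() + 0.1 * np.full(10, 0.1)
        far = 0.6 * mix / mix.sum() + 0.4 * np.full(10, 0.1)
        s2 = 0.05
        assert mle_loglik(diet, near / near.sum(), means, s2) > \
            mle_loglik(diet, far / far.sum(), means, s2)


class TestMleDiet:
    def test_isotropic_equals_ait_qfasa(self, small_db):
        """The stated equivalence: constant-variance MLE == AIT-distance fit."""
        db, _ = small_db
        means = db.species_means()
        preds = pseudo_preds(np.array([0.4, 0.3, 0.2, 0.1, 0.0]), db, 6,
                             preysize=1, seed=9)
        fit = mle_diet(preds.to_numpy(), means, None, "isotropic", seed=2)
        for j, x in enumerate(preds.to_numpy()):
            ait = estimate_diet(x, means, "AIT", seed=2)
            np.testing.assert_allclose(fit.diets[j], ait.biomass_proportions, atol=1e-3)

    def test_noiseless_mixture_variance_floored(self, small_db):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.5, 0.3, 0.2, 0.0, 0.0])
        mix = diet @ means.to_numpy()
        fit = mle_diet(mix / mix.sum(), means, None, "isotropic", seed=0)
        np.testing.assert_allclose(fit.diets[0], diet, atol=1e-4)
        assert fit.sigma2 >= 1e-12

    def test_per_fa_beats_isotropic_on_heteroscedastic_data(self, small_db, rng):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.4, 0.3, 0.3, 0.0, 0.0])
        mix = diet @ means.to_numpy()
        cmix = clr(mix / mix.sum())
        sds = np.linspace(0.02, 0.4, 10)
        X = []
        for _ in range(8):
            e = rng.normal(0, sds)
            e = e - e.mean()
            z = np.exp(cmix + e)
            X.append(z / z.sum())
        X = np.array(X)
        iso = mle_diet(X, means, None, "isotropic", seed=1)
        pfa = mle_diet(X, means, None, "per_fa", seed=1)
        assert pfa.loglik > iso.loglik
        assert pfa.n_params > iso.n_params

    def test_common_diet_shared_across_predators(self, small_db):
        db, _ = small_db
        means = db.species_means()
        preds = pseudo_preds(np.array([0.4, 0.3, 0.2, 0.1, 0.0]), db, 5,
                             preysize=2, seed=4)
        fit = mle_diet(preds.to_numpy(), means, None, "isotropic", common_diet=True, seed=0)
        assert np.ptp(fit.diets, axis=0).max() == 0.0

    def test_model_front_end(self, small_db):
        db, _ = small_db
        preds = pseudo_preds(np.array([0.4, 0.3, 0.2, 0.1, 0.0]), db, 3,
                             preysize=2, seed=4)
        res = MLEDietModel(preds, db).fit(seed=0)
        assert res.diets.shape == (3, 5)
        assert np.isfinite(res.loglik)
        assert "log-likelihood" in res.summary()


class TestMufasa:
    def test_collapses_to_mle_as_dispersion_vanishes(self, small_db):
        db, _ = small_db
        means = db.species_means()
        preds = pseudo_preds(np.array([0.4, 0.3, 0.2, 0.1, 0.0]), db, 5,
                             preysize=1, seed=9)
        mle = mle_diet(preds.to_numpy(), means, None, "isotropic", seed=2)
        muf = mufasa_diet(preds.to_numpy(), db, cov_scale=1e-6, seed=2, laplace=False)
        np.testing.assert_allclose(muf.diets, mle.diets, atol=5e-3)

    def test_single_species_database(self):
        import pandas as pd
        from fasdiet import PreyDatabase
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(6) * 30, size=5)
        df = pd.DataFrame(X, columns=[f"fa{i}" for i in range(6)])
        df.insert(0, "species", "only")
        db = PreyDatabase(df)
        fit = mufasa_diet(X[:2], db, seed=0)
        np.testing.assert_array_equal(fit.diets, np.ones((2, 1)))

    def test_generative_model_recovery(self, small_db):
        db, _ = small_db
        diet = np.array([0.35, 0.3, 0.2, 0.1, 0.05])
        X = pseudo_preds_norm(diet, db, 10, seed=5)
        fit = mufasa_diet(X.to_numpy(), db, seed=3)
        assert fit.converged
        assert np.abs(fit.diets - diet).mean() < 0.05

    def test_laplace_loglik_finite_and_model_front_end(self, small_db):
        db, _ = small_db
        X = pseudo_preds_norm(np.array([0.5, 0.5, 0, 0, 0]), db, 4, seed=6)
        res = MufasaModel(X, db).fit(seed=0)
        assert np.isfinite(res.loglik)
        assert res.re_modes.shape == (5, 10)
        assert "MUFASA" in res.summary()
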