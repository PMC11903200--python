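"""Tests for the synthetic prey generator and pseudo-predator simulation."""
import numpy as np
import pandas as pd
import pytest

from fasdiet import (
    SyntheticScenario, clr, clr_inv, estimate_diet, fat_rescale, prey_on_prey,
    pseudo_pred, pseudo_pred_norm, pseudo_preds, synth_prey_db,
)


class TestScenario:
    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            SyntheticScenario(seed=None)

    def test_same_seed_identical_database(self):
        a, _ = synth_prey_db(SyntheticScenario(n_species=4, n_individuals=5, n_fa=8, seed=9))
        b, _ = synth_prey_db(SyntheticScenario(n_species=4, n_individuals=5, n_fa=8, seed=9))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_default_shape_matches_study_conditions(self):
        db, truth = synth_prey_db(SyntheticScenario(seed=1))
        assert db.n_species == 11
        assert len(db.fa_names) == 39
        assert truth.mean_signatures.shape == (11, 39)

    def test_per_species_counts(self):
        counts = [3, 4, 5]
        db, _ = synth_prey_db(SyntheticScenario(n_species=3, n_individuals=counts,
                                                n_fa=6, seed=2))
        assert db.counts().tolist() == counts

    def test_infeasible_request_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(separation=-1.0, seed=1)


class TestPseudoPred:
    def test_seed_mandatory(self, small_db):
        db, _ = small_db
        with pytest.raises(ValueError, match="seed"):
            pseudo_pred(np.full(5, 0.2), db)

    def test_noiseless_loop_closure(self):
        """Identical individuals per species: the pseudo-predator is the exact
        mixture and the estimator recovers the diet exactly."""
        rng = np.random.default_rng(4)
        means = rng.dirichlet(np.ones(8) * 2, size=4)
        rows, labels = [], []
        for i, m in enumerate(means):
            rows += [m, m]
            labels += [f"s{i}", f"s{i}"]
        from fasdiet import PreyDatabase
        df = pd.DataFrame(rows, columns=[f"fa{k}" for k in range(8)])
        df.insert(0, "species", labels)
        db = PreyDatabase(df)
        diet = np.array([0.4, 0.3, 0.2, 0.1])
        p = pseudo_pred(diet, db, preysize=2, seed=6)
        est = estimate_diet(p.signature, db.species_means(), "KL", seed=0)
        np.testing.assert_allclose(est.proportions, diet, atol=1e-6)

    def test_preysize_one_uses_single_individuals(self, small_db):
        db, _ = small_db
        p = pseudo_pred(np.array([0.5, 0.5, 0, 0, 0]), db, preysize=1, seed=3)
        assert all(len(v) == 1 for v in p.provenance["indices"].values())

    def test_provenance_regenerates_signature(self, small_db):
        db, _ = small_db
        diet = np.array([0.6, 0.4, 0, 0, 0])
        p = pseudo_pred(diet, db, preysize=2, seed=11)
        X = db.individuals().to_numpy()
        lab = db.labels.to_numpy()
        sig = np.zeros(10)
        for sp, w in zip(db.species, diet):
            if w > 0:
                rowset = X[lab == sp][p.provenance["indices"][sp]]
                sig += w * rowset.mean(axis=0)
        np.testing.assert_allclose(p.signature.to_numpy(), sig / sig.sum(), atol=1e-12)

    def test_cc_and_fat_loop_closure(self, small_db, rng):
        """Generate with (cc, fat); estimate with the same cc and rescale by
        fat: recovery is unbiased for the exact-mixture construction."""
        db, _ = small_db
        means = db.species_means()
        cc = rng.uniform(0.6, 1.8, 10)
        fat = rng.uniform(0.1, 0.5, 5)
        diet = np.array([0.4, 0.3, 0.2, 0.1, 0.0])
        errs = []
        for s in range(30):
            p = pseudo_pred(diet, db, preysize=2, cc=cc, fat=fat, seed=500 + s)
            est = estimate_diet(p.signature, means, "KL", cc=cc, fat=fat,
                                n_starts=3, seed=s)
            errs.append(est.proportions - diet)
        bias = np.abs(np.mean(errs, axis=0))
        assert bias.max() < 0.02

    def test_cc_mismatch_biases_estimates(self, small_db, rng):
        db, _ = small_db
        means = db.species_means()
        cc = np.exp(rng.normal(0, 0.4, 10))
        diet = np.array([0.4, 0.3, 0.2, 0.1, 0.0])
        err_match, err_unit = [], []
        for s in range(15):
            p = pseudo_pred(diet, db, preysize=2, cc=cc, seed=900 + s)
            em = estimate_diet(p.signature, means, "KL", cc=cc, n_starts=3, seed=s)
            eu = estimate_diet(p.signature, means, "KL", n_starts=3, seed=s)
            err_match.append(np.abs(em.proportions - diet).mean())
            err_unit.append(np.abs(eu.proportions - diet).mean())
        assert np.mean(err_match) < np.mean(err_unit)

    def test_batch_deterministic(self, small_db):
        db, _ = small_db
        a = pseudo_preds(np.full(5, 0.2), db, 4, seed=8)
        b = pseudo_preds(np.full(5, 0.2), db, 4, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestPseudoPredNorm:
    def test_mean_matches_clr_mean(self, small_db):
        db, truth = small_db
        diet = np.zeros(5)
        diet[1] = 1.0
        X = np.vstack([pseudo_pred_norm(diet, db, seed=1000 + s).signature
                       for s in range(600)])
        mu, _, _ = db.clr_stats()
        sample_clr_mean = clr(X).mean(axis=0)
        np.testing.assert_allclose(sample_clr_mean, mu[1], atol=0.05)

    def test_clr_covariance_matches_pooled(self, small_db):
        db, _ = small_db
        diet = np.zeros(5)
        diet[0] = 1.0
        X = np.vstack([pseudo_pred_norm(diet, db, seed=3000 + s).signature
                       for s in range(600)])
        mu, covs, ns = db.clr_stats()
        pooled = sum((n - 1) * S for S, n in zip(covs, ns)) / sum(n - 1 for n in ns)
        emp = np.cov(clr(X).T)
        assert np.abs(emp - pooled).max() < 0.02

    def test_requires_replicated_species(self):
        from fasdiet import PreyDatabase
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.dirichlet(np.ones(5) * 5, size=3),
                          columns=[f"fa{k}" for k in range(5)])
        df.insert(0, "species", ["a", "a", "b"])
        db = PreyDatabase(df)
        with pytest.raises(Exception):
            pseudo_pred_norm(np.array([0.0, 1.0]), db, seed=1)


class TestFullPipelineClosure:
    @pytest.mark.parametrize("kind", ["KL", "AIT", "CS"])
    def test_exact_mean_mixture_recovery(self, separated_db, kind):
        db, _ = separated_db
        means = db.species_means()
        rng = np.random.default_rng(7)
        diet = rng.dirichlet(np.ones(11))
        mix = diet @ means.to_numpy()
        est = estimate_diet(mix / mix.sum(), means, kind, seed=0)
        np.testing.assert_allclose(est.biomass_proportions, diet, atol=1e-4)

    def test_separation_limit_sharpens_prey_on_prey(self):
        lo_db, _ = synth_prey_db(SyntheticScenario(n_species=4, n_individuals=6,
                                                   n_fa=10, separation=0.3,
                                                   within_sd=0.25, seed=13))
        hi_db, _ = synth_prey_db(SyntheticScenario(n_species=4, n_individuals=6,
                                                   n_fa=10, separation=3.0,
                                                   within_sd=0.02, seed=13))
        lo = np.diag(prey_on_prey(lo_db, seed=0).to_numpy()).mean()
        hi = np.diag(prey_on_prey(hi_db, seed=0).to_numpy()).mean()
        assert hi > lo
        assert hi > 0.97
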