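"""Tests for the distance-minimization diet estimator."""
import numpy as np
import pandas as pd
import pytest

from fasdiet import DietModel, estimate_diet, estimate_diets, prey_means
from fasdiet.distances import DistanceSpec, fa_terms

KINDS = ["KL", "AIT", "CS"]


def grid_min(x, M, spec, step=0.02):
    """Brute-force oracle: objective minimum over a simplex grid (3 species)."""
    n = int(round(1.0 / step))
    best = np.inf
    for i in range(n + 1):
        for j in range(n + 1 - i):
            a = np.array([i, j, n - i - j]) / n
            y = a @ M
            val = fa_terms(x, y / y.sum(), spec).sum()
            best = min(best, val)
    return best


class TestPreyMeans:
    def test_means_match_column_averages(self, small_db):
        db, _ = small_db
        means = prey_means(db)
        X = db.individuals()
        for sp in db.species:
            manual = X[db.labels.to_numpy() == sp].mean(axis=0)
            manual = manual / manual.sum()
            np.testing.assert_allclose(means.loc[sp].to_numpy(), manual.to_numpy(),
                                       atol=1e-12)

    def test_single_individual_species_mean_is_itself(self):
        df = pd.DataFrame({"species": ["a", "b"],
                           "fa1": [0.5, 0.2], "fa2": [0.3, 0.5], "fa3": [0.2, 0.3]})
        from fasdiet import PreyDatabase
        db = PreyDatabase(df)
        np.testing.assert_allclose(db.species_means().loc["a"].to_numpy(), [0.5, 0.3, 0.2])


@pytest.mark.parametrize("kind", KINDS)
class TestRecovery:
    def test_vertex_recovery(self, small_db, kind):
        db, _ = small_db
        means = db.species_means()
        est = estimate_diet(means.iloc[2], means, kind, seed=0)
        expected = np.zeros(db.n_species)
        expected[2] = 1.0
        np.testing.assert_allclose(est.proportions, expected, atol=1e-6)
        assert est.min_distance < 1e-10

    def test_noiseless_mixture_recovery(self, small_db, kind):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
        mix = diet @ means.to_numpy()
        est = estimate_diet(mix / mix.sum(), means, kind, seed=0)
        np.testing.assert_allclose(est.biomass_proportions, diet, atol=1e-4)

    def test_optimizer_beats_grid_oracle(self, small_db, kind, rng):
        db, _ = small_db
        means3 = db.species_means().iloc[:3]
        x = rng.dirichlet(np.ones(means3.shape[1]))
        spec = DistanceSpec(kind)
        est = estimate_diet(x, means3, spec, seed=1)
        assert est.min_distance <= grid_min(x, means3.to_numpy(), spec) + 1e-6


class TestDiagnostics:
    def test_contributions_sum_to_objective(self, small_db, rng):
        db, _ = small_db
        means = db.species_means()
        for kind in KINDS:
            est = estimate_diet(rng.dirichlet(np.ones(10)), means, kind, seed=2)
            assert est.fa_contributions.sum() == pytest.approx(est.min_distance, abs=1e-9)
            assert est.proportions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_modeled_signature_is_mixture(self, small_db):
        db, _ = small_db
        means = db.species_means()
        est = estimate_diet(means.iloc[0], means, "KL", seed=0)
        manual = est.biomass_proportions @ means.to_numpy()
        np.testing.assert_allclose(est.modeled_signature, manual / manual.sum(), atol=1e-8)

    def test_fat_rescale_applied_after_fit(self, small_db):
        db, _ = small_db
        means = db.species_means()
        diet = np.array([0.4, 0.6, 0.0, 0.0, 0.0])
        mix = diet @ means.to_numpy()
        fat = np.array([0.3, 0.1, 0.2, 0.2, 0.2])
        est = estimate_diet(mix / mix.sum(), means, "KL", fat=fat, seed=0)
        np.testing.assert_allclose(est.biomass_proportions, diet, atol=1e-4)
        expected = diet / fat
        np.testing.assert_allclose(est.proportions, expected / expected.sum(), atol=1e-3)


class TestCalibrationChain:
    def test_cc_invariance(self, small_db, rng):
        """Estimating with CC c on (mixture * c) equals unit-CC on the mixture."""
        db, _ = small_db
        means = db.species_means()
        cc = rng.uniform(0.5, 2.0, means.shape[1])
        diet = np.array([0.3, 0.3, 0.2, 0.2, 0.0])
        mix = diet @ means.to_numpy()
        mix = mix / mix.sum()
        raw = estimate_diet(mix, means, "KL", seed=0)
        cal = estimate_diet(mix * cc / (mix * cc).sum(), means, "KL", cc=cc, seed=0)
        np.testing.assert_allclose(raw.biomass_proportions, cal.biomass_proportions,
                                   atol=1e-5)


class TestBatch:
    def test_batch_equals_map_of_singles(self, small_db, rng):
        db, _ = small_db
        means = db.species_means()
        X = rng.dirichlet(np.ones(10), size=4)
        batch = estimate_diets(X, means, "AIT", seed=5)
        assert len(batch) == 4
        for j, x in enumerate(X):
            rng_j = np.random.default_rng(np.random.SeedSequence([5, j]))
            single = estimate_diet(x, means, "AIT", _rng=rng_j)
            np.testing.assert_allclose(batch[j].proportions, single.proportions, atol=1e-9)

    def test_non_uniqueness_warning(self):
        from fasdiet import SyntheticScenario, synth_prey_db
        db, _ = synth_prey_db(SyntheticScenario(n_species=6, n_individuals=3, n_fa=4, seed=8))
        means = db.species_means()
        with pytest.warns(UserWarning, match="not be unique"):
            estimate_diet(means.iloc[0], means, "KL", n_starts=2, seed=0)


class TestModelFrontEnd:
    def test_fit_and_summary(self, small_db, rng):
        db, _ = small_db
        preds = pd.DataFrame(rng.dirichlet(np.ones(10), size=3),
                             index=["p1", "p2", "p3"], columns=db.fa_names)
        res = DietModel(preds, db, distance="KL").fit(n_starts=4, seed=0)
        assert res.diets.shape == (3, 5)
        np.testing.assert_allclose(res.diets.sum(axis=1), 1.0, atol=1e-6)
        text = res.summary()
        assert "KL" in text and "p1" not in text  # summary aggregates, not per-row
        assert (res.fa_contributions.sum(axis=1) - res.min_distance).abs().max() < 1e-8
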