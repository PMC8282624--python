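"""Pseudo-absence strategies, replicate fitting, prediction and ensembling."""

import numpy as np
import pytest
from scipy import ndimage, stats

from pftshift.sdm_ensemble import (
    LearnerSpec,
    default_learners,
    draw_pseudo_absences,
    ensemble_mean,
    fit_replicates,
    predict_map,
    presence_cells,
    select_projection_replicates,
)
from pftshift.synthetic_landscape import (
    NicheSpec,
    sample_occurrences,
    true_suitability,
)

VARS = ["temperature", "precipitation"]


@pytest.fixture
def occ(env, warm_niche):
    return sample_occurrences(env, warm_niche, 400, seed=1)


class TestPseudoAbsences:
    def test_random_avoids_presences_and_counts(self, env, occ):
        spec = LearnerSpec("gam", pa_strategy="random", pa_count=300)
        r, c = draw_pseudo_absences(env, occ, spec, seed=0)
        assert len(r) == 300
        pres = presence_cells(occ, env)
        assert not pres[r, c].any()

    def test_disk_respects_minimum_distance(self, env, occ):
        spec = LearnerSpec(
            "rf", pa_strategy="disk", pa_count=100, hyperparams={"d_min": 2.0}
        )
        r, c = draw_pseudo_absences(env, occ, spec, seed=0)
        pres = presence_cells(occ, env)
        dist = ndimage.distance_transform_edt(~pres)
        assert (dist[r, c] >= 2.0).all()

    def test_empty_annulus_errors(self, env, occ):
        spec = LearnerSpec(
            "rf", pa_strategy="disk", pa_count=10,
            hyperparams={"d_min": 500.0, "d_max": 501.0},
        )
        with pytest.raises(ValueError, match="annulus"):
            draw_pseudo_absences(env, occ, spec, seed=0)

    def test_deterministic_per_seed(self, env, occ):
        spec = LearnerSpec("gam", pa_count=200)
        a = draw_pseudo_absences(env, occ, spec, seed=5)
        b = draw_pseudo_absences(env, occ, spec, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_stratified_avoids_presence_bins(self, env, occ):
        spec = LearnerSpec("gam", pa_strategy="stratified", pa_count=100)
        r, c = draw_pseudo_absences(env, occ, spec, seed=0)
        assert len(r) == 100
        assert not presence_cells(occ, env)[r, c].any()


@pytest.fixture(scope="module")
def fitted():
    from pftshift.synthetic_landscape import GridSpec, generate_landscape
    grid = GridSpec(20, 25, 4.0, 24.0, -100.0, -68.0)
    env = generate_landscape(grid, {"elevation_ramp": 2000.0}, seed=7)
    niche = NicheSpec("warm_sp", {"temperature": 26.0}, {"temperature": 2.0}, 0.9)
    occ = sample_occurrences(env, niche, 400, seed=1)
    pres = np.nonzero(presence_cells(occ, env))
    spec = LearnerSpec("gam", pa_count=500)
    absent = draw_pseudo_absences(env, occ, spec, seed=2)
    fits = fit_replicates(
        spec, pres, absent, env, VARS, species_id="warm_sp",
        n_replicates=15, seed=3,
    )
    return env, fits


class TestFitReplicates:

    def test_replicate_count(self, fitted):
        _, fits = fitted
        assert len(fits) == 15

    def test_train_holdout_disjoint_and_sized(self, fitted):
        _, fits = fitted
        for f in fits:
            assert np.intersect1d(f.train_idx, f.holdout_idx).size == 0
            n = len(f.train_idx) + len(f.holdout_idx)
            assert abs(len(f.train_idx) - 0.7 * n) <= 2

    def test_separable_species_near_perfect_auc(self, flat_env):
        # niche occupies only the warm end of the ramp: classes separable
        niche = NicheSpec("sep", {"temperature": 29.5}, {"temperature": 0.4}, 1.0)
        occ = sample_occurrences(flat_env, niche, 200, seed=4)
        pres = np.nonzero(presence_cells(occ, flat_env))
        spec = LearnerSpec("rf", pa_count=300, hyperparams={"n_estimators": 50})
        absent = draw_pseudo_absences(flat_env, occ, spec, seed=5)
        fits = fit_replicates(
            spec, pres, absent, flat_env, ["temperature"], n_replicates=10, seed=6
        )
        mean_auc = np.mean([f.metrics.auc for f in fits])
        assert mean_auc > 0.95

    def test_prediction_bounds_and_missing_variable(self, fitted):
        env, fits = fitted
        m = predict_map(fits[0], env)
        assert np.nanmin(m) >= 0.0 and np.nanmax(m) <= 1.0
        bad = env.copy()
        del bad.layers["temperature"]
        with pytest.raises(KeyError, match="temperature"):
            predict_map(fits[0], bad)

    def test_constant_environment_gives_constant_map(self, fitted, grid):
        from pftshift.synthetic_landscape import EnvStack
        env, fits = fitted
        const = EnvStack(
            grid,
            {v: np.full(grid.shape, float(np.mean(env.layers[v]))) for v in env.layer_names},
        )
        m = predict_map(fits[0], const)
        assert np.ptp(m) == pytest.approx(0.0, abs=1e-12)


class TestEnsembleMean:
    def test_identity_and_midpoint(self):
        a = np.zeros((3, 3))
        b = np.ones((3, 3))
        np.testing.assert_array_equal(ensemble_mean([a, a]), a)
        np.testing.assert_array_equal(ensemble_mean([a, b]), np.full((3, 3), 0.5))

    def test_matches_cellwise_mean_oracle(self):
        rng = np.random.default_rng(7)
        maps = [rng.uniform(0, 1, (4, 6)) for _ in range(7)]
        out = ensemble_mean(maps)
        expect = sum(maps) / 7.0
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_bounded_by_input_envelope_and_order_invariant(self):
        rng = np.random.default_rng(8)
        maps = [rng.uniform(0, 1, (5, 5)) for _ in range(5)]
        out = ensemble_mean(maps)
        assert (out >= np.min(maps, axis=0) - 1e-12).all()
        assert (out <= np.max(maps, axis=0) + 1e-12).all()
        np.testing.assert_allclose(out, ensemble_mean(maps[::-1]), atol=1e-15)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            ensemble_mean([np.zeros((2, 2)), np.zeros((3, 3))])


class TestReplicateSelection:
    def fake_fits(self, n_per=20):
        from pftshift.sdm_ensemble import ReplicateFit
        from pftshift.evaluation import EvaluationMetrics
        m = EvaluationMetrics(0.9, 0.9, 0.9, 10, 10)
        fits = []
        for name in ("gam", "rf"):
            for i in range(n_per):
                fits.append(ReplicateFit("s", name, i, None, VARS, m,
                                         np.array([]), np.array([]),
                                         np.array([]), np.array([])))
        return fits

    def test_k_per_learner(self):
        sel = select_projection_replicates(self.fake_fits(), k=10, seed=1)
        for name in ("gam", "rf"):
            assert sum(f.learner == name for f in sel) == 10

    def test_k_equal_all_is_identity(self):
        fits = self.fake_fits(5)
        sel = select_projection_replicates(fits, k=5, seed=1)
        assert {(f.learner, f.replicate) for f in sel} == {
            (f.learner, f.replicate) for f in fits
        }

    def test_deterministic_and_bounds(self):
        fits = self.fake_fits()
        a = select_projection_replicates(fits, k=7, seed=3)
        b = select_projection_replicates(fits, k=7, seed=3)
        assert [(f.learner, f.replicate) for f in a] == [(f.learner, f.replicate) for f in b]
        with pytest.raises(ValueError):
            select_projection_replicates(fits, k=21, seed=0)


class TestRankRecovery:
    def test_ensemble_map_tracks_true_suitability(self, env):
        # moderately sized check; the full-scale version lives in the
        # acceptance suite
        niche = NicheSpec(
            "sp", {"temperature": 24.0, "precipitation": 1800.0},
            {"temperature": 2.5, "precipitation": 400.0}, 0.9,
        )
        occ = sample_occurrences(env, niche, 500, seed=9)
        pres = np.nonzero(presence_cells(occ, env))
        maps = []
        for spec in default_learners():
            spec = LearnerSpec(spec.name, spec.pa_strategy,
                               500 if spec.pa_count != "equal" else "equal",
                               spec.hyperparams, spec.presence_only)
            absent = draw_pseudo_absences(env, occ, spec, seed=10)
            fits = fit_replicates(spec, pres, absent, env, VARS,
                                  n_replicates=3, seed=11)
            maps.extend(predict_map(f, env) for f in fits)
        overall = ensemble_mean(maps)
        truth = true_suitability(env, niche)
        rho = stats.spearmanr(overall.ravel(), truth.ravel()).statistic
        assert rho > 0.8
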