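import numpy as np
import pytest

import traitshift as ts
from traitshift import maxent
from traitshift.maxent import penalized_objective

from conftest import gaussian_niche_instance, implied_optimum


def grid_search_lambda(F_pres, F_bg, beta, span=6.0, rounds=8, n_grid=25):
    """Independent oracle: nested coordinate grid search of the penalised objective.

    Works for 1- and 2-feature problems; refines an axis-aligned grid around
    the best point until the spacing is far below the comparison tolerance.
    """
    k = F_pres.shape[1]
    center = np.zeros(k)
    width = span
    best = center.copy()
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        grids_nd = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids_nd], axis=1)
        vals = [penalized_objective(p, F_pres, F_bg, beta) for p in pts]
        best = pts[int(np.argmax(vals))]
        center = best
        width = 2 * width / (n_grid - 1)
    return best


def binary_feature_problem(n_cells=100, n_pos=20, n_pres=10):
    """1-D binary feature; presences only where the feature is 1."""
    x = np.zeros(n_cells)
    x[:n_pos] = 1.0
    mean, sd = x.mean(), x.std()
    F = ((x - mean) / sd)[:, None]
    presence_rows = np.arange(n_pres)
    return F, presence_rows


class TestFit:
    def test_constant_features_dropped_and_uniform(self, small_env):
        env = small_env.copy()
        env.layers["clim1"] = np.full(env.shape, 3.0)
        fm = maxent.build_features(env)
        assert all(layer != "clim1" for layer, _, _ in fm.defs)

    def test_feature_counts(self, small_env):
        fm = maxent.build_features(small_env)
        kinds = [kind for _, kind, _ in fm.defs]
        assert kinds.count("linear") == 2
        assert kinds.count("quadratic") == 2
        # one indicator per categorical code actually present
        assert kinds.count("indicator") == len(small_env.code_sets["soil1"])

    def test_uninformative_features_give_uniform(self):
        """With presences sampled uniformly, lambda shrinks to ~0 under L1."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 2))
        X = (X - X.mean(0)) / X.std(0)
        fm = maxent.FeatureMatrix(X=X, defs=[("a", "linear", None),
                                             ("b", "linear", None)],
                                  means=np.zeros(2), sds=np.ones(2),
                                  cells=np.arange(80),
                                  background_rows=np.arange(80),
                                  grid_shape=(8, 10))
        model = maxent.fit(fm, presence_rows=np.arange(80), beta=0.1)
        assert np.abs(model.lambdas).max() < 1e-6

    def test_huge_beta_forces_zero_weights(self):
        F, pres = binary_feature_problem()
        fm = maxent.FeatureMatrix(X=F, defs=[("x", "linear", None)],
                                  means=np.zeros(1), sds=np.ones(1),
                                  cells=np.arange(len(F)),
                                  background_rows=np.arange(len(F)),
                                  grid_shape=(10, 10))
        model = maxent.fit(fm, pres, beta=100.0)
        assert np.abs(model.lambdas).max() < 1e-9

    @pytest.mark.parametrize("beta", [0.05, 0.1, 0.5])
    def test_matches_grid_search_oracle_1d(self, beta):
        F, pres = binary_feature_problem()
        fm = maxent.FeatureMatrix(X=F, defs=[("x", "linear", None)],
                                  means=np.zeros(1), sds=np.ones(1),
                                  cells=np.arange(len(F)),
                                  background_rows=np.arange(len(F)),
                                  grid_shape=(10, 10))
        model = maxent.fit(fm, pres, beta=beta)
        oracle = grid_search_lambda(F[pres], F, beta)
        np.testing.assert_allclose(model.lambdas, oracle, atol=1e-3)

    def test_matches_grid_search_oracle_2d(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((150, 2))
        X = (X - X.mean(0)) / X.std(0)
        # presences biased toward high values of both features
        w = np.exp(X @ np.array([1.0, 0.5]))
        pres = rng.choice(150, size=40, replace=True, p=w / w.sum())
        fm = maxent.FeatureMatrix(X=X, defs=[("a", "linear", None),
                                             ("b", "linear", None)],
                                  means=np.zeros(2), sds=np.ones(2),
                                  cells=np.arange(150),
                                  background_rows=np.arange(150),
                                  grid_shape=(10, 15))
        model = maxent.fit(fm, pres, beta=0.1)
        oracle = grid_search_lambda(X[pres], X, 0.1)
        np.testing.assert_allclose(model.lambdas, oracle, atol=1e-3)

    def test_objective_never_below_zero_model(self, small_env, small_occurrences):
        fm = maxent.build_features(small_env)
        sp = small_occurrences.species_ids()[0]
        recs = small_occurrences.for_species(sp)
        flat = np.ravel_multi_index((recs["row"], recs["col"]), small_env.shape)
        rows = fm.row_of_cell(np.sort(flat))
        model = maxent.fit(fm, rows, beta=0.1)
        at_zero = penalized_objective(np.zeros(fm.X.shape[1]),
                                      fm.X[rows], fm.X[fm.background_rows], 0.1)
        assert model.objective >= at_zero - 1e-12

    def test_no_presences_rejected(self, small_env):
        fm = maxent.build_features(small_env)
        with pytest.raises(ValueError, match="presence"):
            maxent.fit(fm, np.array([], dtype=int))


class TestProject:
    def test_raw_projection_sums_to_one(self, small_env, small_occurrences):
        fm = maxent.build_features(small_env)
        sp = small_occurrences.species_ids()[0]
        recs = small_occurrences.for_species(sp)
        flat = np.ravel_multi_index((recs["row"], recs["col"]), small_env.shape)
        model = maxent.fit(fm, fm.row_of_cell(np.sort(flat)), beta=0.1)
        surf = maxent.project(model, small_env, scale="raw")
        total = np.nansum(surf.values)
        assert abs(total - 1.0) < 1e-9

    def test_zero_model_is_uniform(self, small_env):
        fm = maxent.build_features(small_env)
        model = maxent.fit(fm, np.array([0, 1, 2]), beta=1e6)
        surf = maxent.project(model, small_env, scale="raw")
        vals = surf.values[~np.isnan(surf.values)]
        np.testing.assert_allclose(vals, 1.0 / small_env.n_valid, rtol=1e-9)

    def test_logistic_in_unit_interval_and_monotone(self, small_env,
                                                    small_occurrences):
        fm = maxent.build_features(small_env)
        sp = small_occurrences.species_ids()[0]
        recs = small_occurrences.for_species(sp)
        flat = np.ravel_multi_index((recs["row"], recs["col"]), small_env.shape)
        model = maxent.fit(fm, fm.row_of_cell(np.sort(flat)), beta=0.1)
        raw = maxent.project(model, small_env, scale="raw").values
        logi = maxent.project(model, small_env, scale="logistic").values
        ok = ~np.isnan(raw)
        # strictly inside (0, 1) up to floating saturation at 1.0
        assert ((logi[ok] > 0) & (logi[ok] <= 1)).all()
        order_raw = np.argsort(raw[ok])
        assert np.all(np.diff(logi[ok][order_raw]) >= 0)

    def test_scenario_toward_optimum_raises_suitability(self):
        env, truth, rows = gaussian_niche_instance(seed=5)
        fm = maxent.build_features(env)
        model = maxent.fit(fm, rows, beta=0.1)
        # shift the layer mean halfway toward the species optimum
        delta = ts.scenario_towards(env, [truth], strength=0.5)
        shifted = ts.apply_scenario(env, delta)
        cur = maxent.project(model, env, scale="logistic").values
        fut = maxent.project(model, shifted, scale="logistic").values
        assert np.nanmean(fut) > np.nanmean(cur)

    def test_missing_layer_rejected(self, small_env, small_occurrences):
        fm = maxent.build_features(small_env)
        sp = small_occurrences.species_ids()[0]
        recs = small_occurrences.for_species(sp)
        flat = np.ravel_multi_index((recs["row"], recs["col"]), small_env.shape)
        model = maxent.fit(fm, fm.row_of_cell(np.sort(flat)), beta=0.1)
        smaller = ts.EnvStack(layers={"clim1": small_env.layers["clim1"]},
                              kinds={"clim1": "continuous"},
                              mask=small_env.mask)
        with pytest.raises(KeyError):
            maxent.project(model, smaller)


class TestNicheRecovery:
    def test_quadratic_negative_and_optimum_close(self):
        """A fitted linear+quadratic response recovers a 1-D Gaussian niche."""
        env, truth, rows = gaussian_niche_instance(seed=1)
        fm = maxent.build_features(env)
        model = maxent.fit(fm, rows, beta=0.1)
        opt, lam2 = implied_optimum(model)
        assert lam2 < 0
        assert abs(opt - truth.optima["clim1"]) < 0.5 * truth.breadths["clim1"]


class TestFitAll:
    def test_counts_classes_and_determinism(self, small_occurrences, small_env):
        res1 = ts.fit_all(small_occurrences, small_env, min_presences=5, seed=0)
        res2 = ts.fit_all(small_occurrences, small_env, min_presences=5, seed=0)
        assert set(res1.models) == set(res2.models)
        for key in res1.models:
            np.testing.assert_array_equal(res1.models[key].lambdas,
                                          res2.models[key].lambdas)
            a = res1.surfaces[key]["current"].values
            b = res2.surfaces[key]["current"].values
            np.testing.assert_array_equal(a, b)
        # every fitted class had enough records; every skip is logged with count
        for sp, cls, n in res1.skipped:
            assert n < 5
            assert (sp, cls) not in res1.models

    def test_single_class_species(self, small_env):
        import pandas as pd
        rng = np.random.default_rng(3)
        cells = rng.choice(small_env.valid_indices(), 20, replace=False)
        r, c = np.unravel_index(cells, small_env.shape)
        occ = ts.OccurrenceSet(pd.DataFrame({
            "species_id": "only", "row": r, "col": c, "abundance_class": 3}))
        res = ts.fit_all(occ, small_env, min_presences=5)
        assert set(res.models) == {("only", 3)}
        assert {(s, k) for s, k, _ in res.skipped} == {("only", 1), ("only", 2)}

    def test_model_json_round_trip(self, small_env, small_occurrences):
        res = ts.fit_all(small_occurrences, small_env, min_presences=5)
        (key, model), = list(res.models.items())[:1]
        back = maxent.MaxentModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.lambdas, model.lambdas)
        surf_a = maxent.project(model, small_env, scale="logistic")
        surf_b = maxent.project(back, small_env, scale="logistic")
        np.testing.assert_allclose(surf_a.values, surf_b.values, equal_nan=True)
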