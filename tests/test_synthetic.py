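import math

import numpy as np
import pandas as pd
import pytest

import traitshift as ts
from traitshift.phylo import phylo_covariance


class TestGenerateLandscape:
    def test_deterministic_given_seed(self):
        a = ts.generate_landscape(20, 20, 4, 2, 5, seed=1)
        b = ts.generate_landscape(20, 20, 4, 2, 5, seed=1)
        assert list(a.layers) == list(b.layers)
        assert len(a.layers) == 6 and a.n_valid == 400
        for name in a.layers:
            assert np.array_equal(a.layers[name], b.layers[name])

    def test_different_seeds_differ(self):
        a = ts.generate_landscape(2, 2, 1, 0, 1, seed=7)
        b = ts.generate_landscape(2, 2, 1, 0, 1, seed=8)
        assert not np.array_equal(a.layers["clim1"], b.layers["clim1"])

    def test_long_correlation_flattens_field(self):
        # Without per-layer rescaling, smoothing shrinks cell-to-cell variance
        # toward zero as the correlation length grows.
        short = ts.generate_landscape(16, 16, 1, 0, 1, seed=3, standardize=False)
        long = ts.generate_landscape(16, 16, 1, 0, 100, seed=3, standardize=False)
        assert long.layers["clim1"].var() < 1e-3 * short.layers["clim1"].var()

    def test_standardized_layers_have_unit_variance(self, small_env):
        for name in small_env.layer_names("continuous"):
            vals = small_env.layers[name][small_env.mask]
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std() - 1) < 1e-12

    def test_categorical_codes_in_declared_set(self, small_env):
        codes = small_env.layers["soil1"][small_env.mask]
        assert set(np.unique(codes)) <= set(small_env.code_sets["soil1"])

    @pytest.mark.parametrize("nrows,ncols", [(1, 5), (5, 1), (0, 0)])
    def test_bad_dimensions_rejected(self, nrows, ncols):
        with pytest.raises(ValueError):
            ts.generate_landscape(nrows, ncols, 1, 0, 1, seed=0)

    def test_nodata_fraction_masks_cells(self):
        env = ts.generate_landscape(20, 20, 1, 0, 3, seed=5, nodata_fraction=0.2)
        assert 0 < env.n_valid < 400


class TestGenerateSpecies:
    def test_all_pfgs_present(self, small_env):
        truths = ts.generate_species(small_env, 30, seed=4)
        assert {t.pfg for t in truths} == set(ts.PFGS)

    def test_deterministic(self, small_env):
        a = ts.generate_species(small_env, 5, seed=9)
        b = ts.generate_species(small_env, 5, seed=9)
        assert [(t.species, t.optima, t.max_abundance) for t in a] == \
               [(t.species, t.optima, t.max_abundance) for t in b]

    def test_single_species_valid(self, small_env):
        (t,) = ts.generate_species(small_env, 1, seed=2)
        for name in small_env.layer_names("continuous"):
            lo = small_env.layers[name][small_env.mask].min()
            hi = small_env.layers[name][small_env.mask].max()
            assert lo <= t.optima[name] <= hi
            assert t.breadths[name] > 0


class TestTrueAbundance:
    def test_peak_equals_max_abundance(self):
        env = ts.EnvStack(layers={"clim1": np.zeros((3, 3))},
                          kinds={"clim1": "continuous"},
                          mask=np.ones((3, 3), dtype=bool),
                          climatic={"clim1"})
        t = ts.SpeciesTruth("s", {"clim1": 0.0}, {"clim1": 1.0}, {}, 10.0,
                            "graminoid", ("fen",))
        A = ts.true_abundance(t, env).values
        np.testing.assert_allclose(A, 10.0)

    def test_two_layer_toy_value(self):
        # optima (0,0), breadths (1,1), cell values (1,1), max 10:
        # 10 * exp(-0.5) * exp(-0.5) = 10 e^-1
        env = ts.EnvStack(layers={"a": np.ones((2, 2)), "b": np.ones((2, 2))},
                          kinds={"a": "continuous", "b": "continuous"},
                          mask=np.ones((2, 2), dtype=bool))
        t = ts.SpeciesTruth("s", {"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0},
                            {}, 10.0, "herbaceous", ("bog",))
        A = ts.true_abundance(t, env).values
        np.testing.assert_allclose(A, 10.0 * math.exp(-1.0), rtol=1e-12)

    def test_tiny_breadth_off_optimum_vanishes(self):
        env = ts.EnvStack(layers={"a": np.ones((2, 2))},
                          kinds={"a": "continuous"},
                          mask=np.ones((2, 2), dtype=bool))
        t = ts.SpeciesTruth("s", {"a": 0.0}, {"a": 1e-6}, {}, 5.0,
                            "shrub", ("fen",))
        assert ts.true_abundance(t, env).values.max() < 1e-200

    def test_missing_layer_named_in_error(self, small_env):
        t = ts.SpeciesTruth("s", {"absent": 0.0}, {"absent": 1.0}, {}, 1.0,
                            "moss", ("bog",))
        with pytest.raises(KeyError, match="absent"):
            ts.true_abundance(t, small_env)


class TestSampleOccurrences:
    def test_zero_abundance_species_never_recorded(self, small_env):
        t = ts.SpeciesTruth("s", {"clim1": 0.0}, {"clim1": 1.0}, {}, 0.0,
                            "moss", ("bog",))
        occ = ts.sample_occurrences([t], small_env, 100, seed=1)
        assert len(occ) == 0

    def test_class_thresholding(self):
        env = ts.EnvStack(layers={"a": np.zeros((5, 5))},
                          kinds={"a": "continuous"},
                          mask=np.ones((5, 5), dtype=bool))
        t = ts.SpeciesTruth("s", {"a": 1.1973}, {"a": 1.0}, {}, 1.0,
                            "graminoid", ("fen",))
        # normalized abundance = exp(-0.5 * 1.1973^2) ~= 0.488 -> class 2
        occ = ts.sample_occurrences([t], env, 25, seed=0, detection=1.0)
        assert len(occ) == 25
        assert (occ.records["abundance_class"] == 2).all()
        # at the optimum -> class 3 with thresholds (0.1, 0.5)
        t3 = ts.SpeciesTruth("s", {"a": 0.0}, {"a": 1.0}, {}, 1.0,
                             "graminoid", ("fen",))
        occ3 = ts.sample_occurrences([t3], env, 25, seed=0, detection=1.0)
        assert (occ3.records["abundance_class"] == 3).all()

    def test_perfect_detection_records_everywhere(self):
        """With detection 1 and all cells surveyed, records = cells with A > 0."""
        env = ts.generate_landscape(5, 5, 1, 0, 2, seed=6)
        truths = ts.generate_species(env, 3, seed=7)
        occ = ts.sample_occurrences(truths, env, 25, seed=8, detection=1.0)
        for t in truths:
            A = ts.true_abundance(t, env).values
            expected = int((A > 0).sum())
            assert len(occ.for_species(t.species)) == expected
            # recorded classes match thresholded normalized abundance exactly
            recs = occ.for_species(t.species)
            a = A[recs["row"], recs["col"]] / t.max_abundance
            want = np.where(a > 0.5, 3, np.where(a > 0.1, 2, 1))
            assert np.array_equal(recs["abundance_class"].to_numpy(), want)

    def test_bad_thresholds_rejected(self, small_truths, small_env):
        with pytest.raises(ValueError, match="t1 < t2"):
            ts.sample_occurrences(small_truths, small_env, 10,
                                  class_thresholds=(0.5, 0.5), seed=0)

    def test_class_codes_validated(self):
        with pytest.raises(ValueError, match="class"):
            ts.OccurrenceSet(pd.DataFrame({"species_id": ["s"], "row": [0],
                                           "col": [0], "abundance_class": [4]}))


class TestSimulateTraits:
    def test_no_missing_when_fraction_zero(self, three_tip_tree):
        tm = ts.simulate_traits(three_tip_tree, 2, 1.0, 0.0,
                                missing_fraction=0.0, seed=1)
        assert not tm.mask.any().any()

    def test_deterministic(self, three_tip_tree):
        a = ts.simulate_traits(three_tip_tree, 2, 1.0, 0.0, 0.0, seed=3)
        b = ts.simulate_traits(three_tip_tree, 2, 1.0, 0.0, 0.0, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_star_tree_moments(self, star_tree):
        """Tips on a star tree are independent with variance sigma2 * T."""
        sigma2, T = 1.0, 2.0
        vals = np.array([
            ts.simulate_traits(star_tree, 1, sigma2, 0.0, 0.0, seed=s
                               ).data["SLA"].to_numpy()
            for s in range(10_000)])
        var = vals.var(axis=0).mean()
        assert abs(var - sigma2 * T) / (sigma2 * T) < 0.05
        cov = np.cov(vals[:, 0], vals[:, 1])[0, 1]
        assert abs(cov) < 0.05 * sigma2 * T

    def test_two_tip_difference_variance(self):
        import dendropy
        tree = dendropy.Tree.get(data="(A:1.5,B:1.5);", schema="newick")
        diffs = np.array([
            np.diff(ts.simulate_traits(tree, 1, 1.0, 0.0, 0.0, seed=s)
                    .data["SLA"].to_numpy())[0]
            for s in range(10_000)])
        assert abs(diffs.var() - 2 * 1.5) / 3.0 < 0.05

    def test_categorical_from_pfg_scheme(self, three_tip_tree):
        pfg = pd.Series({"A": "shrub", "B": "graminoid", "C": "moss"})
        tm = ts.simulate_traits(three_tip_tree, 1, 1.0, 0.0, 0.0, seed=0,
                                pfg=pfg)
        assert tm.data.loc["A", "leaf_persistence"] == "evergreen"
        assert tm.data.loc["B", "clonality"] == "tussock"
        assert tm.data.loc["C", "mycorrhiza"] == "nonmycorrhizal"

    def test_full_missingness_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            ts.simulate_traits(three_tip_tree, 1, 1.0, 0.0,
                               missing_fraction=1.0, seed=0)


class TestGenerateTree:
    def test_tips_match_species_and_seed(self):
        ids = [f"sp{i}" for i in range(6)]
        t1 = ts.generate_tree(ids, seed=5)
        t2 = ts.generate_tree(ids, seed=5)
        labels = sorted(l.taxon.label for l in t1.leaf_node_iter())
        assert labels == sorted(ids)
        C1, _ = phylo_covariance(t1)
        C2, _ = phylo_covariance(t2)
        np.testing.assert_allclose(C1, C2)
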