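"""Generators: standardization, determinism, autocorrelation and containment."""

import numpy as np
import pytest

from rangegap import synth


def lag1_autocorr(field):
    """Mean lag-1 spatial correlation (rows and columns), a Moran's-I-style statistic."""
    a = field - field.mean()

    def corr(x, y):
        return (x * y).mean() / np.sqrt((x**2).mean() * (y**2).mean())

    return 0.5 * (corr(a[:-1, :], a[1:, :]) + corr(a[:, :-1], a[:, 1:]))


class TestLandscape:
    def test_layers_standardized_over_valid_cells(self, landscape):
        for layer in landscape.layers:
            vals = layer[landscape.valid_mask]
            assert abs(vals.mean()) < 1e-6
            assert vals.std() == pytest.approx(1.0, abs=1e-6)
        assert landscape.layers.shape == (6, 50, 50)

    def test_same_seed_bit_identical(self):
        a = synth.generate_landscape(7, (30, 30), 4, 3.0)
        b = synth.generate_landscape(7, (30, 30), 4, 3.0)
        assert np.array_equal(a.layers, b.layers)

    def test_larger_scale_more_autocorrelated(self):
        smooth = synth.generate_landscape(2, (60, 60), 2, autocorr_scale=10.0)
        rough = synth.generate_landscape(2, (60, 60), 2, autocorr_scale=1.0)
        for i in range(2):
            assert lag1_autocorr(smooth.layers[i]) > lag1_autocorr(rough.layers[i])

    @pytest.mark.parametrize("shape", [(0, 10), (10, -1)])
    def test_bad_dimensions_rejected(self, shape):
        with pytest.raises(ValueError, match="positive"):
            synth.generate_landscape(1, shape, 3, 2.0)


class TestFuture:
    def test_zero_shift_zero_noise_identical(self, landscape):
        fut = synth.generate_future(landscape, np.zeros(6), noise_sd=0.0)
        assert np.array_equal(fut.layers, landscape.layers)

    def test_shift_applied_exactly_without_noise(self, landscape):
        shift = np.zeros(6)
        shift[1] = 2.0
        fut = synth.generate_future(landscape, shift, noise_sd=0.0)
        np.testing.assert_allclose(fut.layers[1] - landscape.layers[1], 2.0)
        np.testing.assert_allclose(fut.layers[0], landscape.layers[0])

    def test_noise_reproducible_per_seed(self, landscape):
        a = synth.generate_future(landscape, np.zeros(6), noise_sd=0.5, seed=9)
        b = synth.generate_future(landscape, np.zeros(6), noise_sd=0.5, seed=9)
        assert np.array_equal(a.layers, b.layers)

    def test_shift_length_mismatch_rejected(self, landscape):
        with pytest.raises(ValueError, match="one entry per layer"):
            synth.generate_future(landscape, np.zeros(4))


class TestVirtualSpecies:
    def test_optimum_cell_scores_one(self, landscape):
        r, c = 10, 40
        niche = {
            name: (float(landscape.layers[i, r, c]), 1.0)
            for i, name in enumerate(landscape.var_names)
        }
        sp = synth.generate_virtual_species(landscape, niche, range_cut=0.5)
        assert sp.true_suitability[r, c] == pytest.approx(1.0)
        assert sp.true_suitability.max() == pytest.approx(1.0)

    def test_zero_cut_range_is_valid_mask(self, landscape, species):
        sp = synth.generate_virtual_species(landscape, species.niche_params, range_cut=0.0)
        assert np.array_equal(sp.true_range, landscape.valid_mask)

    def test_narrower_breadth_shrinks_range(self, landscape, species):
        wide = species
        narrow_params = {v: (o, b / 2) for v, (o, b) in wide.niche_params.items()}
        narrow = synth.generate_virtual_species(landscape, narrow_params, wide.range_cut)
        assert narrow.true_range.sum() <= wide.true_range.sum()

    def test_range_inside_endemism_region(self, species):
        assert not (species.true_range & ~species.endemism_region).any()

    def test_empty_range_warns(self, landscape, species):
        # rescaling guarantees the best cell scores exactly 1, so only a cut
        # above 1 can empty the range
        with pytest.warns(UserWarning, match="empty true range"):
            sp = synth.generate_virtual_species(
                landscape, species.niche_params, range_cut=1.1
            )
        assert not sp.true_range.any()

    def test_unknown_variable_rejected(self, landscape):
        with pytest.raises(ValueError, match="unknown layers"):
            synth.generate_virtual_species(landscape, {"nope": (0, 1)}, 0.5)


class TestOccurrences:
    def test_exhaustive_sample_equals_range(self, species):
        n = int(species.true_range.sum())
        occ = synth.sample_occurrences(species, n, seed=1)
        got = set(map(tuple, occ.cells))
        want = set(map(tuple, np.argwhere(species.true_range)))
        assert got == want

    def test_minimum_realistic_count(self, species):
        occ = synth.sample_occurrences(species, 8, seed=2)
        assert occ.n_unique == 8

    def test_different_seeds_contained_in_range(self, species):
        a = synth.sample_occurrences(species, 20, seed=1)
        b = synth.sample_occurrences(species, 20, seed=2)
        rng_cells = set(map(tuple, np.argwhere(species.true_range)))
        assert set(map(tuple, a.cells)) <= rng_cells
        assert set(map(tuple, b.cells)) <= rng_cells

    def test_oversampling_rejected(self, species):
        with pytest.raises(ValueError, match="true range"):
            synth.sample_occurrences(species, int(species.true_range.sum()) + 1, seed=1)


class TestProtectedAreas:
    def test_requested_count_and_categories(self):
        pas = synth.generate_protected_areas((80, 80), n_areas=347, seed=1)
        assert len(pas) == 347
        assert all(a.category in {"SPA", "SUA", "IT"} for a in pas)

    def test_unit_size_range_single_cells(self):
        pas = synth.generate_protected_areas((20, 20), 10, size_range=(1, 1), seed=1)
        assert all(len(a.footprint) == 1 for a in pas)

    def test_footprints_inside_grid_and_reproducible(self):
        a = synth.generate_protected_areas((30, 30), 25, seed=5)
        b = synth.generate_protected_areas((30, 30), 25, seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.footprint, pb.footprint)
            assert pa.footprint.min() >= 0
            assert pa.footprint.max() < 30


class TestLandcover:
    @pytest.mark.parametrize("frac,lo,hi", [(1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (0.5, 0.45, 0.55)])
    def test_forest_share(self, frac, lo, hi):
        lc = synth.generate_landcover((100, 100), forest_fraction=frac, seed=8)
        share = lc.forest_mask.mean()
        assert lo <= share <= hi

    def test_clumped_not_salt_and_pepper(self):
        lc = synth.generate_landcover((100, 100), 0.5, autocorr_scale=5.0, seed=8)
        assert lag1_autocorr(lc.forest_mask.astype(float)) > 0.5
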