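"""Binarization, masking, area change and richness stacking."""

import numpy as np
import pytest

from rangegap import postprocess as pp
from rangegap.grids import LandCoverGrid
from rangegap.sdm import jaccard


def grid(vals):
    return np.asarray(vals, dtype=float)


def make_range(mask, taxon="t", scenario="present", threshold=0.5, cell_area=25.0):
    return pp.BinaryRange(taxon, scenario, np.asarray(mask, dtype=bool), threshold, cell_area)


class TestSelectThreshold:
    def test_clean_separation_picks_lowest_presence_value(self):
        suit = grid([[0.8, 0.6, 0.3]])
        t = pp.select_threshold(suit, np.array([[0, 0], [0, 1]]), np.array([[0, 2]]))
        assert t == 0.6
        vals = suit[0]
        assert jaccard(vals >= t, [True, True, False]) == 1.0

    def test_inverted_scores_all_positive_prediction(self):
        # presences score lower than absences: including everything maximizes Jaccard
        suit = grid([[0.1, 0.2, 0.9]])
        t = pp.select_threshold(suit, np.array([[0, 0], [0, 1]]), np.array([[0, 2]]))
        assert t == 0.1

    def test_equals_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            suit = rng.integers(0, 25, size=(1, n)) / 25.0
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            pres = np.column_stack([np.zeros(labels.sum(), int), np.nonzero(labels)[0]])
            absn = np.column_stack([np.zeros((~labels).sum(), int), np.nonzero(~labels)[0]])
            t = pp.select_threshold(suit, pres, absn)
            ours = jaccard(suit[0] >= t, labels)
            oracle = max(jaccard(suit[0] >= x, labels) for x in np.linspace(0, 1, 401))
            assert ours == pytest.approx(oracle)

    def test_constant_surface_warns_and_returns_constant(self):
        suit = grid([[0.4, 0.4, 0.4]])
        with pytest.warns(UserWarning, match="constant"):
            t = pp.select_threshold(suit, np.array([[0, 0]]), np.array([[0, 1]]))
        assert t == 0.4


class TestBinarize:
    def test_zero_threshold_everything_valid(self):
        suit = grid([[0.2, 0.8], [0.0, 1.0]])
        br = pp.binarize(suit, 0.0)
        assert br.cells.all()

    def test_threshold_above_max_empty(self):
        br = pp.binarize(grid([[0.2, 0.8]]), 0.81)
        assert br.is_empty and br.area_km2 == 0.0

    def test_area_arithmetic(self):
        cells = np.zeros((10, 10))
        cells[:37 // 10 + 1, :] = 1  # any 37 cells
        suit = np.zeros((10, 10))
        suit.ravel()[:37] = 1.0
        br = pp.binarize(suit, 0.5, cell_area=25.0)
        assert br.n_cells == 37
        assert br.area_km2 == 925.0

    def test_monotone_in_threshold(self, rng):
        suit = rng.random((20, 20))
        prev = None
        for t in (0.1, 0.3, 0.5, 0.7, 0.9):
            cur = pp.binarize(suit, t).cells
            if prev is not None:
                assert not (cur & ~prev).any()
            prev = cur


class TestMasksAndRestriction:
    def test_all_forest_unchanged(self):
        br = make_range([[1, 0], [1, 1]])
        lc = LandCoverGrid(np.ones((2, 2), int), frozenset({1}))
        assert np.array_equal(pp.apply_forest_mask(br, lc).cells, br.cells)

    def test_no_forest_empties_range(self):
        br = make_range([[1, 1], [1, 1]])
        lc = LandCoverGrid(np.full((2, 2), 2), frozenset({1}))
        assert pp.apply_forest_mask(br, lc).is_empty

    def test_masked_area_never_grows(self, rng, landcover):
        br = make_range(rng.random((50, 50)) < 0.4)
        assert pp.apply_forest_mask(br, landcover).area_km2 <= br.area_km2

    def test_restrict_future_subset_unchanged(self):
        present = make_range([[1, 1], [1, 0]])
        future = make_range([[1, 0], [0, 0]], scenario="future-optimistic")
        out = pp.restrict_future_to_present(future, present)
        assert np.array_equal(out.cells, future.cells)

    def test_restrict_disjoint_is_empty(self):
        present = make_range([[1, 0]])
        future = make_range([[0, 1]], scenario="f")
        assert pp.restrict_future_to_present(future, present).is_empty

    def test_restrict_result_subset_of_both(self, rng):
        present = make_range(rng.random((8, 8)) < 0.5)
        future = make_range(rng.random((8, 8)) < 0.5, scenario="f")
        out = pp.restrict_future_to_present(future, present)
        assert not (out.cells & ~present.cells).any()
        assert not (out.cells & ~future.cells).any()


class TestAreaChange:
    def test_loss(self):
        # present 4 cells x 25 km2 = 100 km2; future 1 cell x 20 km2 = 20 km2
        present = pp.BinaryRange("t", "present", np.ones((4, 1), bool), 0.5, 25.0)
        future = pp.BinaryRange("t", "f", np.array([[1], [0], [0], [0]], dtype=bool), 0.5, 20.0)
        out = pp.area_change(present, future)
        assert out["pct_change"] == pytest.approx(-80.0)
        assert not out["total_loss"]

    def test_complete_loss_flagged(self):
        present = pp.BinaryRange("t", "present", np.ones((2, 2), bool), 0.5)
        future = pp.BinaryRange("t", "f", np.zeros((2, 2), bool), 0.5)
        out = pp.area_change(present, future)
        assert out["pct_change"] == -100.0
        assert out["total_loss"]

    def test_no_change_and_zero_present_rejected(self):
        r = pp.BinaryRange("t", "present", np.ones((2, 2), bool), 0.5)
        assert pp.area_change(r, r)["pct_change"] == 0.0
        empty = pp.BinaryRange("t", "present", np.zeros((2, 2), bool), 0.5)
        with pytest.raises(ValueError, match="zero"):
            pp.area_change(empty, r)


class TestRichness:
    def test_two_identical_single_cell_ranges(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        rm = pp.stack_richness([make_range(m, "a"), make_range(m, "b")])
        assert rm.richness[1, 1] == 2
        assert rm.richness.sum() == 2

    def test_empty_list_zero_map(self):
        rm = pp.stack_richness([], grid_shape=(4, 4))
        assert (rm.richness == 0).all()

    def test_double_counting_identity_and_order_invariance(self, rng):
        ranges = [make_range(rng.random((10, 10)) < 0.3, f"t{i}") for i in range(6)]
        rm = pp.stack_richness(ranges)
        assert rm.richness.sum() == sum(r.n_cells for r in ranges)
        rm2 = pp.stack_richness(ranges[::-1])
        assert np.array_equal(rm.richness, rm2.richness)

    def test_mixed_scenarios_rejected(self):
        a = make_range([[1]], scenario="present")
        b = make_range([[1]], scenario="future-optimistic")
        with pytest.raises(ValueError, match="scenario"):
            pp.stack_richness([a, b])
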