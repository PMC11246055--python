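"""Region proposal constraints and blockwise masking behaviour."""

import numpy as np
import pytest

from slidemae.sampling import (
    MaskPlan,
    apply_mask,
    blockwise_mask,
    propose_regions,
    systematic_regions,
)
from slidemae.store import SlideFeatureSet


def _slide_from_mask(fg: np.ndarray, d: int = 4) -> SlideFeatureSet:
    ys, xs = np.nonzero(fg)
    rng = np.random.default_rng(0)
    return SlideFeatureSet(
        slide_id="m",
        magnification_tag="10x",
        patch_size_px=224,
        grid_shape=fg.shape,
        features=rng.standard_normal((len(ys), d)).astype(np.float32),
        coords=np.column_stack([xs, ys]),
    )


class TestProposeRegions:
    def test_single_dense_block_is_found(self):
        fg = np.zeros((8, 8), dtype=bool)
        fg[2:6, 3:7] = True  # one 4x4 fully-foreground block
        fset = _slide_from_mask(fg)
        regions = propose_regions(fset, n=4, count=1, rng_seed=0)
        assert len(regions) == 1
        assert regions[0].grid.foreground_fraction >= 0.25

    def test_25_percent_boundary(self):
        # a 4x4 window with exactly 4 foreground cells is admissible (25%);
        # one with 3 cells (18.75%) never is
        fg = np.zeros((4, 4), dtype=bool)
        fg[0, :4] = True
        fset = _slide_from_mask(fg)
        regions = propose_regions(fset, n=4, count=1, rng_seed=1)
        assert len(regions) == 1
        fg3 = np.zeros((4, 4), dtype=bool)
        fg3[0, :3] = True
        with pytest.raises(ValueError, match="25%"):
            propose_regions(_slide_from_mask(fg3), n=4, count=1, rng_seed=1)

    def test_shortfall_returns_fewer_with_warning(self):
        fg = np.ones((4, 4), dtype=bool)  # only one possible window
        fset = _slide_from_mask(fg)
        with pytest.warns(UserWarning, match="1/2"):
            regions = propose_regions(fset, n=4, count=2, max_overlap=0.5, rng_seed=0)
        assert len(regions) == 1

    def test_zero_overlap_cap_gives_disjoint_windows(self):
        fg = np.ones((12, 12), dtype=bool)
        fset = _slide_from_mask(fg)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions = propose_regions(fset, n=4, count=6, max_overlap=0.0, rng_seed=3)
        assert len(regions) >= 2
        for i, a in enumerate(regions):
            for b in regions[i + 1 :]:
                ox = max(0, min(a.origin[0] + 4, b.origin[0] + 4) - max(a.origin[0], b.origin[0]))
                oy = max(0, min(a.origin[1] + 4, b.origin[1] + 4) - max(a.origin[1], b.origin[1]))
                assert ox * oy == 0

    def test_deterministic_given_seed(self):
        fg = np.ones((10, 10), dtype=bool)
        fset = _slide_from_mask(fg)
        a = propose_regions(fset, n=4, count=3, rng_seed=7)
        b = propose_regions(fset, n=4, count=3, rng_seed=7)
        assert [r.origin for r in a] == [r.origin for r in b]

    def test_systematic_raster_respects_overlap(self):
        fg = np.ones((12, 12), dtype=bool)
        fset = _slide_from_mask(fg)
        regions = systematic_regions(fset, n=4, max_overlap=0.5)
        origins = [r.origin for r in regions]
        assert origins == sorted(set(origins), key=origins.index)
        assert all(o[0] % 2 == 0 for o in origins)


class TestBlockwiseMask:
    def test_rate_window_for_various_p(self):
        fg = np.ones((20, 20), dtype=bool)
        for p in (0.25, 0.5, 0.75):
            for seed in range(20):
                plan = blockwise_mask(fg, p, rng_seed=seed)
                assert abs(plan.achieved_rate - p) <= 0.05 + 1e-12

    def test_tiny_p_masks_almost_nothing(self):
        fg = np.ones((20, 20), dtype=bool)
        plan = blockwise_mask(fg, 0.01, rng_seed=0)
        assert plan.masked.sum() <= np.floor(0.06 * 400)

    def test_mean_rate_over_seeds_close_to_p(self):
        fg = np.ones((20, 20), dtype=bool)
        rates = [blockwise_mask(fg, 0.5, rng_seed=s).achieved_rate for s in range(100)]
        assert abs(np.mean(rates) - 0.5) < 0.02

    def test_p_out_of_range_errors(self):
        fg = np.ones((4, 4), dtype=bool)
        for p in (0.0, 1.0, -0.1, 1.3):
            with pytest.raises(ValueError):
                blockwise_mask(fg, p)

    def test_deterministic_given_seed(self):
        fg = np.ones((16, 16), dtype=bool)
        a = blockwise_mask(fg, 0.4, rng_seed=5)
        b = blockwise_mask(fg, 0.4, rng_seed=5)
        np.testing.assert_array_equal(a.masked, b.masked)

    def test_loss_positions_are_masked_and_foreground(self):
        fg = np.zeros((10, 10), dtype=bool)
        fg[:, :5] = True
        plan = blockwise_mask(fg, 0.5, rng_seed=2)
        lp = plan.loss_positions(fg)
        assert (lp <= plan.masked).all() and (lp <= fg).all()

    def test_per_cell_frequency_unbiased(self):
        """No cell is preferentially masked across many seeds."""
        fg = np.zeros((20, 20), dtype=bool)
        fg[:, :10] = True  # half-foreground grid
        p = 0.5
        freq = np.zeros((20, 20))
        n_seeds = 200
        for s in range(n_seeds):
            freq += blockwise_mask(fg, p, rng_seed=s).masked
        freq /= n_seeds
        assert np.abs(freq - p).max() <= 0.05 + 3 * np.sqrt(p * (1 - p) / n_seeds)


class TestApplyMask:
    def _grid(self, n=4, d=3):
        fg = np.ones((n, n), dtype=bool)
        fg[0, 0] = False
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((n, n, d))
        feats[0, 0] = 0.0
        from slidemae.store import PatchGrid

        return PatchGrid(origin=(0, 0), n=n, features=feats, foreground=fg)

    def test_empty_plan_is_identity(self):
        grid = self._grid()
        plan = MaskPlan(np.zeros((4, 4), dtype=bool), 0.5, 0.0)
        out = apply_mask(grid, plan, np.ones(3))
        np.testing.assert_array_equal(out, grid.features)

    def test_full_plan_puts_token_on_every_foreground_cell(self):
        grid = self._grid()
        token = np.array([9.0, 8.0, 7.0])
        plan = MaskPlan(np.ones((4, 4), dtype=bool), 0.5, 1.0)
        out = apply_mask(grid, plan, token)
        for y in range(4):
            for x in range(4):
                if grid.foreground[y, x]:
                    np.testing.assert_array_equal(out[y, x], token)
                else:
                    assert (out[y, x] == 0).all()

    def test_single_cell_changes_exactly_one_row(self):
        grid = self._grid()
        masked = np.zeros((4, 4), dtype=bool)
        masked[2, 3] = True
        out = apply_mask(grid, MaskPlan(masked, 0.1, 1 / 16), np.full(3, 5.0))
        diff = (out != grid.features).any(axis=-1)
        assert diff.sum() == 1 and diff[2, 3]
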