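import numpy as np
import pytest

from cobaltqa import FluenceMap, GridSpec, LeafPair, Segment, generate_plan
from cobaltqa.fluence import (
    aperture_open_area,
    compose_fluence,
    fluence_compare,
    rasterize_aperture,
)

from conftest import supersample_pixel


def _pairs(left, right):
    return [LeafPair(pair_index=i, left_x=left, right_x=right) for i in range(1, 31)]


def _segment(index, time, left=-5.0, right=5.0):
    return Segment(segment_index=index, beam_on_time=time, leaf_pairs=_pairs(left, right))


GRID = GridSpec()  # 1 mm, 31.5 cm square


class TestRasterize:
    def test_fully_open_interior_pixel_is_one(self):
        cov = rasterize_aperture(_pairs(-5.0, 5.0), GRID)
        # pixel at the isocenter axis
        assert cov[GRID.ny // 2, GRID.nx // 2] == pytest.approx(1.0)

    def test_all_closed_is_zero(self):
        cov = rasterize_aperture(_pairs(1.0, 1.0), GRID)
        assert np.all(cov == 0.0)

    def test_pixel_straddling_leaf_tip_gets_half_coverage(self):
        # with the default grid, pixel centers sit on multiples of 1 mm, so a
        # tip at x = 2.00 cm bisects the pixel centered there
        cov = rasterize_aperture(_pairs(-5.0, 2.0), GRID)
        col = int(np.searchsorted(GRID.x_edges(), 1.999)) - 1
        assert cov[GRID.ny // 2, col] == pytest.approx(0.5, abs=1e-9)

    def test_grid_smaller_than_leaf_stack_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(spacing=0.1, x_extent=10.0, y_extent=10.0, leaf_width=1.05)

    @pytest.mark.parametrize("seed", [3, 11])
    def test_agrees_with_supersampling_oracle(self, seed):
        """Area-weighted coverage matches a 0.01 mm point-sampling oracle."""
        plan = generate_plan(seed, n_groups=1, beams_per_group=1, segments_per_beam=2)
        rng = np.random.default_rng(seed)
        for seg in plan.beams[0].segments:
            cov = rasterize_aperture(seg.leaf_pairs, GRID)
            for _ in range(40):
                r = int(rng.integers(0, GRID.ny))
                c = int(rng.integers(0, GRID.nx))
                oracle = supersample_pixel(seg.leaf_pairs, GRID, r, c)
                assert cov[r, c] == pytest.approx(oracle, abs=1e-2)


class TestCompose:
    def test_linearity_over_segment_times(self):
        segs = [_segment(1, 3.0), _segment(2, 7.0)]
        f = compose_fluence(segs, GRID)
        assert f.values[GRID.ny // 2, GRID.nx // 2] == pytest.approx(10.0)
        doubled = [_segment(1, 6.0), _segment(2, 14.0)]
        f2 = compose_fluence(doubled, GRID)
        assert np.allclose(f2.values, 2.0 * f.values)

    def test_zero_time_gives_zero_map(self):
        f = compose_fluence([_segment(1, 0.0)], GRID)
        assert np.all(f.values == 0.0)

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValueError):
            compose_fluence([], GRID)

    def test_conservation_against_analytic_open_area(self):
        """Map integral equals sum_k t_k * open-area(k) from leaf coordinates."""
        segs = [
            _segment(1, 4.0, left=-3.0, right=2.0),
            _segment(2, 9.0, left=-1.0, right=4.5),
        ]
        f = compose_fluence(segs, GRID)
        integral = f.values.sum() * GRID.pixel_area
        analytic = sum(
            s.beam_on_time * aperture_open_area(s.leaf_pairs, GRID) for s in segs
        )
        assert integral == pytest.approx(analytic, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_apertures(self, seed):
        plan = generate_plan(seed, n_groups=1, beams_per_group=1, segments_per_beam=3)
        for seg in plan.beams[0].segments:
            cov = rasterize_aperture(seg.leaf_pairs, GRID)
            assert cov.sum() * GRID.pixel_area == pytest.approx(
                aperture_open_area(seg.leaf_pairs, GRID), rel=1e-3
            )


class TestCompare:
    def _map(self, values, grid):
        return FluenceMap(values=values, grid=grid)

    def test_identical_maps_pass_everywhere(self, coarse_grid):
        vals = np.full((coarse_grid.ny, coarse_grid.nx), 10.0)
        stats = fluence_compare(self._map(vals, coarse_grid), self._map(vals.copy(), coarse_grid))
        assert stats.pass_rate == 100.0
        assert stats.mean_diff == 0.0 and stats.max_diff == 0.0 and stats.sd_diff == 0.0
        assert stats.n_evaluated == coarse_grid.nx * coarse_grid.ny

    def test_uniform_three_percent_shift_fails_everywhere(self, coarse_grid):
        plan = np.full((coarse_grid.ny, coarse_grid.nx), 10.0)
        delivered = plan + 0.03 * plan.max()
        stats = fluence_compare(self._map(plan, coarse_grid), self._map(delivered, coarse_grid))
        assert stats.pass_rate == 0.0

    def test_checkerboard_half_shift_gives_fifty_percent(self, coarse_grid):
        """Pixel-count oracle: shifting exactly half the evaluated pixels by
        3% of max must yield a 50% pass rate."""
        plan = np.full((coarse_grid.ny, coarse_grid.nx), 10.0)
        shift = np.indices(plan.shape).sum(axis=0) % 2 == 0
        delivered = plan + shift * (0.03 * plan.max())
        stats = fluence_compare(self._map(plan, coarse_grid), self._map(delivered, coarse_grid))
        expected = 100.0 * np.count_nonzero(~shift) / plan.size
        assert stats.pass_rate == pytest.approx(expected)
        assert stats.pass_rate == pytest.approx(50.0, abs=0.2)

    def test_low_intensity_pixels_ignored(self, coarse_grid):
        plan = np.full((coarse_grid.ny, coarse_grid.nx), 0.5)
        plan[10:20, 10:20] = 10.0  # only this block exceeds 10% of max
        delivered = plan + 5.0  # huge error everywhere
        stats = fluence_compare(self._map(plan, coarse_grid), self._map(delivered, coarse_grid))
        assert stats.n_evaluated == 100
        assert stats.pass_rate == 0.0

    def test_subthreshold_constant_shift_keeps_pass_rate(self, coarse_grid):
        plan = np.full((coarse_grid.ny, coarse_grid.nx), 10.0)
        delivered = plan + 0.019 * plan.max()  # just under the 2% criterion
        stats = fluence_compare(self._map(plan, coarse_grid), self._map(delivered, coarse_grid))
        assert stats.pass_rate == 100.0

    def test_all_zero_plan_yields_undefined_pass_rate(self, coarse_grid):
        zeros = np.zeros((coarse_grid.ny, coarse_grid.nx))
        stats = fluence_compare(self._map(zeros, coarse_grid), self._map(zeros.copy(), coarse_grid))
        assert stats.pass_rate is None and stats.n_evaluated == 0

    def test_mismatched_grids_rejected(self, coarse_grid):
        a = self._map(np.ones((coarse_grid.ny, coarse_grid.nx)), coarse_grid)
        b = FluenceMap(values=np.ones((GRID.ny, GRID.nx)), grid=GRID)
        with pytest.raises(ValueError):
            fluence_compare(a, b)
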