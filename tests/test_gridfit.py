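"""Corner detection, alley-aware bilinear interpolation and maxima snapping."""

import numpy as np
import pytest

from cytoblot.gridfit import (
    CornerDetectionError,
    detect_corners,
    interpolate_grid,
    read_grid_tsv,
    snap_to_maxima,
    write_grid_tsv,
)
from cytoblot.imaging import MaximaSet, find_local_maxima, gaussian_blur
from cytoblot.layout import ArrayLayout
from cytoblot.pipeline import quantify_membrane
from cytoblot.simulate import SimulationConfig, simulate_membrane


def maxima(points):
    return MaximaSet(np.array([(x, y, v) for x, y, v in points], float), 0.0, 5.0)


def block_layout(n_block=1, size=4, alley=0.0, pitch=10.0) -> ArrayLayout:
    positions = tuple(
        (br, bc, r, c, "", "empty")
        for br in range(n_block) for bc in range(n_block)
        for r in range(size) for c in range(size)
    )
    return ArrayLayout(
        name="grid", n_block_rows=n_block, n_block_cols=n_block,
        rows_per_block=size, cols_per_block=size, pitch=pitch,
        alley_row=alley, alley_col=alley, spot_radius=pitch / 4,
        positions=positions,
    )


class TestDetectCorners:
    def test_axis_aligned_rectangle_assigned_in_order(self):
        pts = maxima([(5, 5, 1), (55, 5, 1), (5, 45, 1), (55, 45, 1)])
        tl, tr, bl, br = detect_corners(pts, (50, 60), None)
        assert (tl, tr, bl, br) == ((5, 5), (55, 5), (5, 45), (55, 45))

    def test_missing_quadrant_named(self):
        pts = maxima([(5, 5, 1), (55, 5, 1), (5, 45, 1)])
        with pytest.raises(CornerDetectionError, match="BR"):
            detect_corners(pts, (50, 60), None)

    def test_brightest_of_nearest_three_wins(self):
        # a dim point sits closest to the TL image corner; a bright one nearby
        pts = maxima([(3, 3, 1), (8, 8, 50), (55, 5, 1), (5, 45, 1), (55, 45, 1)])
        tl, *_ = detect_corners(pts, (50, 60), None)
        assert tl == (8, 8)

    def test_simulated_reference_spots_recovered(self, clean_membrane):
        cfg, img, truth = clean_membrane
        blurred = gaussian_blur(img, 4.0)
        mx = find_local_maxima(blurred, prominence=50.0, min_separation=9.0)
        corners = detect_corners(mx, (img.height, img.width), cfg.layout)
        for found, true in zip(corners, truth.corners_true):
            assert np.hypot(found[0] - true[0], found[1] - true[1]) <= 1.0


class TestInterpolateGrid:
    CORNERS = ((0.0, 0.0), (30.0, 0.0), (0.0, 30.0), (30.0, 30.0))

    def test_single_block_linear_spacing(self):
        grid = interpolate_grid(self.CORNERS, block_layout(1, 4))
        assert len(grid.entries) == 16
        x, y, prov = grid.entries[(0, 0, 1, 2)]
        assert (x, y) == (20.0, 10.0)
        assert prov == "interpolated"

    def test_alley_doubles_inter_block_gap(self):
        lay = block_layout(2, 2, alley=1.0)
        grid = interpolate_grid(self.CORNERS, lay)
        xs = sorted({v[0] for v in grid.entries.values()})
        # columns at unit coords 0,1,3,4 scaled onto [0,30]
        np.testing.assert_allclose(xs, [0.0, 7.5, 22.5, 30.0])
        intra = xs[1] - xs[0]
        inter = xs[2] - xs[1]
        assert inter == pytest.approx(2 * intra)

    def test_sheared_corners_match_bilinear_oracle(self, rng):
        tl, tr = np.array([5.0, 3.0]), np.array([65.0, 8.0])
        bl, br = tl + [12.0, 50.0], tr + [12.0, 50.0]  # parallelogram
        lay = block_layout(2, 3, alley=0.5)
        grid = interpolate_grid((tuple(tl), tuple(tr), tuple(bl), tuple(br)), lay)
        # per axis: block offset = size + alley; span = offset + (size - 1)
        offset = 3 + 0.5
        total = offset + 2
        for (br_, bc, r, c), (x, y, _p) in grid.entries.items():
            u = (bc * offset + c) / total
            v = (br_ * offset + r) / total
            expect = (
                (1 - u) * (1 - v) * tl + u * (1 - v) * tr
                + (1 - u) * v * bl + u * v * br
            )
            np.testing.assert_allclose((x, y), expect, atol=1e-9)
        # rows of a parallelogram warp stay parallel
        row0 = [grid.entries[(0, 0, 0, c)][:2] for c in range(3)]
        row1 = [grid.entries[(0, 0, 1, c)][:2] for c in range(3)]
        d0 = np.subtract(row0[1], row0[0])
        d1 = np.subtract(row1[1], row1[0])
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_translation_and_scale_equivariance(self):
        lay = block_layout(2, 3, alley=1.0)
        base = interpolate_grid(self.CORNERS, lay)
        shifted = interpolate_grid(
            tuple((x * 2 + 7, y * 2 - 3) for x, y in self.CORNERS), lay
        )
        for k in base.entries:
            bx, by, _ = base.entries[k]
            sx, sy, _ = shifted.entries[k]
            assert (sx, sy) == pytest.approx((bx * 2 + 7, by * 2 - 3))

    def test_collinear_corners_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            interpolate_grid(((0, 0), (10, 0), (20, 0), (30, 0)), block_layout())


class TestSnapToMaxima:
    def test_exact_maxima_snap_without_displacement(self):
        lay = block_layout(1, 2)
        grid = interpolate_grid(((0, 0), (10, 0), (0, 10), (10, 10)), lay)
        pts = maxima([(x, y, 1.0) for x, y, _ in grid.entries.values()])
        snapped = snap_to_maxima(grid, pts, snap_radius=4.0)
        for k in grid.entries:
            assert snapped.entries[k][:2] == grid.entries[k][:2]
            assert snapped.entries[k][2] == "snapped"

    def test_empty_maxima_leaves_grid_interpolated(self):
        lay = block_layout(1, 2)
        grid = interpolate_grid(((0, 0), (10, 0), (0, 10), (10, 10)), lay)
        out = snap_to_maxima(grid, MaximaSet(np.empty((0, 3)), 0, 5), 4.0)
        assert all(v[2] == "interpolated" for v in out.entries.values())
        assert {k: v[:2] for k, v in out.entries.items()} == {
            k: v[:2] for k, v in grid.entries.items()
        }

    def test_one_maximum_serves_at_most_one_entry(self):
        lay = block_layout(1, 2)
        grid = interpolate_grid(((0, 0), (10, 0), (0, 10), (10, 10)), lay)
        # single bright maximum between two grid positions
        pts = maxima([(5.0, 1.0, 9.0)])
        out = snap_to_maxima(grid, pts, snap_radius=6.0)
        snapped = [k for k, v in out.entries.items() if v[2] == "snapped"]
        assert len(snapped) == 1

    def test_idempotent(self):
        lay = block_layout(1, 3)
        grid = interpolate_grid(((0, 0), (20, 0), (0, 20), (20, 20)), lay)
        pts = maxima([(0.5, 0.2, 5.0), (10.3, 0.1, 4.0), (19.8, 20.1, 3.0)])
        once = snap_to_maxima(grid, pts, 2.0)
        twice = snap_to_maxima(once, pts, 2.0)
        assert once.entries == twice.entries

    def test_nonpositive_radius_rejected(self):
        lay = block_layout(1, 2)
        grid = interpolate_grid(((0, 0), (10, 0), (0, 10), (10, 10)), lay)
        with pytest.raises(ValueError):
            snap_to_maxima(grid, MaximaSet(np.empty((0, 3)), 0, 5), 0.0)


class TestGridRecovery:
    def test_missing_spots_fall_back_to_interpolation(self):
        cfg = SimulationConfig(seed=3, missing_spot_prob=0.1)
        img, truth = simulate_membrane(cfg, (1, "F", "ckd"))
        grid, _table = quantify_membrane(img, cfg.layout)
        absent = truth.spots[(~truth.spots.present)
                             & (truth.spots.role != "reference")]
        for t in absent.itertuples():
            key = (t.block_row, t.block_col, t.row, t.col)
            assert grid.entries[key][2] == "interpolated"

    def test_noiseless_recovery_within_half_pixel_for_snapped(self, clean_membrane):
        cfg, img, truth = clean_membrane
        # noise-free image: the MAD-based auto prominence degenerates, so fix it
        grid, _ = quantify_membrane(img, cfg.layout, prominence=10.0)
        sp = truth.spots.set_index(["block_row", "block_col", "row", "col"])
        errs = [
            np.hypot(x - sp.loc[k].true_x, y - sp.loc[k].true_y)
            for k, (x, y, prov) in grid.entries.items()
            if prov == "snapped"
        ]
        assert len(errs) > 90  # all rendered spots found
        assert np.max(errs) <= 0.8  # pixel-grid quantization only

    def test_tsv_roundtrip(self, tmp_path):
        lay = block_layout(1, 3)
        grid = interpolate_grid(((0, 0), (20, 0), (0, 20), (20, 20)), lay)
        path = tmp_path / "grid.tsv"
        write_grid_tsv(grid, path)
        back = read_grid_tsv(path)
        for k, (x, y, prov) in grid.entries.items():
            bx, by, bprov = back.entries[k]
            assert (bx, by) == pytest.approx((x, y))
            assert bprov == prov
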