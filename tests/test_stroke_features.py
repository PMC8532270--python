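"""Hough accumulator: oracle equivalence, vote conservation, group tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paintcog.stroke_features import (
    EdgeMap,
    GroupStrokeModel,
    edge_map,
    hough_accumulator,
    hough_peak,
)
from paintcog.stroke_features import _bin_centers


def brute_force_accumulator(mask, theta_step=1.0, r_step=1.0):
    """Independent oracle: per edge pixel and angle, enumerate every r-bin
    center and take the nearest (first on ties, i.e. the smaller r),
    counting line membership.  Uses the same 1e-9 px quantization of r as
    the accumulator so halfway ties are well-defined."""
    r_bins, theta_bins = _bin_centers(mask.shape, theta_step, r_step)
    H = np.zeros((len(r_bins), len(theta_bins)), dtype=np.int64)
    ys, xs = np.nonzero(mask)
    for x, y in zip(xs, ys):
        for j, theta in enumerate(theta_bins):
            t = np.deg2rad(theta)
            r = round(x * np.cos(t) + y * np.sin(t), 9)
            i = int(np.argmin(np.abs(r_bins - r)))
            H[i, j] += 1
    return H, r_bins, theta_bins


class TestEdgeMap:
    def test_uniform_image_has_no_edges(self):
        img = np.full((16, 16, 3), 255, dtype=np.uint8)
        assert edge_map(img).n_edges == 0

    def test_vertical_split_band(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        img[:, 10:] = 255
        em = edge_map(img)
        cols = np.unique(np.nonzero(em.mask)[1])
        assert em.n_edges > 0
        assert set(cols) <= {9, 10, 11}  # boundary columns only

    def test_rendered_stroke_edge_count(self, tiny_cohort):
        sid = next(iter(tiny_cohort.images))
        em = edge_map(tiny_cohort.images[sid])
        # outlines + strokes produce many more edges than one stroke length
        assert em.n_edges >= tiny_cohort.profiles[sid].stroke_params.mean_length


class TestAccumulator:
    def test_single_pixel_sinusoid(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[4, 7] = 1
        grid = hough_accumulator(EdgeMap(mask))
        assert np.all(grid.H.sum(axis=0) == 1)  # one vote per theta column

    def test_empty_map_all_zero(self):
        grid = hough_accumulator(EdgeMap(np.zeros((8, 8), dtype=np.uint8)))
        assert grid.total_votes == 0
        assert hough_peak(grid) is None

    def test_horizontal_line_peak(self):
        """20 collinear pixels on row y=5: peak of 20 votes at |theta|=90, |r|=5."""
        mask = np.zeros((12, 24), dtype=np.uint8)
        mask[5, 2:22] = 1
        grid = hough_accumulator(EdgeMap(mask))
        r, theta, votes = hough_peak(grid)
        assert votes == 20
        assert abs(theta) == 90.0 and abs(r) == 5.0

    def test_longer_of_two_orthogonal_lines_wins(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[3, 1:31] = 1   # horizontal, length 30
        mask[5:15, 8] = 1   # vertical, length 10
        grid = hough_accumulator(EdgeMap(mask))
        r, theta, votes = hough_peak(grid)
        assert votes == 30 and abs(theta) == 90.0 and abs(r) == 3.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=10)
    def test_vote_conservation_random(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((12, 14)) < 0.15).astype(np.uint8)
        grid = hough_accumulator(EdgeMap(mask), theta_step=5.0, r_step=2.0)
        assert grid.total_votes == mask.sum() * len(grid.theta_bins)

    def test_oracle_equivalence_small_fixtures(self):
        """Accumulator equals the brute-force line-membership oracle exactly."""
        rng = np.random.default_rng(42)
        fixtures = []
        m = np.zeros((9, 9), dtype=np.uint8)
        m[4, 1:8] = 1
        fixtures.append((m, 1.0, 1.0))
        m = np.eye(16, dtype=np.uint8)
        fixtures.append((m, 1.0, 1.0))
        for _ in range(4):
            fixtures.append(((rng.random((32, 32)) < 0.08).astype(np.uint8), 1.0, 1.0))
        fixtures.append(((rng.random((24, 31)) < 0.1).astype(np.uint8), 3.0, 2.0))
        for mask, ts, rs in fixtures:
            grid = hough_accumulator(EdgeMap(mask), ts, rs)
            H_ref, r_ref, t_ref = brute_force_accumulator(mask, ts, rs)
            assert np.array_equal(grid.r_bins, r_ref)
            assert np.array_equal(grid.theta_bins, t_ref)
            assert np.array_equal(grid.H, H_ref)

    def test_peak_recovery_for_rendered_lines(self):
        """A noiseless line of length L yields a peak of L votes within one bin."""
        from skimage.draw import line

        cases = [((5, 2), (5, 25)), ((3, 8), (28, 8)), ((2, 2), (21, 21))]
        for (r0, c0), (r1, c1) in cases:
            mask = np.zeros((32, 32), dtype=np.uint8)
            rr, cc = line(r0, c0, r1, c1)
            mask[rr, cc] = 1
            L = len(rr)
            grid = hough_accumulator(EdgeMap(mask))
            _, _, votes = hough_peak(grid)
            assert L - 2 <= votes <= L


class TestGroupStroke:
    def test_identical_grids_give_zero_t(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3, 2:8] = 1
        g = hough_accumulator(EdgeMap(mask))
        res = GroupStrokeModel([g, g, g, g], [0, 0, 1, 1]).fit()
        assert not res.mask_p.any()
        assert np.all(np.isnan(res.tstat) | (res.tstat == 0))

    def test_mismatched_grids_rejected(self):
        a = hough_accumulator(EdgeMap(np.zeros((10, 10), dtype=np.uint8)))
        b = hough_accumulator(EdgeMap(np.zeros((12, 12), dtype=np.uint8)))
        with pytest.raises(ValueError):
            GroupStrokeModel([a, a, b, b], [0, 0, 1, 1])

    def test_central_stroke_effect_located_at_small_r(self, tiny_cohort):
        """Patients' central strokes make significant cells cluster at small |r|."""
        ids = [s.id for s in tiny_cohort.subjects]
        grids = [hough_accumulator(edge_map(tiny_cohort.images[i]), 2.0, 2.0)
                 for i in ids]
        res = GroupStrokeModel(grids, tiny_cohort.labels()).fit(p_threshold=0.01)
        sig_r, _ = np.nonzero(res.mask_p)
        assert len(sig_r) > 0
        r_sig = np.abs(res.r_bins[sig_r])
        # center of a 64x64 canvas projects to |r| well below the diagonal
        assert np.median(r_sig) < 0.75 * np.abs(res.r_bins).max()

    def test_null_calibration_gaussian_cells(self):
        """Identical group distributions reject at ~nominal alpha per cell."""
        rng = np.random.default_rng(5)
        X = rng.normal(100, 12, (24, 1500))
        labels = np.array([0] * 12 + [1] * 12)

        class FakeGrid:
            def __init__(self, row):
                self.H = row.reshape(30, 50)
                self.r_bins = np.arange(30)
                self.theta_bins = np.arange(50)

        grids = [FakeGrid(x) for x in X]
        res = GroupStrokeModel(grids, labels).fit()
        rate = float(np.mean(res.pvalue < 0.05))
        se = np.sqrt(0.05 * 0.95 / res.pvalue.size)
        assert abs(rate - 0.05) < 5 * se
        # and essentially nothing survives the strict threshold
        assert res.mask_p.mean() < 0.005
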