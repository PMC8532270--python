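"""Synthetic cohort generator: determinism, effect realization, round trips."""

import numpy as np
import pytest
from scipy import ndimage

from paintcog.color_features import color_histogram, colors_used, quantize_rgb
from paintcog.synthetic import (
    DEFAULT_PALETTE,
    CohortConfig,
    ColorEffect,
    PaletteSpec,
    PanssModel,
    StrokeParams,
    TemplatePlacementError,
    assign_panss,
    generate_cohort,
    make_template,
    read_cohort,
    render_painting,
    sample_subject,
    write_cohort,
)


class TestPalette:
    def test_default_palette_valid(self):
        assert len(DEFAULT_PALETTE.colors) == 12
        assert len(set(DEFAULT_PALETTE.bins)) == 12
        assert 0 not in DEFAULT_PALETTE.bins and 63 not in DEFAULT_PALETTE.bins

    def test_duplicate_bin_rejected(self):
        colors = list(DEFAULT_PALETTE.colors)
        colors[1] = ("red2", (210, 50, 50))  # same cell as red
        with pytest.raises(ValueError):
            PaletteSpec(colors=tuple(colors))


class TestTemplate:
    def test_single_region_and_determinism(self):
        a = make_template((128, 128), 1, seed=7)
        b = make_template((128, 128), 1, seed=7)
        assert len(a.regions) == 1
        assert a.outline_mask.sum() > 0
        assert np.array_equal(a.outline_mask, b.outline_mask)
        img = a.render_blank()
        vals = set(np.unique(quantize_rgb(img[..., 0], img[..., 1], img[..., 2])))
        assert vals == {0, 63}  # outline + background only

    def test_five_regions_disjoint_by_flood_fill(self):
        """Connected-component labeling finds exactly n_regions interiors."""
        t = make_template((128, 128), 5, seed=1)
        interior = ~t.outline_mask.astype(bool)
        labels, n = ndimage.label(interior)
        # background is one component; each region interior another
        sizes = np.bincount(labels.ravel())[1:]
        inner = [m.sum() for m in t.interior_masks()]
        assert n == 6
        assert sorted(sizes)[:5] == sorted(inner)

    def test_impossible_placement_raises(self):
        with pytest.raises(TemplatePlacementError):
            make_template((64, 64), 200, seed=0)


class TestSampleSubject:
    def test_configured_color_effect_recovered(self):
        """Monte-Carlo means of n_colors match the configured group gap."""
        cfg = CohortConfig(color_effect=ColorEffect(hc_mean=9, scz_mean=5, sd=1.5))
        rng = np.random.default_rng(0)
        hc = [sample_subject("HC", cfg, rng).n_colors for _ in range(1000)]
        scz = [sample_subject("SCZ", cfg, rng).n_colors for _ in range(1000)]
        gap = np.mean(hc) - np.mean(scz)
        se = np.sqrt(np.var(hc) / 1000 + np.var(scz) / 1000)
        assert abs(gap - 4.0) < max(3 * se, 0.25)
        assert all(1 <= v <= 12 for v in hc + scz)

    def test_missing_prob_zero_gives_full_panss(self):
        cfg = CohortConfig(panss_model=PanssModel(missing_prob=0.0))
        rng = np.random.default_rng(1)
        assert all(sample_subject("SCZ", cfg, rng).panss is not None
                   for _ in range(50))

    def test_missing_count_binomial_band(self):
        """With the study's missing rate, 281 draws lose ~37 subjects."""
        cfg = CohortConfig()  # default missing_prob = 37/281
        rng = np.random.default_rng(2)
        missing = sum(sample_subject("SCZ", cfg, rng).panss is None
                      for _ in range(281))
        p = 37 / 281
        sd = np.sqrt(281 * p * (1 - p))
        assert abs(missing - 37) < 3 * sd


class TestAssignPanss:
    def _profile(self):
        return sample_subject("SCZ", CohortConfig(), np.random.default_rng(3))

    def test_minimum_clipping(self):
        model = PanssModel(weights={k: (-1000.0, (0, 0, 0, 0)) for k in "PNG"},
                           noise_sd=0.0, missing_prob=0.0)
        s = assign_panss(self._profile(), [5, 20, 30, 0.5], model,
                         np.random.default_rng(0))
        assert (s.p, s.n, s.g, s.total) == (7, 7, 16, 30)

    def test_maximum_clipping(self):
        model = PanssModel(weights={k: (1000.0, (0, 0, 0, 0)) for k in "PNG"},
                           noise_sd=0.0, missing_prob=0.0)
        s = assign_panss(self._profile(), [5, 20, 30, 0.5], model,
                         np.random.default_rng(0))
        assert (s.p, s.n, s.g, s.total) == (49, 49, 112, 210)

    def test_weight_recovery_by_least_squares(self):
        """Zero-noise scores refit by OLS recover the configured weights."""
        w = (20.0, (-0.8, -0.1, 0.05, 4.0))
        model = PanssModel(weights={"P": w, "N": w, "G": (30.0, (0.0, 0.0, 0.05, 2.0))},
                           noise_sd=0.0, missing_prob=0.0)
        rng = np.random.default_rng(4)
        X, y = [], []
        for _ in range(500):
            f = np.array([rng.uniform(3, 11), rng.uniform(15, 50),
                          rng.uniform(5, 60), rng.uniform(0, 1)])
            s = assign_panss(self._profile(), f, model, rng)
            X.append(np.r_[1.0, f])
            y.append(s.p)
        beta, *_ = np.linalg.lstsq(np.array(X), np.array(y), rcond=None)
        expected = np.r_[w[0], w[1]]
        # rounding to integer scores adds quantization error only
        assert np.allclose(beta, expected, rtol=0.05, atol=0.12)


class TestRender:
    def test_single_color_painting(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        prof = sample_subject("SCZ", cfg, rng)
        prof = type(prof)(**{**prof.__dict__, "n_colors": 1})
        t = make_template((96, 96), 3, seed=2)
        img = render_painting(prof, t, DEFAULT_PALETTE, np.random.default_rng(6))
        h = color_histogram(img)
        assert colors_used(h) == 1

    def test_render_determinism(self):
        cfg = CohortConfig()
        t = make_template((96, 96), 3, seed=2)
        prof = sample_subject("HC", cfg, np.random.default_rng(7))
        a = render_painting(prof, t, DEFAULT_PALETTE, np.random.default_rng(8))
        b = render_painting(prof, t, DEFAULT_PALETTE, np.random.default_rng(8))
        assert np.array_equal(a, b)

    def test_horizontal_strokes_peak_at_horizontal_theta(self):
        """Near-zero dispersion strokes concentrate Hough mass at |theta|=90."""
        from paintcog.stroke_features import edge_map, hough_accumulator

        cfg = CohortConfig()
        prof = sample_subject("HC", cfg, np.random.default_rng(9))
        prof = type(prof)(**{**prof.__dict__,
                             "stroke_params": StrokeParams(40, 0.0, 0.2, 60)})
        t = make_template((96, 96), 3, seed=2)
        img = render_painting(prof, t, DEFAULT_PALETTE, np.random.default_rng(10))
        grid = hough_accumulator(edge_map(img))
        col_max = grid.H.max(axis=0)
        # the strongest column should be the horizontal-line bin theta = -90
        assert grid.theta_bins[int(np.argmax(col_max))] == -90.0


class TestCohort:
    def test_counts_and_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_hc=5, n_scz=7, canvas_size=(64, 64), n_regions=2, seed=3)
        cohort = generate_cohort(cfg)
        assert len(cohort.subjects) == 12 and len(cohort.images) == 12
        out = write_cohort(cohort, tmp_path / "c")
        assert len(list((out / "images").glob("*.png"))) == 12
        back = read_cohort(out)
        assert [s.id for s in back.subjects] == [s.id for s in cohort.subjects]
        for s, t in zip(cohort.subjects, back.subjects):
            for fld in ("group", "age", "sex", "panss_missing"):
                assert getattr(s, fld) == getattr(t, fld)
            if not s.panss_missing:
                assert s.panss_total == t.panss_total
        for sid in cohort.images:
            assert np.array_equal(cohort.images[sid], back.images[sid])

    def test_determinism_and_seed_sensitivity(self):
        cfg = CohortConfig(n_hc=2, n_scz=2, canvas_size=(64, 64), n_regions=2, seed=3)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        c = generate_cohort(CohortConfig(n_hc=2, n_scz=2, canvas_size=(64, 64),
                                         n_regions=2, seed=4))
        for sid in a.images:
            assert np.array_equal(a.images[sid], b.images[sid])
        assert any(not np.array_equal(a.images[s], c.images[s]) for s in a.images)

    def test_panss_bound_safety(self, tiny_cohort):
        for s in tiny_cohort.subjects:
            if s.panss_missing:
                assert np.isnan(s.panss_total)
            else:
                assert 7 <= s.panss_p <= 49
                assert 7 <= s.panss_n <= 49
                assert 16 <= s.panss_g <= 112
                assert s.panss_total == s.panss_p + s.panss_n + s.panss_g

    def test_config_json_roundtrip(self):
        cfg = CohortConfig(n_hc=3, n_scz=4, seed=9)
        back = CohortConfig.from_json(cfg.to_json())
        assert back == cfg
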