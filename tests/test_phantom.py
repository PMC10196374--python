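"""Simulator checks: determinism, geometric invariants, compositing exactness."""

import numpy as np
import pytest
from dataclasses import replace

from lashgan.phantom import (
    EyelashConfig,
    PhantomConfig,
    PhantomConfigError,
    Stroke,
    artifact_background_region,
    build_paired_dataset,
    build_unpaired_dataset,
    composite_artifact,
    derive_seed,
    generate_fundus_phantom,
    render_artifact_layer,
    sample_eyelash_strokes,
)


class TestFundusPhantom:
    def test_deterministic_per_seed(self, small_phantom_cfg):
        a = generate_fundus_phantom(small_phantom_cfg, 7)
        b = generate_fundus_phantom(small_phantom_cfg, 7)
        np.testing.assert_array_equal(a, b)
        c = generate_fundus_phantom(small_phantom_cfg, 8)
        assert (a != c).any()

    def test_surround_is_near_black(self, small_phantom_cfg):
        img = generate_fundus_phantom(small_phantom_cfg, 0)
        size = small_phantom_cfg.image_size
        c = (size - 1) / 2
        y, x = np.mgrid[0:size, 0:size]
        ax, ay = small_phantom_cfg.fov_axes
        outside = ((x - c) / ax) ** 2 + ((y - c) / ay) ** 2 > 1.0
        assert img[outside].mean() <= 5.0

    def test_vessel_free_noise_free_is_pure_gradient(self, small_phantom_cfg):
        cfg = replace(small_phantom_cfg, vessel_root_count=0,
                      texture_noise_sigma=0.0)
        a = generate_fundus_phantom(cfg, 1)
        b = generate_fundus_phantom(cfg, 2)
        np.testing.assert_array_equal(a, b)  # nothing stochastic remains
        # radially symmetric: left-right mirror equality
        np.testing.assert_array_equal(a, a[:, ::-1])

    def test_deeper_vessels_are_thinner(self):
        # child width = parent width * decay per branching level
        cfg = PhantomConfig(branch_depth=3, vessel_width_root=8.0,
                            vessel_width_decay=0.7)
        assert cfg.vessel_width_root * cfg.vessel_width_decay ** \
            (cfg.branch_depth - 1) == pytest.approx(3.92)
        # stronger decay -> fewer vessel pixels overall
        thin = replace(cfg, vessel_width_decay=0.4)
        n_thick = (generate_fundus_phantom(cfg, 3).mean(-1) < 100).sum()
        n_thin = (generate_fundus_phantom(thin, 3).mean(-1) < 100).sum()
        assert n_thin < n_thick

    def test_invalid_config_names_field(self):
        with pytest.raises(PhantomConfigError, match="fov_axes"):
            PhantomConfig(fov_axes=(300.0, 300.0), image_size=256).validate()
        with pytest.raises(PhantomConfigError, match="image_size"):
            PhantomConfig(image_size=96).validate(downsampling_factor=64)


class TestStrokes:
    def test_count_bounds_and_determinism(self, small_eyelash_cfg):
        cfg = replace(small_eyelash_cfg, stroke_count_range=(20, 40))
        a = sample_eyelash_strokes(cfg, 64, 3)
        b = sample_eyelash_strokes(cfg, 64, 3)
        assert 20 <= len(a) <= 40
        assert len(a) == len(b)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.control_points, t.control_points)

    def test_empty_range_yields_no_strokes(self, small_eyelash_cfg):
        cfg = replace(small_eyelash_cfg, stroke_count_range=(0, 0))
        assert sample_eyelash_strokes(cfg, 64, 0) == []

    def test_roots_on_border(self, small_eyelash_cfg):
        for s in sample_eyelash_strokes(small_eyelash_cfg, 64, 5):
            x, y = s.control_points[0]
            assert x in (0.0, 63.0) or y in (0.0, 63.0)

    def test_zero_curvature_gives_collinear_control_points(self,
                                                           small_eyelash_cfg):
        cfg = replace(small_eyelash_cfg, curvature_range=(0.0, 0.0))
        for s in sample_eyelash_strokes(cfg, 64, 9):
            p0, p1, p2 = s.control_points
            u, v = p1 - p0, p2 - p0
            cross = u[0] * v[1] - u[1] * v[0]
            assert abs(cross) < 1e-6 * np.linalg.norm(p2 - p0) ** 2

    def test_arc_length_within_configured_range(self, small_eyelash_cfg):
        lo, hi = small_eyelash_cfg.length_range
        for s in sample_eyelash_strokes(small_eyelash_cfg, 64, 11):
            assert lo - 1e-6 <= s.arc_length() <= hi + 1e-6

    def test_width_strictly_decreasing_toward_tip(self, small_eyelash_cfg):
        s = sample_eyelash_strokes(small_eyelash_cfg, 64, 2)[0]
        t = np.linspace(0, 1, 20)
        w = s.width(t)
        assert (np.diff(w) < 0).all()

    def test_empty_interval_rejected(self, small_eyelash_cfg):
        with pytest.raises(PhantomConfigError, match="length_range"):
            replace(small_eyelash_cfg, length_range=(10.0, 5.0)).validate()


class TestArtifactLayer:
    def test_no_strokes_no_alpha(self, small_eyelash_cfg):
        alpha, mask = render_artifact_layer([], 64, small_eyelash_cfg)
        assert alpha.max() == 0.0 and not mask.any()

    def test_alpha_clipped_to_unit_interval(self, small_eyelash_cfg):
        strokes = sample_eyelash_strokes(small_eyelash_cfg, 64, 4)
        alpha, _ = render_artifact_layer(strokes, 64, small_eyelash_cfg)
        assert 0.0 <= alpha.min() and alpha.max() <= 1.0

    def test_hard_stroke_mask_matches_rasterization_oracle(self):
        """One opaque straight stroke, no blur/halo: support equals the
        brute-force per-pixel distance-to-curve computation."""
        cfg = EyelashConfig(blur_sigma=0.0, halo_opacity=0.0)
        stroke = Stroke(
            control_points=np.array([[10.0, 0.0], [20.0, 20.0], [30.0, 40.0]]),
            width_root=4.0, width_taper=0.5, opacity=1.0)
        _, mask = render_artifact_layer([stroke], 64, cfg)

        t = np.linspace(0, 1, max(int(np.ceil(stroke.arc_length() / 0.25)), 2))
        pts = stroke.point(t)
        radii = stroke.width(t) / 2.0
        yy, xx = np.mgrid[0:64, 0:64]
        oracle = np.zeros((64, 64), dtype=bool)
        for (px, py), r in zip(pts, radii):
            oracle |= (xx - px) ** 2 + (yy - py) ** 2 <= r * r
        np.testing.assert_array_equal(mask, oracle)

    def test_coverage_monotone_in_stroke_count(self, small_eyelash_cfg):
        fractions = []
        for count in ((2, 4), (8, 12), (20, 30)):
            cfg = replace(small_eyelash_cfg, stroke_count_range=count)
            covered = []
            for seed in range(20):
                strokes = sample_eyelash_strokes(cfg, 64, seed)
                _, mask = render_artifact_layer(strokes, 64, cfg)
                covered.append(mask.mean())
            fractions.append(np.mean(covered))
        assert fractions[0] < fractions[1] < fractions[2]


class TestComposite:
    def test_zero_alpha_is_identity(self, small_phantom_cfg, small_eyelash_cfg):
        clean = generate_fundus_phantom(small_phantom_cfg, 0)
        alpha = np.zeros(clean.shape[:2])
        np.testing.assert_array_equal(
            composite_artifact(clean, alpha, small_eyelash_cfg), clean)

    def test_full_opacity_black_shade(self, small_eyelash_cfg):
        cfg = replace(small_eyelash_cfg, shade_color=(0.0, 0.0, 0.0))
        clean = np.full((8, 8, 3), 200, np.uint8)
        out = composite_artifact(clean, np.ones((8, 8)), cfg)
        assert (out == 0).all()

    def test_blend_arithmetic(self, small_eyelash_cfg):
        cfg = replace(small_eyelash_cfg, shade_color=(20.0, 20.0, 20.0))
        clean = np.full((4, 4, 3), 200, np.uint8)
        out = composite_artifact(clean, np.full((4, 4), 0.5), cfg)
        assert (out == 110).all()

    def test_never_brightens_under_dark_shade(self, small_phantom_cfg,
                                              small_eyelash_cfg, rng):
        clean = generate_fundus_phantom(small_phantom_cfg, 3)
        clean = np.maximum(clean, 17)  # shade (16,10,10) darker everywhere
        alpha = rng.uniform(0, 1, clean.shape[:2])
        out = composite_artifact(clean, alpha, small_eyelash_cfg)
        assert (out.astype(int) <= clean.astype(int) + 1).all()  # +1: rounding

    def test_shape_mismatch_rejected(self, small_eyelash_cfg):
        with pytest.raises(ValueError, match="shape"):
            composite_artifact(np.zeros((8, 8, 3), np.uint8),
                               np.zeros((4, 4)), small_eyelash_cfg)


class TestDatasets:
    def test_paired_sample_identity_off_artifact(self, desk_configs):
        pc, ec = desk_configs
        ec = replace(ec, stroke_count_range=(2, 4))  # leave untouched area
        for s in build_paired_dataset(3, pc, ec, 0):
            strokes = sample_eyelash_strokes(ec, pc.image_size,
                                             derive_seed(0, 0, int(s.sample_id), 1))
            alpha, _ = render_artifact_layer(strokes, pc.image_size, ec)
            untouched = alpha == 0.0
            assert untouched.any()
            np.testing.assert_array_equal(s.corrupted[untouched],
                                          s.clean[untouched])

    def test_bit_reproducible_per_master_seed(self, desk_configs):
        pc, ec = desk_configs
        a = build_paired_dataset(5, pc, ec, 42)
        b = build_paired_dataset(5, pc, ec, 42)
        for s, t in zip(a, b):
            assert s.sample_id == t.sample_id
            np.testing.assert_array_equal(s.corrupted, t.corrupted)
            np.testing.assert_array_equal(s.clean, t.clean)
            np.testing.assert_array_equal(s.mask, t.mask)

    def test_dataset_extension_preserves_prefix(self, desk_configs):
        pc, ec = desk_configs
        short = build_paired_dataset(2, pc, ec, 9)
        long = build_paired_dataset(4, pc, ec, 9)
        for s, t in zip(short, long):
            np.testing.assert_array_equal(s.corrupted, t.corrupted)

    def test_unpaired_pools_are_disjoint(self, desk_configs):
        pc, ec = desk_configs
        corrupted, clean = build_unpaired_dataset(3, 3, pc, ec, 0)
        clean_bytes = {img.tobytes() for img in clean}
        for s in corrupted:
            assert s.clean.tobytes() not in clean_bytes

    def test_counts_validated(self, desk_configs):
        pc, ec = desk_configs
        with pytest.raises(ValueError):
            build_paired_dataset(0, pc, ec, 0)
        with pytest.raises(ValueError):
            build_unpaired_dataset(0, 1, pc, ec, 0)

    def test_background_region_excludes_vessels_and_surround(self, desk_configs):
        pc, ec = desk_configs
        s = build_paired_dataset(1, pc, ec, 4)[0]
        region = artifact_background_region(s)
        assert region.sum() > 0
        assert (region <= s.mask).all()
        assert s.clean.mean(axis=-1)[region].min() > 100


def test_derive_seed_stable_and_bounded():
    assert derive_seed(0, 1, 2) == derive_seed(0, 1, 2)
    assert derive_seed(0, 1, 2) != derive_seed(0, 2, 1)
    assert 0 <= derive_seed(2 ** 40, 5) < 2 ** 31
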