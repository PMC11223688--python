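"""Pixel-wise motility imaging, spatial filtering and region statistics."""

import numpy as np
import pytest

from nutsoct import (
    ImageStack,
    SimulationConfig,
    Spheroid,
    StackGeometry,
    full_schedule,
    mean_filter,
    motility_from_series,
    motility_image,
    nuts_schedule,
    region_mean,
    restrict_stack,
    simulated_mean_M,
    synthesize_stack,
    uts_schedule,
)


def random_full_stack(rng, n=40, shape=(6, 5)):
    frames = rng.normal(1.0, 0.3, (n, *shape))
    return ImageStack(frames, ts=1.0, schedule=full_schedule(n))


class TestMotilityImage:
    def test_constant_stack_has_zero_motility(self):
        stack = ImageStack(np.full((20, 4, 4), 2.0), ts=1.0, schedule=full_schedule(20))
        img = motility_image(stack)
        assert np.all(img.m == 0.0)
        assert np.all(img.mean_image == 2.0)
        assert not img.clamp_mask.any()

    @pytest.mark.parametrize(
        "schedule", [full_schedule(40), uts_schedule(40, 4), nuts_schedule(40, 4)]
    )
    def test_matches_single_series_path_per_pixel(self, rng, schedule):
        stack = restrict_stack(random_full_stack(rng), schedule)
        img = motility_image(stack)
        for ax in range(stack.shape[0]):
            for lat in range(stack.shape[1]):
                expected = motility_from_series(stack.frames[:, ax, lat], schedule).m
                assert img.m[ax, lat] == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_pixel_flagged_nan(self):
        frames = np.ones((10, 3, 3))
        frames[:, 1, 1] = np.tile([1.0, -1.0], 5)
        img = motility_image(ImageStack(frames, 1.0, full_schedule(10)))
        assert np.isnan(img.m[1, 1])
        assert np.isfinite(np.delete(img.m.ravel(), 4)).all()

    def test_frame_count_must_match_schedule(self):
        with pytest.raises(ValueError):
            ImageStack(np.ones((9, 3, 3)), 1.0, full_schedule(10))


class TestRestrictStack:
    def test_commutes_with_per_pixel_subsampling(self, rng):
        full = random_full_stack(rng)
        sched = nuts_schedule(40, 4)
        sub = restrict_stack(full, sched)
        assert sub.frames.shape[0] == sched.n_samples
        expected = full.frames[np.array(sched.indices)]
        assert np.array_equal(sub.frames, expected)
        # Imaging the restricted stack equals restricting then imaging: both
        # consume exactly the retained frames.
        img = motility_image(sub)
        manual = motility_image(ImageStack(expected, 1.0, sched))
        assert np.array_equal(img.m, manual.m, equal_nan=True)

    def test_only_full_stacks_can_be_restricted(self, rng):
        sub = restrict_stack(random_full_stack(rng), uts_schedule(40, 4))
        with pytest.raises(ValueError):
            restrict_stack(sub, uts_schedule(40, 8))


class TestMeanFilter:
    def test_constant_map_unchanged_even_at_edges(self):
        out = mean_filter(np.full((10, 12), 3.3), 4, 2)
        assert out == pytest.approx(np.full((10, 12), 3.3))

    def test_interior_impulse_spreads_over_window_footprint(self):
        m = np.zeros((12, 12))
        m[6, 6] = 8.0
        out = mean_filter(m, window_lateral=4, window_axial=2)
        assert np.count_nonzero(out) == 8
        assert out[out > 0] == pytest.approx(np.ones(8))

    def test_identity_window(self, rng):
        m = rng.normal(size=(5, 7))
        assert np.array_equal(mean_filter(m, 1, 1), m)

    def test_nan_pixels_excluded_from_windows(self):
        m = np.full((6, 8), 2.0)
        m[3, 3] = np.nan
        out = mean_filter(m, 4, 2)
        assert np.nanmax(np.abs(out - 2.0)) < 1e-12
        assert np.isfinite(out).all()

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            mean_filter(np.zeros((3, 3)), window_lateral=4, window_axial=2)

    def test_filter_of_nonnegative_map_is_nonnegative(self, rng):
        m = np.abs(rng.normal(size=(9, 9)))
        assert (mean_filter(m, 4, 2) >= 0).all()


class TestRegionMean:
    def test_uniform_region(self):
        m = np.full((5, 5), 0.3)
        mask = np.zeros((5, 5), np.uint8)
        mask[1:4, 1:4] = 1
        assert region_mean(m, mask)[1] == pytest.approx(0.3)

    def test_invariant_to_relabeling_and_outside_pixels(self, rng):
        m = rng.normal(0.5, 0.1, (8, 8))
        mask = np.zeros((8, 8), np.uint8)
        mask[:4, :4] = 1
        mask[5:, 5:] = 2
        base = region_mean(m, mask)
        relabeled = np.where(mask == 1, 7, np.where(mask == 2, 3, 0)).astype(np.uint8)
        swapped = region_mean(m, relabeled)
        assert swapped[7] == base[1] and swapped[3] == base[2]
        m2 = m.copy()
        m2[mask == 0] = 99.0  # outside pixels must not matter
        assert region_mean(m2, mask).equals(base)

    def test_all_pixel_mask_on_zero_map(self):
        assert region_mean(np.zeros((4, 4)), np.ones((4, 4), np.uint8))[1] == 0.0

    def test_empty_mask_and_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            region_mean(np.zeros((4, 4)), np.zeros((4, 4), np.uint8))
        with pytest.raises(ValueError):
            region_mean(np.zeros((4, 4)), np.ones((3, 3), np.uint8))


class TestSynthesizeStack:
    def test_empty_noiseless_scene_is_constant_one(self):
        stack, mask = synthesize_stack(StackGeometry(shape=(6, 6)), cn=0.0, p=5, n_frames=20)
        assert np.array_equal(stack.frames, np.ones((20, 6, 6)))
        assert not mask.any()

    def test_spheroid_motility_recovered(self):
        geom = StackGeometry(
            shape=(36, 36),
            spheroids=(Spheroid(center=(18, 18), semi_axes=(12, 12), cm=0.4),),
        )
        stack, mask = synthesize_stack(geom, cn=0.25, p=20, n_frames=100, seed=3)
        img = motility_image(stack)
        inside = float(region_mean(img.m, mask)[1])
        background = float(np.nanmean(img.m[mask == 0]))
        # Cross-check against the single-pixel simulator path at the same
        # weights; the recovered mean sits a little below cm by construction.
        reference = simulated_mean_M(
            SimulationConfig(cn=0.25, cm=0.4, p=20, n_frames=100, replicates=2000, seed=30)
        )
        assert inside == pytest.approx(reference, abs=0.02)
        assert inside > 2 * background

    def test_region_means_ordered_by_motile_weight(self):
        geom = StackGeometry(
            shape=(30, 60),
            spheroids=(
                Spheroid(center=(15, 15), semi_axes=(9, 10), cm=0.2),
                Spheroid(center=(15, 44), semi_axes=(9, 10), cm=0.4),
            ),
        )
        stack, mask = synthesize_stack(geom, cn=0.25, p=20, n_frames=100, seed=4)
        means = region_mean(motility_image(stack).m, mask)
        assert means[1] < means[2]

    def test_matches_single_pixel_simulator_statistics(self):
        # Imaging a homogeneous scene must agree with the replicate-averaged
        # single-pixel path: same model, two code paths.
        geom = StackGeometry(
            shape=(60, 60), spheroids=(Spheroid((30, 30), (100, 100), cm=0.3),)
        )
        stack, mask = synthesize_stack(geom, cn=0.25, p=20, n_frames=100, seed=5)
        assert mask.all()  # spheroid covers the scene
        img_mean = float(np.nanmean(motility_image(stack).m))
        cfg = SimulationConfig(cn=0.25, cm=0.3, p=20, n_frames=100, replicates=3600, seed=6)
        sim_mean = simulated_mean_M(cfg)
        assert img_mean == pytest.approx(sim_mean, abs=0.01)

    def test_restriction_bookkeeping(self):
        stack, _ = synthesize_stack(StackGeometry(shape=(5, 5)), cn=0.1, p=4, n_frames=50, seed=1)
        sched = nuts_schedule(50, 8)
        assert restrict_stack(stack, sched).frames.shape[0] == sched.n_samples
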