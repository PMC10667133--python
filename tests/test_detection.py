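"""Detection stage: threshold, binarization, artifact masking, particle counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ihrf import (
    DetectionParams,
    DrusenSpec,
    ExclusionMask,
    FocusSpec,
    VolumeSpec,
    binarize,
    build_artifact_mask,
    compute_threshold,
    count_particles,
    generate_surfaces,
    make_slab_stack,
    quantify_eye,
    render_volume,
    sample_interior_foci,
)
from ihrf.benchmark import detection_recovery, flood_fill_count


class TestThreshold:
    def test_rpe_fraction_of_noise_free_phantom(self, noise_free_spec, flat_surfaces):
        volume, _ = render_volume(noise_free_spec, flat_surfaces)
        p1 = DetectionParams(threshold_value=1.0)
        assert compute_threshold(volume, flat_surfaces, p1) == pytest.approx(0.8)
        p09 = DetectionParams(threshold_value=0.9)
        assert compute_threshold(volume, flat_surfaces, p09) == pytest.approx(0.72)

    def test_median_reference_is_robust_to_speckle(self, flat_surfaces):
        """Monte-Carlo: at shape >= 20 the threshold stays within 10% of clean."""
        clean_vol, _ = render_volume(VolumeSpec(speckle_shape=0.0), flat_surfaces)
        clean = compute_threshold(clean_vol, flat_surfaces)
        for seed in range(5):
            noisy, _ = render_volume(VolumeSpec(speckle_shape=20.0, seed=seed), flat_surfaces)
            thr = compute_threshold(noisy, flat_surfaces)
            assert abs(thr - clean) / clean < 0.10

    def test_degenerate_rpe_sample_raises(self, flat_surfaces):
        dark = np.zeros((128, 32, 256), dtype=np.float32)
        with pytest.raises(ValueError, match="degenerate RPE"):
            compute_threshold(dark, flat_surfaces)

    def test_absolute_and_percentile_modes(self, noise_free_spec, flat_surfaces):
        volume, _ = render_volume(noise_free_spec, flat_surfaces)
        assert compute_threshold(
            volume, flat_surfaces, DetectionParams(threshold_mode="absolute", threshold_value=0.5)
        ) == pytest.approx(0.5)
        thr = compute_threshold(
            volume, flat_surfaces, DetectionParams(threshold_mode="percentile", threshold_value=99.0)
        )
        stack = make_slab_stack(volume, flat_surfaces)
        assert thr == pytest.approx(np.percentile(stack.images, 99.0))


class TestBinarize:
    def test_direct_comparison(self):
        img = np.array([[0.1, 0.9], [0.8, 0.2]])
        assert binarize(img, 0.75).astype(int).tolist() == [[0, 1], [1, 0]]

    def test_exclusion_dominates(self):
        img = np.ones((3, 3))
        assert not binarize(img, 0.5, mask=np.ones((3, 3), bool)).any()

    def test_zero_threshold_is_mask_complement(self):
        img = np.random.default_rng(0).random((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        assert np.array_equal(binarize(img, 0.0, mask), ~mask)

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.ones((2, 2)), float("nan"))


class TestParticleAnalysis:
    def test_minimum_area_filter_drops_small_components(self):
        img = np.zeros((8, 8), bool)
        img[1:3, 1:3] = True  # area 4
        img[5, 5:7] = True  # area 2
        comps = count_particles(img, DetectionParams(min_area_px=3), slab_index=1)
        assert len(comps) == 1
        assert comps[0].area_px == 4

    def test_diagonal_touch_counts_per_connectivity(self):
        img = np.zeros((3, 3), bool)
        img[0, 0] = img[1, 1] = img[2, 2] = True
        c8 = count_particles(img, DetectionParams(connectivity=8, min_area_px=1), 1)
        c4 = count_particles(img, DetectionParams(connectivity=4, min_area_px=1), 1)
        assert (len(c8), len(c4)) == (1, 3)

    @given(
        arrays(bool, (12, 12), elements=st.booleans()),
        st.sampled_from([4, 8]),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_counts_match_brute_force_flood_fill(self, img, connectivity):
        params = DetectionParams(connectivity=connectivity, min_area_px=1)
        assert len(count_particles(img, params, 1)) == flood_fill_count(img, connectivity)

    def test_separated_clustered_foci_count_individually(self):
        img = np.zeros((10, 10), bool)
        img[1:3, 1:3] = True
        img[1:3, 5:8] = True  # separated by background
        comps = count_particles(img, DetectionParams(), 1)
        assert len(comps) == 2


class TestArtifactMask:
    def test_vessel_masked_in_inner_slabs_count_zero(self, noise_free_spec, flat_surfaces):
        volume, _ = render_volume(noise_free_spec, flat_surfaces, vessels=[(30, 10)])
        stack = make_slab_stack(volume, flat_surfaces)
        thr = compute_threshold(volume, flat_surfaces)
        assert (stack.image(5) >= thr).any()  # the confounder is really there
        table = quantify_eye(volume, flat_surfaces)
        assert table.per_slab_counts().tolist() == [0, 0, 0, 0, 0]

    def test_drusen_bleed_masked_when_segmentation_misses_apex(self, noise_free_spec):
        drusen = [DrusenSpec(x=90, y=20, radius_px=10, height_px=8)]
        true_surfaces = generate_surfaces(noise_free_spec, drusen)
        missed = generate_surfaces(noise_free_spec)
        volume, _ = render_volume(noise_free_spec, true_surfaces)
        stack = make_slab_stack(volume, missed)
        thr = compute_threshold(volume, missed)
        with_mask = quantify_eye(volume, missed).per_slab_counts()
        assert (stack.image(1) >= thr).sum() > 40  # bleed present before masking
        assert with_mask.tolist() == [0, 0, 0, 0, 0]

    def test_no_confounders_mask_changes_nothing(self, small_spec, small_surfaces, rng):
        foci = sample_interior_foci(rng, small_spec, small_surfaces, 4)
        volume, truth = render_volume(small_spec, small_surfaces, foci)
        stack = make_slab_stack(volume, small_surfaces)
        thr = compute_threshold(volume, small_surfaces)
        mask = build_artifact_mask(volume, small_surfaces, stack, thr)
        assert not mask.masks.any()
        empty = ExclusionMask.empty(stack.lateral_shape)
        counts = quantify_eye(volume, small_surfaces, user_mask=empty).per_slab_counts()
        assert np.array_equal(counts, truth.per_slab_counts())


class TestQuantifyEye:
    def test_two_outer_and_one_mid_focus(self, noise_free_spec, flat_surfaces):
        foci = [
            FocusSpec(x=30, y=8, frac_depth=0.9),
            FocusSpec(x=90, y=24, frac_depth=0.85),
            FocusSpec(x=64, y=16, frac_depth=0.5),
        ]
        volume, _ = render_volume(noise_free_spec, flat_surfaces, foci)
        counts = quantify_eye(volume, flat_surfaces).per_slab_counts()
        assert counts.tolist() == [2, 0, 1, 0, 0]

    def test_boundary_straddling_lesion_counts_twice(self, noise_free_spec, flat_surfaces):
        volume, _ = render_volume(
            noise_free_spec, flat_surfaces, [FocusSpec(x=64, y=16, frac_depth=0.8)]
        )
        table = quantify_eye(volume, flat_surfaces)
        assert table.total_count == 2
        assert table.per_slab_counts().tolist() == [1, 1, 0, 0, 0]

    def test_no_foci_gives_all_zero_table(self, noise_free_spec, flat_surfaces):
        volume, _ = render_volume(noise_free_spec, flat_surfaces)
        assert quantify_eye(volume, flat_surfaces).total_count == 0

    def test_slab5_detection_is_not_hardcoded_away(self, noise_free_spec, flat_surfaces):
        """The observed innermost-slab emptiness is data, not a rule."""
        volume, _ = render_volume(
            noise_free_spec, flat_surfaces, [FocusSpec(x=64, y=16, frac_depth=0.1)]
        )
        assert quantify_eye(volume, flat_surfaces).per_slab_counts().tolist() == [0, 0, 0, 0, 1]

    def test_threshold_monotonicity_and_min_area_monotonicity(
        self, small_spec, small_surfaces, rng
    ):
        foci = sample_interior_foci(rng, small_spec, small_surfaces, 5)
        volume, _ = render_volume(small_spec, small_surfaces, foci)
        counts = {}
        for tv in (0.6, 0.8, 1.0):
            params = DetectionParams(threshold_mode="absolute", threshold_value=tv)
            counts[tv] = quantify_eye(volume, small_surfaces, params).per_slab_counts()
        assert (counts[0.6] >= counts[0.8]).all() and (counts[0.8] >= counts[1.0]).all()
        loose = quantify_eye(
            volume, small_surfaces, DetectionParams(min_area_px=1)
        ).per_slab_counts()
        strict = quantify_eye(
            volume, small_surfaces, DetectionParams(min_area_px=5)
        ).per_slab_counts()
        assert (loose >= strict).all()

    def test_exact_recovery_on_random_noise_free_phantoms(self):
        """Per-slab counts equal ground truth on random interior-foci phantoms."""
        r = detection_recovery(
            n_phantoms=25,
            seed=99,
            speckle_shape=0.0,
            spec_kwargs=dict(n_ascans_x=64, n_bscans_y=16, n_depth_z=128),
            n_foci_range=(1, 6),
        )
        assert r["exact_match_fraction"] == 1.0
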