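"""Micrograph quantification: thresholding, particle analysis, ground truth."""

import numpy as np
import pytest

from tinassay.ihc import (
    Micrograph,
    particle_analysis,
    quantify,
    quantify_cohort,
    synth_ihc_cohort,
    synth_micrograph,
    threshold_image,
    to_grayscale,
)


def flood_fill_components(mask):
    """Brute-force 8-connected component count (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    n = 0
    sizes = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                sizes.append(size)
    return n, sizes


class TestSynthMicrograph:
    def test_zero_density_zero_truth(self):
        micro, truth = synth_micrograph(n_blobs=0, seed=0)
        assert truth.true_fraction == 0.0 and truth.stained_pixels == 0

    def test_disk_arithmetic_verified_by_pixel_counting(self):
        """5 disks of 21 px (r^2 = 5) in a 1050-px AOI: exactly 10% stained."""
        aoi = np.zeros((40, 70), dtype=bool)
        aoi[5:26, 10:60] = True  # 21 x 50 = 1050 px
        blobs = [(15.0, 15.0 + 9 * k, np.sqrt(5.0)) for k in range(5)]
        micro, truth = synth_micrograph(
            shape=(40, 70), aoi=aoi, blobs=blobs, noise_sigma=0.0, seed=0
        )
        # independent pixel count
        stained = (micro.image < 150) & aoi
        assert stained.sum() == 105 == truth.stained_pixels
        assert truth.true_fraction == pytest.approx(0.10)

    def test_fixed_seed_byte_identical(self):
        a, _ = synth_micrograph(seed=12, n_blemishes=2, border_width=3)
        b, _ = synth_micrograph(seed=12, n_blemishes=2, border_width=3)
        assert np.array_equal(a.image, b.image)

    def test_infeasible_density_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth_micrograph(shape=(32, 32), n_blobs=500, min_separation=4.0, seed=0)

    def test_adding_a_blob_never_decreases_percent_area(self):
        base_blobs = [(30.0, 30.0, 5.0), (60.0, 60.0, 5.0)]
        micro1, truth1 = synth_micrograph(blobs=base_blobs, noise_sigma=2.0, seed=3)
        micro2, truth2 = synth_micrograph(
            blobs=base_blobs + [(90.0, 90.0, 4.0)], noise_sigma=2.0, seed=3
        )
        assert truth2.true_fraction >= truth1.true_fraction
        assert quantify(micro2).percent_area >= quantify(micro1).percent_area


class TestGrayscale:
    def test_single_channel_identity(self):
        img = np.arange(12, dtype=float).reshape(3, 4)
        np.testing.assert_array_equal(to_grayscale(img), img)

    def test_uniform_rgb_maps_to_value(self):
        img = np.full((5, 5, 3), 37.0)
        np.testing.assert_allclose(to_grayscale(img), 37.0)

    def test_pure_channels_ordered_by_luminance_weight(self):
        outs = []
        for c in range(3):
            img = np.zeros((2, 2, 3))
            img[..., c] = 100.0
            outs.append(to_grayscale(img)[0, 0])
        # green weighs most, blue least
        assert outs[1] > outs[0] > outs[2]

    def test_unsupported_layout_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestThreshold:
    def two_valued(self):
        img = np.full((32, 32), 200.0)
        img[10:14, 10:14] = 50.0
        aoi = np.ones_like(img, dtype=bool)
        return Micrograph(image=img, aoi=aoi)

    def test_otsu_separates_two_valued_image_exactly(self):
        micro = self.two_valued()
        mask, thr = threshold_image(micro, "otsu")
        np.testing.assert_array_equal(mask, micro.image == 50.0)
        assert 50.0 < thr < 200.0

    def test_otsu_equivariant_under_affine_rescaling(self):
        micro, _ = synth_micrograph(seed=5, n_blobs=20)
        mask1, _ = threshold_image(micro, "otsu")
        rescaled = Micrograph(image=2.5 * micro.image + 7.0, aoi=micro.aoi)
        mask2, _ = threshold_image(rescaled, "otsu")
        np.testing.assert_array_equal(mask1, mask2)

    def test_fixed_threshold_by_definition(self):
        micro, _ = synth_micrograph(seed=6)
        mask, thr = threshold_image(micro, ("fixed", 120.0))
        np.testing.assert_array_equal(mask, micro.image < 120.0)
        assert thr == 120.0

    def test_percentile_threshold_within_aoi(self):
        micro = self.two_valued()
        mask, thr = threshold_image(micro, ("percentile", 5.0))
        assert mask[10:14, 10:14].all()

    def test_constant_image_under_otsu_advises_alternatives(self):
        micro = Micrograph(image=np.full((8, 8), 5.0), aoi=np.ones((8, 8), bool))
        with pytest.raises(ValueError, match="fixed or"):
            threshold_image(micro, "otsu")


class TestParticleAnalysis:
    def test_empty_mask(self):
        aoi = np.ones((16, 16), bool)
        st = particle_analysis(np.zeros((16, 16), bool), aoi)
        assert st.n_particles == 0 and st.percent_area == 0.0

    def test_entire_aoi_stained(self):
        aoi = np.zeros((16, 16), bool)
        aoi[4:12, 4:12] = True
        st = particle_analysis(aoi.copy(), aoi, min_size_px=0, exclude_border=False)
        assert st.percent_area == 100.0 and st.n_particles == 1

    def test_min_size_filter(self):
        aoi = np.ones((16, 16), bool)
        mask = np.zeros((16, 16), bool)
        mask[2, 2] = True  # 1 px, below default min size 4
        mask[8:11, 8:11] = True  # 9 px
        st = particle_analysis(mask, aoi)
        assert st.n_particles == 1
        assert st.stained_area == 9

    def test_border_touching_components_excluded(self):
        aoi = np.ones((16, 16), bool)
        mask = np.zeros((16, 16), bool)
        mask[0:4, 0:4] = True  # touches border -> blemish/section edge
        mask[8:12, 8:12] = True
        st = particle_analysis(mask, aoi)
        assert st.n_particles == 1 and st.stained_area == 16

    def test_percent_area_calibration_invariant(self):
        aoi = np.ones((20, 20), bool)
        mask = np.zeros((20, 20), bool)
        mask[5:9, 5:9] = True
        a = particle_analysis(mask, aoi, pixel_area=1.0)
        b = particle_analysis(mask, aoi, pixel_area=0.25)
        assert a.percent_area == b.percent_area
        assert b.stained_area == pytest.approx(a.stained_area * 0.25)

    def test_empty_aoi_rejected(self):
        with pytest.raises(ValueError, match="AOI"):
            particle_analysis(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    def test_component_counts_match_flood_fill_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            h, w = rng.integers(3, 13, size=2)
            mask = rng.random((h, w)) < rng.uniform(0.1, 0.6)
            aoi = np.ones((h, w), bool)
            st = particle_analysis(mask, aoi, min_size_px=0, exclude_border=False)
            n_oracle, _ = flood_fill_components(mask)
            assert st.n_particles == n_oracle


class TestQuantifyRecovery:
    def test_percent_area_within_one_point_of_truth(self):
        micro, truth = synth_micrograph(seed=41, n_blobs=20, min_separation=2.0)
        st = quantify(micro)
        assert st.percent_area == pytest.approx(100 * truth.true_fraction, abs=1.0)

    def test_blemishes_and_border_do_not_inflate_area(self):
        kwargs = dict(seed=13, n_blobs=15, min_separation=2.0)
        clean, truth_c = synth_micrograph(**kwargs)
        dirty, truth_d = synth_micrograph(**kwargs, n_blemishes=4, border_width=3)
        assert truth_c.stained_pixels == truth_d.stained_pixels
        assert quantify(dirty).percent_area == pytest.approx(
            100 * truth_d.true_fraction, abs=1.0
        )


class TestQuantifyCohort:
    def test_repeated_sections_averaged_per_animal(self):
        m1, _ = synth_micrograph(seed=1, n_blobs=10, animal_id="a1", micrograph_id="a1_sec1")
        m2, _ = synth_micrograph(seed=2, n_blobs=30, animal_id="a1", micrograph_id="a1_sec2")
        per_micro, per_animal = quantify_cohort([m1, m2])
        assert len(per_micro) == 2 and len(per_animal) == 1
        assert per_animal.iloc[0]["percent_area"] == pytest.approx(
            per_micro["percent_area"].mean()
        )

    def test_duplicate_micrograph_ids_rejected(self):
        m1, _ = synth_micrograph(seed=1, micrograph_id="dup")
        m2, _ = synth_micrograph(seed=2, micrograph_id="dup")
        with pytest.raises(ValueError, match="duplicate"):
            quantify_cohort([m1, m2])

    def test_blank_images_quantify_to_zero(self):
        micros = [
            Micrograph(
                image=np.full((32, 32), 200.0),
                aoi=np.ones((32, 32), bool),
                animal_id=f"a{i}",
                micrograph_id=f"a{i}",
            )
            for i in range(3)
        ]
        per_micro, _ = quantify_cohort(micros, method=("fixed", 100.0))
        assert (per_micro["percent_area"] == 0.0).all()

    def test_synth_cohort_carries_group_effect(self):
        micros, truth = synth_ihc_cohort(n_exposed=4, n_unexposed=3, effect=2.0, seed=5)
        _, per_animal = quantify_cohort(micros)
        merged = per_animal.merge(truth, on="animal_id")
        exp = merged[merged["exposed"]]["percent_area"].mean()
        ctl = merged[~merged["exposed"]]["percent_area"].mean()
        assert exp > ctl
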