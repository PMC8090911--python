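"""Segmentation primitives against brute-force oracles and ground truth."""

import numpy as np
import pytest
from skimage import measure

import oracles
from perilyso import segment
from perilyso.synthcells import FieldSpec, render_cell_field
from perilyso.types import BinaryMask, LabelMask


def _disk_image(shape, centers_radii, level=1000.0, background=0.0):
    img = np.full(shape, background)
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    for (r, c), rad in centers_radii:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= rad * rad] = level
    return img


class TestFindRoundObjects:
    def test_blank_image_gives_empty_mask(self):
        out = segment.find_round_objects(np.zeros((32, 32)), 4, 20,
                                         intensity_threshold=10)
        assert out.n_labels == 0

    def test_recovers_generator_nuclei(self):
        spec = FieldSpec(n_cells=5, noise_sd=0.0, seed=21)
        img, truth = render_cell_field(spec)
        out = segment.find_round_objects(img.channels["nucleus"], 10, 60)
        assert out.n_labels == 5
        centroids = np.array([p.centroid
                              for p in measure.regionprops(out.labels)])
        for c in truth.nucleus_centers:
            assert np.min(np.hypot(*(centroids - c).T)) <= 1.0

    def test_diameter_band_excludes_out_of_range_disks(self):
        img = _disk_image((96, 96), [((20, 20), 4), ((60, 60), 20)])
        # brute-force: measured equivalent diameters are ~8 and ~40
        for prop in measure.regionprops(measure.label(img > 500)):
            d = 2 * np.sqrt(prop.area / np.pi)
            assert not 10 <= d <= 30
        out = segment.find_round_objects(img, 10, 30,
                                         intensity_threshold=500)
        assert out.n_labels == 0

    def test_labels_are_sequential_in_raster_order(self):
        img = _disk_image((64, 64), [((40, 10), 5), ((10, 40), 5),
                                     ((55, 55), 5)])
        out = segment.find_round_objects(img, 5, 20, intensity_threshold=500)
        firsts = []
        for lab in (1, 2, 3):
            pix = np.argwhere(out.labels == lab)
            firsts.append(tuple(pix[np.lexsort((pix[:, 1], pix[:, 0]))[0]]))
        assert firsts == sorted(firsts)

    def test_rejects_non_2d_input(self):
        with pytest.raises(ValueError, match="2-D"):
            segment.find_round_objects(np.zeros((4, 4, 4)), 2, 10,
                                       intensity_threshold=1)


class TestShrinkLabels:
    def test_zero_shrink_is_identity(self):
        lab = LabelMask(oracles.random_label_image(np.random.default_rng(0)))
        out = segment.shrink_labels(lab, 0)
        assert np.array_equal(out.labels, lab.labels)

    def test_matches_brute_force_erosion(self):
        img = _disk_image((64, 64), [((32, 32), 10)])
        lab = LabelMask((img > 0).astype(np.int32))
        out = segment.shrink_labels(lab, 2)
        assert np.array_equal(out.labels, oracles.erode_labels(lab.labels, 2))

    def test_annihilated_label_dropped_and_logged(self, caplog):
        lab = LabelMask(_disk_image((32, 32), [((16, 16), 1)]
                                    ).astype(bool).astype(np.int32))
        with caplog.at_level("WARNING", logger="perilyso.segment"):
            out = segment.shrink_labels(lab, 2)
        assert out.n_labels == 0
        assert "removed 1 label" in caplog.text

    def test_negative_shrink_rejected(self):
        with pytest.raises(ValueError):
            segment.shrink_labels(LabelMask(np.zeros((8, 8), dtype=int)), -1)


class TestGrowWithoutTouching:
    def test_zero_growth_is_identity(self):
        lab = LabelMask(oracles.random_label_image(np.random.default_rng(1)))
        out = segment.grow_labels_without_touching(lab, 0)
        assert np.array_equal(out.labels, lab.labels)

    def test_single_disk_matches_exhaustive_oracle(self):
        img = _disk_image((128, 128), [((64, 64), 10)])
        lab = LabelMask((img > 0).astype(np.int32))
        out = segment.grow_labels_without_touching(lab, 25)
        assert np.array_equal(out.labels, oracles.grow_labels(lab.labels, 25))

    def test_tie_pixels_take_smaller_label(self):
        lab = np.zeros((64, 64), dtype=np.int32)
        lab[30, 25] = 2   # deliberately: left seed has the larger id
        lab[30, 35] = 1
        out = segment.grow_labels_without_touching(LabelMask(lab), 25)
        assert np.array_equal(out.labels, oracles.grow_labels(lab, 25))
        # the equidistant column belongs to label 1 (the smaller id)
        assert (out.labels[:, 30][out.labels[:, 30] > 0] == 1).all()

    def test_input_pixels_keep_their_labels(self):
        lab = oracles.random_label_image(np.random.default_rng(2))
        out = segment.grow_labels_without_touching(LabelMask(lab), 7)
        assert np.array_equal(out.labels[lab > 0], lab[lab > 0])

    def test_territory_monotonicity_two_steps_subset_one(self, rng):
        for _ in range(5):
            lab = oracles.random_label_image(rng)
            two = segment.grow_labels_without_touching(
                segment.grow_labels_without_touching(LabelMask(lab), 4), 6)
            one = segment.grow_labels_without_touching(LabelMask(lab), 10)
            assert not ((two.labels > 0) & (one.labels == 0)).any()

    def test_shrink_then_grow_never_relabels(self):
        spec = FieldSpec(n_cells=6, noise_sd=0.0, seed=13)
        img, _ = render_cell_field(spec)
        nuclei = segment.find_round_objects(img.channels["nucleus"], 10, 60)
        back = segment.grow_labels_without_touching(
            segment.shrink_labels(nuclei, 3), 3)
        orig = nuclei.labels
        both = (orig > 0) & (back.labels > 0)
        assert np.array_equal(back.labels[both], orig[both])


class TestRemoveBorderObjects:
    def test_interior_labels_unchanged(self):
        lab = LabelMask(_disk_image((64, 64), [((32, 32), 8)]
                                    ).astype(bool).astype(np.int32))
        out = segment.remove_border_objects(lab)
        assert np.array_equal(out.labels, lab.labels)

    def test_clipped_disk_removed(self):
        lab = LabelMask(_disk_image((64, 64), [((0, 32), 8)]
                                    ).astype(bool).astype(np.int32))
        assert segment.remove_border_objects(lab).n_labels == 0

    def test_only_edge_labels_removed(self):
        lab = np.zeros((64, 64), dtype=np.int32)
        spots = [((0, 10), 1), ((63, 50), 2), ((20, 20), 3), ((40, 40), 4),
                 ((20, 45), 5)]
        for (r, c), i in spots:
            lab[max(0, r - 2):r + 3, max(0, c - 2):c + 3] = i
        out = segment.remove_border_objects(LabelMask(lab))
        assert set(out.ids) == {3, 4, 5}


class TestDetectPuncta:
    def test_matches_truth_on_noise_free_field(self, noise_free_field):
        _, img, truth = noise_free_field
        det = segment.detect_puncta(img.channels["organelle"])
        centroids = np.array([p.centroid
                              for p in measure.regionprops(det.labels)])
        used = set()
        matched = 0
        for t in truth.puncta_centers:
            d = np.hypot(*(centroids - t).T)
            for j in np.argsort(d):
                if d[j] > 2.0:
                    break
                if j not in used:
                    used.add(j)
                    matched += 1
                    break
        assert matched / truth.n_puncta >= 0.95

    def test_threshold_above_max_gives_empty(self, noise_free_field):
        _, img, _ = noise_free_field
        det = segment.detect_puncta(img.channels["organelle"],
                                    intensity_threshold=1e6)
        assert det.n_labels == 0

    def test_spaced_pair_separates_at_default_threshold(self):
        from perilyso.synthcells import (PUNCTUM_AMPLITUDE, FieldSpec,
                                         _render_spots)
        centers = np.array([[32.0, 29.0], [32.0, 35.0]])  # 6 px apart
        img = _render_spots((64, 64), centers, FieldSpec().punctum_sigma_px,
                            np.full(2, PUNCTUM_AMPLITUDE)) + 100.0
        assert segment.detect_puncta(img).n_labels == 2
        # at a low threshold the pair fuses into one component
        assert segment.detect_puncta(img, intensity_threshold=110.0
                                     ).n_labels == 1


class TestBottomHat:
    def test_flat_image_maps_to_zero(self):
        out = segment.bottom_hat(np.full((32, 32), 7.0), 5)
        assert np.allclose(out, 0.0)

    def test_dark_square_enhanced_exactly_as_oracle(self):
        img = np.full((64, 64), 200.0)
        img[20:31, 20:31] = 50.0  # dark square, side 11
        out = segment.bottom_hat(img, 15)
        exp = oracles.bottom_hat(img, 15)
        assert np.array_equal(out, exp)
        assert (out[20:31, 20:31] == 150.0).all()
        assert out[0, 0] == 0.0

    def test_small_radius_leaves_object_core_dark(self):
        img = np.full((64, 64), 200.0)
        img[12:53, 12:53] = 50.0  # side 41 > structuring element
        out = segment.bottom_hat(img, 8)
        assert out[32, 32] < out[12, 12]

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            segment.bottom_hat(np.zeros((8, 8)), 0)


class TestAutoThreshold:
    def test_bimodal_image_split_exactly(self):
        rng = np.random.default_rng(3)
        img = np.full(1000, 10.0)
        idx = rng.choice(1000, 100, replace=False)
        img[idx] = 200.0
        mask = segment.auto_threshold(img.reshape(20, 50))
        assert np.array_equal(mask.mask, img.reshape(20, 50) == 200.0)

    def test_inverted_contrast_swaps_foreground_count(self):
        rng = np.random.default_rng(4)
        img = np.full((20, 50), 10.0)
        img.flat[rng.choice(1000, 100, replace=False)] = 200.0
        a = segment.auto_threshold(img)
        b = segment.auto_threshold(210.0 - img)
        assert a.area_px + b.area_px == img.size

    def test_equal_split_threshold_between_modes(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        mask = segment.auto_threshold(img)
        assert mask.area_px == 50
        assert mask.mask[:, 5:].all()

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment.auto_threshold(np.full((8, 8), 3.0))


class TestBinaryCleanup:
    def test_fill_holes_turns_annulus_into_disk(self):
        yy, xx = np.ogrid[:64, :64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        ann = (d2 <= 400) & (d2 >= 100)
        out = segment.fill_holes(BinaryMask(ann))
        assert np.array_equal(out.mask, oracles.fill_holes(ann))
        assert np.array_equal(out.mask, d2 <= 400)

    def test_filter_min_area_zero_is_identity(self, rng):
        m = BinaryMask(oracles.random_label_image(rng) > 0)
        out = segment.filter_min_area(m, 0)
        assert np.array_equal(out.mask, m.mask)

    def test_filter_min_area_keeps_large_components(self):
        m = np.zeros((64, 64), dtype=bool)
        m[2:7, 2:3] = True          # area 5
        m[20:30, 20:25] = True      # area 50
        m[40:60, 30:55] = True      # area 500
        out = segment.filter_min_area(BinaryMask(m), 40)
        assert measure.label(out.mask, connectivity=2).max() == 2
        assert out.area_px == 550

    def test_dilate_binary_matches_disk_oracle(self):
        m = np.zeros((32, 32), dtype=bool)
        m[16, 16] = True
        out = segment.dilate_binary(BinaryMask(m), 3)
        yy, xx = np.ogrid[:32, :32]
        assert np.array_equal(out.mask,
                              (yy - 16) ** 2 + (xx - 16) ** 2 <= 9)


class TestTranslationEquivariance:
    """Interior objects shifted 3 px shift every operator's output 3 px."""

    @pytest.mark.parametrize("op", [
        lambda m: segment.shrink_labels(m, 2).labels,
        lambda m: segment.grow_labels_without_touching(m, 5).labels,
    ])
    def test_label_ops(self, op, rng):
        lab = np.zeros((64, 64), dtype=np.int32)
        lab[20:30, 22:30] = 1
        lab[40:46, 40:44] = 2
        base = op(LabelMask(lab))
        shifted = op(LabelMask(np.roll(lab, (3, 3), axis=(0, 1))))
        assert np.array_equal(shifted, np.roll(base, (3, 3), axis=(0, 1)))

    def test_bottom_hat(self):
        img = np.full((64, 64), 100.0)
        img[28:35, 28:35] = 10.0
        base = segment.bottom_hat(img, 6)
        shifted = segment.bottom_hat(np.roll(img, (3, 3), axis=(0, 1)), 6)
        # compare away from the border where clipping differs
        assert np.array_equal(shifted[12:52, 12:52],
                              np.roll(base, (3, 3), axis=(0, 1))[12:52, 12:52])
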