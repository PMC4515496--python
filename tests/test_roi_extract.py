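"""ROI extraction: binarization, labeling vs flood-fill oracle, mask logic."""

import numpy as np
import pytest
from scipy import ndimage

from hriq.fuzzy_stretch import fuzzy_stretch
from hriq.phantom import PhantomSpec, generate_phantom
from hriq.roi_extract import (
    ExtractionError,
    LabeledRegion,
    RegionSet,
    average_binarize,
    extract_rois,
    filter_noise,
    restore_boundaries,
    trace_and_label,
)

EIGHT = np.ones((3, 3), dtype=int)


def floodfill_partition(mask):
    """Independent oracle: scipy connected components, 8-connected."""
    lab, n = ndimage.label(mask, structure=EIGHT)
    return {frozenset(map(tuple, np.argwhere(lab == i))) for i in range(1, n + 1)}


def region_partition(rs):
    return {frozenset((int(r), int(c)) for r, c in reg.pixels) for reg in rs.regions}


def bright_regions(img, min_area=200, max_area=20000):
    """Stretch → binarize → label → noise filter, as the pipeline runs it."""
    stretched, _ = fuzzy_stretch(img)
    rs = filter_noise(trace_and_label(average_binarize(stretched)),
                      min_area, max_area)
    return stretched, rs


def dice(a, b):
    inter = (a & b).sum()
    return 2 * inter / (a.sum() + b.sum())


class TestAverageBinarize:
    def test_positive_pixel_mean_threshold(self):
        img = np.array([[0, 0], [100, 200]], np.uint8)
        # threshold over {100, 200} is 150; only 200 passes
        assert average_binarize(img).tolist() == [[False, False], [False, True]]

    def test_all_zero_image(self):
        assert not average_binarize(np.zeros((4, 4), np.uint8)).any()

    def test_constant_positive_image_all_foreground(self):
        assert average_binarize(np.full((3, 3), 9, np.uint8)).all()


class TestTraceAndLabel:
    def test_solid_square_boundary_circuit(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        rs = trace_and_label(mask)
        assert len(rs) == 1
        reg = rs.regions[0]
        assert reg.area == 9
        path = reg.boundary_path
        assert path[0] == path[-1] == (1, 1)
        border = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        assert set(path) == border
        assert len(path) == 9  # 8 border pixels + closing step

    @pytest.mark.parametrize("second", [(1, 1), (1, 0)])
    def test_diagonal_contact_is_one_region(self, second):
        # 8-connectivity convention: diagonal touch joins regions
        mask = np.zeros((2, 2), bool)
        start = (0, 0) if second == (1, 1) else (0, 1)
        mask[start] = mask[second] = True
        rs = trace_and_label(mask)
        assert len(rs) == 1
        assert rs.regions[0].area == 2

    def test_partition_matches_flood_fill_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            mask = rng.random((32, 32)) < (0.2 + 0.02 * seed)
            rs = trace_and_label(mask)
            assert region_partition(rs) == floodfill_partition(mask), seed

    def test_boundary_paths_are_closed_and_inside_region(self):
        rng = np.random.default_rng(5)
        mask = rng.random((24, 24)) < 0.5
        for reg in trace_and_label(mask).regions:
            path = reg.boundary_path
            assert path[0] == path[-1]
            assert set(path) <= reg.pixel_set

    def test_bboxes_are_half_open(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 1:5] = True
        reg = trace_and_label(mask).regions[0]
        assert reg.bbox == (2, 1, 4, 5)
        assert reg.width == 4


def _dummy_region(label, area):
    pixels = np.stack([np.zeros(area, np.intp), np.arange(area, dtype=np.intp)], 1)
    return LabeledRegion(label=label, pixels=pixels, boundary_path=[(0, 0), (0, 0)])


class TestFilterNoise:
    @pytest.mark.parametrize(
        "area, kept", [(199, False), (200, True), (20000, True), (20001, False)]
    )
    def test_strict_area_boundaries(self, area, kept):
        rs = RegionSet([_dummy_region(1, area)], (1, 30000))
        assert (len(filter_noise(rs)) == 1) is kept

    def test_idempotent_and_order_independent(self):
        regs = [_dummy_region(i, a) for i, a in enumerate([5, 300, 25000, 1000])]
        rs = RegionSet(regs, (1, 30000))
        once = filter_noise(rs)
        assert region_partition(filter_noise(once)) == region_partition(once)
        rev = filter_noise(RegionSet(regs[::-1], (1, 30000)))
        assert region_partition(rev) == region_partition(once)

    def test_empty_set_passes_through(self):
        assert len(filter_noise(RegionSet([], (4, 4)))) == 0


class TestRestoreBoundaries:
    def test_connected_membrane_unchanged(self, zero_noise_phantom):
        stretched, rs = bright_regions(zero_noise_phantom.image)
        out = restore_boundaries(stretched, rs)
        assert region_partition(out) == region_partition(rs)

    def test_fragmented_membrane_reconnected(self):
        ph = generate_phantom(
            PhantomSpec(noise_cv=0.0, seed=1, membrane_gap_px=6)
        )
        stretched, rs = bright_regions(ph.image)
        H, W = ph.image.shape
        # the dashes themselves fall under the area floor and were filtered
        assert all(not (0.3 * H < r.mean_row < 0.64 * H) for r in rs.regions)
        out = restore_boundaries(stretched, rs)
        membrane = [r for r in out.regions if 0.3 * H < r.mean_row < 0.64 * H]
        assert len(membrane) == 1
        assert membrane[0].width >= 0.9 * W

    def test_blank_corridor_raises(self, zero_noise_phantom):
        spec = zero_noise_phantom.spec
        img = zero_noise_phantom.image.copy()
        H = img.shape[0]
        band = np.zeros_like(img, bool)
        band[int(0.2 * H):int(0.64 * H), :] = True
        img[(img == spec.membrane_mean) & band] = round(spec.liver_mean)
        stretched, rs = bright_regions(img)
        with pytest.raises(ExtractionError):
            restore_boundaries(stretched, rs)

    def test_too_few_candidates_raises(self):
        rs = RegionSet([_dummy_region(1, 500)], (64, 64))
        with pytest.raises(ExtractionError):
            restore_boundaries(np.zeros((64, 64), np.uint8), rs)


class TestExtractRois:
    def test_zero_noise_masks_subset_of_truth(self, zero_noise_phantom):
        ph = zero_noise_phantom
        stretched, rs = bright_regions(ph.image)
        rois = extract_rois(rs, stretched)
        assert rois.liver_mask.any() and rois.kidney_mask.any()
        assert not (rois.liver_mask & ~ph.liver_mask).any()
        assert not (rois.kidney_mask & ~ph.kidney_mask).any()
        assert not (rois.liver_mask & rois.kidney_mask).any()

    def test_masks_avoid_bright_structures(self, noisy_phantom):
        stretched, rs = bright_regions(noisy_phantom.image)
        rois = extract_rois(rs, stretched)
        bright = rs.mask()
        assert not (rois.liver_mask & bright).any()
        assert not (rois.kidney_mask & bright).any()

    def test_vertically_flipped_scan_fails_extraction(self, zero_noise_phantom):
        img = np.flipud(zero_noise_phantom.image).copy()
        stretched, rs = bright_regions(img)
        with pytest.raises(ExtractionError):
            extract_rois(restore_boundaries(stretched, rs), stretched)

    def test_noisy_dice_overlap_with_truth(self):
        hits = 0
        for seed in range(10):
            ph = generate_phantom(
                PhantomSpec(liver_mean=52.159, kidney_mean=43.724,
                            noise_cv=0.1, seed=seed)
            )
            stretched, rs = bright_regions(ph.image)
            rois = extract_rois(restore_boundaries(stretched, rs), stretched)
            if (dice(rois.liver_mask, ph.liver_mask) >= 0.5
                    and dice(rois.kidney_mask, ph.kidney_mask) >= 0.5):
                hits += 1
        assert hits >= 9
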