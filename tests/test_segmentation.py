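"""Compartment segmentation: geometry rules, erosion split, ectoderm arms."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import morphology

from mamrud import phantom, segmentation
from mamrud.compartments import Compartment
from mamrud.errors import SegmentationError, ValidationError

from conftest import jaccard, section_by_index


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestAnnotationSet:
    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(ValidationError):
            segmentation.AnnotationSet(
                mr_contour=bowtie,
                basement_membrane=np.array([[0.0, 0.0], [0.0, 20.0]]),
                mr_center=(5.0, 5.0),
            )

    def test_center_outside_polygon_rejected(self):
        square = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
        with pytest.raises(ValidationError) as err:
            segmentation.AnnotationSet(
                mr_contour=square,
                basement_membrane=np.array([[0.0, 0.0], [0.0, 20.0]]),
                mr_center=(50.0, 50.0),
            )
        assert err.value.field == "mr_center"

    def test_dict_round_trip(self):
        square = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
        ann = segmentation.AnnotationSet(
            mr_contour=square,
            basement_membrane=np.array([[0.0, 0.0], [0.0, 20.0]]),
            mr_center=(5.0, 5.0),
            is_central_section=True,
        )
        again = segmentation.AnnotationSet.from_dict(ann.to_dict())
        assert np.allclose(again.mr_contour, ann.mr_contour)
        assert again.is_central_section


class TestMammaryBand:
    def test_disk_band_is_annulus(self):
        mr = disk_mask((128, 128), (64, 64), 30)
        band = segmentation.mammary_mesenchyme_band(mr, pixel_size_um=1.0)
        expected = np.pi * (45**2 - 30**2)
        assert band.sum() == pytest.approx(expected, rel=0.05)
        assert not (band & mr).any()
        # every band pixel lies within 15 um (+1 px) of the rudiment
        dist = ndi.distance_transform_edt(~mr)
        assert dist[band].max() <= 16.0

    def test_dilation_radius_rounding(self):
        mr = disk_mask((100, 100), (50, 50), 20)
        band = segmentation.mammary_mesenchyme_band(mr, pixel_size_um=1.5)
        dist = ndi.distance_transform_edt(~mr)
        # 15 um / 1.5 um/px rounds to a 10 px disk
        assert dist[band].max() <= 11.0
        assert dist[band].max() > 9.0

    def test_too_coarse_resolution_rejected(self):
        mr = disk_mask((64, 64), (32, 32), 10)
        with pytest.raises(ValidationError):
            segmentation.mammary_mesenchyme_band(mr, pixel_size_um=40.0)

    def test_ectoderm_excluded(self):
        mr = disk_mask((128, 128), (40, 64), 30)
        ect = np.zeros((128, 128), dtype=bool)
        ect[:20] = True
        band = segmentation.mammary_mesenchyme_band(mr, 1.0, ectoderm_mask=ect)
        assert not (band & ect).any()


class TestErodeToCore:
    def test_disk_reaches_one_third(self):
        mr = disk_mask((160, 160), (80, 80), 60)
        split = segmentation.erode_to_core(mr)
        assert not split.warning
        assert split.achieved_ratio == pytest.approx(1.0 / 3.0, abs=0.05)
        equivalent_radius = np.sqrt(split.core.sum() / np.pi)
        assert equivalent_radius == pytest.approx(60 / np.sqrt(3), abs=2.0)
        assert ((split.core | split.periphery) == mr).all()
        assert not (split.core & split.periphery).any()

    def test_tiny_mask_returns_empty_core_with_warning(self):
        mr = np.zeros((16, 16), dtype=bool)
        mr[8, 8:11] = True
        split = segmentation.erode_to_core(mr)
        assert split.warning
        assert split.core.sum() == 0
        assert (split.periphery == mr).all()

    def test_non_central_section_rejected(self):
        mr = disk_mask((64, 64), (32, 32), 20)
        with pytest.raises(ValidationError):
            segmentation.erode_to_core(mr, is_central_section=False)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_erosion_scan(self, seed):
        """Chosen level minimizes |ratio - 1/3| over all erosion depths."""
        rng = np.random.default_rng(seed)
        blob = np.zeros((64, 64), dtype=bool)
        for _ in range(4):
            r, c = rng.integers(18, 46, size=2)
            blob |= disk_mask((64, 64), (r, c), rng.integers(8, 16))
        split = segmentation.erode_to_core(blob)
        area = blob.sum()
        best_oracle = np.inf
        for k in range(1, 30):
            eroded = morphology.erosion(blob, morphology.disk(k))
            if not eroded.any():
                break
            best_oracle = min(best_oracle, abs(eroded.sum() / area - 1.0 / 3.0))
        assert abs(split.achieved_ratio - 1.0 / 3.0) <= best_oracle + 0.02


class TestDermalWindow:
    def test_axis_aligned_band_below_centre(self):
        membrane = np.array([[20.0, 0.0], [20.0, 99.0]])
        window, clipped = segmentation.dermal_window((60.0, 50.0), membrane, (200, 100))
        rows = np.where(window.any(axis=1))[0]
        assert rows.min() == 60
        assert rows.max() == 124  # 65 rows: 60..124 inclusive
        assert not clipped

    def test_window_clipped_near_image_bottom(self):
        membrane = np.array([[20.0, 0.0], [20.0, 99.0]])
        window, clipped = segmentation.dermal_window((70.0, 50.0), membrane, (100, 100))
        assert clipped
        assert window.any()

    def test_exclusions_respected(self):
        membrane = np.array([[20.0, 0.0], [20.0, 99.0]])
        mr = disk_mask((200, 100), (70, 50), 25)
        window, _ = segmentation.dermal_window((60.0, 50.0), membrane, (200, 100), exclude=[mr])
        assert not (window & mr).any()

    def test_window_stays_below_membrane(self, default_stack):
        spec, _, truth = default_stack
        ann = phantom.annotations_from_truth(truth, truth.central_index)
        window, _ = segmentation.dermal_window(
            ann.mr_center, ann.basement_membrane, truth.labels.shape[1:], spec.pixel_size_um
        )
        rows = np.where(window.any(axis=1))[0]
        assert rows.min() >= truth.basement_row


class TestSplitEctoderm:
    def _band_and_bud(self):
        ect = np.zeros((80, 200), dtype=bool)
        ect[10:28] = True
        mr = disk_mask((80, 200), (45, 100), 25)
        ect &= ~mr
        return ect, mr

    def test_symmetric_arms_equal_within_2pct(self):
        ect, mr = self._band_and_bud()
        dorsal, ventral = segmentation.split_ectoderm(ect, mr)
        assert abs(dorsal.sum() - ventral.sum()) <= 0.02 * max(dorsal.sum(), ventral.sum())

    def test_orientation_flip_swaps_masks_exactly(self):
        ect, mr = self._band_and_bud()
        d1, v1 = segmentation.split_ectoderm(ect, mr, ventral_left=True)
        d2, v2 = segmentation.split_ectoderm(ect, mr, ventral_left=False)
        assert (d1 == v2).all() and (v1 == d2).all()

    def test_partition_identity(self):
        ect, mr = self._band_and_bud()
        dorsal, ventral = segmentation.split_ectoderm(ect, mr)
        touch = morphology.dilation(mr, morphology.disk(2)) & ect
        cols = np.where(touch.any(axis=0))[0]
        attachment_zone = ect & (np.arange(200)[None, :] >= cols[0]) & (np.arange(200)[None, :] <= cols[-1])
        assert ((dorsal | ventral) == (ect & ~attachment_zone)).all()
        assert not (dorsal & ventral).any()

    def test_detached_rudiment_rejected(self):
        ect = np.zeros((80, 200), dtype=bool)
        ect[10:28] = True
        mr = disk_mask((80, 200), (60, 100), 10)  # nowhere near the band
        with pytest.raises(SegmentationError):
            segmentation.split_ectoderm(ect, mr)


class TestRefineEctoderm:
    def test_phantom_band_recovered(self, default_stack):
        spec, sections, truth = default_stack
        index = truth.central_index
        section = section_by_index(sections, index)
        ann = phantom.annotations_from_truth(truth, index)
        ect = segmentation.refine_ectoderm(section.image, ann.basement_membrane, pixel_size_um=spec.pixel_size_um)
        ect &= ~truth.mr_mask(index)  # the band proper, as in the composed labelling
        # full geometric band (both arms plus the attachment zone)
        true_band = np.zeros(ect.shape, dtype=bool)
        true_band[spec.ect_top_row : truth.basement_row] = True
        true_band &= ~truth.mr_mask(index)
        assert jaccard(ect, true_band) >= 0.9

    def test_uniform_background_rejected(self):
        flat = np.full((64, 64, 3), 250, dtype=np.uint8)
        membrane = np.array([[30.0, 0.0], [30.0, 63.0]])
        with pytest.raises(SegmentationError):
            segmentation.refine_ectoderm(flat, membrane)

    def test_zero_iterations_returns_prior_band(self):
        image = np.full((64, 64, 3), 250, dtype=np.uint8)
        membrane = np.array([[30.0, 0.0], [30.0, 63.0]])
        band = segmentation.refine_ectoderm(image, membrane, band_prior_um=20, max_iter=0)
        rows = np.where(band.any(axis=1))[0]
        assert rows.min() == 10 and rows.max() == 29

    def test_polyline_outside_image_rejected(self):
        image = np.zeros((64, 64, 3), dtype=np.uint8)
        membrane = np.array([[30.0, 0.0], [30.0, 200.0]])
        with pytest.raises(ValidationError):
            segmentation.refine_ectoderm(image, membrane)


def test_split_by_line_partitions_mask():
    mask = disk_mask((64, 64), (32, 32), 20)
    first, second = segmentation.split_by_line(mask, np.array([[0.0, 32.0], [63.0, 32.0]]))
    assert ((first | second) == mask).all()
    assert not (first & second).any()
    assert first.any() and second.any()


class TestLabelCompartments:
    def test_per_compartment_jaccard_against_truth(self, default_stack, central_labeling):
        _, _, truth = default_stack
        _, _, labeling, _ = central_labeling
        index = truth.central_index
        for comp in (
            Compartment.DORSAL_ECTODERM,
            Compartment.VENTRAL_ECTODERM,
            Compartment.MR_CORE,
            Compartment.MR_PERIPHERY,
            Compartment.MAMMARY_MESENCHYME,
            Compartment.DERMAL_MESENCHYME,
        ):
            score = jaccard(labeling.mask(comp), truth.mask(index, comp))
            assert score >= 0.85, f"{comp.name}: Jaccard {score:.3f}"

    def test_labels_pairwise_disjoint_by_construction(self, central_labeling):
        _, _, labeling, _ = central_labeling
        masks = [labeling.mask(c) for c in Compartment if c is not Compartment.BACKGROUND]
        total = np.sum([m.sum() for m in masks])
        union = np.logical_or.reduce(masks).sum()
        assert total == union

    def test_overlay_matches_image_shape(self, central_labeling):
        section, _, _, overlay = central_labeling
        assert overlay.shape == section.image.shape
        assert overlay.dtype == np.uint8

    def test_non_central_section_reports_single_epithelial_compartment(self, default_stack):
        spec, sections, truth = default_stack
        index = truth.central_index - 2
        section = section_by_index(sections, index)
        ann = phantom.annotations_from_truth(truth, index)
        labeling, _ = segmentation.label_compartments(section.image, ann, spec.pixel_size_um)
        assert not labeling.core_split
        assert labeling.mask(Compartment.MR_CORE).sum() == 0
        assert labeling.mask(Compartment.MR_PERIPHERY).sum() > 0
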