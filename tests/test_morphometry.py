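"""Segmentation and shape-measurement unit/property tests.

The Feret diameter is the load-bearing measurement: it is checked exactly
against an O(n^2) brute-force pairwise maximum on randomized masks, and
for rotation invariance and scale equivariance.
"""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk, ellipse, polygon

from organoid_qc.errors import DomainError, MeasurementError, SegmentationError
from organoid_qc.morphometry import (
    LabeledMask,
    _boundary_points,
    _brute_force_diameter,
    corrected_fluorescence_intensity,
    detect_cysts,
    max_feret_distance,
    mean_fluorescence_intensity,
    measure_shape,
    max_feret_distance as feret,
    section_feret,
    segment_organoid,
)
from conftest import random_blob_mask


class TestFeret:
    try:
        from hypothesis import given, settings, strategies as st

        @given(
            st.lists(
                st.tuples(st.integers(0, 100), st.integers(0, 100)),
                min_size=2,
                max_size=60,
            )
        )
        @settings(max_examples=200, deadline=None, derandomize=True)
        def test_property_equals_brute_force(self, pts):
            """Calipers == brute force on arbitrary lattice point sets."""
            pts = np.asarray(pts, dtype=float)
            assert max_feret_distance(pts) == pytest.approx(
                _brute_force_diameter(pts), abs=1e-9
            )
    except ImportError:  # pragma: no cover - hypothesis is an optional extra
        pass

    def test_equals_brute_force_on_random_masks(self):
        """Rotating calipers == O(n^2) pairwise maximum, exactly, on 120 blobs."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            pts = _boundary_points(random_blob_mask(rng))
            assert max_feret_distance(pts) == pytest.approx(_brute_force_diameter(pts), abs=1e-9)

    def test_equals_brute_force_on_random_point_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pts = rng.integers(0, 80, size=(rng.integers(2, 120), 2)).astype(float)
            assert max_feret_distance(pts) == pytest.approx(_brute_force_diameter(pts), abs=1e-9)

    def test_collinear_points(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [5, 5]], dtype=float)
        assert max_feret_distance(pts) == pytest.approx(np.hypot(5, 5))

    def test_degenerate_sizes(self):
        assert max_feret_distance(np.array([[3.0, 4.0]])) == 0.0
        with pytest.raises(DomainError):
            max_feret_distance(np.zeros((4, 3)))

    def test_right_triangle_hypotenuse(self):
        """Legs 300 um x 400 um at 10 um/px -> Feret = 500 um (+-2 px)."""
        mask = np.zeros((50, 50), dtype=bool)
        rr, cc = polygon([5, 35, 5], [5, 5, 45])
        mask[rr, cc] = True
        rec = measure_shape(LabeledMask(mask, 10.0), "tri")
        assert rec.feret_um == pytest.approx(500.0, abs=20.0)

    def test_rotation_invariance(self):
        mask = np.zeros((160, 160), dtype=bool)
        rr, cc = ellipse(80, 80, 30, 55)
        mask[rr, cc] = True
        base = feret(_boundary_points(mask))
        for angle in (20, 45, 70):
            rot = ndimage.rotate(mask.astype(np.uint8), angle, order=0, reshape=True) > 0
            assert feret(_boundary_points(rot)) == pytest.approx(base, abs=1.0)


class TestMeasureShape:
    def test_disc_limit(self):
        """A large discretized disc: circularity, solidity, AR -> 1 within 3%."""
        mask = np.zeros((220, 220), dtype=bool)
        rr, cc = disk((110, 110), 100)
        mask[rr, cc] = True
        rec = measure_shape(LabeledMask(mask, 1.0), "disc")
        assert rec.circularity == pytest.approx(1.0, abs=0.03)
        assert rec.solidity == pytest.approx(1.0, abs=0.03)
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.03)
        assert rec.roundness == pytest.approx(1.0, abs=0.03)
        assert rec.feret_um == pytest.approx(200.0, abs=2.0)

    def test_isodiametric_inequality_random_masks(self):
        """area <= pi * feret^2 / 4 for every measured record."""
        rng = np.random.default_rng(5)
        for _ in range(60):
            mask = random_blob_mask(rng, size=64)
            rec = measure_shape(LabeledMask(mask, 2.5), "blob")
            assert rec.area_um2 <= np.pi * rec.feret_um**2 / 4 * 1.0001

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        mask = random_blob_mask(rng, size=64)
        r1 = measure_shape(LabeledMask(mask, 1.0))
        r2 = measure_shape(LabeledMask(mask, 2.0))
        assert r2.feret_um == pytest.approx(2 * r1.feret_um)
        assert r2.perimeter_um == pytest.approx(2 * r1.perimeter_um)
        assert r2.area_um2 == pytest.approx(4 * r1.area_um2)
        for attr in ("aspect_ratio", "circularity", "roundness", "solidity"):
            assert getattr(r2, attr) == pytest.approx(getattr(r1, attr))

    def test_descriptor_ranges(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            rec = measure_shape(LabeledMask(random_blob_mask(rng), 1.0))
            assert 0 < rec.circularity <= 1
            assert 0 < rec.roundness <= 1
            assert 0 < rec.solidity <= 1
            assert rec.aspect_ratio >= 1

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4] = True
        with pytest.raises(MeasurementError):
            measure_shape(LabeledMask(mask, 1.0))


class TestSegmentation:
    def test_uniform_image_raises(self):
        with pytest.raises(SegmentationError):
            segment_organoid(np.full((50, 50), 128, dtype=np.uint8), 1.0)

    def test_disc_area_within_one_percent(self):
        img = np.full((200, 200), 220, dtype=np.uint8)
        rr, cc = disk((100, 100), 60)
        img[rr, cc] = 60
        mask = segment_organoid(img, 1.0)
        assert mask.mask.sum() == pytest.approx(np.pi * 60**2, rel=0.01)

    def test_largest_component_kept_and_holes_filled(self):
        img = np.full((120, 120), 220, dtype=np.uint8)
        rr, cc = disk((60, 60), 40)
        img[rr, cc] = 70
        rr, cc = disk((60, 60), 10)  # bright interior cyst = hole after threshold
        img[rr, cc] = 230
        rr, cc = disk((10, 105), 6)  # small satellite blob
        img[rr, cc] = 70
        mask = segment_organoid(img, 1.0)
        labels, n = ndimage.label(mask.mask)
        assert n == 1
        assert mask.mask[60, 60]  # hole filled

    def test_border_touching_sets_warning(self):
        img = np.full((60, 60), 220, dtype=np.uint8)
        img[:, :40] = 60
        with pytest.warns(UserWarning):
            mask = segment_organoid(img, 1.0)
        assert mask.border_warning


class TestCysts:
    @staticmethod
    def _organoid_with_discs(n_discs, disc_radius=8):
        img = np.full((240, 240), 220, dtype=np.uint8)
        rr, cc = disk((120, 120), 90)
        img[rr, cc] = 80
        centers = [(80, 80), (160, 160), (80, 160), (160, 80)][:n_discs]
        for ctr in centers:
            rr, cc = disk(ctr, disc_radius)
            img[rr, cc] = 185
        return img

    def test_cyst_free(self):
        img = self._organoid_with_discs(0)
        mask = segment_organoid(img, 10.0)
        assert detect_cysts(img, mask, min_cyst_area_um2=1000) == (0, 0.0)

    def test_count_matches_rendered_discs(self):
        img = self._organoid_with_discs(3)
        mask = segment_organoid(img, 10.0)
        count, ratio = detect_cysts(img, mask, min_cyst_area_um2=1000)
        assert count == 3
        assert ratio == pytest.approx(3 * np.pi * 8**2 / (np.pi * 90**2), rel=0.1)

    def test_single_disc_area_ratio(self):
        """One disc with ~10% of the organoid area -> ratio 0.10 +- 0.01."""
        img = np.full((240, 240), 220, dtype=np.uint8)
        rr, cc = disk((120, 120), 90)
        img[rr, cc] = 80
        rr, cc = disk((120, 120), int(round(90 * np.sqrt(0.1))))
        img[rr, cc] = 185
        mask = segment_organoid(img, 10.0)
        _, ratio = detect_cysts(img, mask, min_cyst_area_um2=1000)
        assert ratio == pytest.approx(0.10, abs=0.01)

    def test_min_area_domain_error(self):
        img = self._organoid_with_discs(1)
        mask = segment_organoid(img, 10.0)
        with pytest.raises(DomainError):
            detect_cysts(img, mask, min_cyst_area_um2=0)


class TestFluorescence:
    @staticmethod
    def _mask(val=7.0):
        img = np.zeros((40, 40))
        img[10:20, 10:20] = val
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:20] = True
        bg = np.zeros((40, 40), dtype=bool)
        bg[30:, 30:] = True
        return img, LabeledMask(mask, 1.0), bg

    def test_cfi_zero_background(self):
        img, mask, bg = self._mask(5.0)
        cfi, _ = corrected_fluorescence_intensity(img, mask, bg)
        assert cfi == pytest.approx(img[mask.mask].sum())

    def test_cfi_exact_cancellation(self):
        img, mask, bg = self._mask(3.0)
        img[:, :] = 3.0
        cfi, per_area = corrected_fluorescence_intensity(img, mask, bg)
        assert cfi == pytest.approx(0.0)
        assert per_area == pytest.approx(0.0)

    def test_cfi_plug_in_arithmetic(self):
        """IntDen 1000, area 10 px, background mean 5 -> CFI = 950."""
        img = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :] = True  # 10 px
        img[0, :] = 100.0  # IntDen = 1000
        bg = np.zeros((10, 10), dtype=bool)
        bg[5, :] = True
        img[5, :] = 5.0
        cfi, _ = corrected_fluorescence_intensity(img, LabeledMask(mask, 1.0), bg)
        assert cfi == pytest.approx(950.0)

    def test_cfi_needs_background(self):
        img, mask, _ = self._mask()
        with pytest.raises(MeasurementError):
            corrected_fluorescence_intensity(img, mask, np.zeros((40, 40), dtype=bool))

    def test_mfi_constant_field_and_masking(self):
        img, mask, _ = self._mask(7.0)
        assert mean_fluorescence_intensity(img, mask) == pytest.approx(7.0)
        img2 = img.copy()
        img2[~mask.mask] = 999.0  # background must not matter
        assert mean_fluorescence_intensity(img2, mask) == pytest.approx(7.0)

    def test_section_feret_matches_brute_force(self):
        """Brute-force pairwise maximum over the boundary-pixel corner points."""
        rng = np.random.default_rng(23)
        mask = random_blob_mask(rng, size=60)
        lm = LabeledMask(mask, 4.0)
        centers = _boundary_points(mask)
        offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
        corners = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        assert section_feret(lm) == pytest.approx(_brute_force_diameter(corners) * 4.0)
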