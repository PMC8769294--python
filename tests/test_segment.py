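"""Segmentation geometry: threshold behaviour, Feret calipers, volumes, measurement."""
import numpy as np
import pytest

from viatrace import (
    AbsorbanceImage,
    CellSpec,
    PhantomSpec,
    PixelDoseModel,
    SegmentationParams,
    ellipsoid_volume,
    generate_field,
    measure_cells,
    segment_cells,
    to_absorbance,
)
from viatrace.errors import InvalidInputError
from viatrace.segment import feret_diameters


def absorbance(arr, pixel_size=1.0):
    return AbsorbanceImage(np.asarray(arr, dtype=float), pixel_size=pixel_size)


class TestEllipsoidVolume:
    def test_sphere_closed_form(self):
        # 10 um diameter sphere: (4/3) pi (5 um)^3 = 5.236e-13 L
        assert ellipsoid_volume(10.0, 10.0) == pytest.approx(5.236e-13, rel=1e-3)

    def test_prolate_spheroid_scalar_oracle(self):
        expect = (4.0 / 3.0) * np.pi * 8.0 * 4.5 * 4.5 * 1e-15
        assert ellipsoid_volume(16.0, 9.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(6.79e-13, rel=1e-2)

    @pytest.mark.parametrize("fmax,fmin", [(10.0, 0.0), (0.0, 0.0), (-1.0, 1.0), (5.0, 6.0)])
    def test_contract_violations(self, fmax, fmin):
        with pytest.raises(InvalidInputError):
            ellipsoid_volume(fmax, fmin)


class TestFeret:
    def test_single_pixel_has_pixel_sized_feret(self):
        fmax, fmin = feret_diameters(np.array([[3, 5]]), pixel_size=0.5)
        assert fmax == pytest.approx(np.sqrt(2) * 0.5)
        assert fmin == pytest.approx(0.5)

    def test_square_block(self):
        coords = np.argwhere(np.ones((10, 10), dtype=bool))
        fmax, fmin = feret_diameters(coords, pixel_size=1.0)
        assert fmax == pytest.approx(10 * np.sqrt(2))
        assert fmin == pytest.approx(10.0)

    def test_row_of_pixels(self):
        coords = np.array([[0, c] for c in range(7)])
        fmax, fmin = feret_diameters(coords)
        assert fmax == pytest.approx(np.hypot(7, 1))
        assert fmin == pytest.approx(1.0)

    def test_invariants_on_random_blobs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(1, 60)
            coords = np.unique(rng.integers(0, 15, size=(n, 2)), axis=0)
            fmax, fmin = feret_diameters(coords)
            assert fmin <= fmax + 1e-12
            d_eq = 2 * np.sqrt(len(coords) / np.pi)
            assert d_eq <= fmax + 1e-9


class TestSegmentCells:
    def test_constant_image_yields_no_objects(self, seg_params):
        labels = segment_cells(absorbance(np.full((64, 64), 0.3)), seg_params)
        assert labels.max() == 0

    def test_window_larger_than_image_rejected(self):
        p = SegmentationParams(window=99)
        with pytest.raises(InvalidInputError):
            segment_cells(absorbance(np.zeros((32, 32))), p)

    def _disk_field(self, radii_um, pixel_size=1.0, value=0.8, shape=(200, 200)):
        A = np.zeros(shape)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        centers = [(40, 40), (40, 120), (120, 40), (120, 120), (160, 160)]
        for (cy, cx), r in zip(centers, radii_um):
            A[(yy - cy) ** 2 + (xx - cx) ** 2 <= (r / pixel_size) ** 2] = value
        return absorbance(A, pixel_size), centers

    def test_five_disks_found_with_matching_centroids(self, seg_params):
        img, centers = self._disk_field([8.0] * 5)
        labels = segment_cells(img, seg_params)
        assert labels.max() == 5
        from scipy import ndimage

        found = ndimage.center_of_mass(labels > 0, labels, range(1, 6))
        found = sorted(tuple(np.round(c)) for c in found)
        assert found == sorted((float(r), float(c)) for r, c in centers)

    def test_small_disk_removed_by_size_filter(self, seg_params):
        img, _ = self._disk_field([8.0, 8.0, 8.0, 8.0, 2.0])
        labels = segment_cells(img, seg_params)
        assert labels.max() == 4  # the 2 um disk fails r_min = 4 um

    def test_size_filter_invariant_on_random_fields(self, seg_params, model):
        """Every returned object has equivalent-circle radius inside [r_min, r_max]."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            A = rng.normal(0.0, 0.01, (128, 128))
            for _ in range(rng.integers(1, 6)):
                r = rng.uniform(2.0, 20.0)
                cy, cx = rng.uniform(20, 108, 2)
                yy, xx = np.mgrid[:128, :128]
                A[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = rng.uniform(0.4, 1.0)
            img = absorbance(A)
            labels = segment_cells(img, seg_params)
            for rec in measure_cells(labels, img, model):
                r_eq = np.sqrt(rec.area_um2 / np.pi)
                assert seg_params.r_min <= r_eq <= seg_params.r_max
                assert rec.feret_min_um <= rec.feret_max_um + 1e-9

    def test_pixel_size_scaling_of_areas(self, model):
        img1, _ = self._disk_field([8.0] * 5, pixel_size=1.0)
        img2 = absorbance(img1.pixels, pixel_size=2.0)
        p1 = SegmentationParams(sensitivity=0.45)
        p2 = SegmentationParams(sensitivity=0.45, r_min=8.0, r_max=32.0)
        rec1 = measure_cells(segment_cells(img1, p1), img1, model)
        rec2 = measure_cells(
            segment_cells(img2, p2), img2, PixelDoseModel(2500.0, 2.0)
        )
        assert len(rec1) == len(rec2)
        for a, b in zip(rec1, rec2):
            assert a.area_px == b.area_px
            assert b.area_um2 == pytest.approx(4 * a.area_um2)


class TestMeasureCells:
    def test_uniform_square_closed_form(self, model):
        A = np.zeros((30, 30))
        A[10:20, 10:20] = 0.2  # 10x10 px at A=0.2 -> sum 20
        labels = np.zeros_like(A, dtype=int)
        labels[10:20, 10:20] = 1
        (rec,) = measure_cells(labels, absorbance(A), model)
        assert rec.sum_absorbance == pytest.approx(20.0)
        # 20 OD.px * 1e-12 m^2 / 2500 = 8 fmol
        assert rec.moles == pytest.approx(8e-15, rel=1e-12)
        assert rec.area_um2 == 100.0

    def test_brute_force_oracle_on_random_labelings(self, model):
        rng = np.random.default_rng(5)
        A = rng.uniform(-0.2, 1.0, (40, 40))
        labels = rng.integers(0, 5, (40, 40))
        recs = measure_cells(labels, absorbance(A), model)
        for rec in recs:
            total = 0.0
            for (r, c), lab in np.ndenumerate(labels):
                if lab == rec.label:
                    total += A[r, c]
            assert rec.sum_absorbance == pytest.approx(total, rel=1e-12)
            assert rec.moles == pytest.approx(total * 1e-12 / 2500.0, rel=1e-12)

    def test_empty_label_set_gives_empty_list(self, model):
        assert measure_cells(np.zeros((10, 10), int), absorbance(np.zeros((10, 10))), model) == []

    def test_missing_requested_label_warns_and_skips(self, model):
        labels = np.zeros((10, 10), int)
        labels[2:8, 2:8] = 1
        with pytest.warns(UserWarning, match="label 7"):
            recs = measure_cells(labels, absorbance(np.ones((10, 10))), model, which=[1, 7])
        assert [r.label for r in recs] == [1]

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(InvalidInputError):
            measure_cells(np.zeros((5, 5), int), absorbance(np.zeros((6, 6))), model)


class TestPhantomSegmentationAgreement:
    def test_counts_match_ground_truth_on_separated_cells(self, seg_params, model):
        """Well-separated synthetic cells at high SNR are all found, exactly once."""
        rng = np.random.default_rng(21)
        cells = []
        for i in range(5):
            cells.append(
                CellSpec(
                    center_um=(40.0 + 50.0 * (i // 3), 40.0 + 50.0 * (i % 3)),
                    semiaxes_um=(6.0, 5.5),
                    moles=15e-15,
                    ring_moles=3e-15,
                )
            )
        spec = PhantomSpec(shape=(256, 256), cells=tuple(cells), medium_absorbance=0.3)
        trip = generate_field(spec)
        A = to_absorbance(trip.I, trip.Imax, trip.Imin)
        labels = segment_cells(A, seg_params)
        assert labels.max() == 5
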