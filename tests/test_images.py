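import json
import math

import numpy as np
import pytest

from cmrtexture.images import (DEFAULT_SPACING_MM, RoiMask, RoiPolygon,
                               normalize_and_quantize, rasterize_roi, read_image,
                               resample_to_spacing, write_pgm)

from conftest import make_gray
from oracles import bf_bilinear, bf_point_in_polygon


def _write_dicom(path, pixels, spacing=None):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if spacing is not None:
        ds.PixelSpacing = [str(spacing), str(spacing)]
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


class TestReadImage:
    def test_dicom_spacing_passthrough(self, tmp_path, rng):
        px = rng.integers(0, 4000, (16, 16))
        path = tmp_path / "img.dcm"
        _write_dicom(path, px, spacing=0.390625)
        img = read_image(path)
        assert img.spacing_row == img.spacing_col == 0.390625
        np.testing.assert_array_equal(img.pixels, px.astype(float))

    def test_raster_fixture_roundtrip(self, tmp_path, rng):
        original = make_gray(rng.normal(400, 60, (12, 12)), spacing=0.78125)
        path = tmp_path / "img.pgm"
        write_pgm(original, path)
        back = read_image(path)
        assert back.spacing_row == back.spacing_col == 0.78125
        # 16-bit storage: error bounded by one grey step of the dynamic range
        step = np.ptp(original.pixels) / 65535
        assert np.max(np.abs(back.pixels - original.pixels)) <= step

    def test_missing_spacing_is_hard_error(self, tmp_path):
        path = tmp_path / "img.pgm"
        write_pgm(make_gray(np.zeros((4, 4)) + [[0, 1, 2, 3]]), path, sidecar=False)
        with pytest.raises(ValueError, match="spacing unavailable"):
            read_image(path)
        path.with_suffix(".json").write_text(json.dumps({"slope": 1.0}))
        with pytest.raises(ValueError, match="spacing unavailable"):
            read_image(path)

    def test_dicom_without_spacing_errors(self, tmp_path, rng):
        path = tmp_path / "img.dcm"
        _write_dicom(path, rng.integers(0, 100, (8, 8)))
        with pytest.raises(ValueError, match="spacing"):
            read_image(path)


class TestResample:
    def test_default_target_matches_fov200_matrix512(self):
        assert DEFAULT_SPACING_MM == 200 / 512
        img = make_gray(np.zeros((512, 512)) + np.arange(512), spacing=200 / 512)
        out = resample_to_spacing(img, DEFAULT_SPACING_MM)
        assert out.spacing_row == out.spacing_col == 0.390625
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_already_at_target_is_identity(self, rng):
        img = make_gray(rng.normal(size=(9, 7)), spacing=0.5)
        out = resample_to_spacing(img, 0.5)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_upsampled_ramp_matches_bilinear_oracle(self):
        img = make_gray([[0, 2], [0, 2]], spacing=1.0)
        out = resample_to_spacing(img, 0.5)
        assert out.shape == (3, 3)
        for r in range(3):
            for c in range(3):
                expected = bf_bilinear(img.pixels, r * 0.5, c * 0.5)
                assert out.pixels[r, c] == pytest.approx(expected, abs=1e-12)

    def test_random_image_matches_bilinear_oracle(self, rng):
        img = make_gray(rng.normal(size=(7, 5)), spacing=1.25)
        out = resample_to_spacing(img, 0.4)
        for r in range(0, out.shape[0], 2):
            for c in range(0, out.shape[1], 2):
                expected = bf_bilinear(img.pixels, r * 0.4 / 1.25, c * 0.4 / 1.25)
                assert out.pixels[r, c] == pytest.approx(expected, rel=1e-12)

    def test_resampling_is_idempotent(self, rng):
        img = make_gray(rng.normal(size=(32, 32)), spacing=0.7)
        once = resample_to_spacing(img, 0.45)
        twice = resample_to_spacing(once, 0.45)
        np.testing.assert_allclose(twice.pixels, once.pixels, rtol=1e-9)

    def test_extent_preserved_within_one_pixel(self, rng):
        img = make_gray(rng.normal(size=(64, 48)), spacing=1.0)
        out = resample_to_spacing(img, 0.39)
        for n_in, n_out in zip(img.shape, out.shape):
            assert abs((n_in - 1) * 1.0 - (n_out - 1) * 0.39) <= 0.39

    def test_too_small_output_errors(self):
        img = make_gray(np.arange(4.0).reshape(2, 2), spacing=0.1)
        with pytest.raises(ValueError):
            resample_to_spacing(img, 5.0)


class TestRasterize:
    def test_rectangle_center_rule_pixel_count(self):
        poly = RoiPolygon([[1.5, 2.5], [5.5, 2.5], [5.5, 7.5], [1.5, 7.5]])
        mask = rasterize_roi(poly, (12, 12))
        assert mask.n_pixels == 4 * 5
        rr, cc = np.nonzero(mask.inside)
        assert rr.min() == 3 and rr.max() == 7 and cc.min() == 2 and cc.max() == 5

    def test_triangle_matches_pointwise_oracle(self):
        verts = np.array([[1.2, 1.1], [10.7, 2.3], [4.9, 11.6]])
        mask = rasterize_roi(RoiPolygon(verts), (14, 14))
        for r in range(14):
            for c in range(14):
                assert mask.inside[r, c] == bf_point_in_polygon(c, r, verts)

    def test_vertex_rotation_invariance(self):
        verts = np.array([[1.2, 1.1], [10.7, 2.3], [8.0, 9.0], [4.9, 11.6]])
        base = rasterize_roi(RoiPolygon(verts), (14, 14)).inside
        for shift in range(1, 4):
            rolled = rasterize_roi(RoiPolygon(np.roll(verts, shift, axis=0)), (14, 14))
            np.testing.assert_array_equal(rolled.inside, base)

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(ValueError):
            RoiPolygon([[0, 0], [1, 1]])                     # 2 vertices
        with pytest.raises(ValueError):
            RoiPolygon([[0, 0], [4, 4], [4, 0], [0, 4]])     # bowtie
        with pytest.raises(ValueError, match="too small"):
            rasterize_roi(RoiPolygon([[0.4, 0.4], [2.6, 0.4], [1.5, 2.6]]), (32, 32))


class TestNormalizeQuantize:
    def _probe_image(self):
        # 33 in-mask values with mean exactly 100 and SD exactly 10, containing
        # the probes 70 (=mu-3s), 100 (=mu) and 130 (=mu+3s)
        a = math.sqrt(50.0)
        vals = [70.0, 100.0, 130.0] + [100 + a] * 15 + [100 - a] * 15
        px = np.full((6, 6), 100.0)
        px.flat[:33] = vals
        mask = np.zeros((6, 6), dtype=bool)
        mask.flat[:33] = True
        return make_gray(px), RoiMask(mask)

    def test_stated_mapping_on_probe_values(self):
        img, mask = self._probe_image()
        q = normalize_and_quantize(img, mask, bits=6)
        assert q.window.mu == pytest.approx(100.0)
        assert q.window.sigma == pytest.approx(10.0)
        flat = q.levels.flat
        assert flat[0] == 1      # v = 70 -> level 1
        assert flat[1] == 33     # v = 100 -> level 33
        assert flat[2] == 64     # v = 130 -> level 64 (clamped)

    def test_values_outside_window_clamp(self):
        img, mask = self._probe_image()
        px = img.pixels.copy()
        px.flat[0] = 100 - 5 * 10.2   # far below the window
        q = normalize_and_quantize(make_gray(px), mask, bits=6)
        assert q.levels.flat[0] == 1

    def test_constant_roi_degenerates_with_warning(self):
        img = make_gray(np.full((6, 6), 7.0))
        mask = RoiMask(np.ones((6, 6), dtype=bool))
        with pytest.warns(UserWarning, match="sigma = 0"):
            q = normalize_and_quantize(img, mask, bits=4)
        assert np.all(q.levels == 1)

    def test_quantization_is_monotone(self, rng):
        img = make_gray(rng.normal(100, 25, (8, 8)))
        mask = RoiMask(np.ones((8, 8), dtype=bool))
        q = normalize_and_quantize(img, mask, bits=6)
        order = np.argsort(img.pixels.ravel())
        levels_sorted = q.levels.ravel()[order]
        assert np.all(np.diff(levels_sorted) >= 0)

    @pytest.mark.parametrize("k,c", [(2.5, 30.0), (0.3, -500.0), (17.0, 0.0)])
    def test_window_is_affine_equivariant(self, rng, k, c):
        px = rng.normal(0, 1, (8, 8))
        mask = RoiMask(np.ones((8, 8), dtype=bool))
        q1 = normalize_and_quantize(make_gray(px), mask, bits=6)
        q2 = normalize_and_quantize(make_gray(k * px + c), mask, bits=6)
        np.testing.assert_array_equal(q1.levels, q2.levels)

    def test_out_of_mask_pixels_flagged_zero(self, rng):
        px = rng.normal(size=(6, 6))
        mask = np.ones((6, 6), dtype=bool)
        mask[0, :3] = False
        q = normalize_and_quantize(make_gray(px), RoiMask(mask), bits=6)
        assert np.all(q.levels[~mask] == 0) and np.all(q.levels[mask] >= 1)
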