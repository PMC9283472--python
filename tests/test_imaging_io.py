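"""I/O round trips, preprocessing semantics, and resize contracts."""

import numpy as np
import pytest
from PIL import Image

from mammodensity import imaging_io as iio


@pytest.fixture
def gradient_image():
    return np.linspace(0.0, 1.0, 48 * 64).reshape(48, 64)


class TestLoadSave:
    def test_png8_round_trip(self, tmp_path, gradient_image):
        p = tmp_path / "x.png"
        iio.save_image(gradient_image, p, bit_depth=8)
        back = iio.load_image(p)
        assert back.original_size == (48, 64)
        assert np.abs(back.pixels - gradient_image).max() <= 0.5 / 255 + 1e-12

    def test_png8_save_load_save_identical_bytes(self, tmp_path, gradient_image):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        iio.save_image(gradient_image, p1)
        iio.save_image(iio.load_image(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_16bit_tiff_scaled_to_unit_range(self, tmp_path, gradient_image):
        p = tmp_path / "x.tiff"
        Image.fromarray((gradient_image * 65535).round().astype(np.uint16)).save(p)
        back = iio.load_image(p)
        assert np.abs(back.pixels - gradient_image).max() <= 0.5 / 65535 + 1e-12

    def test_constant_zero_image(self, tmp_path):
        p = tmp_path / "z.png"
        iio.save_image(np.zeros((40, 40)), p)
        assert np.all(iio.load_image(p).pixels == 0.0)

    def test_color_rejected(self, tmp_path):
        p = tmp_path / "c.png"
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8), "RGB").save(p)
        with pytest.raises(ValueError, match="grayscale"):
            iio.load_image(p)

    def test_dicom_read(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        ds = FileDataset(str(tmp_path / "x.dcm"), {}, file_meta=meta,
                         preamble=b"\x00" * 128)
        arr = (np.linspace(0, 4095, 16 * 16).reshape(16, 16)).astype(np.uint16)
        ds.Rows, ds.Columns = 16, 16
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 12, 11
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arr.tobytes()
        ds.save_as(tmp_path / "x.dcm", enforce_file_format=True)
        back = iio.load_image(tmp_path / "x.dcm")
        assert back.pixels.max() == pytest.approx(1.0, abs=1e-6)
        assert back.original_size == (16, 16)

    def test_mask_round_trip(self, tmp_path, rng):
        mask = iio.BinaryMask((rng.random((20, 30)) > 0.5).astype(np.uint8))
        p = tmp_path / "m.png"
        iio.save_mask(mask, p)
        back = iio.load_mask(p)
        np.testing.assert_array_equal(back.pixels, mask.pixels)
        assert set(np.unique(np.asarray(Image.open(p)))) <= {0, 255}


class TestApplyBreastMask:
    def test_identity_and_zero(self, gradient_image):
        img = iio.Mammogram(gradient_image)
        ones = iio.BinaryMask(np.ones_like(gradient_image, dtype=np.uint8))
        zeros = iio.BinaryMask(np.zeros_like(gradient_image, dtype=np.uint8))
        np.testing.assert_array_equal(
            iio.apply_breast_mask(img, ones).pixels, gradient_image)
        assert np.all(iio.apply_breast_mask(img, zeros).pixels == 0)

    def test_half_plane_elementwise(self, gradient_image):
        half = np.zeros_like(gradient_image, dtype=np.uint8)
        half[:, 32:] = 1
        out = iio.apply_breast_mask(iio.Mammogram(gradient_image),
                                    iio.BinaryMask(half))
        np.testing.assert_array_equal(out.pixels, gradient_image * half)

    def test_idempotent(self, gradient_image, rng):
        mask = iio.BinaryMask((rng.random(gradient_image.shape) > 0.3).astype(np.uint8))
        once = iio.apply_breast_mask(iio.Mammogram(gradient_image), mask)
        twice = iio.apply_breast_mask(once, mask)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_dimension_mismatch(self, gradient_image):
        with pytest.raises(ValueError, match="mismatch"):
            iio.apply_breast_mask(iio.Mammogram(gradient_image),
                                  iio.BinaryMask(np.ones((4, 4), dtype=np.uint8)))


class TestNormalize:
    def test_affine_forcing(self):
        img = iio.Mammogram(np.array([[10.0, 20.0, 30.0]]))
        out = iio.normalize_intensity(img)
        np.testing.assert_allclose(out.pixels, [[0.0, 0.5, 1.0]])

    def test_already_normalized_unchanged(self):
        img = iio.Mammogram(np.array([[0.0, 0.5, 1.0]]))
        np.testing.assert_allclose(iio.normalize_intensity(img).pixels,
                                   img.pixels)

    def test_idempotent(self, rng):
        img = iio.Mammogram(rng.random((16, 16)) * 7 + 3)
        once = iio.normalize_intensity(img)
        twice = iio.normalize_intensity(once)
        np.testing.assert_allclose(once.pixels, twice.pixels, atol=1e-12)

    def test_constant_region_warns_all_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            out = iio.normalize_intensity(iio.Mammogram(np.full((8, 8), 3.0)))
        assert np.all(out.pixels == 0.0)

    def test_region_restricted_uses_masked_min_max(self, rng):
        px = rng.random((10, 10))
        region = np.zeros((10, 10), dtype=np.uint8)
        region[2:8, 2:8] = 1
        out = iio.normalize_intensity(iio.Mammogram(px),
                                      iio.BinaryMask(region))
        vals = px[region.astype(bool)]
        expected = (px - vals.min()) / (vals.max() - vals.min())
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)


class TestResize:
    def test_identity_resize(self, rng):
        img = iio.Mammogram(rng.random((64, 64)))
        out = iio.resize_for_model(img, 64)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-6)

    def test_mask_resize_stays_binary(self, rng):
        mask = iio.BinaryMask((rng.random((100, 70)) > 0.5).astype(np.uint8))
        out = iio.resize_for_model(mask, 64)
        assert set(np.unique(out.pixels)) <= {0, 1}
        assert out.shape == (64, 64)
        assert out.original_size == (100, 70)

    def test_nearest_neighbor_source_selection(self):
        # center-aligned 4->2 downsampling picks source rows/cols 1 and 3
        from mammodensity.imaging_io import _resize_mask_array
        checker = (np.indices((4, 4)).sum(axis=0) % 2).astype(np.uint8)
        out = _resize_mask_array(checker, (2, 2))
        np.testing.assert_array_equal(out, checker[np.ix_([1, 3], [1, 3])])

    def test_restore_round_trip_at_native_size(self, rng):
        mask = iio.BinaryMask((rng.random((64, 64)) > 0.5).astype(np.uint8))
        restored = iio.restore_to_original(iio.resize_for_model(mask, 64), (64, 64))
        np.testing.assert_array_equal(restored.pixels, mask.pixels)

    def test_restore_all_ones(self):
        mask = iio.BinaryMask(np.ones((64, 64), dtype=np.uint8),
                              original_size=(300, 211))
        out = iio.restore_to_original(mask)
        assert out.shape == (300, 211)
        assert np.all(out.pixels == 1)

    def test_upscaled_blob_area_scales_quadratically(self):
        blob = np.zeros((64, 64), dtype=np.uint8)
        blob[20:40, 15:45] = 1
        up = iio.restore_to_original(iio.BinaryMask(blob), (128, 128))
        assert up.pixels.sum() == pytest.approx(4 * blob.sum(), rel=0.05)

    def test_probability_map_restore_bilinear_threshold(self):
        probs = np.zeros((8, 8))
        probs[:4] = 0.9
        out = iio.restore_to_original(probs, (16, 16), threshold=0.5)
        assert out.dtype == np.uint8
        assert set(np.unique(out)) <= {0, 1}
        assert out[:6].mean() > 0.9  # upper band stays foreground


def test_annotated_sample_dimension_check(rng):
    img = iio.Mammogram(rng.random((8, 8)))
    m8 = iio.BinaryMask(np.ones((8, 8), dtype=np.uint8))
    with pytest.raises(ValueError, match="share dimensions"):
        iio.AnnotatedSample(img, m8, iio.BinaryMask(np.ones((4, 4), dtype=np.uint8),
                                                    role="dense"))


def test_annotated_sample_nesting_warning(rng):
    img = iio.Mammogram(rng.random((8, 8)))
    breast = np.zeros((8, 8), dtype=np.uint8)
    breast[:4] = 1
    dense = np.zeros((8, 8), dtype=np.uint8)
    dense[5, 5] = 1  # outside breast
    with pytest.warns(UserWarning, match="outside"):
        iio.AnnotatedSample(img, iio.BinaryMask(breast),
                            iio.BinaryMask(dense, role="dense"))
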