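import numpy as np
import pytest
from PIL import Image

from tumorkit import image_io, phantoms
from tumorkit.errors import (ArityError, FormatError, ShapeError,
                             UnlabeledNameError)
from tumorkit.image_io import GrayImage2D


class TestLabelFromName:
    @pytest.mark.parametrize("name,expected", [
        ("Y12.jpg", 1),
        ("N3.png", 0),
        ("y7.png", 1),
        ("n1.dcm", 0),
        ("/some/dir/Y1.png", 1),
    ])
    def test_convention(self, name, expected):
        assert image_io.label_from_name(name) == expected

    @pytest.mark.parametrize("name", ["brain.png", "", "12Y.png", "_N.png"])
    def test_nonconforming_names_raise(self, name):
        with pytest.raises(UnlabeledNameError):
            image_io.label_from_name(name)


class TestReadImage:
    def test_png_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 256, (40, 30)).astype(float)
        img = GrayImage2D(arr, value_range="byte")
        path = tmp_path / "x.png"
        image_io.write_png(img, path)
        back = image_io.read_image(path)
        assert back.value_range == "byte"
        np.testing.assert_array_equal(back.pixels, arr)

    def test_constant_png(self, tmp_path):
        path = tmp_path / "c.png"
        Image.fromarray(np.full((32, 32), 100, dtype=np.uint8)).save(path)
        img = image_io.read_image(path)
        assert img.pixels.min() == img.pixels.max() == 100

    def test_rgb_equal_channels_gives_gray_value(self, tmp_path):
        rgb = np.full((16, 16, 3), 50, dtype=np.uint8)
        path = tmp_path / "rgb.jpg"
        Image.fromarray(rgb).save(path, quality=100)
        img = image_io.read_image(path)
        assert abs(float(img.pixels.mean()) - 50) <= 1  # JPEG tolerance

    def test_dicom_minmax_rescale(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian

        rng = np.random.default_rng(1)
        arr = rng.integers(0, 4001, (20, 20)).astype(np.uint16)
        arr.flat[0], arr.flat[1] = 0, 4000  # pin the extremes
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "s.dcm"), {}, file_meta=meta,
                         preamble=b"\0" * 128)
        ds.Rows, ds.Columns = arr.shape
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arr.tobytes()
        ds.save_as(str(tmp_path / "s.dcm"))

        img = image_io.read_image(tmp_path / "s.dcm")
        oracle = (arr.astype(float) - arr.min()) * 255.0 / (arr.max() - arr.min())
        np.testing.assert_allclose(img.pixels, oracle, atol=1e-9)
        assert img.pixels.min() == 0 and img.pixels.max() == 255

    def test_unreadable_file_raises(self, tmp_path):
        path = tmp_path / "bad.png"
        path.write_bytes(b"not an image")
        with pytest.raises(FormatError):
            image_io.read_image(path)


class TestCjData:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "rec.mat"
        phantoms.make_cjdata_fixture(phantoms.PhantomSpec(seed=4), path)
        rec = image_io.read_cjdata_record(path)
        assert rec.label == 1
        assert rec.image.pixels.shape == (512, 512)
        assert rec.mask.shape == rec.image.pixels.shape
        assert rec.mask.sum() > 0

    def test_single_pixel_mask_conserved(self, tmp_path):
        import h5py

        path = tmp_path / "one.mat"
        mask = np.zeros((64, 64))
        mask[10, 20] = 1
        with h5py.File(path, "w") as f:
            f.create_dataset("image", data=np.ones((64, 64)) * 7)
            f.create_dataset("tumorMask", data=mask)
            f.create_dataset("label", data=1)
        rec = image_io.read_cjdata_record(path)
        assert rec.mask.sum() == 1

    def test_missing_mask_raises(self, tmp_path):
        import h5py

        path = tmp_path / "broken.mat"
        with h5py.File(path, "w") as f:
            f.create_dataset("image", data=np.ones((8, 8)))
        with pytest.raises(FormatError):
            image_io.read_cjdata_record(path)


class TestMultimodal:
    def test_modality_order_preserved(self, tmp_path):
        vol = phantoms.make_multimodal_phantom(
            phantoms.PhantomSpec(size=(32, 32, 155), seed=5))
        paths = phantoms.write_multimodal_case(vol, tmp_path / "case")
        loaded = image_io.read_multimodal_case(
            [paths[m] for m in image_io.MODALITY_ORDER], mask_path=paths["mask"])
        for m in image_io.MODALITY_ORDER:
            np.testing.assert_allclose(getattr(loaded, m), getattr(vol, m),
                                       rtol=1e-6)
        np.testing.assert_array_equal(loaded.mask, vol.mask)

    def test_wrong_arity_raises(self, tmp_path):
        with pytest.raises(ArityError):
            image_io.read_multimodal_case([tmp_path / "a.nii.gz"] * 3)

    def test_shape_mismatch_raises(self, tmp_path):
        import nibabel as nib

        a = tmp_path / "a.nii.gz"
        b = tmp_path / "b.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 140), np.float32), np.eye(4)), a)
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 139), np.float32), np.eye(4)), b)
        with pytest.raises(ShapeError):
            image_io.read_multimodal_case([a, a, a, b])


class TestOverlay:
    def test_empty_mask_reproduces_grayscale(self, tmp_path):
        arr = np.arange(64, dtype=float).reshape(8, 8)
        img = GrayImage2D(arr, value_range="byte")
        path = tmp_path / "o.png"
        image_io.write_overlay(img, np.zeros((8, 8)), path)
        out = np.asarray(Image.open(path))
        for c in range(3):
            np.testing.assert_array_equal(out[:, :, c], arr.astype(np.uint8))

    def test_single_pixel_mask_gives_one_red_pixel(self, tmp_path):
        img = GrayImage2D(np.full((16, 16), 90.0), value_range="byte")
        mask = np.zeros((16, 16))
        mask[3, 5] = 1
        path = tmp_path / "o.png"
        image_io.write_overlay(img, mask, path)
        out = np.asarray(Image.open(path)).astype(int)
        red = (out[:, :, 0] == 255) & (out[:, :, 1] == 0) & (out[:, :, 2] == 0)
        assert red.sum() == 1 and red[3, 5]

    def test_full_mask_red_dominant(self, tmp_path):
        img = GrayImage2D(np.full((8, 8), 10.0), value_range="byte")
        path = tmp_path / "o.png"
        image_io.write_overlay(img, np.ones((8, 8)), path)
        out = np.asarray(Image.open(path)).astype(int)
        assert (out[:, :, 0] > out[:, :, 1]).all()
        assert (out[:, :, 0] > out[:, :, 2]).all()

    def test_shape_mismatch_raises(self):
        img = GrayImage2D(np.zeros((8, 8)), value_range="byte")
        with pytest.raises(ShapeError):
            image_io.write_overlay(img, np.zeros((9, 9)), "x.png")
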