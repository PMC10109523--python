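"""File I/O for every input family the pipeline touches.

Readers cover 2D grayscale images (PNG/JPEG/DICOM), CjData-style container
records (HDF5 layout with ``image``/``tumorMask``/``label`` datasets, one
tumor-bearing slice per file), and four co-registered NIfTI volumes per
multimodal case.  Class labels for the detection task are derived from the
``Yxx`` / ``Nxx`` filename convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import nibabel as nib
import numpy as np
from PIL import Image

from .errors import ArityError, FormatError, ShapeError, UnlabeledNameError

__all__ = [
    "GrayImage2D",
    "MultiModalVolume",
    "LabeledRecord",
    "label_from_name",
    "read_image",
    "read_cjdata_record",
    "read_multimodal_case",
    "write_overlay",
    "write_png",
    "MODALITY_ORDER",
]

MODALITY_ORDER = ("t1", "t2", "t1ce", "flair")


@dataclass
class GrayImage2D:
    """Single-channel intensity raster.

    ``value_range`` tags the pixel scale: ``byte`` ([0, 255]), ``unit``
    ([0, 1]), ``raw`` (arbitrary finite), or ``zscore`` (standardized).
    """

    pixels: np.ndarray
    value_range: str = "raw"
    source: str = "synthetic"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError(f"expected non-empty 2D raster, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("non-finite pixel values")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if self.value_range == "byte" and (lo < 0 or hi > 255):
            raise FormatError(f"byte range violated: [{lo}, {hi}]")
        if self.value_range == "unit" and (lo < 0 or hi > 1):
            raise FormatError(f"unit range violated: [{lo}, {hi}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MultiModalVolume:
    """Four co-registered scalar volumes (T1, T2, T1ce, FLAIR), optional
    integer-labelled tumor mask, shared shape ``(H, W, D)`` with axial slices
    along the last axis."""

    t1: np.ndarray
    t2: np.ndarray
    t1ce: np.ndarray
    flair: np.ndarray
    mask: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self):
        vols = [np.asarray(getattr(self, m), dtype=np.float64) for m in MODALITY_ORDER]
        shapes = {v.shape for v in vols}
        if len(shapes) != 1 or vols[0].ndim != 3:
            raise ShapeError(f"modalities must share one 3D shape, got {shapes}")
        for m, v in zip(MODALITY_ORDER, vols):
            setattr(self, m, v)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != vols[0].shape:
                raise ShapeError(
                    f"mask {self.mask.shape} vs modality {vols[0].shape}")

    @property
    def shape(self):
        return self.t1.shape

    def modalities(self):
        return tuple(getattr(self, m) for m in MODALITY_ORDER)


@dataclass
class LabeledRecord:
    """One detection/segmentation training record: image, optional binary
    mask of identical shape, and a 0/1 tumor label."""

    image: GrayImage2D
    mask: np.ndarray | None
    label: int
    name: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise FormatError(f"label must be 0 or 1, got {self.label!r}")
        if self.mask is not None:
            self.mask = (np.asarray(self.mask) != 0).astype(np.uint8)
            if self.mask.shape != self.image.pixels.shape:
                raise ShapeError(
                    f"mask {self.mask.shape} vs image {self.image.pixels.shape}")


def label_from_name(name: str) -> int:
    """Map a ``Yxx``/``Nxx`` file name to its class label (1 = tumor)."""
    base = os.path.basename(str(name))
    if not base:
        raise UnlabeledNameError("empty file name")
    first = base[0].upper()
    if first == "Y":
        return 1
    if first == "N":
        return 0
    raise UnlabeledNameError(
        f"{name!r} does not follow the Y*/N* labeling convention")


def _minmax_byte(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - lo) * (255.0 / (hi - lo))


def read_image(path) -> GrayImage2D:
    """Read a PNG/JPEG/DICOM file as a grayscale byte-range raster.

    DICOM pixel data is rescaled (slope/intercept applied, then min-max
    mapped to [0, 255]); color images are reduced by luminance weighting.
    """
    path = str(path)
    suffix = os.path.splitext(path)[1].lower()
    try:
        if suffix in (".dcm", ".dicom", ".ima"):
            import pydicom

            ds = pydicom.dcmread(path)
            arr = ds.pixel_array.astype(np.float64)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
            if arr.ndim == 3:  # color DICOM: luminance
                arr = arr @ np.array([0.299, 0.587, 0.114])
            arr = _minmax_byte(arr)
        else:
            with Image.open(path) as img:
                arr = np.asarray(img.convert("L"), dtype=np.float64)
    except (OSError, ValueError, KeyError, AttributeError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"{path}: empty or non-2D raster")
    return GrayImage2D(arr, value_range="byte", source=path)


def read_cjdata_record(path) -> LabeledRecord:
    """Read a CjData-style HDF5 container (``image``, ``tumorMask``,
    ``label`` datasets, at the root or under a ``cjdata`` group).

    Every such record documents a tumor, so the returned label is 1.
    """
    path = str(path)
    try:
        with h5py.File(path, "r") as f:
            root = f["cjdata"] if "cjdata" in f else f
            missing = [k for k in ("image", "tumorMask") if k not in root]
            if missing:
                raise FormatError(f"{path}: missing field(s) {missing}")
            image = np.asarray(root["image"], dtype=np.float64)
            mask = np.asarray(root["tumorMask"])
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if image.shape != mask.shape:
        raise ShapeError(f"{path}: image {image.shape} vs mask {mask.shape}")
    img = GrayImage2D(image, value_range="raw" if image.max() > 255 else "byte",
                      source=path)
    return LabeledRecord(image=img, mask=mask, label=1,
                         name=os.path.basename(path))


def read_multimodal_case(paths, mask_path=None, case_id: str = "") -> MultiModalVolume:
    """Load four NIfTI volumes in the fixed order (T1, T2, T1ce, FLAIR)."""
    paths = list(paths)
    if len(paths) != 4:
        raise ArityError(f"need exactly 4 modality files, got {len(paths)}")
    vols = []
    for p in paths:
        try:
            vols.append(np.asarray(nib.load(str(p)).get_fdata(), dtype=np.float64))
        except Exception as exc:  # nibabel raises a zoo of types
            raise FormatError(f"cannot read {p}: {exc}") from exc
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()).astype(np.int64)
    return MultiModalVolume(*vols, mask=mask,
                            case_id=case_id or os.path.basename(str(paths[0])))


def _as_mask_array(mask) -> np.ndarray:
    arr = getattr(mask, "pixels", mask)
    return (np.asarray(arr) != 0)


def write_overlay(image: GrayImage2D, mask, path) -> None:
    """Write an RGB PNG with mask-positive pixels rendered pure red over the
    grayscale background."""
    m = _as_mask_array(mask)
    m = np.squeeze(m)
    gray = image.pixels
    if m.shape != gray.shape:
        raise ShapeError(f"mask {m.shape} vs image {gray.shape}")
    if image.value_range == "unit":
        gray = gray * 255.0
    elif image.value_range not in ("byte",):
        gray = _minmax_byte(gray)
    g8 = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    rgb = np.stack([g8, g8, g8], axis=-1)
    rgb[m] = (255, 0, 0)
    Image.fromarray(rgb, mode="RGB").save(str(path))


def write_png(image: GrayImage2D, path) -> None:
    """Write a byte-range raster as an 8-bit grayscale PNG (lossless)."""
    gray = image.pixels
    if image.value_range == "unit":
        gray = gray * 255.0
    elif image.value_range != "byte":
        gray = _minmax_byte(gray)
    Image.fromarray(np.clip(np.round(gray), 0, 255).astype(np.uint8), mode="L").save(str(path))
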