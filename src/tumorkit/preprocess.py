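"""Stage-specific preprocessing.

Each network consumes a differently conditioned input, and the stages are
deliberately not harmonized (they mirror the published pipeline):

* detection: resize to 256x256, keep the byte [0, 255] scale, replicate to
  3 channels;
* 2D segmentation: grayscale -> resize 512x512 -> divide by 255 into [0, 1]
  -> add channel axis -> downsample to 128x128;
* multimodal segmentation: per-modality global z-scoring, the middle 70
  axial slices (0-based indices 60..129 of a 155-slice volume), each slice
  resized to 128x128 and the four contrasts stacked channel-wise in the
  fixed order (T1, T2, T1ce, FLAIR).

Intensity rasters are resized with bilinear interpolation; masks with
nearest-neighbour followed by re-binarization, so no intermediate gray
values survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import ArityError, ShapeError
from .image_io import GrayImage2D, MultiModalVolume, MODALITY_ORDER

__all__ = [
    "DetectionInput",
    "Seg2DInput",
    "Seg3DSample",
    "TumorMask",
    "SLICE_WINDOW",
    "prep_detection",
    "prep_seg2d",
    "prep_seg2d_training",
    "prep_seg3d",
    "prep_seg3d_training",
]

#: Half-open axial slice window [60, 130): the middle 70 of 155 slices.
SLICE_WINDOW = (60, 130)


@dataclass
class TumorMask:
    """Binary raster aligned with its paired input (values exactly {0, 1})."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = (np.asarray(self.pixels) != 0).astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class DetectionInput:
    """256x256x3 byte-range raster (grayscale replicated across channels)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (256, 256, 3):
            raise ShapeError(f"detection input must be (256,256,3), got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ShapeError("detection input must be in [0, 255]")


@dataclass
class Seg2DInput:
    """128x128x1 unit-range raster."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (128, 128, 1):
            raise ShapeError(f"2D segmentation input must be (128,128,1), got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ShapeError("2D segmentation input must be in [0, 1]")


@dataclass
class Seg3DSample:
    """One 128x128x4 multimodal slice (channels T1, T2, T1ce, FLAIR,
    z-scored per modality per volume) with its source slice index."""

    pixels: np.ndarray
    slice_index: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (128, 128, 4):
            raise ShapeError(f"multimodal sample must be (128,128,4), got {self.pixels.shape}")


def _resize_bilinear(arr: np.ndarray, shape) -> np.ndarray:
    return resize(arr, shape, order=1, preserve_range=True,
                  anti_aliasing=False, mode="edge")


def _resize_mask(mask: np.ndarray, shape) -> np.ndarray:
    out = resize(mask.astype(np.float64), shape, order=0, preserve_range=True,
                 anti_aliasing=False, mode="edge")
    return (out > 0.5).astype(np.uint8)


def _to_byte(image: GrayImage2D) -> np.ndarray:
    px = image.pixels
    if image.value_range == "byte":
        return px
    if image.value_range == "unit":
        return px * 255.0
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        return np.zeros_like(px)
    return (px - lo) * (255.0 / (hi - lo))


def prep_detection(image: GrayImage2D) -> DetectionInput:
    """Resize to 256x256 (bilinear), normalize to the byte scale, replicate
    the grayscale plane across 3 channels."""
    if image.height < 2 or image.width < 2:
        raise ShapeError("degenerate image")
    byte = np.clip(_to_byte(image), 0.0, 255.0)
    r = np.clip(_resize_bilinear(byte, (256, 256)), 0.0, 255.0)
    return DetectionInput(np.repeat(r[:, :, None], 3, axis=-1))


def prep_seg2d(image: GrayImage2D) -> Seg2DInput:
    """Grayscale -> 512x512 -> /255 into [0, 1] -> channel axis -> 128x128."""
    if image.height < 2 or image.width < 2:
        raise ShapeError("degenerate image")
    byte = np.clip(_to_byte(image), 0.0, 255.0)
    up = np.clip(_resize_bilinear(byte, (512, 512)), 0.0, 255.0)
    unit = (up / 255.0)[:, :, None]
    down = np.clip(_resize_bilinear(unit, (128, 128, 1)), 0.0, 1.0)
    return Seg2DInput(down)


def prep_seg2d_training(image: GrayImage2D, mask) -> tuple:
    """Image as :func:`prep_seg2d`; the mask follows the same geometric path
    with nearest-neighbour resizing and stays strictly binary."""
    m = getattr(mask, "pixels", mask)
    m = np.asarray(m)
    if m.shape != image.pixels.shape:
        raise ShapeError(f"mask {m.shape} vs image {image.pixels.shape}")
    x = prep_seg2d(image)
    m512 = _resize_mask(m, (512, 512))
    m128 = _resize_mask(m512, (128, 128))
    return x, TumorMask(m128[:, :, None])


def _zscore(volume: np.ndarray) -> np.ndarray:
    """Global per-volume standardization; constant volumes map to zero."""
    mu = float(volume.mean())
    sd = float(volume.std())
    if sd == 0.0:
        return np.zeros_like(volume)
    return (volume - mu) / sd


def prep_seg3d(volume: MultiModalVolume) -> list:
    """Standardize each modality, keep axial slices [60, 130), resize each to
    128x128 and stack the four contrasts channel-wise.

    Returns exactly 70 :class:`Seg3DSample` for a 155-slice case.
    """
    for m in MODALITY_ORDER:
        if getattr(volume, m) is None:
            raise ArityError(f"missing modality {m}")
    depth = volume.shape[2]
    lo, hi = SLICE_WINDOW
    if depth < hi + 1:
        raise ShapeError(f"depth {depth} < {hi + 1}: slice window [{lo},{hi}) unavailable")
    standardized = [_zscore(v) for v in volume.modalities()]
    samples = []
    for z in range(lo, hi):
        channels = [_resize_bilinear(v[:, :, z], (128, 128)) for v in standardized]
        samples.append(Seg3DSample(np.stack(channels, axis=-1), slice_index=z))
    return samples


def prep_seg3d_training(volume: MultiModalVolume) -> list:
    """As :func:`prep_seg3d`, with the label volume first binarized (any
    nonzero tumor label -> 1), windowed, and resized nearest-neighbour.

    Returns a list of ``(Seg3DSample, TumorMask)`` pairs.
    """
    if volume.mask is None:
        raise ArityError("training preprocessing requires a mask volume")
    samples = prep_seg3d(volume)
    binary = (volume.mask != 0).astype(np.uint8)
    lo, hi = SLICE_WINDOW
    pairs = []
    for sample, z in zip(samples, range(lo, hi)):
        m = _resize_mask(binary[:, :, z], (128, 128))
        pairs.append((sample, TumorMask(m[:, :, None])))
    return pairs
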