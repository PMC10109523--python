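"""Deterministic synthetic phantoms for every input family.

A phantom is a bright elliptical "brain" on a dark background with additive
Gaussian noise; a tumor, when present, is a brighter ellipse fully inside
the brain with an analytically known binary mask.  The generators emulate
the three clinical input families (detection PNGs with Y/N names,
CjData-style records, four-modality NIfTI volumes with labelled masks) so
the full pipeline is exercisable without any download.  Every generator is
a pure function of its spec and seed.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, replace

import h5py
import nibabel as nib
import numpy as np

from .errors import SpecError
from .image_io import GrayImage2D, MultiModalVolume, write_png
from .preprocess import SLICE_WINDOW, TumorMask

__all__ = [
    "PhantomSpec",
    "make_phantom2d",
    "make_multimodal_phantom",
    "make_detection_dataset",
    "make_cjdata_fixture",
    "write_multimodal_case",
    "MODALITY_GAINS",
]

#: Per-modality multiplicative gains (T1, T2, T1ce, FLAIR): the same anatomy
#: rendered at four different contrasts.
MODALITY_GAINS = (1.0, 0.8, 1.2, 0.9)
_MODALITY_OFFSETS = (0.0, 4.0, -4.0, 2.0)

_BACKGROUND = 8.0
_BRAIN_INTENSITY = 110.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one phantom.

    ``tumor_center``/``tumor_axes`` default to seed-derived placements fully
    inside the brain ellipse.  ``contrast`` is the additive tumor-over-brain
    intensity offset (byte scale); ``noise_sd`` the additive Gaussian noise.
    """

    size: tuple = (256, 256)
    with_tumor: bool = True
    tumor_center: tuple | None = None
    tumor_axes: tuple | None = None
    contrast: float = 60.0
    noise_sd: float = 5.0
    seed: int = 0


def _ellipse(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _brain_geometry(shape):
    center = tuple(s / 2.0 for s in shape)
    axes = tuple(0.40 * s for s in shape)
    return center, axes


def _tumor_geometry(spec: PhantomSpec, shape, rng):
    b_center, b_axes = _brain_geometry(shape)
    if spec.tumor_axes is not None:
        axes = tuple(float(a) for a in spec.tumor_axes)
    else:
        axes = tuple(float(rng.uniform(0.08, 0.16) * s) for s in shape)
    if spec.tumor_center is not None:
        center = tuple(float(c) for c in spec.tumor_center)
    else:
        center = tuple(c + rng.uniform(-0.4, 0.4) * (b - a)
                       for c, b, a in zip(b_center, b_axes, axes))
    # the tumor ellipse must sit fully inside the brain ellipse
    margin = sum(((c - bc) / (ba - a)) ** 2 if ba > a else np.inf
                 for c, bc, ba, a in zip(center, b_center, b_axes, axes))
    if margin > 1.0:
        raise SpecError(f"tumor ellipse (center {center}, axes {axes}) "
                        f"outside brain ellipse")
    return center, axes


def make_phantom2d(spec: PhantomSpec):
    """Return ``(GrayImage2D, TumorMask, label)`` for a 2D phantom."""
    if len(spec.size) != 2:
        raise SpecError(f"2D phantom needs a 2D size, got {spec.size}")
    if spec.with_tumor and spec.contrast == 0:
        raise SpecError("tumor phantom needs nonzero contrast")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.size)
    b_center, b_axes = _brain_geometry(shape)
    brain = _ellipse(shape, b_center, b_axes)
    img = np.full(shape, _BACKGROUND)
    img[brain] = _BRAIN_INTENSITY
    mask = np.zeros(shape, dtype=np.uint8)
    if spec.with_tumor:
        t_center, t_axes = _tumor_geometry(spec, shape, rng)
        tumor = _ellipse(shape, t_center, t_axes)
        img[tumor] += spec.contrast
        mask[tumor] = 1
    img = np.clip(img + rng.normal(0.0, spec.noise_sd, shape), 0.0, 255.0)
    image = GrayImage2D(img, value_range="byte", source="synthetic")
    return image, TumorMask(mask), int(spec.with_tumor)


def make_multimodal_phantom(spec: PhantomSpec) -> MultiModalVolume:
    """Four-modality volume phantom with an integer-labelled tumor mask.

    The four contrasts share one anatomy under modality-specific gains and
    offsets.  The tumor occupies a contiguous axial band placed inside the
    preprocessing slice window [60, 130), and its mask voxels carry labels
    {1, 2, 4} (concentric sub-regions) so downstream binarization is
    genuinely exercised.
    """
    if len(spec.size) != 3:
        raise SpecError(f"multimodal phantom needs (H, W, D), got {spec.size}")
    shape = tuple(int(s) for s in spec.size)
    lo, hi = SLICE_WINDOW
    if shape[2] < hi + 1:
        raise SpecError(f"depth {shape[2]} cannot contain slice window [{lo},{hi})")
    rng = np.random.default_rng(spec.seed)
    b_center, b_axes = _brain_geometry(shape)
    brain = _ellipse(shape, b_center, b_axes)
    anatomy = np.full(shape, _BACKGROUND)
    anatomy[brain] = _BRAIN_INTENSITY

    mask = np.zeros(shape, dtype=np.int16)
    if spec.with_tumor:
        z_center = float(rng.uniform(lo + 15, hi - 15))
        z_axis = float(rng.uniform(8, 12))
        if not (lo <= z_center - z_axis and z_center + z_axis < hi):
            raise SpecError("tumor slice band escapes the slice window")
        in_plane = tuple(float(rng.uniform(0.10, 0.16) * s) for s in shape[:2])
        center2d, _ = _tumor_geometry(
            replace(spec, tumor_axes=in_plane, tumor_center=None, size=shape[:2]),
            shape[:2], rng)
        t_center = center2d + (z_center,)
        t_axes = in_plane + (z_axis,)
        tumor = _ellipse(shape, t_center, t_axes)
        core = _ellipse(shape, t_center, tuple(0.45 * a for a in t_axes))
        mid = _ellipse(shape, t_center, tuple(0.75 * a for a in t_axes))
        mask[tumor] = 2          # edema-like rim
        mask[mid] = 4            # enhancing ring
        mask[core] = 1           # necrotic core
        anatomy = anatomy + tumor * spec.contrast

    modalities = []
    for gain, offset in zip(MODALITY_GAINS, _MODALITY_OFFSETS):
        vol = gain * anatomy + offset + rng.normal(0.0, spec.noise_sd, shape)
        modalities.append(np.clip(vol, 0.0, None))
    return MultiModalVolume(*modalities, mask=mask,
                            case_id=f"phantom-{spec.seed}")


def make_detection_dataset(n: int, tumor_fraction: float, seed: int, out_dir):
    """Write ``n`` phantom PNGs named Y1..Yk / N1..Nm (k = round(n * fraction))
    plus a ``manifest.csv``; returns the list of written file paths."""
    if n < 2 or not (0.0 < tumor_fraction < 1.0):
        raise SpecError("need n >= 2 and 0 < tumor_fraction < 1")
    os.makedirs(out_dir, exist_ok=True)
    k = int(round(n * tumor_fraction))
    paths = []
    rows = []
    for i in range(n):
        with_tumor = i < k
        name = f"Y{i + 1}.png" if with_tumor else f"N{i + 1 - k}.png"
        spec = PhantomSpec(size=(256, 256), with_tumor=with_tumor,
                           seed=seed * 100003 + i)
        image, _, label = make_phantom2d(spec)
        path = os.path.join(str(out_dir), name)
        write_png(image, path)
        paths.append(path)
        rows.append({"name": name, "label": label, "seed": spec.seed,
                     "contrast": spec.contrast, "noise_sd": spec.noise_sd})
    with open(os.path.join(str(out_dir), "manifest.csv"), "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return paths


def make_cjdata_fixture(spec: PhantomSpec, path) -> None:
    """Write a CjData-style container (512x512 image, binary tumorMask,
    label) readable by :func:`tumorkit.image_io.read_cjdata_record`."""
    spec = replace(spec, size=(512, 512), with_tumor=True)
    image, mask, label = make_phantom2d(spec)
    with h5py.File(str(path), "w") as f:
        f.create_dataset("image", data=image.pixels)
        f.create_dataset("tumorMask", data=mask.pixels)
        f.create_dataset("label", data=label)


def write_multimodal_case(volume: MultiModalVolume, out_dir) -> dict:
    """Persist a multimodal phantom as five NIfTI files; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    affine = np.eye(4)
    paths = {}
    for name in ("t1", "t2", "t1ce", "flair"):
        p = os.path.join(str(out_dir), f"{name}.nii.gz")
        nib.save(nib.Nifti1Image(getattr(volume, name).astype(np.float32), affine), p)
        paths[name] = p
    if volume.mask is not None:
        p = os.path.join(str(out_dir), "mask.nii.gz")
        nib.save(nib.Nifti1Image(volume.mask.astype(np.int16), affine), p)
        paths["mask"] = p
    return paths
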