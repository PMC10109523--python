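"""Hand-crafted image features for tumor/non-tumor classification.

The 42-element feature vector concatenates six blocks in fixed order:

====================  ==  =======================================================
intensity              4  mean, population variance, skewness, excess kurtosis
GLCM                   6  contrast, dissimilarity, homogeneity, ASM, energy,
                          correlation (distance 1, angle 0, 256 levels,
                          symmetric, normalized)
DWT                    8  mean and energy of each single-level Haar sub-band
                          LL, LH, HL, HH
entropy                1  Shannon entropy (base 2) of the 256-bin histogram
LBP                   10  normalized histogram of uniform local binary
                          patterns (P=8, R=1)
Haralick              13  classic second-order co-occurrence statistics,
                          averaged over the four directions
====================  ==  =======================================================

Moments of constant images are guarded (skewness and kurtosis 0, GLCM
correlation 1) so degenerate inputs yield finite vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern

from .errors import ShapeError
from .image_io import GrayImage2D
from .preprocess import _resize_bilinear, _to_byte

__all__ = [
    "FeatureVector",
    "intensity_features",
    "glcm_features",
    "dwt_features",
    "texture_features",
    "haralick_features",
    "extract_all",
    "feature_names",
    "FEATURE_BLOCKS",
    "write_feature_table",
    "read_feature_table",
]

_SUBBANDS = ("ll", "lh", "hl", "hh")

#: Block name -> slice into the 42-element vector.  ``other`` groups the
#: entropy, LBP and Haralick blocks; ``all`` is the full vector.
FEATURE_BLOCKS = {
    "intensity": slice(0, 4),
    "glcm": slice(4, 10),
    "dwt": slice(10, 18),
    "other": slice(18, 42),
    "all": slice(0, 42),
}


def feature_names() -> list:
    names = ["mean", "variance", "skewness", "kurtosis"]
    names += [f"glcm_{p}" for p in
              ("contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation")]
    for band in _SUBBANDS:
        names += [f"dwt_{band}_mean", f"dwt_{band}_energy"]
    names += ["entropy"]
    names += [f"lbp_{i}" for i in range(10)]
    names += [f"haralick_{i}" for i in range(1, 14)]
    return names


@dataclass
class FeatureVector:
    """Named, ordered feature vector with optional class label."""

    values: np.ndarray
    label: int | None = None
    name: str = ""
    names: list = field(default_factory=feature_names)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("non-finite feature values")

    def block(self, block: str) -> np.ndarray:
        return self.values[FEATURE_BLOCKS[block]]

    def __len__(self):
        return len(self.values)


def _pixels(image) -> np.ndarray:
    px = getattr(image, "pixels", image)
    px = np.asarray(px, dtype=np.float64)
    if px.ndim == 3:
        if px.shape[-1] in (3, 4) and np.allclose(px[..., 0], px[..., 1]):
            px = px[..., 0]
        else:
            px = np.squeeze(px, axis=-1)
    if px.ndim != 2 or px.size == 0:
        raise ShapeError(f"expected non-empty 2D image, got shape {px.shape}")
    return px


def _quantize(image) -> np.ndarray:
    """Map a raster to uint8 gray levels (256 bins)."""
    if isinstance(image, GrayImage2D):
        px = _to_byte(image)
    else:
        px = _pixels(image)
        if px.size and 0 <= px.min() and px.max() <= 1.0 and px.max() <= 1.0:
            px = px * 255.0
    return np.clip(np.round(px), 0, 255).astype(np.uint8)


def intensity_features(image) -> np.ndarray:
    """(mean, population variance, skewness, excess kurtosis)."""
    px = _pixels(image)
    mean = px.mean()
    var = px.var()
    if var == 0.0:
        return np.array([mean, 0.0, 0.0, 0.0])
    z = (px - mean) / np.sqrt(var)
    skew = (z ** 3).mean()
    kurt = (z ** 4).mean() - 3.0
    return np.array([mean, var, skew, kurt])


def glcm_features(image) -> np.ndarray:
    """(contrast, dissimilarity, homogeneity, ASM, energy, correlation) from
    the symmetric normalized co-occurrence matrix at distance 1, angle 0."""
    q = _quantize(_pixels(image) if not isinstance(image, GrayImage2D) else image)
    if q.shape[1] < 2:
        raise ShapeError("GLCM at distance 1, angle 0 needs at least 2 columns")
    glcm = graycomatrix(q, distances=[1], angles=[0.0], levels=256,
                        symmetric=True, normed=True)
    props = ["contrast", "dissimilarity", "homogeneity", "ASM", "energy", "correlation"]
    return np.array([float(graycoprops(glcm, p)[0, 0]) for p in props])


def dwt_features(image) -> np.ndarray:
    """Mean and energy (mean squared coefficient) of each sub-band of a
    single-level Haar decomposition, in order LL, LH, HL, HH.

    Odd-sized images are padded to even dimensions by edge replication.
    """
    px = _pixels(image)
    pad_h, pad_w = px.shape[0] % 2, px.shape[1] % 2
    if pad_h or pad_w:
        px = np.pad(px, ((0, pad_h), (0, pad_w)), mode="edge")
    ca, (ch, cv, cd) = pywt.dwt2(px, "haar")
    out = []
    for band in (ca, ch, cv, cd):
        out += [band.mean(), (band ** 2).mean()]
    return np.array(out)


def haralick_features(image) -> np.ndarray:
    """The 13 classic second-order texture statistics, computed from the
    distance-1 symmetric normalized GLCM and averaged over the four
    directions (0, 45, 90, 135 degrees)."""
    q = _quantize(_pixels(image) if not isinstance(image, GrayImage2D) else image)
    if min(q.shape) < 2:
        raise ShapeError("Haralick features need at least a 2x2 image")
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    glcm = graycomatrix(q, distances=[1], angles=angles, levels=256,
                        symmetric=True, normed=True)
    feats = np.stack([_haralick_one(glcm[:, :, 0, a]) for a in range(len(angles))])
    return feats.mean(axis=0)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _haralick_one(p: np.ndarray) -> np.ndarray:
    """13 statistics of one normalized co-occurrence matrix."""
    n = p.shape[0]
    idx = np.arange(n, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sd_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    # p_{x+y}(k), k = 0..2n-2 and p_{|x-y|}(k), k = 0..n-1
    psum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=p.ravel(),
                       minlength=2 * n - 1)
    pdiff = np.bincount(np.abs(ii - jj).astype(np.int64).ravel(), weights=p.ravel(),
                        minlength=n)
    ks = np.arange(2 * n - 1, dtype=np.float64)
    kd = np.arange(n, dtype=np.float64)

    f1 = float((p ** 2).sum())                                  # ASM
    f2 = float((kd ** 2) @ pdiff)                               # contrast
    if sd_x * sd_y == 0.0:
        f3 = 1.0                                                # constant image
    else:
        f3 = (float((ii * jj * p).sum()) - mu_x * mu_y) / (sd_x * sd_y)
    f4 = float((((ii - mu_x) ** 2) * p).sum())                  # sum of squares
    f5 = float((p / (1.0 + (ii - jj) ** 2)).sum())              # inverse diff moment
    f6 = float(ks @ psum)                                       # sum average
    f7 = float(((ks - f6) ** 2) @ psum)                         # sum variance
    f8 = _entropy_bits(psum)                                    # sum entropy
    f9 = _entropy_bits(p.ravel())                               # entropy
    mu_d = float(kd @ pdiff)
    f10 = float(((kd - mu_d) ** 2) @ pdiff)                     # difference variance
    f11 = _entropy_bits(pdiff)                                  # difference entropy
    # information measures of correlation
    pxy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxy[nz], where=pxy[nz] > 0,
                                   out=np.full(pxy[nz].shape, -np.inf))).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    denom = max(hx, hy)
    f12 = (f9 - hxy1) / denom if denom > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - f9)))))
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])


def texture_features(image):
    """(entropy, 10-bin uniform-LBP histogram, 13 Haralick statistics)."""
    q = _quantize(_pixels(image) if not isinstance(image, GrayImage2D) else image)
    hist = np.bincount(q.ravel(), minlength=256) / q.size
    entropy = _entropy_bits(hist)
    lbp = local_binary_pattern(q, P=8, R=1, method="uniform")
    lbp_hist = np.bincount(lbp.astype(np.int64).ravel(), minlength=10)[:10] / lbp.size
    return entropy, lbp_hist, haralick_features(image)


def extract_all(image: GrayImage2D, name: str = "", label=None) -> FeatureVector:
    """Resize to 256x256, then concatenate all blocks in fixed order
    intensity | GLCM | DWT | entropy | LBP | Haralick (42 values)."""
    byte = np.clip(_resize_bilinear(np.clip(_to_byte(image), 0, 255), (256, 256)), 0, 255)
    img = GrayImage2D(byte, value_range="byte", source=image.source)
    entropy, lbp, haralick = texture_features(img)
    values = np.concatenate([
        intensity_features(img),
        glcm_features(img),
        dwt_features(img),
        [entropy],
        lbp,
        haralick,
    ])
    return FeatureVector(values, label=label, name=name)


def write_feature_table(vectors, path) -> None:
    """Write feature vectors as CSV with header ``name,label,<features>``."""
    rows = []
    for v in vectors:
        row = {"name": v.name, "label": v.label}
        row.update(dict(zip(v.names, v.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path) -> list:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c not in ("name", "label")]
    out = []
    for _, row in df.iterrows():
        label = row.get("label")
        label = None if pd.isna(label) else int(label)
        out.append(FeatureVector(row[cols].to_numpy(dtype=np.float64),
                                 label=label, name=str(row.get("name", "")),
                                 names=cols))
    return out
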