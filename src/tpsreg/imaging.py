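"""Geometric transforms and the mutual-information similarity metric.

Conventions
-----------
All geometry is 0-based, pixel-center. The transform parameterization
follows the MRI-registration convention used throughout this package:

* ``x`` — translation along the image's **vertical** axis, in pixels,
  positive **up** (toward row 0);
* ``y`` — translation along the **horizontal** axis, in pixels, positive
  **left** (toward column 0);
* ``theta`` — rotation in **degrees**, positive counterclockwise as the
  image is displayed;
* ``z`` — isotropic scale factor about the image center, ``z > 0``.

This differs from the usual (col, row) image convention on purpose and is
honored everywhere, including ground-truth inverses.

The forward transform composes **scale about the center, then rotate about
the center, then translate**. Resampling is done by inverse mapping with
bilinear interpolation; destination pixels whose source coordinate falls
outside the input domain receive fill value 0 and an invalid mask entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "Image2D",
    "TransformParams",
    "JointHistogram",
    "DegenerateOverlapError",
    "apply_transform",
    "joint_histogram",
    "mutual_information",
    "marginal_entropy",
    "similarity",
]


class DegenerateOverlapError(ValueError):
    """Raised when two images share no jointly valid pixels."""


@dataclass(frozen=True)
class Image2D:
    """A 2D grayscale raster with intensities in [0, 1] and a validity mask.

    ``valid_mask`` is True where the pixel carries real data rather than
    out-of-domain fill introduced by resampling. Source images always have
    at least one valid pixel; a resampled image translated fully out of
    frame may carry an all-False mask, which every pairwise operation
    treats as degenerate overlap.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("Image2D requires a nonempty 2D pixel array")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        mask = np.asarray(self.valid_mask, dtype=bool)
        if mask.shape != px.shape:
            raise ValueError("valid_mask shape must equal pixel shape")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, normalize: bool = True) -> "Image2D":
        """Wrap a raw 2D array, min-max normalizing to [0, 1] by default.

        A constant array normalizes to all zeros.
        """
        arr = np.asarray(arr, dtype=np.float64)
        if normalize:
            lo, hi = float(arr.min()), float(arr.max())
            arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        return cls(pixels=arr, valid_mask=np.ones(arr.shape, dtype=bool))


@dataclass(frozen=True)
class TransformParams:
    """Rigid+scale transform parameters (x up, y left, theta CCW deg, z scale)."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0
    z: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.theta, self.z)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("transform parameters must be finite")
        if self.z <= 0:
            raise ValueError(f"scale factor must be positive, got {self.z}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta, self.z], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "TransformParams":
        x, y, theta, z = (float(v) for v in arr)
        return cls(x=x, y=y, theta=theta, z=z)

    def inverse(self) -> "TransformParams":
        """Exact inverse under the scale -> rotate -> translate composition.

        If this transform built a float image from a reference, the inverse
        is the registration ground truth that maps the float back.
        """
        rot = _rotation_matrix(-self.theta)
        t = rot @ np.array([self.x, self.y]) / self.z
        return TransformParams(x=-t[0], y=-t[1], theta=-self.theta, z=1.0 / self.z)


@dataclass(frozen=True)
class JointHistogram:
    """Binned joint intensity counts of a reference/moved image pair."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square 2D array")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if int(counts.sum()) != self.total or self.total <= 0:
            raise ValueError("total must be positive and equal the count sum")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def bins(self) -> int:
        return self.counts.shape[0]


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """CCW rotation matrix in the (up, left) frame.

    Entries within 1e-12 of {-1, 0, 1} are snapped so that quarter-turn
    rotations are exact index permutations rather than near-identities.
    """
    rad = math.radians(theta_deg)

    def snap(v: float) -> float:
        r = round(v)
        return float(r) if abs(v - r) < 1e-12 else v

    c, s = snap(math.cos(rad)), snap(math.sin(rad))
    return np.array([[c, -s], [s, c]], dtype=np.float64)


@lru_cache(maxsize=8)
def _centered_grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Destination coordinates in the centered (up, left) frame, cached
    per shape since optimizers resample the same raster thousands of times."""
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    u = cr - rows
    v = cc - cols
    u.setflags(write=False)
    v.setflags(write=False)
    return u, v


def apply_transform(img: Image2D, params: TransformParams) -> Image2D:
    """Resample ``img`` under the forward transform ``params``.

    For every output pixel the source coordinate is found by inverting the
    composition (scale by z about the center, rotate by theta CCW about the
    center, translate by (x up, y left)); values are bilinearly interpolated.
    Source coordinates outside the input domain, or touching invalid input
    pixels, yield fill 0 and ``valid_mask`` False.
    """
    if params.z <= 0:
        raise ValueError("scale factor must be positive")
    h, w = img.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0

    u, v = _centered_grid(h, w)
    du = u - params.x
    dv = v - params.y
    rot = _rotation_matrix(-params.theta)
    su = (rot[0, 0] * du + rot[0, 1] * dv) / params.z
    sv = (rot[1, 0] * du + rot[1, 1] * dv) / params.z
    src_r = cr - su
    src_c = cc - sv

    inside = (src_r >= 0) & (src_r <= h - 1) & (src_c >= 0) & (src_c <= w - 1)
    vals = ndimage.map_coordinates(
        img.pixels, [src_r, src_c], order=1, mode="constant", cval=0.0
    )
    if img.valid_mask.all():
        valid = inside
    else:
        # conservative: a resampled pixel is valid only if every contributing
        # source neighbor is valid
        mvals = ndimage.map_coordinates(
            img.valid_mask.astype(np.float64),
            [src_r, src_c],
            order=1,
            mode="constant",
            cval=0.0,
        )
        valid = inside & (mvals >= 1.0 - 1e-9)
    pixels = np.where(valid, np.clip(vals, 0.0, 1.0), 0.0)
    return Image2D(pixels=pixels, valid_mask=valid)


def joint_histogram(ref: Image2D, moved: Image2D, bins: int = 64) -> JointHistogram:
    """Joint intensity histogram over the jointly valid region.

    Intensities are quantized into ``bins`` equal-width levels on [0, 1]
    (the last bin right-closed). A pixel contributes only where both
    validity masks are True.
    """
    if ref.shape != moved.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {moved.shape}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint = ref.valid_mask & moved.valid_mask
    n = int(joint.sum())
    if n == 0:
        raise DegenerateOverlapError("no jointly valid pixels")
    counts, _, _ = np.histogram2d(
        ref.pixels[joint], moved.pixels[joint], bins=bins, range=[[0, 1], [0, 1]]
    )
    return JointHistogram(counts=counts.astype(np.int64), total=n)


def mutual_information(hist: JointHistogram) -> float:
    """Mutual information in bits from a joint count histogram.

    MI = sum_ab p(a,b) log2[p(a,b) / (p(a) p(b))], zero-probability terms
    skipped; tiny negatives from rounding are clamped to 0.
    """
    p = hist.counts / hist.total
    # marginals from integer counts: exact, hence identical under transpose
    pa = hist.counts.sum(axis=1) / hist.total
    pb = hist.counts.sum(axis=0) / hist.total
    nz = p > 0
    outer = np.outer(pa, pb)
    # fsum: correctly rounded independent of term order, so MI(H) == MI(H^T)
    mi = math.fsum(p[nz] * np.log2(p[nz] / outer[nz]))
    return max(mi, 0.0)


def marginal_entropy(img: Image2D, bins: int = 64) -> float:
    """Shannon entropy (bits) of an image's binned intensity marginal."""
    vals = img.pixels[img.valid_mask]
    counts, _ = np.histogram(vals, bins=bins, range=(0, 1))
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def similarity(
    ref: Image2D, flt: Image2D, params: TransformParams, bins: int = 64
) -> float:
    """MI (bits) between ``ref`` and ``flt`` resampled under ``params``.

    The objective every optimizer maximizes. Degenerate overlap (the float
    moved fully out of frame) returns the worst score 0 instead of raising,
    so optimizers can move away from it.
    """
    moved = apply_transform(flt, params)
    try:
        hist = joint_histogram(ref, moved, bins=bins)
    except DegenerateOverlapError:
        return 0.0
    return mutual_information(hist)
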