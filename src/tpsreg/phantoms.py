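"""Synthetic brain-slice phantoms and benchmark fixtures.

Generates a head-like 2D slice from nested ellipses — skull boundary,
gray-matter rim, white-matter interior and V-shaped ventricle-like CSF
cavities — with per-class base intensities plus seeded Gaussian noise.
From one tissue label map, :func:`make_modality_pair` derives a T1-like /
T2-like contrast pair in which the CSF class is dark in T1 and bright in
T2 (the inverted contrast that makes the pair genuinely multimodal), and
:func:`make_float` builds a moving image from a reference by a known
translation + rotation + scaling whose exact inverse is the registration
ground truth.

The geometry is deliberately asymmetric (offset interior, tilted
ventricles) so that rotation is identifiable and the mutual-information
surface has a unique optimum over the search box. Everything is a pure
function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import Image2D, TransformParams, apply_transform

__all__ = [
    "PhantomSpec",
    "CLASS_NAMES",
    "make_phantom",
    "make_modality_pair",
    "make_float",
]

#: label values in the tissue map, in priority order of painting
CLASS_NAMES: tuple[str, ...] = ("background", "csf", "gray", "white")
_LABEL = {name: i for i, name in enumerate(CLASS_NAMES)}

# per-class mean intensities; CSF sits in the lowest third for T1-like
# contrast and the highest third for T2-like contrast
_BASE_INTENSITY = {"background": 0.05, "csf": 0.15, "gray": 0.45, "white": 0.75}
_T1_INTENSITY = {"background": 0.05, "csf": 0.12, "gray": 0.50, "white": 0.80}
_T2_INTENSITY = {"background": 0.05, "csf": 0.90, "gray": 0.45, "white": 0.25}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head slice."""

    size: int = 128
    noise_sd: float = 0.01
    seed: int = 0
    tissue_classes: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("phantom size must be >= 32 pixels")
        if not (0 <= self.noise_sd < 0.5):
            raise ValueError("noise_sd must lie in [0, 0.5)")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    tilt_deg: float = 0.0,
) -> np.ndarray:
    """Boolean mask of a (possibly tilted) filled ellipse in row/col space."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    t = np.deg2rad(tilt_deg)
    a = np.cos(t) * dr + np.sin(t) * dc
    b = -np.sin(t) * dr + np.cos(t) * dc
    return (a / semi_axes[0]) ** 2 + (b / semi_axes[1]) ** 2 <= 1.0


def make_labels(spec: PhantomSpec) -> np.ndarray:
    """Tissue label map of the head slice (values index CLASS_NAMES)."""
    n = spec.size
    c = (n - 1) / 2.0
    labels = np.full((n, n), _LABEL["background"], dtype=np.int8)

    head = _ellipse_mask((n, n), (c, c), (0.44 * n, 0.36 * n))
    labels[head] = _LABEL["gray"]
    # white-matter interior, slightly offset to break 180-degree symmetry
    interior = _ellipse_mask((n, n), (c - 0.03 * n, c + 0.02 * n), (0.34 * n, 0.27 * n))
    labels[head & interior] = _LABEL["white"]
    # V-shaped lateral-ventricle pair (opposite tilts: no rotational symmetry)
    left = _ellipse_mask((n, n), (c, c - 0.09 * n), (0.13 * n, 0.045 * n), tilt_deg=20)
    right = _ellipse_mask((n, n), (c, c + 0.09 * n), (0.13 * n, 0.045 * n), tilt_deg=-20)
    labels[(left | right) & head] = _LABEL["csf"]
    return labels


def _paint(
    labels: np.ndarray, intensity: dict, noise_sd: float, rng: np.random.Generator
) -> Image2D:
    img = np.empty(labels.shape, dtype=np.float64)
    for name, value in intensity.items():
        img[labels == _LABEL[name]] = value
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, labels.shape)
    img = np.clip(img, 0.0, 1.0)
    return Image2D(pixels=img, valid_mask=np.ones(labels.shape, dtype=bool))


def make_phantom(spec: PhantomSpec) -> tuple[Image2D, np.ndarray]:
    """Build the base (T1-like) phantom image and its tissue label map."""
    labels = make_labels(spec)
    rng = np.random.default_rng(spec.seed)
    return _paint(labels, _BASE_INTENSITY, spec.noise_sd, rng), labels


def make_modality_pair(
    phantom: Image2D, labels: np.ndarray, spec: PhantomSpec
) -> tuple[Image2D, Image2D]:
    """Derive a T1-like / T2-like pair from one tissue label map.

    Both modalities share geometry but use different per-class intensity
    lookups with independent seeded noise; CSF is dark in the T1-like
    image and bright in the T2-like image.
    """
    if labels.shape != phantom.shape:
        raise ValueError("labels must align with the phantom image")
    ss = np.random.SeedSequence(spec.seed)
    rng_t1, rng_t2 = (np.random.default_rng(s) for s in ss.spawn(2))
    t1 = _paint(labels, _T1_INTENSITY, spec.noise_sd, rng_t1)
    t2 = _paint(labels, _T2_INTENSITY, spec.noise_sd, rng_t2)
    return t1, t2


def make_float(img: Image2D, true_params: TransformParams) -> Image2D:
    """Build a moving image from ``img`` by a known forward transform.

    The registration ground truth for the returned float image is
    ``true_params.inverse()`` under the documented scale -> rotate ->
    translate composition.
    """
    return apply_transform(img, true_params)
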