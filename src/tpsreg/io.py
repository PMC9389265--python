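"""Raster and NIfTI loading/saving for registration inputs.

PNG/TIFF files load through imageio; RGB(A) rasters are averaged to one
channel. NIfTI volumes load through nibabel and, when 3D, require an
explicit slice axis and index. Every loaded image is min-max normalized
to [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .imaging import Image2D

__all__ = ["load_image", "save_image"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def load_image(
    path, slice_axis: int | None = None, slice_index: int | None = None
) -> Image2D:
    """Load a 2D grayscale image (or one slice of a NIfTI volume)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if data.ndim == 3:
            if slice_axis is None or slice_index is None:
                raise ValueError(
                    "3D NIfTI volumes require slice_axis and slice_index"
                )
            data = np.take(data, slice_index, axis=slice_axis)
        if data.ndim != 2:
            raise ValueError(f"cannot reduce {path} to a 2D slice")
        return Image2D.from_array(data)

    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # RGB(A) -> grayscale by channel average
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a 2D grayscale raster")
    return Image2D.from_array(arr)


def save_image(img: Image2D, path) -> None:
    """Write an image as an 8-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    data = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)
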