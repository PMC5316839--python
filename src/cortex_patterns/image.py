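"""Image container and TIFF I/O.

All imaging stages exchange a single currency: a 2-D intensity grid together
with its physical pixel size in nanometres.  Arrays are row-major (row, col)
with the origin at the top-left pixel centre; physical x runs along columns
and physical y along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile


@dataclass(frozen=True)
class Image:
    """2-D grayscale image with a physical pixel size.

    Parameters
    ----------
    data
        2-D float array of intensities (arbitrary units).
    pixel_size_nm
        Physical edge length of one pixel, in nanometres. Must be positive.
    """

    data: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"image data must be 2-D, got shape {data.shape}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def nm_to_px(self, length_nm: float) -> float:
        return length_nm / self.pixel_size_nm

    def px_to_nm(self, length_px: float) -> float:
        return length_px * self.pixel_size_nm

    def with_data(self, data: np.ndarray) -> "Image":
        return replace(self, data=np.asarray(data, dtype=float))


def read_tiff(path, pixel_size_nm: float) -> Image:
    """Read a single-plane grayscale TIFF as an :class:`Image`."""
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    return Image(data=data, pixel_size_nm=pixel_size_nm)


def read_tiff_stack(path, pixel_size_nm: float) -> list[Image]:
    """Read a multi-plane TIFF stack as a list of :class:`Image` frames."""
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return [Image(data=frame, pixel_size_nm=pixel_size_nm) for frame in data]


def write_tiff(path, image: Image | np.ndarray, *, dtype=np.float32) -> None:
    data = image.data if isinstance(image, Image) else np.asarray(image)
    tifffile.imwrite(path, data.astype(dtype))
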