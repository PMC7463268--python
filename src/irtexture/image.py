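"""Core raster containers and grayscale image I/O.

Images are 2-D integer intensity rasters with a declared bit depth; analysis
masks are same-shaped boolean arrays (True = pixel participates in feature
computation). Infrared scanning-laser-ophthalmoscope reflectance scans are
single-channel, so colour inputs are rejected at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np


class ParameterError(ValueError):
    """A configuration or call parameter violates its contract."""


@dataclass
class GrayImage:
    """2-D grayscale raster with intensities in ``[0, 2**bit_depth)``."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ParameterError(f"expected a 2-D array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ParameterError("image must have at least one pixel per axis")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        if arr.min() < 0 or arr.max() >= 2**self.bit_depth:
            raise ParameterError(
                f"intensities outside [0, {2**self.bit_depth}) for declared bit depth"
            )
        self.pixels = arr.astype(dtype)

    @property
    def ny(self) -> int:
        """Height in pixels."""
        return self.pixels.shape[0]

    @property
    def nx(self) -> int:
        """Width in pixels."""
        return self.pixels.shape[1]

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def like(self, values: np.ndarray) -> "GrayImage":
        """New image with the same bit depth; values clipped and rounded."""
        clipped = np.clip(np.rint(values), 0, self.max_intensity)
        return GrayImage(clipped, bit_depth=self.bit_depth)


@dataclass
class RegionMask:
    """Boolean inclusion mask paired with an image of identical shape."""

    flags: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ParameterError("mask must be 2-D")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "RegionMask":
        return cls(np.ones(shape, dtype=bool))

    def complement(self) -> "RegionMask":
        return RegionMask(~self.flags)

    @property
    def n_included(self) -> int:
        return int(self.flags.sum())


def read_image(path: str | Path) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF; reject colour inputs."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ParameterError(
            f"{path}: image is not single-channel (shape {arr.shape}); "
            "IR reflectance scans must be grayscale"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ParameterError(f"{path}: unsupported dtype {arr.dtype}")
    return GrayImage(arr, bit_depth=depth)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write as PNG (8-bit) or TIFF (16-bit) depending on extension/depth."""
    iio.imwrite(Path(path), img.pixels)
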