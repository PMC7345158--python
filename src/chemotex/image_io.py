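"""Grayscale image reading, gray-level quantization, and patch extraction.

The texture pipeline works on square patches of a quantized grayscale
image (by default 150 x 150 pixels at 256 gray levels, matching the
acquisition convention of the optical-microscopy workflow this package
implements).  This module owns the two container types — :class:`GrayImage`
and :class:`GrayPatch` — and the plumbing that turns files into patches.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "GrayPatch",
    "FormatError",
    "read_gray_image",
    "quantize",
    "extract_patches",
    "write_patches",
]

# Rec. 601 luma weights for the RGB -> gray convenience path.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised for image files whose sample format is unsupported."""


@dataclass(frozen=True)
class GrayImage:
    """A single-channel image of non-negative integers.

    Parameters
    ----------
    pixels
        2-D integer array, values in ``[0, 2**bit_depth)``.
    bit_depth
        Native sample depth, 8 or 16.
    gray_levels
        Number of gray levels G the pixel values are expressed in after
        :func:`quantize`; ``None`` for a raw (unquantized) image.
    """

    pixels: np.ndarray
    bit_depth: int
    gray_levels: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() >= 2**self.bit_depth:
            raise ValueError("pixel values out of range for bit depth")
        if self.gray_levels is not None and px.max() >= self.gray_levels:
            raise ValueError("pixel values exceed declared gray_levels")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayPatch:
    """A square, quantized tile cut from a :class:`GrayImage`.

    ``origin`` is the (row, column) of the patch's top-left corner in the
    source image, 0-based.  ``source`` optionally records where the patch
    came from (file stem or image index) for bookkeeping in feature tables.
    """

    pixels: np.ndarray
    gray_levels: int
    origin: tuple[int, int] = (0, 0)
    source: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("patch pixels must be square")
        if px.min() < 0 or px.max() > self.gray_levels - 1:
            raise ValueError("patch values must lie in [0, gray_levels - 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def read_gray_image(path: str | os.PathLike) -> GrayImage:
    """Read a PNG or TIFF file as a :class:`GrayImage`.

    8- and 16-bit single-channel images are read verbatim; RGB(A) input is
    converted to luminance with Rec. 601 weights (the acquisition camera is
    monochrome, so this path is a convenience only).  Float or palette
    sample formats raise :class:`FormatError`.
    """
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"unsupported sample format {arr.dtype} in {path}; expected uint8 or uint16"
        )
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise FormatError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = np.floor(arr[..., :3].astype(np.float64) @ _LUMA + 0.5)
        arr = arr.astype(np.uint16 if depth == 16 else np.uint8)
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return GrayImage(pixels=arr, bit_depth=depth)


def quantize(image: GrayImage, gray_levels: int = 256) -> GrayImage:
    """Map pixel values to the range ``[0, gray_levels - 1]``.

    Uses fixed bit-depth rescaling ``floor(p * G / 2**bit_depth)`` rather
    than per-image min-max stretching, so absolute brightness differences
    between experimental groups survive quantization.  An 8-bit image at
    G = 256 passes through unchanged.
    """
    if gray_levels < 2:
        raise ValueError(f"gray_levels must be >= 2, got {gray_levels}")
    # Already expressed in G levels (including 8-bit at G = 256): no-op,
    # which also makes quantization idempotent.
    native_G = image.gray_levels if image.gray_levels is not None else 2**image.bit_depth
    if native_G == gray_levels:
        return GrayImage(
            pixels=image.pixels, bit_depth=image.bit_depth, gray_levels=gray_levels
        )
    px = image.pixels.astype(np.int64)
    px = (px * gray_levels) // native_G  # floor(p * G / native levels)
    return GrayImage(
        pixels=px.astype(np.uint16 if gray_levels > 256 else np.uint8),
        bit_depth=8 if gray_levels <= 256 else 16,
        gray_levels=gray_levels,
    )


def extract_patches(
    image: GrayImage,
    side: int = 150,
    min_foreground_fraction: float = 0.2,
    threshold: int = 5,
    source: str = "",
) -> list[GrayPatch]:
    """Tile an image into non-overlapping ``side x side`` patches.

    The grid is anchored at the top-left corner (0, 0) and traversed in
    row-major order, so the tiling is deterministic.  The modal gray level
    of the whole image estimates the blank background; a pixel counts as
    foreground when it differs from that mode by more than ``threshold``
    gray levels, and tiles whose foreground fraction falls below
    ``min_foreground_fraction`` are dropped.
    """
    if side > min(image.height, image.width):
        raise ValueError(
            f"patch side {side} exceeds image extent "
            f"{image.height}x{image.width}"
        )
    if not 0.0 <= min_foreground_fraction <= 1.0:
        raise ValueError("min_foreground_fraction must be in [0, 1]")
    G = image.gray_levels if image.gray_levels is not None else 2**image.bit_depth
    px = image.pixels
    mode = int(np.bincount(px.ravel(), minlength=G).argmax())
    foreground = np.abs(px.astype(np.int64) - mode) > threshold

    patches: list[GrayPatch] = []
    for r in range(0, image.height - side + 1, side):
        for c in range(0, image.width - side + 1, side):
            tile_fg = foreground[r : r + side, c : c + side]
            if tile_fg.mean() >= min_foreground_fraction:
                patches.append(
                    GrayPatch(
                        pixels=px[r : r + side, c : c + side].copy(),
                        gray_levels=G,
                        origin=(r, c),
                        source=source,
                    )
                )
    return patches


def write_patches(patches: list[GrayPatch], out_dir: str | os.PathLike, stem: str) -> list[Path]:
    """Export patches as 8-bit PNGs named ``<stem>_r<row>_c<col>.png``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in patches:
        if p.gray_levels > 256:
            raise ValueError("only patches with at most 256 gray levels export to 8-bit PNG")
        path = out / f"{stem}_r{p.origin[0]}_c{p.origin[1]}.png"
        iio.imwrite(path, p.pixels.astype(np.uint8))
        paths.append(path)
    return paths
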