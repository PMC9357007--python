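"""Calibrated image containers and raster I/O.

Conventions used throughout the package: arrays are row-major with the
origin at the top-left corner; the x axis is the column axis; angles are
measured in degrees anticlockwise from +x with the y axis pointing *up*
(i.e. towards decreasing row index), so a fibre drawn at +30 deg appears
rotated anticlockwise when the image is displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio


@dataclass
class CalibratedImage:
    """A single-plane grayscale image with physical pixel calibration.

    Parameters
    ----------
    pixels : 2-D float array of non-negative intensities.
    pixel_size_um : physical size of one pixel in micrometres (> 0).
    bit_depth : bit depth of the source data (informational).
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ZStack:
    """An ordered stack of co-registered planes with a fixed z spacing."""

    planes: list[CalibratedImage]
    z_step_um: float

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("z-stack must contain at least one plane")
        if not self.z_step_um > 0:
            raise ValueError("z_step_um must be > 0")
        shape = self.planes[0].shape
        cal = self.planes[0].pixel_size_um
        for p in self.planes:
            if p.shape != shape or p.pixel_size_um != cal:
                raise ValueError("all planes must share shape and calibration")

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def depth_um(self) -> float:
        return len(self.planes) * self.z_step_um


@dataclass
class RGBImage:
    """An 8-bit RGB image (h, w, 3), optionally calibrated."""

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("RGB pixels must have shape (h, w, 3)")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RGB channel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def write_image(path: str | Path, image: CalibratedImage | ZStack | RGBImage) -> None:
    """Write a calibrated TIFF (grayscale / multi-page z-stack) or PNG/TIFF RGB.

    Calibration is stored in the TIFF X/YResolution tags as pixels per
    centimetre so that a round-trip through :func:`read_image` restores
    ``pixel_size_um``.
    """
    path = Path(path)
    if isinstance(image, RGBImage):
        if path.suffix.lower() == ".png":
            iio.imwrite(path, image.pixels)
        else:
            tifffile.imwrite(path, image.pixels, photometric="rgb")
        return
    if isinstance(image, ZStack):
        data = np.stack([p.pixels for p in image.planes])
        cal = image.planes[0].pixel_size_um
        bit = image.planes[0].bit_depth
    else:
        data = image.pixels
        cal = image.pixel_size_um
        bit = image.bit_depth
    dtype = np.uint16 if bit > 8 else np.uint8
    px_per_cm = 1e4 / cal
    tifffile.imwrite(
        path,
        data.astype(dtype),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_um": cal},
    )


def _resolution_to_um(page: "tifffile.TiffPage") -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags.get("ResolutionUnit")
    unit_name = (getattr(unit.value, "name", str(unit.value)).upper()
                 if unit is not None else "NONE")
    if num == den and unit_name.startswith("NONE"):
        return None  # writer default, not a real calibration
    px_per_unit = num / den
    if unit is not None and getattr(unit.value, "name", str(unit.value)).upper().startswith("CENT"):
        return 1e4 / px_per_unit
    if unit is not None and getattr(unit.value, "name", str(unit.value)).upper().startswith("INCH"):
        return 25400.0 / px_per_unit
    return 1e4 / px_per_unit


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> CalibratedImage | ZStack | RGBImage:
    """Read a TIFF or PNG into the appropriate container.

    ``pixel_size_um`` overrides any calibration found in the TIFF
    resolution tags (explicit override > metadata > error for grayscale
    images, which always require physical calibration).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        data = iio.imread(path)
        if data.ndim == 3:
            return RGBImage(data[..., :3], pixel_size_um)
        data = np.asarray(data)
        # fall through to grayscale handling
        meta_cal = None
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_cal = _resolution_to_um(tf.pages[0])
    if data.ndim == 3 and data.shape[-1] == 3:
        return RGBImage(data, pixel_size_um or meta_cal)
    cal = pixel_size_um if pixel_size_um is not None else meta_cal
    if cal is None:
        raise ValueError(
            f"{path}: no pixel-size calibration in metadata and no override given"
        )
    bit = 16 if data.dtype.itemsize > 1 else 8
    if data.ndim == 3:  # multi-page grayscale stack
        planes = [CalibratedImage(pl, cal, bit) for pl in data]
        return ZStack(planes, z_step_um if z_step_um is not None else 1.0)
    return CalibratedImage(data, cal, bit)


@dataclass
class EightBitResult:
    image: CalibratedImage
    lo: float
    hi: float
    degenerate: bool = False


def to_8bit(image: CalibratedImage, lo_hi: tuple[float, float] | None = None,
            percentiles: tuple[float, float] | None = None) -> EightBitResult:
    """Linearly rescale intensities to integers 0-255.

    Bounds come from ``lo_hi`` (explicit values), ``percentiles``
    (e.g. (1, 99)), or default to the image min/max. A constant image
    cannot be rescaled: the result is all zeros with ``degenerate=True``.
    """
    px = image.pixels
    if lo_hi is not None:
        lo, hi = lo_hi
    elif percentiles is not None:
        lo, hi = np.percentile(px, percentiles)
    else:
        lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        out = np.zeros_like(px)
        return EightBitResult(CalibratedImage(out, image.pixel_size_um, 8), lo, hi, True)
    scaled = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    out = np.round(scaled * 255.0)
    return EightBitResult(CalibratedImage(out, image.pixel_size_um, 8), lo, hi, False)


@dataclass
class Tile:
    image: CalibratedImage
    row_offset: int
    col_offset: int


def grid_rois(image: CalibratedImage, rows: int = 3, cols: int = 3) -> list[Tile]:
    """Cut the image into a near-equal ``rows x cols`` tiling.

    Remainder pixels are assigned to the last row/column so the tiles
    partition the image exactly.
    """
    h, w = image.shape
    if h < rows or w < cols:
        raise ValueError(f"image {h}x{w} too small for a {rows}x{cols} grid")
    rb = [i * (h // rows) for i in range(rows)] + [h]
    cb = [j * (w // cols) for j in range(cols)] + [w]
    tiles = []
    for i in range(rows):
        for j in range(cols):
            sub = image.pixels[rb[i]:rb[i + 1], cb[j]:cb[j + 1]]
            tiles.append(Tile(CalibratedImage(sub, image.pixel_size_um, image.bit_depth),
                              rb[i], cb[j]))
    return tiles
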