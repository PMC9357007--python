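"""Histological stain quantification by HSB thresholding.

Covers picrosirius-red fibrillar-collagen area, polarised-light
birefringence hue classes (red/yellow/green, tracking fibre bundle
thickness and maturity), and DAB-positive area for immunohistochemistry.
All thresholds live on the ImageJ-style 0-255 hue wheel with inclusive
bounds; results are fractions of *tissue* area, where tissue is any
non-white (non-slide-background) pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color

from .images import RGBImage


@dataclass(frozen=True)
class HSBBox:
    """An inclusive hue/saturation/brightness box on 0-255 channels.

    ``wrap=True`` means the hue interval crosses the 255->0 seam
    (e.g. h_lo=240, h_hi=15 selects reds around the wheel origin).
    """

    h_lo: int
    h_hi: int
    s_lo: int = 0
    s_hi: int = 255
    b_lo: int = 0
    b_hi: int = 255
    wrap: bool = False

    def __post_init__(self) -> None:
        for v in (self.h_lo, self.h_hi, self.s_lo, self.s_hi, self.b_lo, self.b_hi):
            if not (0 <= v <= 255):
                raise ValueError("HSB bounds must lie in [0, 255]")
        if not self.wrap:
            if self.h_lo > self.h_hi:
                raise ValueError("h_lo > h_hi without wrap flag")
        if self.s_lo > self.s_hi or self.b_lo > self.b_hi:
            raise ValueError("saturation/brightness bounds out of order")

    def contains(self, hsb: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the box; hsb is (..., 3) in 0-255."""
        h, s, b = hsb[..., 0], hsb[..., 1], hsb[..., 2]
        if self.wrap:
            in_h = (h >= self.h_lo) | (h <= self.h_hi)
        else:
            in_h = (h >= self.h_lo) & (h <= self.h_hi)
        return (in_h & (s >= self.s_lo) & (s <= self.s_hi)
                & (b >= self.b_lo) & (b <= self.b_hi))

    def _hue_interval(self) -> list[tuple[int, int]]:
        if self.wrap:
            return [(self.h_lo, 255), (0, self.h_hi)]
        return [(self.h_lo, self.h_hi)]

    def overlaps(self, other: "HSBBox") -> bool:
        if self.s_hi < other.s_lo or other.s_hi < self.s_lo:
            return False
        if self.b_hi < other.b_lo or other.b_hi < self.b_lo:
            return False
        for a0, a1 in self._hue_interval():
            for b0, b1 in other._hue_interval():
                if a0 <= b1 and b0 <= a1:
                    return True
        return False


# Printed picrosirius-red fibrillar-collagen thresholds, inclusive, on the
# 0-255 hue wheel: 200 <= H <= 240, 150 <= S <= 255, 0 <= B <= 255.
PICROSIRIUS_RED_BOX = HSBBox(200, 240, 150, 255, 0, 255)

# Birefringence hue classes. The red box is the published picrosirius
# threshold; yellow and green are package defaults (documented choices).
DEFAULT_BIREFRINGENCE_BOXES: dict[str, HSBBox] = {
    "red": PICROSIRIUS_RED_BOX,
    "yellow": HSBBox(30, 60, 150, 255, 0, 255),
    "green": HSBBox(70, 140, 150, 255, 0, 255),
}

# Default DAB (brown) box; colour-deconvolution is the alternative method.
DEFAULT_DAB_BOX = HSBBox(10, 40, 60, 255, 30, 230)


def rgb_to_hsb(image: RGBImage | np.ndarray) -> np.ndarray:
    """Convert RGB (0-255) to integer H,S,B channels on 0-255.

    Standard hue/saturation/value conversion scaled to the 0-255 wheel
    (ImageJ convention); achromatic pixels get H = 0.
    """
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    hsv = color.rgb2hsv(px.astype(float) / 255.0)
    return np.round(hsv * 255.0).astype(int)


def hsb_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Inverse conversion: H,S,B on 0-255 to uint8 RGB."""
    hsv = np.asarray(hsb, dtype=float) / 255.0
    rgb = color.hsv2rgb(np.clip(hsv, 0.0, 1.0))
    return np.round(rgb * 255.0).astype(np.uint8)


def tissue_mask(hsb: np.ndarray, b_max: int = 230, s_min: int = 30) -> np.ndarray:
    """Tissue = any pixel that is not white slide background: brightness
    at most ``b_max`` OR saturation at least ``s_min``."""
    return (hsb[..., 2] <= b_max) | (hsb[..., 1] >= s_min)


@dataclass
class StainAreaResult:
    class_fractions: dict[str, float]
    class_areas_px: dict[str, int]
    tissue_area_px: int


def stain_area(
    image: RGBImage,
    boxes: dict[str, HSBBox] | None = None,
    tissue_b_max: int = 230,
    tissue_s_min: int = 30,
    allow_overlap: bool = False,
) -> StainAreaResult:
    """Per-class stained area as a fraction of total tissue area.

    Classes must be non-overlapping in HSB space unless ``allow_overlap``.
    Raises ``ValueError`` on zero tissue area (e.g. an all-white slide).
    """
    if boxes is None:
        boxes = {"red": PICROSIRIUS_RED_BOX}
    names = list(boxes)
    if not allow_overlap:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if boxes[a].overlaps(boxes[b]):
                    raise ValueError(f"HSB boxes {a!r} and {b!r} overlap")
    hsb = rgb_to_hsb(image)
    tissue = tissue_mask(hsb, tissue_b_max, tissue_s_min)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("zero tissue area: image appears to be all background")
    areas = {name: int((boxes[name].contains(hsb) & tissue).sum()) for name in names}
    fracs = {name: areas[name] / n_tissue for name in names}
    return StainAreaResult(fracs, areas, n_tissue)


def dab_positive_area(
    image: RGBImage,
    method: str = "hsb-box",
    box: HSBBox = DEFAULT_DAB_BOX,
    dab_threshold: float = 0.15,
    tissue_b_max: int = 230,
    tissue_s_min: int = 30,
) -> StainAreaResult:
    """DAB-positive fraction of tissue area.

    ``method='hsb-box'`` thresholds a brown HSB box (default);
    ``method='colour-deconvolution'`` unmixes the H-DAB stain pair and
    thresholds the DAB optical-density channel.
    """
    hsb = rgb_to_hsb(image)
    tissue = tissue_mask(hsb, tissue_b_max, tissue_s_min)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("zero tissue area: image appears to be all background")
    if method == "hsb-box":
        pos = box.contains(hsb) & tissue
    elif method == "colour-deconvolution":
        od = color.separate_stains(image.pixels.astype(float) / 255.0,
                                   color.hdx_from_rgb)
        pos = (od[..., 1] > dab_threshold) & tissue
    else:
        raise ValueError(f"unknown DAB method {method!r}")
    n_pos = int(pos.sum())
    return StainAreaResult({"dab": n_pos / n_tissue}, {"dab": n_pos}, n_tissue)
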