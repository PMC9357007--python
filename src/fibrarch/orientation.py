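"""Per-pixel fibre orientation by structure tensors and alignment summaries.

Spatial derivatives are taken from the cubic B-spline representation of
the image (derivative of the interpolant evaluated at the grid points);
the tensor components are the Gaussian-window-averaged products of these
derivatives. The dominant local orientation is the fibre direction —
perpendicular to the intensity gradient — reported on the half-circle
(-90, 90] in degrees, anticlockwise from +x with y up. Coherency
(lambda1 - lambda2)/(lambda1 + lambda2) measures how anisotropic the
local gradient field is; alignment of a whole image is summarised by the
peak-to-baseline ratio of its orientation histogram (about 1 for an
isotropic fibre field, large for an aligned one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import CalibratedImage

# cubic B-spline values / first-derivative values at integer offsets -1,0,1
_B3 = np.array([1.0 / 6.0, 4.0 / 6.0, 1.0 / 6.0])
_DB3 = np.array([0.5, 0.0, -0.5])  # weights for c[k-1], c[k], c[k+1]


@dataclass
class OrientationField:
    """Per-pixel orientation (degrees in (-90, 90]), coherency in [0, 1]
    and energy (tensor trace, >= 0)."""

    theta: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray


def _wrap_axial(theta_deg: np.ndarray) -> np.ndarray:
    out = (np.asarray(theta_deg) + 90.0) % 180.0 - 90.0
    return np.where(out == -90.0, 90.0, out)


def structure_tensor(
    image: CalibratedImage | np.ndarray,
    gradient_scale: float = 1.0,
    smoothing_scale: float = 4.0,
) -> OrientationField:
    """Compute the orientation field of a grayscale image.

    ``gradient_scale`` is the sigma (pixels) of a small isotropising
    Gaussian applied before the B-spline derivatives: without it the
    discrete derivative pair responds anisotropically to pixel-level
    noise and the orientation of background pixels piles up on the grid
    diagonals. ``smoothing_scale`` is the sigma of the Gaussian window
    that averages the tensor components Jxx = <fx^2>, Jyy = <fy^2>,
    Jxy = <fx fy>.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image, float)
    if smoothing_scale <= 0:
        raise ValueError("smoothing_scale must be > 0")
    if gradient_scale < 0:
        raise ValueError("gradient_scale must be >= 0")
    if gradient_scale > 0:
        px = ndimage.gaussian_filter(px, gradient_scale, mode="mirror")
    coeffs = ndimage.spline_filter(px, order=3, mode="mirror")
    # d/dcol (x) and d/drow; smooth the perpendicular axis with the B3 kernel
    fx = ndimage.correlate1d(coeffs, _DB3[::-1], axis=1, mode="mirror")
    fx = ndimage.correlate1d(fx, _B3, axis=0, mode="mirror")
    frow = ndimage.correlate1d(coeffs, _DB3[::-1], axis=0, mode="mirror")
    frow = ndimage.correlate1d(frow, _B3, axis=1, mode="mirror")
    # y points up while rows increase downwards
    fy = -frow
    s = smoothing_scale
    jxx = ndimage.gaussian_filter(fx * fx, s, mode="mirror")
    jyy = ndimage.gaussian_filter(fy * fy, s, mode="mirror")
    jxy = ndimage.gaussian_filter(fx * fy, s, mode="mirror")
    # gradient direction of the dominant eigenvector, then fibre = +90 deg
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = _wrap_axial(np.rad2deg(phi) + 90.0)
    energy = jxx + jyy
    spread = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(energy > 0, spread / energy, 0.0)
    return OrientationField(theta, np.clip(coherency, 0.0, 1.0), energy)


@dataclass
class OrientationDistribution:
    """Normalised angular histogram of fibre orientation over 180 degrees."""

    bin_centres: np.ndarray
    weights: np.ndarray
    aligned: bool = False
    peak_angle: float | None = None
    peak_to_baseline: float | None = None

    @property
    def n_bins(self) -> int:
        return len(self.weights)


def orientation_distribution(
    field: OrientationField,
    n_bins: int = 180,
    weighting: str = "coherency",
    energy_floor_frac: float = 0.0,
) -> OrientationDistribution:
    """Weighted histogram of the orientation field.

    ``weighting`` is one of ``coherency`` (default: each pixel votes with
    its anisotropy confidence, independent of brightness, so bright
    bundles do not dominate the distribution), ``coherency-energy``,
    ``energy`` or ``none``. A positive
    ``energy_floor_frac`` additionally excludes pixels whose tensor
    energy falls below that fraction of the 99th-percentile energy,
    for images where even down-weighted background votes are unwanted.
    """
    if weighting == "coherency":
        w = field.coherency
    elif weighting == "coherency-energy":
        w = field.coherency * field.energy
    elif weighting == "energy":
        w = field.energy
    elif weighting == "none":
        w = np.ones_like(field.theta)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w.ravel().copy()
    if energy_floor_frac > 0:
        floor = energy_floor_frac * np.percentile(field.energy, 99)
        w[field.energy.ravel() < floor] = 0.0
    if w.sum() == 0:
        raise ValueError("all histogram weights are zero")
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    theta = field.theta.ravel()
    hist, _ = np.histogram(theta, bins=edges, weights=w)
    # theta = 90 belongs to the last bin already by np.histogram's closed
    # right edge; normalise to sum 1
    weights = hist / hist.sum()
    centres = (edges[:-1] + edges[1:]) / 2.0
    return OrientationDistribution(centres, weights)


def _circular_smooth(weights: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    n = len(weights)
    padded = np.concatenate([weights[-(window // 2):], weights, weights[: window // 2]])
    return np.convolve(padded, kernel, mode="valid")[:n]


def align_and_ratio(
    dists: list[OrientationDistribution],
    baseline_rule: str = "lowest-quartile-mean",
    smooth_window: int = 3,
) -> list[OrientationDistribution]:
    """Align each distribution's peak to 0 degrees and compute the
    peak-to-baseline ratio.

    The curve is smoothed by a circular moving average (window 3 bins by
    default); peak = modal smoothed weight, baseline per ``baseline_rule``
    (``min``, ``lowest-quartile-mean`` or ``lowest-decile-mean``). A zero
    baseline yields ``peak_to_baseline = inf``.
    """
    if not dists:
        raise ValueError("need at least one distribution")
    out = []
    for d in dists:
        sm = _circular_smooth(d.weights, smooth_window)
        mode = int(np.argmax(sm))
        peak = float(sm[mode])
        s = np.sort(sm)
        if baseline_rule == "min":
            baseline = float(s[0])
        elif baseline_rule == "lowest-quartile-mean":
            baseline = float(s[: max(len(s) // 4, 1)].mean())
        elif baseline_rule == "lowest-decile-mean":
            baseline = float(s[: max(len(s) // 10, 1)].mean())
        else:
            raise ValueError(f"unknown baseline rule {baseline_rule!r}")
        ratio = float("inf") if baseline == 0 else peak / baseline
        n = len(d.weights)
        centre_bin = n // 2
        shifted = np.roll(d.weights, centre_bin - mode)
        offsets = d.bin_centres - d.bin_centres[centre_bin]  # peak at offset 0
        out.append(OrientationDistribution(
            bin_centres=offsets,
            weights=shifted,
            aligned=True,
            peak_angle=float(d.bin_centres[mode]),
            peak_to_baseline=ratio,
        ))
    return out


def mean_sem_curve(aligned: list[OrientationDistribution]) -> tuple[np.ndarray, np.ndarray]:
    """Group mean and SEM of aligned orientation curves."""
    stack = np.stack([d.weights for d in aligned])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(aligned)) if len(aligned) > 1 \
        else np.zeros_like(mean)
    return mean, sem


def hsb_orientation_map(field: OrientationField) -> np.ndarray:
    """Colour-coded orientation map: hue = angle, saturation = coherency,
    brightness = normalised energy. Returns uint8 RGB."""
    from skimage import color as _color

    h = (field.theta + 90.0) / 180.0
    s = np.clip(field.coherency, 0, 1)
    e = field.energy
    v = e / e.max() if e.max() > 0 else np.zeros_like(e)
    rgb = _color.hsv2rgb(np.stack([h, s, v], axis=-1))
    return np.round(rgb * 255).astype(np.uint8)
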