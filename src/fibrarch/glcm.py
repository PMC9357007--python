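"""Grey-level co-occurrence texture analysis of the SHG collagen signal.

The quantity of interest is the Haralick correlation of the co-occurrence
matrix as a function of pixel offset distance: in an organised collagen
network, pixel intensities stay correlated over longer offsets, so a
higher mean correlation indicates more matrix organisation. Co-occurrence
counts are direction-specific (asymmetric), evaluated at 0, 90, 180 and
270 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import CalibratedImage

# (drow, dcol) offsets; angle 0 = +x (column), anticlockwise positive with
# y up, so 90 deg looks towards decreasing row index.
DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    90: (-1, 0),
    180: (0, -1),
    270: (1, 0),
}


def quantize(image8: CalibratedImage | np.ndarray, levels: int = 64) -> np.ndarray:
    """Uniformly rebin 8-bit intensities (0-255) into ``levels`` grey bins."""
    px = image8.pixels if isinstance(image8, CalibratedImage) else np.asarray(image8)
    if px.min() < 0 or px.max() > 255:
        raise ValueError("expected 8-bit intensities in [0, 255]")
    return np.minimum((px.astype(int) * levels) // 256, levels - 1)


def glcm_counts(quantized: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Direction-specific co-occurrence counts.

    ``counts[i, j]`` is the number of ordered pixel pairs with value ``i``
    at position p and ``j`` at p + offset, over all p for which both
    positions lie inside the image.
    """
    dr, dc = offset
    h, w = quantized.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError("offset larger than image")
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantized[r0:r1, c0:c1].ravel()
    b = quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    return counts.reshape(levels, levels).astype(float)


def haralick_correlation(counts: np.ndarray) -> float:
    """Haralick correlation of a co-occurrence count matrix.

    Normalises counts to joint probabilities p(i, j) and returns
    sum_ij (i - mu_i)(j - mu_j) p(i, j) / (sigma_i sigma_j). Returns NaN
    (undefined) when either marginal standard deviation is zero.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    p = counts / total
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = (i * pi).sum(), (i * pj).sum()
    var_i = ((i - mu_i) ** 2 * pi).sum()
    var_j = ((i - mu_j) ** 2 * pj).sum()
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        return float("nan")
    cov = ((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum()
    return float(cov / denom)


@dataclass
class GLCMCurve:
    """Haralick correlation vs offset distance, per direction.

    ``correlation`` is a (D, 4) array over distances 1..D and directions
    (0, 90, 180, 270); NaN marks undefined (zero-variance) entries, which
    are excluded from the direction means. ``normalised_mean`` is the
    direction-mean curve divided by its d=1 value (reported alongside the
    raw curve for cross-image averaging).
    """

    distances: np.ndarray
    directions: tuple[int, ...]
    correlation: np.ndarray
    mean_correlation: np.ndarray
    summary_mean_correlation: float
    normalised_mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for di, d in enumerate(self.distances):
            for ai, ang in enumerate(self.directions):
                rows.append({"distance": int(d), "direction": ang,
                             "correlation": self.correlation[di, ai],
                             "mean_correlation": self.mean_correlation[di]})
        return pd.DataFrame(rows)


def glcm_correlation_curve(
    image8: CalibratedImage | np.ndarray,
    max_distance_px: int = 50,
    levels: int = 64,
) -> GLCMCurve:
    """Correlation at every distance 1..D in all four directions.

    Undefined (zero-variance) entries are excluded from per-distance
    means; an image undefined at every distance/direction raises.
    """
    px = image8.pixels if isinstance(image8, CalibratedImage) else np.asarray(image8)
    if max_distance_px < 1:
        raise ValueError("max_distance_px must be >= 1")
    if max_distance_px >= min(px.shape) / 2:
        raise ValueError("max_distance_px must be < min(image dims)/2")
    q = quantize(px, levels)
    dirs = tuple(DIRECTION_OFFSETS)
    D = max_distance_px
    corr = np.full((D, len(dirs)), np.nan)
    for di, d in enumerate(range(1, D + 1)):
        for ai, ang in enumerate(dirs):
            dr, dc = DIRECTION_OFFSETS[ang]
            corr[di, ai] = haralick_correlation(glcm_counts(q, (dr * d, dc * d), levels))
    if np.all(np.isnan(corr)):
        raise ValueError("degenerate image: correlation undefined at every offset")
    with np.errstate(invalid="ignore"):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean_corr = np.nanmean(corr, axis=1)
    summary = float(np.nanmean(mean_corr))
    if mean_corr[0] != 0 and np.isfinite(mean_corr[0]):
        normalised = mean_corr / mean_corr[0]
    else:
        normalised = np.full_like(mean_corr, np.nan)
    return GLCMCurve(np.arange(1, D + 1), dirs, corr, mean_corr, summary, normalised)
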