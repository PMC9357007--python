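"""Closed-form study morphometrics.

Invasive index of an organotypic invasion assay, callipered tumour
volume, pulmonary metastasis burden and the bulk (compressive elastic)
modulus from unconfined compression. Boundary semantics follow the study
definitions literally: a cell invades only when strictly deeper than the
depth threshold, and a focus counts as a metastasis only when strictly
above the minimum area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOUR_VOLUME_CONSTANT = 0.52


@dataclass
class InvasionCounts:
    n_invading: int
    n_non_invading: int
    depth_threshold_um: float = 50.0

    def __post_init__(self) -> None:
        if self.n_invading < 0 or self.n_non_invading < 0:
            raise ValueError("counts must be >= 0")


def classify_invading(cell_depths_um, threshold: float = 50.0) -> InvasionCounts:
    """Split cells into invading / non-invading by depth below the matrix
    upper surface. Strictly greater than ``threshold`` counts as invading
    (a cell at exactly the threshold does not)."""
    depths = np.asarray(list(cell_depths_um), dtype=float)
    if depths.size and depths.min() < 0:
        raise ValueError("cell depths must be >= 0 (measured downward)")
    inv = int((depths > threshold).sum())
    return InvasionCounts(inv, int(depths.size) - inv, threshold)


def invasive_index(c: InvasionCounts) -> float:
    """Fraction of cells that invaded: invading / (invading + non-invading)."""
    total = c.n_invading + c.n_non_invading
    if total == 0:
        raise ValueError("invasive index undefined: no cells counted")
    return c.n_invading / total


@dataclass
class TumourDims:
    """Callipered tumour dimensions in mm; auto-swapped (with a warning)
    if given out of order."""

    max_dim_mm: float
    min_dim_mm: float

    def __post_init__(self) -> None:
        if self.max_dim_mm < 0 or self.min_dim_mm < 0:
            raise ValueError("dimensions must be >= 0")
        if self.max_dim_mm < self.min_dim_mm:
            warnings.warn("max_dim < min_dim: swapping", stacklevel=2)
            self.max_dim_mm, self.min_dim_mm = self.min_dim_mm, self.max_dim_mm


def tumour_volume(d: TumourDims) -> float:
    """Modified-ellipsoid tumour volume in mm^3:
    (max_dim^2 x min_dim) x 0.52."""
    return (d.max_dim_mm ** 2 * d.min_dim_mm) * TUMOUR_VOLUME_CONSTANT


@dataclass
class MetastasisRecord:
    focus_areas_um2: list[float]
    lung_area_um2: float
    min_focus_um2: float = 100.0
    n_sections: int = 3  # serial step sections, 250 um apart

    def __post_init__(self) -> None:
        if not self.lung_area_um2 > 0:
            raise ValueError("lung area must be > 0")
        if any(a <= 0 for a in self.focus_areas_um2):
            raise ValueError("focus areas must be > 0")


@dataclass
class MetastasisBurden:
    n_mets: int
    mets_per_unit_lung_area: float
    mean_focus_area_um2: float  # NaN when no foci retained


def metastasis_burden(r: MetastasisRecord) -> MetastasisBurden:
    """Count metastatic foci (area strictly above ``min_focus_um2``),
    normalise the count to total lung cross-sectional area, and report
    the mean retained focus area."""
    retained = [a for a in r.focus_areas_um2 if a > r.min_focus_um2]
    n = len(retained)
    mean_area = float(np.mean(retained)) if n else float("nan")
    return MetastasisBurden(n, n / r.lung_area_um2, mean_area)


def foci_from_label_mask(mask: np.ndarray, pixel_size_um: float) -> list[float]:
    """Convert a labelled focus mask (0 = background) into per-focus
    areas in um^2 using the pixel calibration."""
    labels = np.asarray(mask)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return list(counts * pixel_size_um ** 2)


@dataclass
class StressStrainCurve:
    """Strain (dimensionless, non-decreasing, in [0, 1)) with either a
    stress series or a force series plus contact area (mm^2) to convert."""

    strain: np.ndarray
    stress: np.ndarray | None = None
    force: np.ndarray | None = None
    contact_area_mm2: float | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be non-decreasing")
        if self.strain.size and (self.strain.min() < 0 or self.strain.max() >= 1):
            raise ValueError("strains must lie in [0, 1)")
        if self.stress is None:
            if self.force is None or self.contact_area_mm2 is None:
                raise ValueError("need stress, or force plus contact_area_mm2")
            self.stress = np.asarray(self.force, dtype=float) / self.contact_area_mm2
        else:
            self.stress = np.asarray(self.stress, dtype=float)
        if self.stress.shape != self.strain.shape:
            raise ValueError("stress and strain must have equal length")


@dataclass
class ModulusResult:
    modulus: float
    r_squared: float
    fit_start: int
    fit_stop: int       # exclusive index
    strain_bounds: tuple[float, float]
    min_r2_used: float


def _ols_slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), r2


def bulk_modulus(
    curve: StressStrainCurve,
    window_frac: float = 0.3,
    min_r2: float = 0.99,
) -> ModulusResult:
    """Bulk elastic modulus: slope of the linear region of the curve.

    A window of ``window_frac`` of the points slides across the curve and
    ordinary least squares is fitted in each. The linear viscoelastic
    region is taken as the contiguous run of windows, containing the
    steepest one, whose smoothed slopes stay within 10% of the maximum window slope
    (the toe, having a lower local slope, is excluded); the modulus is
    one OLS fit over that whole run. The fit must reach R^2 >= ``min_r2``;
    if it does not, the criterion is relaxed stepwise (x0.99 per step,
    with a warning, down to 0.5) against the best single window before
    giving up. The fitted region is always reported so the selection can
    be audited. Units follow the stress series (stress in kPa gives
    modulus in kPa).
    """
    n = curve.strain.size
    if n < 4:
        raise ValueError("insufficient data: need at least 4 points")
    win = min(max(int(round(window_frac * n)), 3), n)
    slopes = np.empty(n - win + 1)
    r2s = np.empty(n - win + 1)
    for i in range(n - win + 1):
        slopes[i], r2s[i] = _ols_slope_r2(curve.strain[i:i + win],
                                          curve.stress[i:i + win])
    # smooth the window-slope series so the run selection is not driven
    # by a single noisy window
    k = max(win // 2, 1)
    kern = np.ones(k) / k
    sm = np.convolve(np.pad(slopes, k // 2, mode="edge"), kern, mode="same")
    sm = sm[k // 2: k // 2 + len(slopes)]
    best = int(np.argmax(sm))
    near_max = sm >= 0.90 * sm[best]
    start = best
    while start > 0 and near_max[start - 1]:
        start -= 1
    stop_w = best
    while stop_w < len(slopes) - 1 and near_max[stop_w + 1]:
        stop_w += 1
    stop = stop_w + win  # exclusive point index
    slope, r2 = _ols_slope_r2(curve.strain[start:stop], curve.stress[start:stop])
    thresh = min_r2
    if r2 < thresh:
        # relax the criterion stepwise until the selected region (or,
        # failing that, the best single window) qualifies
        best_w = int(np.argmax(r2s))
        while thresh >= 0.5:
            thresh *= 0.99
            if r2 >= thresh:
                warnings.warn(
                    f"linear-region R^2 criterion relaxed to {thresh:.3f}",
                    stacklevel=2)
                break
        else:
            if r2s[best_w] >= 0.5:
                # region fit is genuinely nonlinear; best single window
                # is the only defensible estimate
                thresh = 0.5
                warnings.warn(
                    "linear-region fit failed the relaxed criterion; "
                    "falling back to the best single window", stacklevel=2)
                start, stop = best_w, best_w + win
                slope, r2 = slopes[best_w], r2s[best_w]
            else:
                raise ValueError("no window met the (relaxed) linearity criterion")
    return ModulusResult(
        modulus=float(slope), r_squared=float(r2),
        fit_start=start, fit_stop=stop,
        strain_bounds=(float(curve.strain[start]), float(curve.strain[stop - 1])),
        min_r2_used=thresh)
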