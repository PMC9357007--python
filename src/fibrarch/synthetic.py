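"""Synthetic ground-truth generators for every input class of the pipeline.

Four generator families: fibre-network phantoms (stand-ins for SHG
acquisitions of collagen I), stained-slide phantoms with planted hue-class
area fractions, protein-abundance matrices with planted temporal cluster
profiles, and stress-strain curves with a toe plus a linear region of known
slope. Each is deterministic under a fixed seed and returns the ground
truth alongside the data so downstream estimators can be validated without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import CalibratedImage, RGBImage, ZStack
from .stain import HSBBox, DEFAULT_BIREFRINGENCE_BOXES, hsb_to_rgb

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

TISSUES = ("healthy", "tumour")
STAGES = ("early", "mid", "late")


@dataclass
class FibrePhantomParams:
    """Parameters of a rendered fibre-network image.

    Angles are axial (period 180 deg): each fibre's orientation is drawn
    from a von Mises distribution on the doubled angle and halved, the
    standard construction for axial data. ``kappa = 0`` gives an isotropic
    network; ``kappa >= 1e6`` is treated as the aligned limit where every
    fibre takes ``mean_angle`` exactly.
    """

    image_size: tuple[int, int] = (256, 256)
    n_fibres: int = 100
    mean_angle: float = 0.0          # degrees in (-90, 90]
    kappa: float = 0.0               # von Mises concentration, >= 0
    fibre_fwhm_px: float = 4.0       # Gaussian cross-section FWHM, > 0
    fibre_length_px: float = 80.0
    intensity: float = 200.0
    noise_sd: float = 5.0
    background: float = 10.0
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image dimensions must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not self.fibre_fwhm_px > 0:
            raise ValueError("fibre_fwhm_px must be > 0")
        if self.n_fibres < 0:
            raise ValueError("n_fibres must be >= 0")


def sample_axial_angles(rng: np.random.Generator, n: int, mean_angle: float,
                        kappa: float) -> np.ndarray:
    """Draw axial orientations (degrees in (-90, 90]) via the doubled-angle
    von Mises construction."""
    if kappa >= 1e6:
        return np.full(n, mean_angle, dtype=float)
    if kappa == 0:
        doubled = rng.uniform(-np.pi, np.pi, n)
    else:
        doubled = rng.vonmises(np.deg2rad(2.0 * mean_angle), kappa, n)
    theta = np.rad2deg(doubled) / 2.0
    theta = (theta + 90.0) % 180.0 - 90.0
    theta[theta == -90.0] = 90.0
    return theta


def make_fibre_phantom(params: FibrePhantomParams) -> tuple[CalibratedImage, pd.DataFrame]:
    """Render a fibre-network phantom and return it with its ground truth.

    Fibres are straight segments with a Gaussian cross-section of the
    stated FWHM; overlapping fibres combine by maximum (not sum) so the
    per-fibre width ground truth stays valid under crossings. The returned
    table has one row per fibre: centre, axial angle and FWHM.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    angles = sample_axial_angles(rng, params.n_fibres, params.mean_angle, params.kappa)
    cx = rng.uniform(0, w, params.n_fibres)
    cy = rng.uniform(0, h, params.n_fibres)

    canvas = np.zeros((h, w), dtype=float)
    sigma = params.fibre_fwhm_px * FWHM_TO_SIGMA
    half_len = params.fibre_length_px / 2.0
    reach = int(np.ceil(3.0 * sigma)) + 1
    rows = np.arange(h)
    cols = np.arange(w)
    for k in range(params.n_fibres):
        a = np.deg2rad(angles[k])
        # y points up in the angle convention; rows increase downwards.
        dx, dy_row = np.cos(a), -np.sin(a)
        x0, y0 = cx[k] - half_len * dx, cy[k] - half_len * dy_row
        x1, y1 = cx[k] + half_len * dx, cy[k] + half_len * dy_row
        r_lo = max(int(np.floor(min(y0, y1))) - reach, 0)
        r_hi = min(int(np.ceil(max(y0, y1))) + reach, h - 1)
        c_lo = max(int(np.floor(min(x0, x1))) - reach, 0)
        c_hi = min(int(np.ceil(max(x0, x1))) + reach, w - 1)
        if r_lo > r_hi or c_lo > c_hi:
            continue
        yy = rows[r_lo:r_hi + 1, None].astype(float)
        xx = cols[None, c_lo:c_hi + 1].astype(float)
        # distance to segment
        vx, vy = x1 - x0, y1 - y0
        seg2 = vx * vx + vy * vy
        if seg2 == 0:
            d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        else:
            t = ((xx - x0) * vx + (yy - y0) * vy) / seg2
            t = np.clip(t, 0.0, 1.0)
            d2 = (xx - (x0 + t * vx)) ** 2 + (yy - (y0 + t * vy)) ** 2
        patch = params.intensity * np.exp(-d2 / (2.0 * sigma * sigma))
        region = canvas[r_lo:r_hi + 1, c_lo:c_hi + 1]
        np.maximum(region, patch, out=region)

    img = canvas + params.background
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    truth = pd.DataFrame({
        "fibre": np.arange(params.n_fibres),
        "centre_x": cx, "centre_y": cy,
        "angle_deg": angles,
        "fwhm_px": np.full(params.n_fibres, params.fibre_fwhm_px),
    })
    return CalibratedImage(img, params.pixel_size_um), truth


def make_fibre_stack(params: FibrePhantomParams, n_planes: int = 10,
                     z_step_um: float = 2.52,
                     peak_plane: int | None = None) -> ZStack:
    """A z-stack of phantoms whose fibre density peaks at one plane,
    mimicking an SHG acquisition through a section."""
    if peak_plane is None:
        peak_plane = n_planes // 2
    planes = []
    for z in range(n_planes):
        frac = np.exp(-0.5 * ((z - peak_plane) / (n_planes / 4.0)) ** 2)
        p = FibrePhantomParams(
            image_size=params.image_size,
            n_fibres=max(int(round(params.n_fibres * frac)), 0),
            mean_angle=params.mean_angle, kappa=params.kappa,
            fibre_fwhm_px=params.fibre_fwhm_px,
            fibre_length_px=params.fibre_length_px,
            intensity=params.intensity, noise_sd=params.noise_sd,
            background=params.background, pixel_size_um=params.pixel_size_um,
            seed=params.seed * 1009 + z,
        )
        planes.append(make_fibre_phantom(p)[0])
    return ZStack(planes, z_step_um)


def make_stain_phantom(
    area_fractions: dict[str, float],
    image_size: tuple[int, int] = (100, 100),
    seed: int = 0,
    boxes: dict[str, HSBBox] | None = None,
    background_rgb: tuple[int, int, int] = (200, 200, 200),
) -> tuple[RGBImage, dict[str, float]]:
    """Render an RGB slide phantom with exact planted hue-class fractions.

    Each class's pixels get hue/saturation/brightness drawn uniformly
    inside the interior of its HSB box (a 2-step margin keeps integer
    round-trips in-box). Remaining pixels are unstained pale-grey tissue
    so that class fractions are fractions of tissue area. Returns the
    image and the true (pixel-rounded) fractions.
    """
    if boxes is None:
        boxes = DEFAULT_BIREFRINGENCE_BOXES
    fracs = dict(area_fractions)
    for name, f in fracs.items():
        if f < 0:
            raise ValueError(f"negative fraction for class {name!r}")
        if name not in boxes:
            raise ValueError(f"no HSB box defined for class {name!r}")
    if sum(fracs.values()) > 1.0 + 1e-12:
        raise ValueError("area fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    h, w = image_size
    n = h * w
    counts = {name: int(round(f * n)) for name, f in fracs.items()}
    if sum(counts.values()) > n:
        raise ValueError("rounded class pixel counts exceed the image")
    order = rng.permutation(n)
    hsb = np.zeros((n, 3), dtype=float)
    # background: pale grey (S=0, B in tissue range)
    bg = np.array(background_rgb, dtype=np.uint8)
    rgb = np.tile(bg, (n, 1)).astype(np.uint8)
    pos = 0
    true_fracs = {}
    for name in sorted(counts):
        c = counts[name]
        box = boxes[name]
        idx = order[pos:pos + c]
        pos += c
        # interior margin absorbs the <=4-step integer round-trip error of
        # the HSB<->RGB conversion at high saturation
        margin = 4
        hh = rng.uniform(box.h_lo + margin, box.h_hi - margin, c)
        ss = rng.uniform(box.s_lo + margin, box.s_hi - margin, c)
        bb = rng.uniform(max(box.b_lo + margin, 60), box.b_hi - margin, c)
        rgb[idx] = hsb_to_rgb(np.stack([hh, ss, bb], axis=-1))
        true_fracs[name] = c / n
    return RGBImage(rgb.reshape(h, w, 3)), true_fracs


@dataclass
class AbundanceSimParams:
    """Planted-profile abundance simulation over 2 tissues x 3 stages.

    Four planted clusters mirror the qualitative temporal shapes seen in
    tumour-matrisome profiling: C1 rises in both tissues but starts higher
    and rises faster in tumour; C2 is uniformly elevated in tumour at all
    stages; C3 is progressively downregulated with progression; C4 dips at
    early/mid stages and rises late. A null set has no group effect.
    ``effect_size`` scales the profile amplitudes in log2 units.
    """

    n_per_cluster: int = 40
    n_null: int = 100
    n_replicates: int = 5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")


# log2 offsets per condition, in units of effect_size; order:
# healthy early/mid/late then tumour early/mid/late.
CLUSTER_PROFILES: dict[str, np.ndarray] = {
    "C1": np.array([0.0, 0.5, 1.0, 0.5, 1.5, 2.5]),
    "C2": np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
    "C3": np.array([0.0, 0.0, 0.0, -0.5, -1.0, -1.5]),
    "C4": np.array([0.0, 0.0, 0.0, -1.0, -1.0, 1.0]),
}


def condition_labels() -> list[tuple[str, str]]:
    return [(t, s) for t in TISSUES for s in STAGES]


def simulate_abundance(
    params: AbundanceSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a raw-intensity proteins x samples matrix.

    Returns ``(matrix, design, truth)``: the matrix holds positive raw
    intensities with NaN for missing entries; the design table maps each
    sample to its tissue and stage; truth holds the planted cluster label
    per protein ('C1'..'C4' or 'null').
    """
    rng = np.random.default_rng(params.seed)
    conds = condition_labels()
    sample_ids, tissues, stages = [], [], []
    for t, s in conds:
        for r in range(params.n_replicates):
            sample_ids.append(f"{t}_{s}_{r + 1}")
            tissues.append(t)
            stages.append(s)
    design = pd.DataFrame({"sample": sample_ids, "tissue": tissues,
                           "stage": stages}).set_index("sample")

    labels, rows_log2 = [], []
    cluster_names = list(CLUSTER_PROFILES)
    n_samples = len(sample_ids)
    cond_index = np.repeat(np.arange(6), params.n_replicates)
    for name in cluster_names + ["null"]:
        n = params.n_null if name == "null" else params.n_per_cluster
        profile = (np.zeros(6) if name == "null"
                   else CLUSTER_PROFILES[name] * params.effect_size)
        base = rng.normal(params.baseline_mean, params.baseline_sd, n)
        noise = rng.normal(0.0, params.noise_sd, (n, n_samples))
        rows_log2.append(base[:, None] + profile[cond_index][None, :] + noise)
        labels += [name] * n
    log2m = np.vstack(rows_log2)
    values = np.power(2.0, log2m)
    if params.missing_rate > 0:
        mask = rng.random(values.shape) < params.missing_rate
        values[mask] = np.nan
    protein_ids = [f"P{i:04d}" for i in range(values.shape[0])]
    matrix = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    truth = pd.Series(labels, index=protein_ids, name="cluster")
    return matrix, design, truth


def simulate_stress_strain(
    modulus: float,
    toe_strain: float = 0.05,
    noise_sd: float = 0.0,
    n_points: int = 100,
    max_strain: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an unconfined-compression stress-strain curve.

    The toe region (strain < ``toe_strain``) is a quadratic ramp whose
    slope grows linearly from 0 to ``modulus`` (C1-continuous with the
    linear region of slope ``modulus`` that follows), mimicking the
    J-shaped response of soft tissue. Stress units follow ``modulus``
    (kPa); noise is additive Gaussian on stress.
    """
    if not modulus > 0:
        raise ValueError("modulus must be > 0")
    if not (0.0 <= toe_strain < max_strain):
        raise ValueError("toe_strain must lie in [0, max_strain)")
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, max_strain, n_points)
    if toe_strain > 0:
        stress = np.where(
            strain < toe_strain,
            modulus * strain ** 2 / (2.0 * toe_strain),
            modulus * (strain - toe_strain / 2.0),
        )
    else:
        stress = modulus * strain
    if noise_sd > 0:
        stress = stress + rng.normal(0.0, noise_sd, stress.shape)
    return pd.DataFrame({"strain": strain, "stress": stress})
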