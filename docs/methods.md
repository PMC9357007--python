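# Methods

This note documents the models, estimators and numerical choices behind
`fibrarch`, what the synthetic generators do and do not emulate, and the
known limitations.

## Conventions

Images are row-major with the origin at the top-left; x is the column
axis. Angles are in degrees, measured anticlockwise from +x with y
pointing *up* (towards decreasing row index), and fibre orientation is
axial: it lives on the half-circle (−90°, 90°] with period 180°.
Grayscale images carry a physical calibration in µm/pixel; calibration
precedence is explicit override > TIFF resolution tags > error (microscope
TIFF dialects vary, so a writer-default resolution tag of 1 pixel/unit
with no unit is treated as absent).

## Fibre phantoms

`make_fibre_phantom` renders straight segments with a Gaussian
cross-section of a stated FWHM. Orientations are sampled by the standard
axial-data construction: the doubled angle is drawn from a von Mises
distribution with concentration κ and halved, so κ = 0 is isotropic and
κ ≥ 10⁶ is treated as the perfectly aligned limit. Overlapping fibres
combine by **maximum**, not sum: the bundle-width ground truth of each
fibre then stays valid under crossings, mirroring the way SHG intensity
saturates rather than adding linearly. Additive Gaussian noise and a
constant background complete the image. The generator returns a per-fibre
table (centre, angle, FWHM) as ground truth.

What the phantoms do *not* emulate: fibre curvature, bundling/merging,
depth attenuation, optical point-spread blurring, or the intensity
statistics of real SHG detectors. Passing recovery tests therefore
demonstrates correctness of the estimators on idealised networks, not
performance on real acquisitions.

## GLCM correlation

Images are first linearly rescaled to 8 bit and uniformly rebinned to 64
grey levels (a common Haralick default; configurable). Co-occurrence
counts are **direction-specific** (asymmetric) at the four offsets 0°,
90°, 180°, 270°, and the Haralick correlation is computed from the joint
probability table; zero-variance marginals make the statistic undefined
and are flagged (NaN) and excluded from direction means. Correlation is
invariant to count-matrix transposition, so the 0° and 180° curves agree
to machine precision — kept as a self-check. The scalar summary is the
mean of the direction-mean correlation over distances 1…D (D = 50 px by
default); a curve normalised to its d = 1 value is reported alongside the
raw curve, since cross-image averaging conventions differ.

## Orientation and alignment

Spatial derivatives come from the cubic B-spline representation of the
image: the spline coefficients are filtered with the exact B-spline
derivative weights (±½ at the neighbouring coefficients) along the
derivative axis and the B-spline smoothing weights (1/6, 4/6, 1/6) along
the other. A small isotropising Gaussian (σ = 1 px, `gradient_scale`)
precedes the derivatives: without it, the discrete derivative pair
responds anisotropically to pixel-level noise and the orientations of
background pixels pile up on the grid diagonals (measured max/min bin
ratio ≈ 6 on pure noise; ≈ 1.2 with the pre-blur). Tensor components are
averaged in a Gaussian window of σ = 4 px (`smoothing_scale`).

The orientation histogram weights each pixel by its **coherency** by
default. Coherency is the natural per-pixel confidence of the orientation
estimate and is independent of brightness; weighting by coherency·energy
(available as an option, along with energy-only and unweighted schemes)
lets the brightest bundles dominate and roughly doubles the sampling
variability of the histogram, which degrades the isotropy behaviour of the
alignment ratio. An optional energy floor excludes background pixels
entirely for images where even down-weighted background votes are
unwanted.

Alignment is summarised per curve after smoothing with a circular moving
average (window 3 bins): peak = modal smoothed weight, baseline = mean of
the lowest quartile of smoothed weights (the minimum alone is
noise-sensitive; `min` and lowest-decile rules are available), ratio =
peak/baseline. A zero baseline — a genuinely empty histogram tail, as in
a dense noiseless perfectly aligned phantom where every pixel inherits
the fibre direction — is reported as +inf rather than clipped. Real
acquisitions always carry enough background for a finite baseline; the
alignment-vs-κ experiments therefore use phantoms with a visible noise
floor (noise SD 20 at fibre intensity 200).

Experiment sizes in the test suite and acceptance script were set by
statistical design: the isotropy-ratio bound (< 1.5) is only meaningful
when per-bin angular sampling error is small, which needs a few thousand
independent fibre angles — hence a dense 640², 9000-fibre network for
that measurement; mode-recovery and monotonicity experiments use 256²–384²
phantoms with 300–2000 fibres.

## Bundle widths

Within each tile of a 3×3 grid, the tile's dominant orientation is the
coherency-weighted axial mean of its orientation field, and intensity
profiles are sampled (bilinear interpolation, 1-px steps) along lines
perpendicular to it — automating the manual across-fibre transects of
interactive profile plots; a fixed-axis mode exists for strict mimicry.
Peaks are detected above a prominence of 0.2× the tile's dynamic range
and measured at **full width at half prominence** (for a Gaussian ridge
on a flat background this equals the FWHM). Widths below 2 px
(sub-resolution) or truncated at profile ends are discarded; an image
with no measurable peaks returns an explicitly empty result rather than
zero. Widths convert to µm via the pixel calibration.

## Stain quantification

HSB thresholding uses inclusive boxes on 0–255 channels (hue on the
0–255 wheel), with a wrap flag for hue intervals crossing the seam. The
fibrillar-collagen (picrosirius red) box is H ∈ [200, 240],
S ∈ [150, 255], B ∈ [0, 255]; the printed source thresholds use a
mixed relational notation read here as lo ≤ · ≤ hi, and the hue-wheel
convention (0–255 rather than 0–360) is inferred, both kept verbatim and
documented rather than "corrected". Yellow (H ∈ [30, 60]) and green
(H ∈ [70, 140]) birefringence boxes are package defaults, not published
values. Tissue is any non-white pixel (B ≤ 230 or S ≥ 30, configurable);
stained fractions are fractions of tissue area, and classes must be
mutually non-overlapping unless explicitly allowed. DAB quantification
defaults to a brown HSB box with an H-DAB colour-deconvolution
alternative.

Stain phantoms draw H/S/B uniformly inside each class box with a 4-step
interior margin (the integer HSB↔RGB round trip moves values by up to ~4
steps at high saturation), and render the unstained remainder as pale
grey *tissue* so planted fractions are exact fractions of tissue area.

## Study metrics

Invasion and metastasis thresholds are strict inequalities, matching
their definitions: a cell invades only when strictly deeper than 50 µm;
a focus is a metastasis only when strictly above 100 µm². Tumour volume
is (max² × min) × 0.52 in mm³, with out-of-order dimensions auto-swapped
under a warning.

The bulk modulus fits the linear viscoelastic region of a stress–strain
curve (force is converted to stress by the contact area when needed). A
window of 30% of the points slides across the curve; the linear region is
the contiguous run of windows — containing the steepest one — whose
moving-average-smoothed slopes stay within 10% of the maximum window
slope (the toe has a lower local slope and is excluded), and the modulus
is a single OLS fit over that run. A pure max-R² window rule proved
noise-fragile at low modulus: a single 30-point window's slope can err by
>10% at realistic noise, while the run-union fit stays within a few
percent. The fit must reach R² ≥ 0.99; failing that the criterion is
relaxed stepwise (×0.99 per step, warning emitted, floor 0.5) and, only
if the region fit is genuinely nonlinear, the best single window is used.
The fitted strain bounds and the R² achieved are always reported so the
selection is auditable.

## Abundance simulation and the matrisome pipeline

`simulate_abundance` plants four temporal profiles over the six
tissue × stage conditions (healthy/tumour × early/mid/late), in log2
units scaled by `effect_size`: C1 rises in both tissues but starts higher
and rises faster in tumour; C2 is uniformly elevated in tumour; C3 is
progressively downregulated with progression; C4 dips at early/mid and
rises late. Null proteins carry no group effect. Per-protein baselines
are N(20, 2) log2 units, noise is i.i.d. Gaussian per observation
(default SD 0.5 log2 units), and missingness is completely at random —
the intensity-dependent missingness of real label-free data is
deliberately out of scope because the presence filter under test is
count-based. Defaults (5 replicates per group, 40 proteins per planted
cluster) mirror the scale of a decellularised-tissue profiling study.

The pipeline: proteins present in ≥ 70% of all samples are retained;
intensities are log2-transformed and per-sample median-centred; one-way
ANOVA across the six groups (no imputation — proteins without ≥ 2
observations in ≥ 2 groups, or with zero within-group variance, are
flagged untestable and never significant) with Benjamini–Hochberg
q-values at FDR 0.05; per-stage tumour-vs-healthy Welch t-tests for
volcano summaries. Clustering operates on per-protein z-scores of the
six condition medians (median over replicates), with Euclidean distance
and average linkage (configurable — the original analysis does not state
a linkage), cut at k = 4; cluster labels are canonicalised by descending
mean tumour-late z-score so C1 is always the most tumour-late-elevated
cluster regardless of input order. Fisher exact tests associate matrisome
categories with clusters (BH across all cluster × category pairs), and
PCA is an SVD on the complete-protein subset (present in all samples).

BH correction is the deterministic step-up procedure (via statsmodels); a
seeded permutation FDR is not implemented — the deterministic choice is
testable against an exact oracle.

## Numerical and testing notes

Determinism: every generator takes an explicit seed, and the CLI runner
embeds parameters and input checksums in its manifest, so reruns are
byte-identical apart from manifest timestamps. Degenerate inputs have
explicit behaviours: constant images flag as degenerate in 8-bit
conversion and raise in the GLCM curve; empty peak sets return empty
results; zero-tissue slides, zero-cell invasion counts and short
stress–strain curves raise. Problem sizes in the test suite (phantom
sizes 192²–640², 3–10 seeds per experiment, 200 null-simulation
replicates) were chosen as the smallest designs whose sampling noise is
comfortably below the tolerances being asserted.

## Limitations

The estimators are validated on synthetic ground truth only; real SHG
and histology images add optics, staining variability and segmentation
questions that are out of scope. The GLCM summary assumes a single-plane
8-bit image; 3-D co-occurrence is not implemented. Orientation analysis
is 2-D. Metastasis quantification ingests pre-segmented focus areas (or
a labelled mask); H&E segmentation itself is not provided. The hue-class
defaults for yellow/green birefringence and DAB are sensible defaults,
not published constants, and should be calibrated per staining protocol.
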