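# fibrarch

Quantification of fibrillar-collagen architecture and the temporal tumour
matrisome, for studies of how the extracellular matrix is remodelled during
breast-cancer progression.

Solid tumours accumulate and re-organise collagen I, and both the amount and
the spatial organisation of the fibre network shape invasion and metastasis.
`fibrarch` implements the image- and data-analysis layer of such studies as a
tested, reusable Python library:

- **SHG image metrics** — peak second-harmonic-generation signal over a
  z-stack; grey-level co-occurrence (GLCM) Haralick correlation as a function
  of pixel offset distance (a texture measure of network organisation);
  structure-tensor orientation fields with coherency, orientation
  distributions and the peak-to-baseline alignment ratio; collagen fibre
  bundle widths from across-fibre intensity profiles on a 3×3 grid.
- **Histology metrics** — picrosirius-red fibrillar-collagen area and
  red/yellow/green birefringence hue-class areas by HSB thresholding, and
  DAB-positive area for immunohistochemistry.
- **Study morphometrics** — organotypic invasive index, callipered tumour
  volume, pulmonary metastasis burden, and the bulk compressive elastic
  modulus from unconfined-compression stress–strain curves.
- **Matrisome temporal proteomics** — presence filtering, log2
  median-centred transformation, six-group (tissue × stage) ANOVA and
  two-group volcano statistics with Benjamini–Hochberg FDR control,
  hierarchical temporal clustering into four canonical profiles, Fisher-exact
  matrisome-category enrichment, and PCA summaries.
- **Synthetic ground truth** — generators for fibre-network phantoms with
  von Mises orientation concentration, stained-slide phantoms with exact
  planted hue-class fractions, abundance matrices with planted temporal
  cluster profiles, and toe-plus-linear stress–strain curves, so every
  estimator is testable without any external data.

## Core quantities

- Haralick correlation of the co-occurrence matrix **P** at offset *d*:
  `corr = Σᵢⱼ (i−μᵢ)(j−μⱼ) P(i,j) / (σᵢ σⱼ)`, evaluated at
  0°, 90°, 180° and 270° for *d* = 1…D and summarised by the mean over
  distances — higher mean correlation indicates a more organised network.
- Fibre orientation from the structure tensor
  `J = G_σ * [∇f ∇fᵀ]` (cubic-B-spline derivatives): orientation
  `θ = ½·atan2(2J_xy, J_xx−J_yy) + 90°` on (−90°, 90°], coherency
  `(λ₁−λ₂)/(λ₁+λ₂)`. Alignment = modal weight of the (smoothed) orientation
  histogram divided by its baseline (mean of the lowest quartile); ≈1 for
  isotropic networks.
- Invasive index = invading / (invading + non-invading), a cell counting as
  invading only when strictly deeper than 50 µm below the matrix surface.
- Tumour volume = (max dimension² × min dimension) × 0.52, in mm³.
- Metastasis burden: foci strictly above 100 µm², count normalised to total
  lung cross-sectional area.
- Bulk modulus = slope of the linear viscoelastic region of the
  stress–strain curve, selected by sliding-window fits and reported with the
  fitted strain bounds.

## Worked example

```python
from fibrarch.synthetic import (FibrePhantomParams, make_fibre_phantom,
                                simulate_stress_strain)
from fibrarch.orientation import (structure_tensor, orientation_distribution,
                                  align_and_ratio)
from fibrarch.morphometry import profile_peak_widths
from fibrarch.metrics import (StressStrainCurve, bulk_modulus,
                              TumourDims, tumour_volume)

params = FibrePhantomParams(image_size=(384, 384), n_fibres=2000,
                            fibre_length_px=80, mean_angle=25.0, kappa=3.0,
                            fibre_fwhm_px=6.0, noise_sd=20.0, seed=0)
image, truth = make_fibre_phantom(params)

field = structure_tensor(image)
aligned = align_and_ratio([orientation_distribution(field, n_bins=36)])[0]
print(f"dominant orientation: {aligned.peak_angle:.1f} deg")
print(f"peak-to-baseline alignment ratio: {aligned.peak_to_baseline:.2f}")

widths = profile_peak_widths(image)
print(f"mean fibre bundle width: {widths.mean_width_um:.1f} um")

curve = simulate_stress_strain(modulus=14.5, toe_strain=0.05,
                               noise_sd=0.01, seed=0)
fit = bulk_modulus(StressStrainCurve(curve.strain.values, curve.stress.values))
print(f"bulk modulus: {fit.modulus:.2f} kPa")
print(f"tumour volume: {tumour_volume(TumourDims(10, 10)):.0f} mm^3")
```

prints

```
dominant orientation: 27.5 deg
peak-to-baseline alignment ratio: 47.66
mean fibre bundle width: 6.4 um
bulk modulus: 14.39 kPa
tumour volume: 520 mm^3
```

The phantom was planted at a mean angle of 25° with concentration κ = 3 and
6-px-FWHM fibres at 1 µm/px: the recovered mode (27.5°, within one 5° bin),
the large alignment ratio, the 6.4 µm mean bundle width and the 14.39 kPa
modulus (true 14.5) all read back the planted ground truth.

A command-line interface mirrors the library
(`fibrarch glcm|orient|widths|stain|invasion|volume|mets|modulus|matrisome|simulate|run`);
`fibrarch run config.yaml` executes a multi-stage analysis with provenance
headers on every output and a checksummed manifest.

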