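# Methods

## Scope and model

The package quantifies chromogenic immunohistochemistry (DAB, with a
hematoxylin counterstain) from transmitted-light hyperspectral microscopy.
The physical model throughout is Beer–Lambert mixing in base 10: at each
pixel the optical density A(λ) = −log₁₀ R(λ) is the concentration-weighted
sum of endmember absorbances (DAB, hematoxylin, background). Absorbance is
therefore the domain in which linear methods (PCA, mean reference spectra)
are applied; reflectance is only the acquisition-side quantity.

Calibration follows the standard dark/white-reference scheme,
R = (raw − dark)/(white − dark), clipped to [0, 1.5]; the ceiling tolerates
specular pixels without letting them dominate downstream statistics. The
absorbance floor (reflectance < 1e−4 treated as 1e−4, i.e. OD capped at 4)
keeps the log transform finite on dead pixels.

## Wavelength grids and windows

The default acquisition grid is 500–1000 nm at 5 nm (101 bands), a
commodity VIS-NIR sampling; the grid spacing is a package choice, as typical
instrument specifications state only the range. Classification operates in
the 520–725 nm window, where the chromogen and counterstain differ most;
per-cell DAB optical density is averaged over 520–650 nm, the DAB
absorption band. Window bounds are inclusive at both ends; on the default
grid the 520–725 nm window retains 42 bands.

## Synthetic tissue generator

The generator is first-class, tested code, not a fixture: it defines the
conditions under which every downstream claim is verified.

* **Geometry.** Cells are non-overlapping discs: a nucleus (radius 3 px)
  inside a cytoplasm annulus (outer radius 6 px), placed by seeded rejection
  sampling. Disc cells with forbidden overlap keep connected-component cell
  recovery exact, so any segmentation error is attributable to the
  classifier rather than to geometry.
* **Spectra.** Endmember absorbances are sums of Gaussian peaks: DAB broad
  at 560 nm (width 80 nm, peak OD 1.0), hematoxylin at 600 nm (width 45 nm,
  peak OD 0.7), and a faint non-flat background (≤ 0.02 OD). The background
  is deliberately sloped rather than flat so that a background pixel has a
  well-defined spectral *shape* and can be matched by correlation; a
  perfectly flat spectrum has zero variance and correlates with nothing.
* **Staining tiers.** Positive cells carry DAB at concentration 0.3 / 0.7 /
  1.2 (weak/moderate/strong, relative units), chosen to straddle the default
  OD bin thresholds 0.2 / 0.45 / 0.9 with margin; nuclei carry hematoxylin
  at 0.8. Tier counts are apportioned by largest remainder — deterministic,
  not multinomial — so the H-score implied by a layout is an exact number
  and recovery tests can assert equality rather than approximation.
* **Noise.** Additive Gaussian noise in the reflectance domain (clipped to
  [0, 1.5]). The robustness condition used throughout is sd 0.02 on a unit
  reflectance scale, roughly 2% full-scale sensor noise.
* **What is not emulated.** Realistic tissue morphology, scattering, stain
  co-localisation chemistry, uneven illumination and slide artefacts.
  Passing recovery tests therefore demonstrates correctness of the
  *computational chain* under the stated model, not performance on real
  tissue, where boundary mixing and morphology would dominate.

Study-condition defaults: cores are 128×128 px with 40 cells; when not
pinned in the configuration, each core's percent-positive is drawn uniformly
from [50, 100] and its weak/moderate/strong mix from a flat Dirichlet, all
from the per-core seed, so recovered scores span the 0–300 scale. Recovery
is asserted over 20 seeded cores (exact at zero noise; within ±10 H-score
units at noise sd 0.02).

## Pixel classification

Two supervised routes, trained from annotated ROIs (in the synthetic
setting, the ground-truth masks):

* **Correlation functions.** Pearson correlation between a pixel spectrum
  and each class's mean ROI spectrum; argmax above `min_corr` (default
  0.8), else UNCLASSIFIED. Cosine similarity is available as an
  alternative. Pearson correlation is exactly invariant to positive affine
  rescaling of the spectrum, which makes the classifier independent of
  stain concentration — the property that lets a single DKK3 reference
  serve weak through strong cells.
* **PCA nearest centroid.** Pixel spectra are SNV-normalised (per-spectrum
  standardisation), projected onto the first three principal components of
  the cube's spectra, and assigned to the nearest ROI centroid (Euclidean).
  The SNV step is a deliberate design choice: without it, a class whose
  chromogen concentration spans a 4× range (weak 0.3 to strong 1.2) is a
  line segment in score space, and its single centroid sits so far from the
  weak end that weak pixels fall nearer the background centroid. SNV removes
  the multiplicative scale, collapsing each class to a compact cluster and
  making the two classification routes agree. `fit_pca` itself remains
  plain covariance PCA on mean-centred absorbance, with eigenvector signs
  fixed so each loading's largest-magnitude entry is positive (reproducible
  false-colour output).

Ties (exactly equal similarity or distance) are broken by the fixed class
order DKK3-positive < nuclei < background; all label maps are deterministic
functions of their inputs.

## Cell scoring

Nuclei are 8-connected components of nucleus-class pixels of at least 4 px.
Cytoplasm is the DAB-positive pixels within Euclidean distance 3 px of a
nucleus, each pixel assigned only to its nearest nucleus (via a distance
transform), so cells partition the positive area and fractions sum
correctly. Intensity bins are half-open and lower-inclusive: a cell exactly
at a threshold takes the higher tier. The Allred proportion score follows
the standard published bins (0; (0,1); [1,10]; (10,33]; (33,66]; >66 %),
and the intensity score is the arithmetic mean tier of positive cells
rounded half-up — a deterministic reading of "the core's intensity
category" where mean, mode and dominant tier would all be defensible.

## Concordance statistics

* Cohen's κ from the 2×2 contingency of dichotomised scores, with the
  Landis–Koch bands (≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80
  substantial, else near-perfect). Degenerate rule: if expected agreement
  Pe = 1, κ is 1 when observed agreement is 1, else 0.
* Dichotomisation: Allred 0–6 = low, 7–8 = high; H-scores split at the
  pooled mean over all methods and cases (strictly above = high). The
  pooled-mean rule is adopted because it reproduces the reference tables'
  visual and digital category columns; a per-method variant is available.
* Wilcoxon signed-rank, two-sided. Zero differences are dropped (classical
  convention); tied absolute differences receive average ranks. The exact
  p-value is computed from the distribution of the signed-rank sum over all
  2ⁿ sign assignments, built by convolution over the (doubled, integer)
  ranks — mathematically identical to explicit enumeration but usable at
  n = 20 and beyond, which the type-I-error validation requires. The
  normal approximation (with tie correction) is available as a mode.
* Shapiro–Wilk is computed and reported as a normality gate only; the
  non-parametric suite always runs regardless of its outcome.

## Reference tables and known non-reproductions

The package bundles a published three-method comparison (97-core
visual-vs-digital Allred agreement table; six exemplary cases scored
visually, digitally and by HSI) as plain constants, and `hsiquant
reproduce` recomputes everything derivable from them. Three printed
statistics are not derivable from the printed inputs and are surfaced with
both values rather than corrected: the visual/HSI κ (printed 0.42, computed
0.25 from the printed category vectors), the visual/HSI Spearman ρ (printed
0.67, computed ≈ 0.24 from the six H-score pairs), and the six-case
visual/digital Wilcoxon (all six differences share a sign, so the exact
two-sided p is 0.03125; the printed non-significant p = 0.278 refers to the
97-core dataset). The HSI H-score category of case 4 likewise does not
follow from the pooled-mean rule.

## Numerical conventions and degenerate inputs

Zero-variance pixel spectra receive correlation 0 (never a division error);
spatially constant cubes are rejected by PCA as degenerate; empty ROIs and
empty masks raise typed errors; a label map without nuclei yields an empty
cell list, and an empty core scores zero and is flagged non-representative
rather than failing the batch. All randomness flows from explicit seeds;
per-core seeds are derived from the base seed with NumPy `SeedSequence`, and
equal configurations produce byte-identical outputs.

## Known limitations

Segmentation quality on real tissue is untested by design (no deposited
data); the generator's disc geometry avoids the boundary-mixing and
touching-nuclei regimes that dominate real-slide error. The Allred
intensity-score convention (mean-rounded) and the OD bin thresholds are
package choices exposed in the configuration, not published constants. ENVI
support covers the BSQ/BIL float dialect this package writes, not the full
format zoo.
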