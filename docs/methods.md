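# Methods

## Pipeline model

The package treats input-function determination as four deterministic
stages around one learned stage.

**Grid standardization.** Acquisitions from different cameras are
resampled to the reference 2.21 mm/pixel grid before any analysis. Each
frame is interpolated bilinearly and independently (pixel pitch is the
only thing standardized; there is no temporal interpolation), and the
interpolated values are rescaled by the pixel-area ratio. This preserves
*counts*, the quantity the TAC/AUC analysis sums, rather than count
densities; a uniform frame therefore stays exactly uniform with its value
scaled by the area ratio. Coordinates are 0-based `(row, col)` with pixel
centers at integer positions, everywhere in the package.

**Peak detection and phase images.** The vascular peak frame is found on
the whole-image count curve: the curve is smoothed with a 3-point moving
average and local maxima whose *topographic prominence* reaches a
fraction `f = 0.3` of the smoothed curve's dynamic range (max − min)
count as peaks. Prominence, rather than absolute height, is used because
a Poisson background baseline of a few thousand counts per frame would
otherwise either mask real peaks or promote noise wiggles near the start
of the acquisition into spurious "first peaks". The PA target takes the
first prominent peak (central pulmonary transit), the AAo target the
second (systemic arrival); a missing required peak raises an
unsuitable-curve error, which is how slow-injection acquisitions are
rejected at this stage. Peak indices are refined to the raw-curve argmax
within one frame (earliest on ties). The phase image is the pixel-wise
sum of frames `[peak−2, peak+2]`; the window is clamped at the series
edges and the effective extent recorded. Both "2 before/after" and "3
before/after" are supported; 2 is the default as the smaller window.

**Segmentation.** A U-Net with five encoder levels (one 3×3 convolution
each, 2×2 max pooling between levels) and four decoder levels (2×
nearest-neighbour upsampling, skip concatenation, two convolutions each)
— 13 convolutional layers in total. Every convolution carries batch
normalization and ReLU except the last, a 1×1 convolution to the
single-channel output trained with squared error against binary {0,1}
masks. Optimization is Adam with α = 0.001, β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁸; "iterations" are epochs over the (augmented) training set,
50 by default, batch size 8. Channel widths double per level from a
configurable `base_width` (16 by default; 8 for desk-scale runs — width
is the one hyperparameter the architecture leaves open). The network is
implemented directly in numpy (im2col convolutions, hand-written
backward passes, verified against central finite differences in float64);
training is seed-deterministic up to the BLAS reduction order, so exact
bit-reproducibility requires a fixed BLAS configuration and otherwise
reproducibility is statistical. Inputs whose dimensions are not multiples
of 2⁴ are zero-padded for the pass and cropped back.

**Augmentation.** Each training pair is expanded by mirror reflection,
rotations of 0/90/180/270°, and 10-pixel translations in the eight
compass directions, applied identically to image and label with
zero-filling of translated-in pixels and no interpolation. The
enumeration is fixed at 64 members containing exactly one identity
composition (so 256 cases yield 16 384 images, and removing the originals
from 108 cases yields 6 804). Those two totals are mutually inconsistent
with a full 2×4×9 factorial (72 members), so the set is defined as the
identity plus the lexicographically first 63 members of the
2×4×8-compass factorial; the printed totals, uniqueness, and the
presence of all eight translation directions are the binding contracts.

**ROI setting.** The candidate score map is binarized with the P-tile
rule: exactly `ceil(p·n)` highest-scoring pixels are kept, ties broken by
score and then row-major position so the result is deterministic. The
P-tile fraction is derived from an expected-region-area prior (60 pixels
on the 2.21 mm grid by default) because a percentile threshold needs an
area anchor and vessel cross-sections are the only available one; both
the area and the raw fraction are configurable. The ROI is a fixed
circle of radius 3 px (6.6 mm) placed at the foreground centroid
(arithmetic mean of foreground coordinates). If the full circle — pixels
whose centers lie within the radius — does not fit inside the candidate
region, the center relocates to the foreground pixel maximizing the
contained fraction (ties: nearest the centroid, then row-major), so the
ROI never extends beyond the vessel; the achieved containment fraction is
recorded and a sub-1.0 value warned about.

**TAC and AUC.** The ROI TAC sums the counts under the circle's pixel
mask per frame. Morphology is classified with the same prominence rule:
one prominent peak → `single` (required for PA/SIMS), two → `double`
(required for AAo/IBUR, where only the second peak is the aortic
transit), anything else → `unsuitable`. Additionally a curve whose
highest peak has FWHM above 8 s is `unsuitable` regardless of peak count:
a normal first-pass bolus (gamma-variate, α ≈ 3, β ≈ 0.8–1.3 s) has FWHM
≈ 4–6 s while an injection slowed threefold exceeds ≈ 10 s, so 8 s sits
between the two populations. The AUC integrates the target peak as the
frame sum × frame duration (counts are already per-frame integrals at
1 frame/s, so a rectangle rule is the natural choice) over the window
where the curve exceeds `f_auc = 0.05` of the target peak value. The
window is confined between the local minima separating the target peak
from its neighbours; without that bound, a between-peak valley higher
than the threshold would let the second-peak window leak into the first
peak on double-peak curves. An explicit window override exists (used,
e.g., to integrate noisy replicates over a common window, where the sum
of Poisson counts over a fixed window is exactly unbiased). SIMS reports
flag that the counts are the PA inflow term only — the lung washout-ratio
factor of the full SIMS input function is outside this package's scope,
as are the downstream rCBF equations and any administered-dose
calibration.

**Agreement evaluation.** Automatic vs reference centers are compared
with inclusive pixel tolerances (PA: ±2 px in x, ±3.5 px in y; AAo: ±4 px
in both; x is the column direction) and summarized as the coincidence
ratio. AUC pairs get Pearson r with OLS of reference on automatic, and
Bland–Altman percent differences with the pairwise mean as denominator
(the standard choice) and mean ± 1.96 SD limits of agreement; pairs with
nonpositive mean are excluded with a warning.

## The phantom generator

Structures are axis-aligned ellipses whose pixels share a gamma-variate
TAC, `K(t−t₀)^α e^{−(t−t₀)/β}`, the canonical first-pass bolus model;
frames are the structure sum plus a constant background (0.5
counts/pixel/frame), optionally with independent Poisson draws per frame.
Ground truth records masks, kinetic parameters, centroid centers and the
closed-form per-pixel AUC `Kβ^{α+1}Γ(α+1)`.

Defaults (on the 128-px grid, scaled proportionally with pixel pitch for
other sizes; no kinetic values exist for clinical TACs, so these are the
package's own choices, fixed once):

* **IMP (60 s):** a sharp PA bolus (t₀ 6 s, α 3, β 0.8 s, peak 100
  counts/px) and two broad lung fields (t₀ 10 s, β 3 s, peak 2 counts/px)
  — high ¹²³I-IMP lung uptake with washout; the whole-image curve shows
  the PA peak first with the lung phase well separated.
* **ECD (100 s):** a central blood pool ("right_heart", t₀ 5 s, β 1 s)
  that overlaps the AAo in projection — as the superimposed right
  heart/SVC does in real anterior planar views — plus PA, a bright AAo
  (t₀ 15 s, β 1.3 s, peak 100 counts/px) and a left-heart structure
  carrying the systemic phase, so both the whole-image curve and the AAo
  ROI TAC are double-peaked, the prerequisite of the IBUR analysis.
  ⁹⁹ᵐTc-ECD lung retention is small and is omitted.

Bolus arrival is ordered right-heart ≤ PA ≤ lungs ≤ AAo and enforced.
The PA and AAo masks must be disjoint (they are the two quantification
targets); other overlaps are allowed as projectional superposition. Slow
injection multiplies β by an `injection_speed` factor while conserving
the analytic AUC (the injected activity), so the bolus gets wider and
proportionally lower; cases with a factor above 2 are flagged `slow` in
the truth metadata. Datasets draw per-case geometry/kinetics jitter
(centers ±2 px, axes ±8 %, amplitudes ±20 %, one-sided t₀ shifts that
preserve arrival order) from a single seeded generator, redrawing on the
rare invalid geometry; a configurable fraction of cases (rounded count)
is generated slow.

What the phantoms do **not** model: attenuation, scatter, detector
resolution, patient motion, anatomical shape variation beyond ellipses,
and overlap patterns more adverse than the ones built in (e.g. a
descending vena cava hugging the PA). Passing tests therefore establish
the correctness of the pipeline's mechanics and its noise behaviour, not
clinical segmentation performance; the clinical coincidence ratios and
correlations are not reproducible from synthetic data and are not
claimed.

## Desk-scale study conditions

Tests and the acceptance script train a reduced-width network
(base width 8) for 40 epochs on 50 simulated IMP phase/label pairs at the
native 128-px grid and evaluate on 20 held-out cases (thresholded
candidate at the 60-px area prior → centroid error vs truth, Dice, and
SIMS AUC agreement against a reference ROI placed from the truth mask).
With the 60-px prior against a ~94-px true PA, the attainable Dice is
bounded at ≈ 0.78, which the trained network reaches; centroid recovery,
not Dice, is the quantity the method ultimately needs. These sizes are
the package's chosen desk-scale study conditions; the full clinical-scale
configuration (width 16, 50 epochs, hundreds of augmented cases, 6-fold
cross-validation) is available through the same interfaces.

## Numerical choices and degenerate inputs

* P-tile on an all-equal map is refused ("no contrast") rather than
  returning an arbitrary subset; empty masks refuse centroid/placement.
* Normalization of an all-zero phase image is an error; normalization is
  idempotent.
* ROIs clipped by the image boundary warn and proceed on the clipped
  pixel set.
* Peak refinement breaks ties toward the earliest frame; P-tile and
  containment ties are resolved by row-major order — every pipeline
  output is deterministic for a given seed.
* Training aborts with diagnostics on non-finite loss. Network arrays are
  float32; gradient correctness was verified in float64.
* `crossval_split` shuffles case ids with the given seed and deals them
  round-robin, giving disjoint folds covering all cases with sizes
  differing by at most one.

## Known limitations

* The P-tile percentage used clinically is unknown; the area-prior
  default is a declared choice, exposed as configuration.
* Whether clinical AUCs were first-pass-windowed or whole-acquisition
  sums is not stated anywhere; the fraction-of-peak window (with a
  full-curve option for PA) is this package's rule.
* SIMS output is the PA inflow term only (no washout ratio); IBUR output
  is the second-peak AUC only — neither is a calibrated rCBF value.
* DICOM import is a best-effort mapping onto the array+sidecar format,
  not a vendor-complete conformance layer.
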