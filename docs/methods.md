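# Methods

## Problem and pipeline

Diabetic macular edema severity is graded from a single OCT B-scan in
three stages. First, biomarkers are detected: a two-class CNN decides
whether the scan shows disorganization of the retinal inner layers (DRIL);
if so, the 1 mm central foveal window is localized and a second classifier
decides whether the DRIL is central or non-central; in parallel, three
U-Nets segment hyperreflective foci (HRF), the outer plexiform layer (OPL)
band, and cystoid spaces. Second, the masks are reduced to crisp features:
HRF counts above vs within/below the OPL upper boundary, and cystoid
count, pixel area, and horizontal/vertical bounding-box diameters in
micrometres. Third, a Mamdani fuzzy rule engine maps the feature vector to
a severity score in [0, 1], a grade (Mild / Moderate / Severe) and three
treatment advisories.

All modules share the raster coordinate convention (row 0 at the top, rows
increasing downward). A clinical description of the form "the HRF lies
above the OPL" therefore translates to *smaller* row index: an HRF whose
centroid row is strictly less than the OPL upper-boundary row at its
column is above the OPL; a tie counts as within/below, the conservative
(higher-severity) reading. The HRF reference point is the component
centroid, which is stable against boundary noise.

## Segmentation

The U-Net is the standard contraction/expansion design: per level two 3×3
convolutions (ReLU, dropout after each), 2×2 stride-2 max-pooling; the
decoder up-samples (nearest neighbour), halves the channels with a 3×3
convolution, concatenates the mirrored encoder map, and applies one more
3×3 convolution block; a final 1×1 convolution and sigmoid yield a
single-channel probability map. Defaults: 192×192 input, 3 input channels,
base_filters 8, depth 3, dropout 0.1 — about 10⁵ parameters, chosen to
train in minutes on one CPU core.

Training minimizes `w·BCE − DSC` with w = 0.3. BCE is the pixel-mean
binary cross-entropy with probabilities clipped to [1e−7, 1−1e−7]. Inside
the loss the Dice term must be differentiable, so the soft form
`(2Σpy + s)/(Σp + Σy + s)` with smoothing s = 1 is used; evaluation uses
the set-based Dice on binarized masks (threshold 0.5), with the empty-vs-
empty case defined as 1.0 (a correct all-negative prediction is perfect).
On binary inputs the two Dice forms agree within `s/(|A|+|B|+s)`. The loss
is bounded below by −1, attained at a perfect prediction. The 0.3 weight
is exposed as `bce_weight` in the configuration. Cystoid inputs are
denoised with a 5×5 Gaussian blur (σ = 1.1) before segmentation, at
training and inference alike.

Optimization is Adam (lr 3e−3, β = 0.9/0.999) with batch size 2. All
randomness — weight init, dropout, shuffling — derives from the config
seed, so identical seeds reproduce identical loss histories on a fixed
backend.

## Classification

Scans are converted to grayscale, resized to a square input and scaled by
1/255. The default backbone is a small seeded CNN: three conv/pool blocks
(8, 16, 32 filters; dropout 0.2), a fourth 3×3 convolution, a **global max
pool** and a softmax head. Global max pooling asks "does this texture
occur anywhere", which is the right inductive bias for lesion-presence
decisions and is what lets ~100 training images generalize. Before the
first convolution the grayscale image is stacked with two fixed
local-standard-deviation maps (window ≈ 1/18 and 1/6 of the image side);
these make texture disruptions such as locally erased layering directly
visible to the first layer and are not learned. A VGG-19 topology (with a
compact global-average-pool head in place of the original 4096-wide dense
stack) is available as a configuration option; no pretrained weights are
shipped.

The foveal region of interest is found deterministically: the scan is
smoothed (Gaussian σ = 2), thresholded midway between its extremes to the
bright retinal band, and the column with the minimum smoothed band
thickness — the foveal depression — becomes the ROI centre. The ROI width
is `round(1000 µm / um_per_px)`. The centrality classifier sees the ROI
crop only. A learned localizer slot exists in the interface but the
geometric default is used throughout.

Optimizer basins matter at this scale: a run occasionally converges to a
poor optimum, which is visible in the *training* accuracy. The desk-scale
recipes therefore retrain with a derived seed (up to two restarts) when
final training accuracy is below 0.95 — a decision made on training data
only and deterministic in the seed.

Evaluation metrics are sensitivity TP/(TP+FN), precision TP/(TP+FP),
specificity TN/(TN+FP), F1 (harmonic mean of precision and sensitivity)
and accuracy; each raises an explicit error when its denominator is zero.

## Fuzzy severity engine

Inputs and their linguistic terms:

| variable | universe | terms (breakpoints) |
|---|---|---|
| dril_present, dril_central | {0, 1} | crisp booleans |
| hrf_within_below, cystoid_count, hrf_total | [0, 20] | none (0→1), few (0,1,2,4), many (2,4,⊤), some (>0) |
| h_diameter | [0, 2000] µm | small / large, crossover 450 µm ± 50 |
| v_diameter | [0, 2000] µm | small / large, crossover 300 µm ± 35 |

The clinical cut points (450 µm, 300 µm, DRIL centrality within the 1 mm
window) are preserved as the 0.5-membership crossovers; transition widths
of roughly ±10 % keep the engine fuzzy without moving the thresholds.

Severity rules: central DRIL → severe; non-central DRIL → moderate; many
sub-OPL HRF → severe, few → moderate; many cystoids → severe; large
horizontal / vertical diameter → severe with weights 0.58 / 0.62; small
diameters → mild with weights 0.73 / 0.69. The weights are the
literature-reported probabilities of the corresponding visual-acuity
outcomes, used verbatim. Advisory rules are crisp: dexamethasone response
(no DRIL and no HRF), driving/reading warning (cyst > 450 µm and
> 300 µm), ranibizumab response (cyst < 450 µm and < 300 µm); cystoid
advisories are false when there is no cystoid, since a recommendation
about cyst response is meaningless without cysts.

Inference is max–min Mamdani: activation = weight × min of antecedent
memberships; consequents are clipped and max-aggregated over a 101-point
discretization of [0, 1]; the crisp score is the aggregate centroid, with
an empty aggregate defined as score 0 (Mild) — absence of any risk-rule
activation is the benign case, and is logged. Grade cut points are 0.35
and 0.65. The consequent sets are narrow triangles (width 0.2) centred at
0.15 / 0.50 / 0.85: with centroid defuzzification, wide overlapping
consequents compress all scores toward 0.5, and the narrow supports are
what keeps the three grades separated under the fixed cut points. The
engine is monotone in each risk feature (verified by sweep tests) and
reduces to a crisp rule table in the boolean limit (verified by exhaustive
enumeration). The rule base round-trips through YAML so rules can be
edited without code changes.

## Synthetic phantoms

A phantom is a five-band retina (GCL-IPL, INL, OPL, ONL, RPE at
reflectivities 0.60/0.30/0.62/0.22/0.85 on a 0.05 vitreous background)
whose inner surface dips at the fovea, pinching the inner layers toward a
fixed OPL top. DRIL is rendered by replacing the inner-band intensities
over a column interval with their mean — the layering simply vanishes
there, and the OPL annotation mask is erased over the same interval
(feature extraction bridges such gaps by linear interpolation). HRF are
bright disks; cystoid spaces are dark ellipses constrained to lie at or
below the INL and to remain mutually disjoint. Multiplicative Gaussian
noise (σ = 0.05) is applied to the image only; masks stay exact.
Generation is a pure function of the spec including its seed.

Default calibration is 11.7 µm/pixel at 192 px (so the 1 mm foveal window
is ≈ 85 px); at other sizes the layer geometry and pixel pitch scale
proportionally. Clinical data offer no such constancy — this is a
config value, not a measured one.

What the phantoms do *not* emulate: real OCT speckle statistics (the noise
is i.i.d. multiplicative), vessel shadows, motion artefacts, pathology
co-occurrence statistics, or annotation noise. Passing phantom tests
therefore demonstrates that the machinery — losses, training loop,
morphometry, rule engine — is correct and internally consistent, not that
the trained weights transfer to clinical scans; on real data the models
must be retrained on expert annotations.

## Desk-scale problem sizes

Chosen so the full suite trains repeatedly on a single CPU core:
segmentation at 192×192 with 20 training / 5 held-out phantoms and 30
epochs (held-out cystoid Dice ≈ 0.97); DRIL classification at 128×128
with the study-sized 100 training / 30 test split and 20 epochs (held-out
accuracy ≈ 0.93–1.0 across seeds); centrality classification on ROI crops
at 128×128. The classifier configuration default of 416×416 and 75
epochs reflects the full-scale setting; the recipes in
`octdme.workflows` use the smaller sizes above.

## Known limitations

* Segmentation masks live on the network grid; for scans of other sizes
  the micrometre calibration is rescaled by the width ratio, which assumes
  isotropic resizing.
* The DRIL-extent criterion (0.5 mm) is represented by centrality only;
  the pipeline does not measure extent, though phantoms record it.
* The surrogate for subretinal fluid is HRF count (they are correlated);
  no direct SRF input exists.
* Bounding-box diameters are axis-aligned; rotated cysts read slightly
  large.
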