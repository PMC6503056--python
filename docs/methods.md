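# Methods

`nethcs` implements a high-content screening (HCS) pipeline for NETosis —
the lytic death program by which neutrophils expel decondensed chromatin
as neutrophil extracellular traps (NETs). The pipeline covers the whole
assay loop: simulated plate imaging, nuclear segmentation, multiparametric
feature extraction, three-class phenotype classification, and
screen-level statistics. Because no public image data exist for this kind
of donor-neutrophil assay, a seeded synthetic-plate generator is a
first-class component: it defines the study conditions under which every
downstream stage is validated.

## The synthetic plate generator

### Phenotype rendering

Each nucleus is rendered as a flat-topped ("super-Gaussian") intensity
profile whose footprint defines the ground-truth mask at 12% of peak
(`MASK_LEVEL`), plus a multiplicative chromatin speckle. The three
phenotypes differ in geometry, brightness, and texture:

| phenotype | area (µm², mean ± sd) | peak (native units) | geometry |
|---|---|---|---|
| resting   | 42 ± 6   | 2600 ± 280 | 3–5 overlapping elongated lobes on a tight ring |
| NETotic   | 126 ± 28 | 1100 ± 140 | single spread region, irregular margin + filament strokes |
| apoptotic | 20 ± 3   | 4400 ± 420 | single compact, nearly round blob |

Ordering constraints (asserted at import): apoptotic < resting < NETotic
in area; NETotic < resting < apoptotic in peak intensity. These encode the
assay's discriminating observations — NETotic chromatin spreads and dims
("chromatin filling the whole cytoplasm"), apoptotic chromatin condenses
and brightens. Areas bracket the human neutrophil nucleus (~30–50 µm²);
the NETotic enlargement factor (3×) and the intensity levels are package
choices at physiologically plausible magnitudes, not measured values.

Two rendering details matter for internal consistency:

* The chromatin speckle is weighted by the profile so it fades to zero at
  the mask boundary. Texture is a property of chromatin; letting speckle
  amplify the dim profile tail would create bright satellites *outside*
  the ground-truth mask, making the ground truth unlearnable in principle.
* The lobe ring radius is small enough (0.78 of the lobe size) that the
  lobe union stays connected at the mask level under placement jitter,
  so a resting nucleus is always a single ground-truth object.

### Fields and noise

Default geometry: 512×512 px at 0.5 µm/px, 4 fields per well, 200 cells
per field (the paper-scale plating of tens of thousands of cells per well
scaled to desk size). Nuclei are placed by rejection sampling with a
minimum center separation of 1.05× the sum of effective radii (+2 px);
after repeated failures the separation relaxes by 10% per round, so dense
fields fill at the cost of realistic crowding. Cells are placed entirely
inside the field. Noise: flat camera offset (120), Poisson shot noise via
a photon gain of 4 native units/photon, Gaussian read noise (sd 6),
16-bit quantization. Setting the gain or read noise to 0 disables that
noise source (used by smooth-fixture tests).

### Population response law

A well's true NETotic fraction is

    f = baseline + (induced(t) − baseline) · (1 − inhibition(c))

with baseline 0.01 (spontaneous NETosis ≤ 1–2%), saturating-exponential
induction `induced(t) = fmax(1 − e^(−t/τ))` calibrated per stimulus —
ionomycin: 63% at 45 min and 70% at the 90-min screening endpoint
(τ ≈ 20.5 min, fmax ≈ 0.709, solved from the two anchors); PMA: 70% at
the 210-min endpoint with fmax = 0.72 (τ ≈ 58.6 min) — and Hill
inhibition `max_inh · c^h/(c^h + EC50^h)`. The reference
"capsaicin-like" inhibitor uses EC50 = 1.5 µM, h = 2, complete inhibition
(complete at 5 µM follows: inhibition(5) ≈ 0.917 of a 70% induction
leaves ~7%, and ~97% at the fitted curve's top). Every well additionally
draws a Beta-distributed jitter of its true fraction (concentration 1000,
i.e. sd ≈ 1.4 pct at f = 0.7) — the inter-well variability that makes a
Z' calculation meaningful; control-well sds were not reported, so the
concentration is a package choice giving a tight, high-quality plate. A
constant 2% spontaneous apoptotic fraction is mixed into every well.
Donor-level random effects are not modeled by default.

### Kinetic channels

Cytosolic ROS (DCF-like) fold-change: `1 + (A−1)(1 − e^(−t/τ))` with
A = 6, τ = 20 min under PMA (so the 95%-of-plateau time is
−τ ln 0.05 = 59.9 min ≈ 1 h) and A = 1.1 for vehicle/ionomycin; additive
Gaussian noise, sd 0.15 fold units per timepoint. TMRM accumulation uses
the same form with plateau 4, τ = 15 min, scaled by a depolarization
factor d (1 = intact; 0.2 = uncoupled, CCCP-like), noise sd 0.12. Domains:
ROS [0, 120] min, TMRM [0, 60] min.

## Segmentation

The segmenter must keep a spread NETotic region as one object while
separating touching compact nuclei, across a 4× intensity range. The
pipeline (all lengths in µm, converted by the image's pixel size):

1. Gaussian smoothing (σ = 0.5 µm) and top-hat background subtraction
   (separable square opening, radius 12 µm).
2. Global threshold: Otsu computed on log(1+signal) — on a linear scale
   the bright apoptotic tail pulls Otsu's threshold above dim NETotic
   chromatin — floored at 8× the robust (MAD) noise sd so blank fields
   produce no seeds (the expected extreme of ~2.6·10⁵ smoothed-noise
   pixels sits near 4.5 sd).
3. Seeding by h-maxima of the log-signal with depth −ln(0.3): a peak is
   a separate seed only if one must descend below 0.3× its height to
   reach a higher peak. On the log scale a fixed h is a fixed
   peak-to-valley *ratio*, so the same rule separates touching dim
   regions and touching bright nuclei, while speckle inside one nucleus
   rarely qualifies.
4. Seeded watershed on −signal restricted to a low-threshold support
   (hysteresis at 0.4× the global threshold): touching fringes are
   divided along the intensity valley, and watershed identity is kept
   through all later steps so adjacent objects never re-merge.
5. Per-object boundary refinement at 12% of the object's peak signal —
   the same fraction-of-peak convention that defines the generator's
   ground-truth footprint — with hole filling and largest-component
   selection.
6. Optional solidity-gated watershed splitting (solidity > 0.9 and area
   < 90 µm², distance-transform maxima ≥ 5 µm apart) for merged compact
   nuclei; diffuse NETotic regions never meet the gate. Area filter
   15–500 µm²; border-touching objects are flagged and excluded from
   summaries.

On simulator fields at default density, detection precision and recall
are ≈ 0.99 with mean per-object Jaccard ≈ 0.9 (slightly lower for small
apoptotic nuclei, whose 1-px boundary band is a large area fraction).

## Features

Per object: morphology (area, Crofton 4-direction perimeter, form factor
4πA/P² capped at 1.1 against raster bias, solidity, equivalent diameter,
lobe count = smoothed distance-transform maxima ≥ 2 µm apart), intensity
(mean/sd/max/total, population sd; density = total/area — "density" is
operationalized as integrated intensity per area), and texture:

* **Haralick / GLCM** — per-object min–max quantization to 32 levels
  (affine-intensity invariant; constant objects map to bin 0: contrast 0,
  energy 1), four distance-1 offsets, symmetric, normalized per offset;
  contrast, correlation (1 for degenerate marginals), energy,
  homogeneity, entropy (0·ln 0 = 0), averaged over offsets. Only pairs
  with both pixels inside the object are counted.
* **Gabor** — 2 frequencies (0.1, 0.25 cycles/px) × 4 orientations;
  response magnitude mean and sd over object pixels. Whole-field
  responses are computed once per field by FFT (kernel spectra cached),
  which makes wraparound a border-only effect.
* **Spots/edges/ridges** — at Gaussian scales 1 and 2 px: edge = mean
  squared scale-normalized gradient magnitude; ridge = mean squared
  Hessian eigenvalue-magnitude asymmetry (zero on rotationally symmetric
  blobs); spot = anisotropy-damped Laplacian energy 4·max(λ₁λ₂, 0),
  which equals the squared Laplacian-of-Gaussian on isotropic blobs but
  vanishes on rank-1 line structure. A pure LoG² spot would respond to a
  line exactly as strongly as the ridge operator does (a line's Hessian
  has one zero eigenvalue), defeating the spot/ridge distinction these
  features exist to make. All three are divided by the squared mean
  object intensity for illumination invariance.

The full vector is 38 features; extraction on a 200-cell field takes
≈ 0.5 s on one CPU.

## Phenotype classification and the lytic gate

A regularized linear discriminant (scikit-learn LDA, `lsqr` solver with
Ledoit–Wolf shrinkage) on standardized features; logistic regression is
available as an alternative. Training labels come from simulator ground
truth: single-phenotype fields are segmented, objects are matched to
truth masks (greedy by overlap, Jaccard ≥ 0.5), and matched objects
inherit the truth label — so training features pass through the same
segmentation used at screening time. With real images the labels would be
human-curated; that substitution is the only difference. Stratified
5-fold cross-validation (seeded folds) is recorded on the model; the
model serializes losslessly to JSON and classification is a pure function
of (model, features).

The *lytic gate* encodes the rule that only lytic NET formation counts as
NETotic: a cell whose discriminant argmax is NETotic must also have area
above the 5th percentile of NETotic training areas and Haralick contrast
below the 95th percentile of the NETotic training class (decondensed
chromatin is texturally homogeneous). Gate failures are relabeled to the
runner-up class and flagged `net_like_nonlytic`. Because the gate's
percentile construction flags ~9% of genuinely NETotic cells by design,
well summaries exclude gated-out cells from the denominator by default
(configurable); counting them as non-NETotic would bias high fractions
down by ~6 percentage points. Border-flagged cells are likewise excluded.

On held-out simulated wells (2,000 cells), three-class accuracy is
≥ 0.98 with NETotic↔apoptotic confusion ≈ 0, and estimated per-well
percent NETotic tracks the generator's true fraction within ~1 point
across f ∈ [0.01, 0.7].

## Screening statistics

* **Z'** = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| with sample (n−1) sds; equal
  arm means are reported as a failure, not a number.
* **Hit calling**: active = percent NETotic strictly below 50 (the ~70%
  induction plateau minus a 30%-reduction margin), strong = strictly
  below 10; replicates are averaged arithmetically before calling.
* **Dose-response**: 4PL `R(c) = bottom + (top − bottom)/(1 + (c/EC50)^h)`
  fitted by Levenberg–Marquardt on (bottom, top, log EC50, log h) from a
  7×4 grid of EC50/Hill starts; c = 0 anchors the top naturally. Exact
  4PL data are recovered to 1e-6 relative from any start. Flat data and
  top ≈ bottom fits are flagged degenerate with EC50 absent; EC50 outside
  [0.1× min positive c, 10× max c] is flagged extrapolated. Covariances
  come from the Jacobian at the optimum.
* **Kinetics**: plateau from an exponential-approach fit (fallback: mean
  of the last three samples); steady state operationalized as the first
  *sampled* time reaching 95% of the plateau; peak fold relative to the
  t0 value, or to the baseline trace's mean when a baseline is given
  (the mean is a lower-variance reference than a single noisy t0 sample).
* **Group statistics**: one-way ANOVA, then Dunnett-vs-control decisions
  with critical values from a seeded Monte Carlo of the multivariate-t
  null (10⁵ draws, cached per design); adjusted p-values from the same
  null sample agree with `scipy.stats.dunnett` to ~0.01. A per-group
  Kolmogorov–Smirnov normality check (against a normal with the group's
  moments) is reported as a warning, never used as a gate. Simulated
  Gaussian nulls give a family-wise error of ≈ 0.05 at α = 0.05.

## Problem sizes and limitations

Validation runs use desk-scale plates: 200 cells/field, 4–10 fields/well
(800–2,000 cells/well), 6–48 wells per experiment — two orders of
magnitude below a production screen but large enough that binomial
counting error (≈ 1 pct at n = 2,000, f = 0.7) is small against the
effects being measured.

What passing tests show — and do not show. The simulator produces
well-separated phenotypes with sharp-edged profiles, flat backgrounds,
and spatially uncorrelated noise. Real Hoechst images add focus drift,
illumination gradients, debris, aggregates, donor-to-donor morphology
shifts, and intermediate (non-lytic) NET stages; classifier accuracy and
segmentation scores here are upper bounds, and the classifier would need
retraining on curated labels. The lytic gate's percentile construction,
the fraction-of-peak boundary convention shared by generator and
segmenter, and the absence of plate-effect normalization (none is
applied, matching the assay's design) are deliberate scope choices.
MPO-like secondary staining is modeled only as label-proportional
intensity; no staining chemistry, 3-D stacks, optics, or cross-timepoint
tracking are modeled.
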