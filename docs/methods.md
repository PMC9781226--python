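# Methods

## The detection model

`maculoc` localizes the macular center in color fundus photographs without
any learned appearance model. It relies on three anatomical regularities:

1. the optic disc (OD) is the brightest large structure of the retina;
2. the retinal vessels entering the disc bundle on its nasal half, so the
   *temporal* side of the disc — where the macula lies — carries fewer
   vessel pixels;
3. the macular center sits about 2.5 disc diameters temporal of the OD
   center and slightly below it, and is the darkest compact region in its
   neighborhood.

The pipeline is fully deterministic: no random number generator is used
anywhere outside the synthetic-data module.

### Stage 1 — standardization and illumination flattening

Images are resized to a working height of h′ = 565 px (bilinear, aspect
preserved, width = round(565/h × w)); the scale factor is recorded so
detections can be mapped back to input coordinates. On the green channel
I the pipeline computes

    Ibt = closing(I, disk θ) − I      (bottom-hat)
    Iop = opening(I, disk σ)
    Ibg = 89×89 average filter of I
    Ic  = clip( ((I + Ibt − Ibg) + (Iop − Ibg)) / 2 , 0, 255 )

Subtracting the average-filter background removes smooth shading and
vignetting; the bottom-hat term refills dark thin structures, so vessels
vanish from Ic while the disc, being wide and bright, survives as the
dominant maximum. θ and σ default to disc elements of radius 8 at the
565-px scale — slightly wider than a major vessel, well below the disc
diameter. If the 89×89 filter exceeds a (tiny) input, it is shrunk to the
largest odd size that fits, with a warning.

### Stage 2 — optic-disc localization

Ic is binarized at 0.89 × max(Ic); the centroid of the largest
8-connected component is the coarse disc candidate (ties: brighter mean
Ic, then scan order). A (w′/4 × h′/4) region around the candidate is
cropped from the **red** channel, where the disc remains bright but
vessels are faint; it is CLAHE-enhanced, opened with a radius-8 disc to
erase residual vessels, Otsu-binarized, then regularized with a binary
closing (radius 10) and opening (radius 15). The surviving largest blob
is the disc; its centroid is the disc center. An empty mask raises a
disc-not-found error that the driver converts into a stage-attributed
failure report — bright lesions or a washed-out disc are expected causes.

The disc-diameter unit is not taken from the segmented blob (lesions and
ragged rims make that fragile) but from the field of view: the grayscale
image is Otsu-segmented against the dark surround, v′ is the width of the
largest component's bounding box, and DD = v′/12. A config switch
(`od.use_measured_dd`) selects the measured blob width instead.

### Stage 3 — temporal direction

On the green-channel crop of the disc bounding box: CLAHE → bottom-hat
with a radius-5 disc (slightly wider than a vessel) → Otsu. Horizontally
oriented vessels are then discarded — a disc criss-crossed by horizontal
branches would bias the count — by opening with a 15×1 vertical element
and consolidating with a 50×15 closing. The mask is split at its middle
column (odd widths: middle column joins the right half); the temporal
side is the one with **fewer** white pixels. An exact tie raises an
error by design: a silent guess would corrupt every downstream landmark,
so ties surface as detection failures.

### Stage 4 — macular ROI and center extraction

With direction, disc center and DD in hand, the search box is placed
purely geometrically:

    xM = xOD ± p·DD   (− toward a LEFT temporal side)
    yM = yOD + q·DD
    box = square of side r·DD centered on (xM, yM), clipped to the image

Defaults p = 3.8, q = 0.25, r = 2.0; the tuner (below) searches
p ∈ {3.6, 3.8, 4.0}, q ∈ {0.25, 0.5}, r ∈ {2.0, 2.25, 2.5}. The box
center is kept as a real number; rounding happens only at reporting.

Inside the box, the grayscale is CLAHE-enhanced and complemented
(Im = 255 − enhanced), so the dark macula becomes Im's brightest
structure. Pixels with Im ≥ 0.98 × max(Im) are kept, dilated and opened
(radius-5 discs), and the largest blob's centroid is the macular center,
reported at both working and input scale. If morphology leaves nothing,
the argmax of Im is used with a warning.

### CLAHE convention

All three CLAHE applications use clip limit 1 with 8×8 tiles. The clip
limit is expressed in multiples of the uniform histogram bin height
(1 = gentlest limit), mapped to scikit-image's normalized parameter as
`clip/256`. An unlimited-clip AHE is unusable here: it maps each tile's
darkest pixel to black, so the 0.98 × max rule on the complement would
select one stray minimum per tile instead of the macula.

### Parameter tuning

`tune_roi_parameters` evaluates the full 3×2×3 Cartesian grid of
(p, q, r) on annotated images, scoring each combination by detection
accuracy under the correctness radius; ties break by lower mean distance,
then smaller r (a smaller box is cheaper and admits fewer confounders).
The expensive front-end stages (disc, temporal direction) run once per
image and are shared across all 18 combinations.

### Evaluation

A detection is correct when its Euclidean distance to the annotated
macular center is **strictly** below 50 px, applied at original image
scale by default (`evaluation.scale` can switch to the working scale).
Failed detections count as incorrect — dropping them would inflate
accuracy. The summary carries per-image distances and (Δx, Δy) offsets
for scatter plots.

## The synthetic generator

`maculoc.synthetic` renders the anatomy the pipeline depends on, with
ground truth exact by construction. Default conditions: 768×584 images,
a circular FOV of radius 0.48 × height, a disc of true diameter
D = 0.126 × FOV width with soft radial falloff, and a macular center at
exactly 2.5 D from the disc center, with a 0.165 D inferior component.
The constant 0.126 ties the anatomy to the pipeline's unit: with
DD = v′/12, the 2.5 D offset equals 3.78 DD and the drop equals 0.25 DD,
so grid tuning on default suites recovers (p, q) = (3.8, 0.25).

The macula is a smooth Gaussian pit (scale 0.35 D) — a flat dark plateau
would be unrealistic and also defeats any local-equalization method.
Perifoveal vessel branches slightly darker than the pit (as retinal
vessels usually are) bound the fovea at 1.15 disc-diameter units on the
temporal, nasal and inferior sides: a correctly placed 2DD box excludes
them, while a shifted or oversized box admits one and the extractor locks
onto it. This reproduces the failure mode that makes ROI tuning
meaningful in the first place. Disc-convergent vessels comprise a
near-vertical trunk offset 0.22 D nasal of the disc center plus two
parabolic arcades arching temporal-ward clear of the macula, so the
nasal-half vessel excess inside the disc holds for every image (asserted
at render time). A gentle vignette and a fine choroidal texture
(σ = 4 gray levels, damped toward the fovea where luteal pigment masks
it) are always rendered: real retinas are never flat fields, and
several pipeline stages (Otsu, CLAHE) are degenerate on piecewise-
constant input.

Difficulty presets: *clean* adds nothing further; *nominal* adds a ±12
gray-level linear illumination gradient and σ = 5 sensor noise; *hard*
adds a ±28–42 gradient, σ = 10 noise, a low-contrast macula (depth 14 vs
45), three bright exudate-like lesions, and — on every third image — a
washed-out disc dimmer than the lesions, which defeats brightness-based
disc localization outright and exercises the structured failure path.
Right-lateral images are exact mirrors of the equivalent left-lateral
render, so laterality symmetry holds to the pixel. Suites derive one RNG
stream per image from (seed, index), making them reproducible and
prefix-extensible.

What the generator does **not** emulate: true vessel calibers and
branching statistics, pigmentation variation between subjects, optic-cup
structure, pathology other than bright blobs, compression artifacts, and
the appearance diversity of real cameras. Passing suites therefore
demonstrate the geometric and morphological logic of the pipeline, not
clinical performance; numbers on real datasets require real images and
their ground truth.

## Numerical choices and degenerate inputs

- Binary morphology border convention: openings treat the outside as
  background in both passes; closings dilate with background padding but
  erode with foreground padding, so structures touching the border are
  not eaten. Grayscale morphology follows scikit-image defaults.
- Largest-component ties break deterministically: larger area, then
  brighter mean intensity, then scan order.
- Otsu on a constant grid is undefined; such crops raise disc-not-found
  (OD stage) or return an empty vessel mask (temporal stage).
- The FOV fallback (segmented component under 10% of the image) uses the
  full image width for v′, with a warning.
- Detection suites in the tests use 20 clean / 40 nominal / 10 hard
  images and the acceptance script tunes on 12 clean images; these sizes
  keep the whole verification suite comfortably fast while leaving every
  accuracy margin wide (clean-suite errors average below 1 px against a
  50 px criterion).

## Known limitations

- The disc localizer is brightness-based by design; images whose
  brightest compact structure is not the disc (large exudates, severe
  flash artifacts) fail, and do so with a stage-attributed report rather
  than a wrong answer — but they still fail.
- The temporal rule assumes vessel asymmetry is visible inside the disc;
  a disc crop with no discernible vessels yields an empty mask and a tie
  error.
- The geometric placement assumes an emmetropic-scale fundus; strong
  myopic elongation changes the macula-to-disc distance and would require
  retuning p.
- The q offset is always applied downward; anatomy-adjusted vertical
  placement per laterality is not modeled, matching the placement rule as
  published.
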