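# Methods

`woundkit` quantifies wound-scratch (wound-healing) assays from
label-free time-lapse microscopy: a confluent monolayer is mechanically
scratched, and the closure of the resulting cell-free gap over time
measures collective cell motility.  The package covers the full chain —
image enhancement, gap segmentation, closure kinetics, and
treatment-versus-control statistics — plus a seeded synthetic generator
that provides ground-truthed benchmarks for every stage.

## Image enhancement

Transmitted-light frames have low contrast between the monolayer and the
gap; what reliably distinguishes them is *texture*.  The enhancement
chain turns a raw frame into a fluorescence-like image (cells bright,
gap dark) in five deterministic stages:

1. **Powering** — intensities are normalized by bit depth and raised to
   `power_exponent` (default 2).  The map is monotone; exponents above 1
   darken the dim background relative to bright cell halos.
2. **Flat-field correction** — a difference of Gaussians,
   `G(img, sigma2) − G(img, sigma1)` with `sigma1 = 2`, `sigma2 = 1` px,
   shifted to mid-gray (`0.5 + dog/2`).  Slowly varying illumination
   (length scale much larger than `sigma1`) maps to a flat 0.5.
3. **Local entropy** — per-pixel Shannon entropy of a disk(4)
   neighborhood after quantizing to 32 gray levels, rescaled by the
   `log2(32)` bound.  Textured cell regions map high; the smooth gap
   maps near zero.  The quantizer is offset by half a bin so a bin is
   *centred* on mid-gray: the flat-field stage maps featureless
   background exactly to 0.5, and without the offset sensor noise would
   dither between two adjacent codes and fake one bit of entropy in
   perfectly smooth regions.
4. **White top-hat** — image minus its opening with disk(25); removes
   bright structures wider than roughly two cell diameters (illumination
   remnants, large plateaus) while keeping cell-scale texture peaks.
   The radius approximates one mammalian cell diameter at 10x.
5. **Averaging** — a 3x3 uniform mean suppresses dust and debris specks.

All filters use reflect padding so the image border is not misread as a
dark gap.  The chain is fully deterministic: identical input and
parameters give bit-identical output.

A note on illumination invariance: stages 2–5 are exactly invariant to
an *additive* linear ramp in the interior (a Gaussian filter preserves
linear functions away from borders, so the DoG removes them).  With the
default `power_exponent = 2` the ramp becomes weakly multiplicative
before stage 2, so invariance is approximate; the test suite checks the
exact property at exponent 1 and a segmentation-level robustness bound
(contrast preserved under a 10% ramp) at the default.

## Gap segmentation

The enhanced image is thresholded at `mean(img) / T`, where the
**T coefficient** is the single tunable parameter of the tool: 3.14 for
16-bit cameras, 2.2 for 8-bit, lowered to 2.2 / 1.2 for low-contrast
lines with thin lamellae (3T3, primary fibroblasts).  Pixels *below*
threshold are candidate gap.

The scratch assay guarantees an empty cleft near the middle of the
field, which is used to validate the candidate mask: after contour
smoothing (binary closing, dilation, closing, erosion with a disk(2) —
minimal radius, sealing thin isthmuses without degrading the contour), a
connected component must have at least `min_area_px` pixels (default ~50
cell cross-sections, i.e. `50 * tophat_radius^2`) and a centroid in the
middle third of both axes.  If the check fails the threshold is
multiplied by 0.85 and the detection repeated, up to 5 times; lowering
the threshold peels spuriously merged monolayer out of an
over-segmented candidate.  If all retries fail an *empty* mask is
returned and still written to disk — a fully closed wound is a valid
outcome, never an error.

On success the largest qualifying central component becomes the gap.
Holes inside it — detached "pioneer" cells that wander into the wound —
are filled by default, so their footprint counts toward the gap area
(`fill_holes=False` disables this).  The component's closed pixel
contour is traced (the mask is padded before tracing so contours stay
closed when the gap touches the image border).  Components use
8-connectivity throughout.

## Closure kinetics

Per-frame gap areas (converted to um^2 by the squared pixel size) are
expressed as absolute area displacements against the first post-scratch
frame, `DT = |T0 − Tn|`, then low-pass filtered with a trailing moving
average of `N = 6` frames — one hour of smoothing at the default 10-min
sampling.  The trailing (causal) form delays a linear trend without
changing its slope.

Edge displacement is `d(t) = DT(t) / (2 L)`: dividing by the wound
length `L` converts area rate to front speed, and by 2 because both
edges advance.  `L` is measured once, on the first frame's mask, and
reused: the scratch length is fixed while the gap narrows.  When the gap
touches one pair of opposite image borders (the normal case — a scratch
runs border to border), `L` is the border-to-border chord along the
scratch axis, with the axis direction taken from a least-squares fit of
the gap midline.  Covariance principal axes are *not* used in this case:
a shrunken band can be nearly square, where the eigenvectors become
degenerate and drift toward the diagonal.  For an enclosed gap (no
border contact) the major covariance axis is used.

**Window fitting.**  Closure is non-linear overall but near-linear in a
mid-phase window; the edge velocity is the OLS slope of `d(t)` over a
stated window (default 5–11 h), reported with r^2, the slope's standard
error and 95% CI.  `find_linear_window` searches windows `[a, a + span]`
on a 0.5-h grid within 0–12 h, longest span first and earliest start
first, returning the first window with `r^2 >= 0.985`; if none
qualifies, the best-r^2 window is returned flagged sub-threshold.  The
12-h horizon reflects two empirical constraints: pioneer-cell events
multiply after ~6–12 h, and edge morphology degrades later, both of
which erode segmentation accuracy.

## Treatment comparison

Per-condition replicate velocities are summarized as mean ± SEM and
compared as ratios, `100 * v_treated / v_control` (values below 100 =
slowdown; negative values = edge retraction).  Significance comes from
standard two-sample routines (Welch's t by default; pooled-t and
Mann-Whitney selectable) at alpha = 0.05, with the usual star marks
(* p<0.05, ** p<0.01, ns).  Dose–response tables sort ascending by dose
and impose no monotonicity — motility dose responses are frequently
non-monotonic.  IC50 fitting is deliberately omitted.

## Synthetic data generator

The generator emulates the features the pipeline keys on, each with a
knob:

- **Scene** — a textured monolayer split by a smooth band-shaped gap.
  Cell texture is band-pass filtered noise (1.6–5.2 um scales) whose
  local amplitude is modulated at the cell scale (13 um): contrast in
  transmitted light concentrates at cell boundaries while interiors are
  smoother, and that patchiness is exactly what the top-hat opening
  keys on.  The modulation floor keeps every monolayer patch visibly
  textured — bare-substrate smoothness only occurs inside the wound.
- **Dynamics** — each edge advances by `d(t)` from a linear law
  (constant `edge_speed_um_per_h`) or a logistic law (sigmoid
  displacement, peak speed `v_max` at `t_mid`).  Edges carry a zero-mean
  jaggedness profile (Gaussian process along the scratch, 30-um
  correlation length, amplitude `edge_roughness_um`).
- **Temporal decorrelation** — texture and roughness evolve as
  stationary AR(1)/Ornstein-Uhlenbeck processes (correlation times 0.5 h
  and 1 h).  Frozen noise fields would be unrealistic — real monolayers
  rearrange continuously — and, importantly, frozen boundary errors act
  as spurious slope trends in window fits.
- **Nuisances** — a linear illumination ramp (`illumination_gradient_pct`
  of dynamic range), additive Gaussian sensor noise, dark debris specks,
  and pioneer cells: textured blobs that appear inside the gap after 6 h
  at `pioneer_rate_per_h` (Poisson).  Ground-truth masks keep counting
  the full band as gap where pioneers sit, mirroring how the
  segmentation's hole-filling treats them.

Identical configs (seed included) produce bit-identical sequences.
Ground-truth band area matches the analytic `width x length` product to
one-pixel-per-boundary-row rounding.

**Geometry defaults** are taken from the optics of a 10x objective with
a 6.5-um sCMOS camera: presets use 1.3 um/px (2x2 binning) with a
500-um scratch in a ~1000-um-wide field; the velocity-recovery preset
uses 2.6 um/px with a 700-um scratch (so a 25 um/h front has not closed
by hour 11) and the full 1331-um field height, which averages the jagged
boundary over the realistic extent.

**Presets.**  `linear-easy` (15 um/h, mild nuisances), `decelerating`
(logistic, `v_max = 22` um/h, `t_mid = 7.5` h, steepness 0.85 /h), and
`hard` (15 um/h plus 10% illumination gradient, stronger noise and
roughness, pioneers at 1.5 /h, 25 debris specks).  The logistic
parameters were chosen by construction so that the noiseless
displacement is near-linear (r^2 >= 0.985) only on late (start >= 4 h,
span >= 6 h) windows while the full 0–12 h fit stays clearly below
threshold — the sigmoid-closure structure the window search is meant to
resolve; a parameter scan showed this choice is stable under the
generator's noise (30/30 seeds).

What the generator does *not* emulate: phase-contrast optics (halos,
defocus), cell division and mitotic rounding, directed single-cell
motion, and gradual edge-morphology changes late in closure.  Passing
benchmarks therefore demonstrate the pipeline's correctness and noise
behavior on data with the assumed statistical structure, not performance
on any particular instrument's images.

## Validation studies and their sizes

The `benchmark` module defines the studies the test suite and
`scripts/acceptance.py` run; sizes are package choices balancing
statistical resolution against runtime:

- *Segmentation accuracy*: 50 frames x 5 seeds for each of
  `linear-easy` and `decelerating` (mean area error vs ground truth,
  and detection rate, where a frame counts as detected when mask/truth
  IoU >= 0.5, or both are empty); the same for `hard` (detection only
  is asserted).
- *Velocity recovery*: 7 seeded runs at each of 5, 15, 25 um/h through
  the full render-segment-fit chain, scored by the 5–11 h window slope.
- *Window discovery*: one full sequence each of `decelerating` and
  `linear-easy`.
- *Sensitivity*: 50 repetitions of a two-arm study (12 positions per
  arm, control 15 um/h, treated 15% slower, between-position velocity
  CV 10% — the low end of observed replicate spreads) using the fast
  series-level simulator; power is the fraction of repetitions with
  Welch p < 0.05.
- *Determinism*: one small library segmented and analyzed twice;
  outputs compared byte for byte.

## Numerical choices and degenerate inputs

- Thresholding uses strict `<`; an all-equal image yields an empty
  candidate and, after retries, an empty mask.
- r^2 of a zero-variance displacement series is defined as 1.0 (a flat
  line fits it perfectly) rather than NaN.
- `area_error_pct` with an empty reference returns 0 if the mask is
  also empty, +inf otherwise; IoU of two empty masks is 1.0.
- Window selection ties break toward the earliest start; window bounds
  are closed with a 1e-9 tolerance on the time grid.
- Frames are ordered by the last integer in the filename (natural
  sort), tolerating both zero-padded and plain counters.
- RGB inputs collapse to Rec. 601 luminance; multi-page TIFFs use the
  first plane with a warning.

## Known limitations

- The T-coefficient mechanism assumes a bimodal enhanced histogram; on
  fields with almost no gap (or almost no monolayer) the mean-referenced
  threshold drifts, which is why analysis is confined to the first 12 h.
- Wound length from the first frame assumes the scratch spans the field
  border to border; heavily curved scratches would need a per-frame
  length model.
- The retry schedule only lowers the threshold; a candidate that is
  *under*-segmented from the start (no pixels below threshold at all)
  is reported as closed rather than rescued.
- Velocities below ~5 um/h approach the noise floor of single-position
  window fits; replicate averaging (as in the sensitivity study) is the
  intended way to resolve small effects.
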