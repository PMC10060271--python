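# Methods

This note documents the models behind `orgscreen`: the synthetic plate
simulator, the two segmentation backends, tracking and well metrics, and
the dose-response statistics, together with the numerical choices and the
limits of what the synthetic validation can show.

## Synthetic plate model

The simulator is the package's source of ground truth. Each well holds a
population of organoids represented as disks in a 2-D projection of the
well bottom; a frame is rendered every `dt_h` hours (default 6 h) for
`n_timepoints` frames (default 9, i.e. a 48 h horizon).

**Geometry and seeding.** The rendered field is a 256 px square at
4 µm/px (~1 mm), a down-scaled view of a 384-well; the default
`seeding_density` of 15 organoids per field keeps object densities
realistic for that area while staying cheap to render. Initial areas are
log-normal around `init_area_um2` = 3000 µm² (≈ 60 µm diameter) with 35 %
CV. Placement is rejection-sampled to be non-overlapping with an edge
margin of twice the initial radius, so organoids that double in radius
over the run still stay inside the field — whole-well imaging rarely
truncates objects, and truth areas are analytic, so clipping would bias
measured fold changes.

**Growth.** Untreated organoid area grows exponentially at
`growth_rate_h` (default ln 2 / 24 h⁻¹: doubling per day). When a well's
object count exceeds `density_slowdown_threshold` the rate is multiplied
by `density_slowdown_factor` (default 0.5), a deliberately simple stand-in
for the crowding-driven slowdown seen at high seeding densities.

**Fusion.** After each growth step, organoids whose disks share any pixel
are merged (union-find): areas sum, the centroid is area-weighted, the
lowest id survives and the `parent_ids` of the merged record list all
contributors. This reproduces the characteristic drop of per-well counts
over time while total area is conserved; counts are therefore
non-increasing after placement.

**Drug effects.** A treated well applies the Hill response
`E(c) = c^h / (c^h + EC50^h)`.

* *Cytostatic* drugs multiply the growth rate by `1 − E(c)` and kill
  nothing.
* *Cytotoxic* drugs follow fractional-kill kinetics: the dose determines
  which fraction of each organoid is killable — the floor of its alive
  fraction is `1 − max_kill_fraction·E(c)` — and the alive fraction decays
  toward that floor at rate `kill_rate_h·E(c)`. Surviving cells grow
  normally while the dead compartment is frozen, so the alive fraction is
  recomputed after each growth step. This choice makes the endpoint
  viable-area fold change approximately affine in E(c): a titration read
  out at 48 h has its half-effect near the generative EC50 (recovered
  IC50 ≈ 0.7× EC50 across seeds; the residual shift is the honest
  consequence of survivor regrowth). A pure "decay toward zero at rate
  ∝ E(c)" model was rejected because the exponential compounding over the
  horizon displaces the apparent IC50 about an order of magnitude below
  the generative EC50, divorcing the simulator's nominal potency from
  every downstream readout.
* The *positive control* (maximal-kill well, e.g. a high-dose
  staurosporine analog) acts at E = 1 with `control_kill_rate_h` = 0.15 h⁻¹,
  reaching an alive fraction ≈ 0 within the default horizon.

**Matched titrations.** All wells of one (drug, replicate) share the same
initial population seed, so differences across a titration isolate the
dose effect — a paired design. This makes the final-viable-area
monotonicity in concentration exact rather than statistical. Controls are
seeded per role and replicate.

**Rendering.** Brightfield: background 0.55; solid organoids are dark
(0.30) textured disks; cystic organoids dark annuli (rim ≈ 22 % of the
radius) with a bright lumen (0.72). Blue (nuclear) channel: signal over
the full object for solid organoids, rim-only for cystic ones — nuclear
dyes only stain the cell layer, so the cystic lumen is blue-negative.
Green (death) channel: a concentric core of area `dead_fraction × area`,
growing from the organoid interior (the spatial pattern of death is not
constrained by data; a compact core is the simplest choice consistent
with "dead area inside the object"). Air bubbles (bright rings) and
debris (small dark specks) are added at Poisson rates per well, placed
off-organoid, and excluded from the truth mask. All channels receive a
smooth multiplicative illumination gradient (±8 %) and Gaussian read
noise (SD 0.02). Identical seeds give bit-identical truth tables and
rendered stacks.

**What the simulator does not emulate:** optics (defocus, PSF), 3-D
structure and z-projection artifacts, organoid migration, irregular
non-circular morphologies, matrix-dome geometry, and instrument-specific
texture statistics. Renderer contrast is tuned only to make segmentation
non-trivial, not to match any instrument; passing tests therefore
demonstrate correctness of the analysis chain, not segmentation
performance on real microscopes.

## Segmentation

**Classical chain** (deterministic, parameter-light): subtract a
large-scale Gaussian background (`background_sigma` = 25 px), form the
response `max(background − image, 0) + 0.5·|∇image|`, threshold at
`max(Otsu, min_contrast = 0.05)`, close with a radius-3 disk, fill holes
(this pulls the bright cystic lumen into the object, so brightfield areas
mean whole-object areas), label connected components and drop objects
under `min_object_area_px` = 50 px (which removes debris specks; bright
bubble rings never enter the darkness response). Edge-touching objects
are kept and flagged. Optional watershed splitting of touching objects
exists but is off by default: organoids that fused in culture are
intentionally counted as one object.

**Fluorescence-derived ground truth**: Otsu threshold of the blue channel,
union with green-positive regions (dead nuclei remain part of the
object), a radius-4 closing to bridge the cystic rim, hole fill, then the
common post-processing. These masks supervise the trainable path.

**Trainable path**: a two-scale fully convolutional encoder–decoder
(conv3×3 → maxpool → conv3×3 → nearest-neighbor upsample → skip
concatenation → conv3×3 → conv1×1, 8/16 channels, ~3k parameters)
implemented directly on NumPy with im2col convolutions and explicit
backprop. Per-image standardized brightfield in, per-pixel sigmoid
foreground probability out. Training uses binary cross-entropy with the
positive class up-weighted by the background/foreground ratio (capped at
10) — organoids cover a few percent of a well, and unweighted training
stalls near the all-background solution — optimized with Adam
(lr 0.01, batch 8). Training is bit-deterministic given the seed. The
probability map is thresholded at 0.5 and passed through the same
post-processing as the classical path. Fifty training pairs and ten
epochs reach a held-out foreground IoU well above the 0.6 floor on
simulator renders.

## Tracking and well metrics

Tracking is greedy maximal-pixel-overlap between consecutive frames (ties
break to the larger predecessor, then the lower label). No motion model:
embedded organoids are near-static. Two or more predecessors mapping onto
one successor record a merge event; unmatched objects record
appearance/disappearance. On simulator truth masks, merge events
correspond one-to-one to scheduled fusions and the per-frame counts equal
the truth counts.

Well metrics follow the definitions in the README. Green-positive pixels
are those above an absolute intensity cut (0.3) inside the mask; green
intensity is background-subtracted with the median of out-of-mask pixels
(the correction used by the instrument is unknown; the median is robust
to the small organoid fraction). Ratios with empty-well denominators are
flagged `undefined`, never silently zeroed, and downstream fits drop
flagged points.

## Dose-response statistics

* **Fold-change basis.** All GR/NDR computations and the pipeline's 4PL
  fits operate on per-well fold changes from T0 (the intra-well
  normalization), not raw endpoint areas: fold changes cancel per-well
  seeding differences, which otherwise dominate cross-well variance.
  Replicate control fold changes are pooled by geometric mean (fold
  changes are ratios).
* **4PL fitting**: `scipy.optimize.least_squares` with five data-driven
  starts (top/bottom from the response range, midpoints from the
  concentration quartiles, both hill signs), tolerances 1e-8, slope
  unconstrained; requires ≥ 5 distinct concentrations so residual df ≥ 1.
  Flat curves are returned flagged degenerate rather than fitted. Fits
  are reported in the canonical orientation top ≥ bottom.
* **Extra sum-of-squares F test**: the null model shares one log IC50
  across both datasets (top/bottom/hill per dataset, 7 parameters), the
  alternative fits 8; `F = ((RSS_sh − RSS_sep)/(df_sh − df_sep)) /
  (RSS_sep/df_sep)` with the p-value from F(1, df_sep). The shared RSS is
  clamped to be ≥ the separate RSS (a nested model cannot beat the full
  model; the clamp absorbs optimizer jitter). Type-I error at α = 0.05 is
  calibrated to ~5 % under a simulated null.
* **NDR algebra.** The anchors (1 = control-matched growth, 0 = arrest,
  −1 = control-matched killing, > 1 proliferative) do not pin down one
  formula. The implementation uses the piecewise log2 form: with
  f = log2 FC, `ndr = f_t/f_v` for f_t ≥ 0 and `ndr = f_t/|f_p|` for
  f_t < 0. It satisfies every anchor exactly, is strictly increasing in
  the treated fold change, and is isolated behind `ndr_metric` so an
  alternative parameterization can be swapped in without interface
  changes.
* **Classification** bands: within ±0.05 of 1 → normal; ±0.05 of 0 →
  complete growth inhibition; > 1 proliferative; (0, 1) cytostatic;
  < 0 cytotoxic.
* **Z-factor** uses sample SDs (ddof = 1); the score is invariant to the
  unit of the control readout.

## Problem sizes

The validation suite runs deliberately small configurations: 96–256 px
fields, 4–15 organoids per well, 2–9 frames, 50 training pairs / 10
epochs for the network, 100 noise seeds for 4PL recovery and 500
replicates for F-test calibration. These sizes were chosen as the
smallest at which each property is meaningfully exercised; all scale
linearly if enlarged.

## Known limitations

* The classical backend assumes organoids darker than a smooth
  background; strongly textured matrices or phase-contrast-like halos
  would need a different response function.
* The trainable network is intentionally small and single-channel; it is
  a methodological demonstration of fluorescence-supervised brightfield
  segmentation, not a state-of-the-art segmenter.
* Tracking has no motion model and no split events; it would mis-link
  rapidly migrating or dividing objects.
* GR/NDR are evaluated at a caller-chosen endpoint frame (default: last).
  Time-integrated variants are not implemented.
* The simulator's truth "areas" are analytic disk areas; rasterization
  introduces up to ~1 px-boundary discrepancy, which is why area
  comparisons in the validation suite use relative tolerances.
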