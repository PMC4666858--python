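# Methods

## The measurement

`fiberratio` quantifies how strongly a fluorescently labelled cellulase (or
an isolated carbohydrate-binding module) binds to *dislocations* — localized
misaligned regions in a plant fiber's cell wall — relative to the
surrounding normal wall, from confocal laser scanning microscopy (CLSM)
z-stacks.

A fiber is imaged as an *image cube*: a stack of optical slices with known
pixel size and slice spacing. In the image plane, three rectangular ROIs
are placed on dislocations, three on normal cell wall, and up to three on
bulk solution, plus one on the lumen. For each retained slice of interest
(SOI) the per-slice ratio

    r_k = mean(3 dislocation-ROI means) / mean(3 wall-ROI means)

is computed, and the per-fiber statistic is

    R = (1/K) Σ_k r_k .

R > 1 means preferential binding to dislocations. Ratioing *within* a slice
makes R invariant to everything that multiplies both compartments equally —
degree of fluorophore labelling, slice thickness, detector gain — which is
why R values from different images are comparable although absolute CLSM
intensities are not.

**Order of operations.** Averaging per-slice ratios (rather than pooling
all emissions over the SOIs and ratioing once) tolerates depth-dependent
attenuation of the emission by absorption and scattering through the cell
wall: any per-slice multiplicative factor cancels inside each r_k. The
pooled alternative is implemented behind `fiber_R(..., pool_across_sois=True)`
for comparison studies only; the two orders coincide exactly when the
per-slice compartment means are depth-constant (tested).

**ROI means.** The triplicate is averaged as a mean of ROI means, not a
pooled-pixel mean: each chosen *position* carries equal weight regardless of
rectangle area. The difference matters only for unequal ROI sizes and is
exercised in the tests.

## SOI selection

Slices showing the fiber surface are excluded (surface-bound enzyme and
fines dominate there and would contaminate the ratio), and only slices
containing the lumen are kept — there the fiber is at or near its widest,
so laterally placed ROIs stay within the S2 wall. The manual judgement is
automated with three per-slice threshold rules against the *wall plateau*
(median of the mean wall-ROI profile over the middle third of slices):

| rule | condition for keeping slice k | default |
|---|---|---|
| surface exclusion | wall mean(k) ≤ `surface_factor` × plateau | 1.5 |
| lumen presence | lumen mean(k) < `lumen_factor` × plateau | 0.5 |
| fiber presence | wall mean(k) ≥ `presence_factor` × plateau | 0.5 |

The fiber-presence rule is needed because slices above or below the fiber
see only dim bulk solution in *both* the wall and lumen ROIs and would
otherwise pass the first two rules. The lumen threshold is a reconstruction
of a qualitative manual criterion ("slice contains lumen"); with enzyme
penetrating into the lumen the dark-lumen assumption weakens, which is why
the factor is configurable and every exclusion is recorded in a rule trace
(logged at INFO). A manual slice list bypasses the rules entirely. A fiber
whose every slice is rejected raises a "no usable SOI" error and is dropped
by the pipeline with a recorded reason — screening is part of the method.

With the default geometry (24 µm fiber, 8 µm lumen, 15 slices at 2 µm, the
equator falling between two slice planes) the rules retain the 4 slices
whose planes cross the lumen, consistent with the 4–6 SOIs typical of this
kind of acquisition.

## Background-zero sensitivity

R uses raw emission values; no background is subtracted. The one systematic
that does not cancel in the ratio is a shift of the intensity zero (e.g.
after instrument adjustments). With wall emission normalized to 1 and a
downward shift by a fraction β of it, a true ratio R is measured as

    R' = (R − β) / (1 − β),        0 ≤ β < 1.

The relative disparity 100·(R'−R)/R is 0 at R = 1 for every β, grows with
both R and β, and reaches ≈21.4 % at R = 2, β = 0.30. Ratios at or below 2
therefore tolerate a ~30 % baseline drift before the disparity exceeds
~21 %. β is defined as a fraction of the wall emission (not of the dynamic
range) — the reading under which the closed form reproduces that bound.

## Group statistics

Per-fiber R values are individual datapoints. Per treatment arm, suspected
outliers are flagged by Tukey fences at 1.5 × IQR with inclusive-median
(hinge) quartiles; flagging and removal are separate explicit steps, and
manual flag lists are accepted. Washed and unwashed arms of the same
protein are pooled when a pooled-variance two-sample test at α = 0.05 finds
no difference (run after outlier removal by default); otherwise pooling is
refused and the refusal carries the full test. Group comparisons use the
pooled-variance two-sample t-test:

    s²  = (SS₁ + SS₂) / (n₁ + n₂ − 2)
    SEM = √(s² (1/n₁ + 1/n₂))
    CI  = (x̄₁ − x̄₂) ± t₀.₀₂₅,df · SEM

with significance declared iff the 95 % CI excludes 0 (equivalent to
|t| > t_crit; the equivalence is property-tested). Zero pooled variance
yields a zero-width CI: not significant when the means agree, significant
when they differ (degenerate but well-defined). No multiple-testing
correction is applied across protein panels, and no nonparametric
alternative is offered. The standard error of a single group mean
(`sem_of_mean`, sd/√n — the error bar on a group mean) is deliberately a
different function from the SEM of a difference above.

## The synthetic-data generator

Because the original microscope data are not deposited, every downstream
stage is validated against simulated fibers with voxel ground truth.

**Geometry.** A latewood-like fiber lies horizontally: a cylinder of outer
diameter 24 µm with an 8 µm lumen, axis along the image x-direction,
centered at mid-height and mid-depth of a 36 µm-tall field scanned by 15
slices at 2 µm (slice planes at k·2 µm, equator at 15 µm, so the lumen
crosses the four planes nearest the equator). Dislocations are axial slabs
perpendicular to the fiber axis (default two bands, 6 µm wide) covering a
configurable fraction ≥ 0.5 of the cross-section — large dislocations
extend at least halfway, often all the way, across a fiber; the default is
full coverage.

**Emission model.** Noise-free emission density: `background_level`
(default 0.05) in bulk solution, 0 in the lumen, 1 in normal wall,
`rho_true` in dislocations, `surface_enrichment_factor` (default 4) in a
1 µm layer at the outer surface — enzyme concentrates within ~1 µm of the
fiber surface, which is exactly why surface slices are excluded. The
enrichment factor is not quantified by the imaging study this emulates;
the default is configurable and recorded in output metadata.

**Optics and noise.** The density is blurred with a separable Gaussian
whose FWHMs default to the optics module's outputs (269 nm lateral, 736 nm
axial for 633 nm excitation, NA 1.2, water immersion) — a practical stand-in
for a physical PSF at matching resolution. Detection is Poisson photon
counting at `photon_scale` (default 200 expected photons per wall voxel)
plus zero-mean Gaussian read noise (sd 1), clipped at 0; no saturation is
modelled. Identical (geometry, acquisition, ρ, seed) reproduce a stack
bit-for-bit; cohorts spawn per-fiber seeds from the master seed via
`numpy.random.SeedSequence`.

**ROI auto-placement.** Rectangles (default 9×9 px) are placed greedily
inside the intersection of each compartment's mask over the lumen-crossing
slices, after eroding the wall/dislocation/bulk footprints by roughly one
lateral FWHM so that PSF bleed across compartment boundaries does not bias
the ROI means (without the margin, recovered R is biased low by a few
tenths of a percent; with it, recovery is unbiased to <0.02 % over
100-fiber cohorts at ρ = 1 and ρ = 2, by the mask-oracle check in the
tests). The lumen ROI, used only as a darkness indicator, is not eroded.

**What the simulator does not emulate.** Real fibers vary in diameter,
wall thickness and dislocation shape; real cohorts carry fiber-to-fiber
biological variability far exceeding photon noise (published between-fiber
SEMs are ~0.26 at n≈28, against ~0.001 here); dislocations are irregular,
not rectangular slabs; attenuation with depth, refractive-index mismatch
and detector nonlinearity are absent. Passing recovery tests therefore
shows the *pipeline* is unbiased and correctly ordered, not that real
fibers behave this simply. One visible artifact: with near-zero spread,
Tukey fences can flag perfectly ordinary values as "outliers" (spread is
photon-limited), which real, more variable data would not show.

## Problem sizes and numerical choices

Simulation-backed tests use 232 nm or 464 nm pixels (the coarser end of
realistic rasters) with the full 15-slice geometry: a 232 nm cohort of 12
fibers simulates and measures in under a second, which lets the suite run
replicate-level checks (100 two-group cohorts for the power check, 20
replicate stacks for the noise-bias check, 2000 draw-level replicates for
the type-I calibration) while the full-resolution 116 nm default is
exercised in the SOI-count and recovery-bias tests. Parameter recovery is
judged against the Student-t 99 % Monte-Carlo interval (df = n−1), the
correct interval when the variance is estimated from the same cohort.
Ratios guard against degenerate denominators at 10⁻⁹ of the stack maximum.
ROI rectangles are half-open, 0-based, minimum 3×3 px. All intensities are
promoted to float64 internally; stacks are stored as float32 TIFF pages
with calibration in a JSON sidecar (never only in TIFF tags), and readers
are strict — missing calibration is an immediate, named error.

## Known limitations

- The SOI lumen rule is a reconstruction of a qualitative criterion; for
  fibers with heavy enzyme penetration into the lumen, the automated rule
  may need a looser `lumen_factor` or a manual slice list.
- The Tukey outlier rule is a stated default where the original practice
  was unformalized eyeballing; manual flag lists reproduce that workflow.
- The axial resolution and lateral resolution constants (0.88, 0.51) are
  the confocal FWHM conventions that reproduce the documented 740/270 nm
  values; other conventions (Rayleigh, 1 AU pinhole variants) differ by
  tens of nm.
- The simulator's dislocation/wall contrast is depth-uniform inside the
  wall; depth-dependent attenuation is exactly what the per-SOI averaging
  order is designed to tolerate, but it is not simulated.
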