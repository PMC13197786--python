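# Methods

This note documents the models, numerical choices and known limitations
of `rnadyn`, in the order the pipeline runs.

## Coordinate and calibration conventions

Pixels use 0-based indices with pixel centers at integer coordinates and
the origin at the top-left; a physical position in micrometres is
`index × pixel_size_um`. The default pixel size is 0.0433 µm/px (a
6.5-µm camera pixel behind 150× magnification); it is configuration, not
a constant, because different microscopes differ. Times are seconds
internally and minutes in all reported kinetic quantities; for bursting
experiments frame 0 is the stimulation time.

## Synthetic-data generators

Every pipeline input can be generated with recorded ground truth. The
generators are deterministic given their seed and are first-class,
tested code: each downstream stage is validated by recovering the
generative parameters.

**Motion.** Four trajectory classes at fast (30-ms default) frames:
stationary (localization noise only), diffusive (2D Brownian increments
with per-axis variance 2·D·Δt), corralled (Brownian steps radially
reflected at a circular boundary — the standard confinement surrogate,
chosen because the classification rules only see the MSD shape, not the
microscopic confinement mechanism), and directed (Brownian plus a
constant-speed drift with a direction drawn uniformly once per
trajectory, matching the "unidirectional" notion the classifier tests).
Isotropic Gaussian localization noise (default σ = 30 nm) is added to
every point.

**Telegraph transcription sites.** Exact event-driven two-state
simulation: ON and OFF dwells are drawn from exponentials in continuous
time, so dwell distributions are exactly exponential *before* frame
discretization — any bias seen after segmentation is attributable to the
inference, not the generator. While ON, nascent transcripts initiate as
a Poisson process (default 40 min⁻¹) and each remains fluorescent for
`site_dwell_min` (default 0.5 min: with the stem-loop array in the
3′UTR, a transcript becomes fluorescent only near the end of elongation,
so its bright residence at the site is short). Sampled intensity is
`background + unit_intensity × nascent_count + N(0, noise_sd)` per
frame. Defaults (unit 10, background 200, noise 20) put the mean ON
plateau at ≈ 2× background, i.e. the standard 1.5×-background threshold
sits at half the burst amplitude with ≈ 5σ margins on both sides; the
per-frame misclassification probability is then below ~0.5%, which is
what "detectable contrast" has to mean for threshold segmentation to be
meaningful at all. Observation starts in the OFF state (sites are
quiescent before stimulation); the first and last generative intervals
are marked censored.

**smFISH fields.** Each cell is a circular nucleus (radius 5 µm) inside
an annular cytoplasm (outer radius 10 µm). Channel-A spot counts are
Poisson per compartment (defaults 20 nuclear / 40 cytoplasmic),
positions uniform; each A spot independently receives a channel-B
partner with probability `tagging_fraction`, displaced by an isotropic
Gaussian offset; channel-B distractors are a spatial Poisson process
over the cell disk. The chance-colocalization rate therefore follows
the closed form 1 − exp(−ρπr²), which the tests verify.

**Spot movies.** Emitters render as integrated 2D Gaussians (error
functions over unit pixels), then Poisson shot noise on signal plus
background and additive Gaussian read noise. Default optics: PSF σ =
1.5 px, background 100 photons, read noise 2. For bursting movies the
per-transcript amplitude default is 320 photons/frame (≈ 24 GFPs × ~10²
detected photons/s × 150-ms exposure), which reproduces the ≈ 2×
background aperture contrast of the trace generator.

**Decay.** Replicate values are exp(−ln2·t/t½) times mean-one lognormal
noise with a given CV; a companion generator emits qPCR Ct tables in
which ΔCt = const − log₂(expression), so the ΔΔCt stage is exercised
end-to-end.

What the generators deliberately do not model: 3D PSFs, photobleaching
of single fluorophores, camera-specific noise calibration, cell
movement, and spatially varying background. Passing recovery tests
therefore demonstrates correctness of the inference chain under the
stated statistical assumptions, not robustness to every real-microscope
artefact.

## Detection

Candidates are local maxima of the normalized cross-correlation between
the frame and a Gaussian template (σ configurable, default 1.5 px),
above a threshold (default 0.5) with non-maximum suppression within 2σ;
ties break by higher score then lexicographic (y, x), so detection is
deterministic. Refinement fits amplitude, subpixel centre, width and
offset in a 7×7 window by Poisson maximum likelihood seeded from a
least-squares fit; fits that leave the window, fail to converge or have
non-positive amplitude are discarded. At SNR 10 the localization RMSE
is ≈ 0.07 px, comfortably below the 0.15-px budget the tests assert.
For z-stacks, detections chain across adjacent slices within a 2-px
lateral radius (the spec of "nearly identical positions" left the radius
open); chains spanning ≥ 3 consecutive slices collapse to the brightest
slice's localization (best focus). Bleach correction divides each frame
by a mono-exponential fit to the frame-mean series renormalized to frame
0; background subtraction removes a boxcar-smoothed (default 25 px ≫
PSF) per-frame background floored at zero.

## Tracking

Greedy ascending-distance one-to-one assignment, gated at
`25 px × pixel size` per elapsed frame; a link across g skipped frames
is allowed for g < 3 with the gate scaled by (g+1). Greedy rather than
globally optimal assignment is deterministic and adequate at the sparse
densities single-molecule imaging requires; ties break lexicographically.
Closed gaps are filled by linear interpolation and flagged; interpolated
points are excluded from MSD displacement pairs by default because they
are not measurements (an option includes them). Tracks need ≥ 14 points
(inclusive) to be analysed.

## Diffusion and motion classification

The time-averaged MSD uses all ordered pairs (i, i+n); the per-lag
standard error is the standard deviation of pair values over √(number of
pairs) — an underestimate at long lags where pairs overlap, which is one
reason the fit window stays at short lags. D comes from a weighted
(1/se²) linear fit of MSD against lag time at lags 2–4Δt, D = slope/4,
intercept free; zero standard errors receive the largest finite weight
so noise-free profiles reduce to ordinary least squares. On simulated
free diffusion the fitted intercept converges to 4σ², the static
localization-error offset, which the tests check.

Classification applies four rules with precedence stationary → directed
→ corralled → diffusive:

- **stationary** if the maximum MSD over lags 1–4Δt is below 0.025 µm²
  (the maximum makes the rule strictest; the lag at which to apply the
  published threshold was left open);
- **directed** if the net start-to-end displacement exceeds 1.5 µm *and*
  the mean turning-angle cosine exceeds 0.2. A pure positivity test on
  the persistence is a coin flip for any diffusive excursion whose net
  displacement happens to be large; 0.2 is ≈ 2 SD above zero for tracks
  of ≥ 25 steps and is what "unidirectional" has to mean operationally;
- **corralled** if the MSD slope over lags 5–7Δt (the window after the
  fit lags), divided by 4 into diffusion units, sits ≥ 2 standard errors
  below the fitted D. The significance gate exists because for free
  diffusion the late slope/4 and the fitted D estimate the same
  quantity, so an ungated comparison fires on ~30–50% of genuinely
  diffusive tracks; with the gate, free tracks essentially never fire
  while genuine plateaus (confinement crossover of a few frames) fire
  reliably on long tracks. The gate multiplier is configurable;
- **diffusive** otherwise.

Each label carries a decision trace (which rule fired and the values
compared) so every call is auditable. Negative fitted D values are kept
in per-trajectory distributions but treated as 0 in the corralled
comparison. Known limitation: on short (≈ 14–50 frame) tracks the gated
corralled rule has limited power, so corralled fractions there are
conservative; tight confinement whose plateau falls below 0.025 µm² is
reported as stationary by precedence.

Ensemble summaries treat cells, not trajectories, as the unit of
replication: a compartment's D is the mean of per-cell mean D values,
with the SEM across cells.

## Bursting

Site positions are seeded (e.g. from detection on the time-mean
projection) and tracked frame-to-frame to the brightest pixel within a
3-px search radius; the position holds when no pixel exceeds the
background by 3 shot-noise standard deviations, so it cannot random-walk
away during OFF periods. Raw intensity is the pixel sum in a 3-px-radius
disk; the local background is the mean nuclear intensity outside 5-px
exclusion disks around all sites, scaled to the same aperture area so
intensity and background are directly comparable — this makes the 1.5×
threshold meaningful for aperture sums.

Segmentation thresholds the raw trace at 1.5× background and demotes ON
runs shorter than 1.5 min (one frame at 90-s sampling); no minimum
applies to OFF runs. A window-3 rolling-mean option exists but is not
the default: box smoothing erases every single-frame dwell, merging the
flanking dwells of the opposite state, and at 90-s frames with time
constants near 7–8 min that inflates both fitted constants by ~25–30%.
With raw thresholding the residual biases are the unavoidable
discretization effects (sub-frame dwells merge their neighbours; site
residence extends apparent ON ends), measured at −8% to +10% — inside
the 15% recovery budget the tests enforce.

Dwell durations (integer multiples of the frame interval) form survival
histograms S(t) = #{dwells ≥ t} at the observed durations, fitted with
A·exp(−t/τ) by nonlinear least squares. The survival form is used
because memorylessness makes a minimum-duration cut shift the curve
without tilting it, leaving τ identifiable. Dwells touching a recording
boundary are censored and excluded by default (their durations are only
bounded below); fits require ≥ 10 events, flag degenerate support, and
report an RMS residual. K-S comparisons use the asymptotic two-sample
statistic. Activity metrics average per dish first (dishes are the
biological replicate), count a cell active if any site is ever ON,
normalise per-frame site activity to 4 alleles, and histogram onset
times (first ON frame) at the frame interval.

## Decay kinetics

ΔΔCt referencing uses the earliest DRB timepoint of each group, so each
group's curve starts at 1 — the quantity whose decay is plotted; a
global reference is available. Replicate outliers are removed by a
3×MAD rule within each (group, timepoint) cell (the published analysis
states only that outliers were removed; the rule is configurable and
removals are counted). The exponential fit uses replicate-level points
rather than timepoint means so heteroscedastic triplicates are weighted
by their actual scatter; a flat curve is rejected as non-identifiable
rather than reported as an infinite half-life. Two-way ANOVA (with
replication, including interaction) requires balanced cells and
otherwise directs the user to per-timepoint one-way tests.

## Problem sizes in the reference workflows

The reference workflows (`rnadyn.workflows`) use: 3 simulated decay
experiments × 6 timepoints × triplicates (CV 10%); 100 telegraph sites
× 160 min (≈ 850–1000 uncensored events per state); 33 and 67 cells ×
30 trajectories × 30 frames for nuclear and cytoplasmic diffusion; 100
smFISH cells (≈ 2000 nuclear spots); and 60 rendered 128×128, 50-frame
movies for the end-to-end bursting check. These sizes give Monte-Carlo
errors several-fold smaller than each check's tolerance while keeping
the full validation run in the tens of seconds.
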