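# rnadyn

Quantitative analysis of single-molecule mRNA imaging experiments:
two-color smFISH counting and colocalization, single-particle tracking
with MSD-based diffusion estimation and four-state motion
classification, transcription-site bursting kinetics, and mRNA-decay
half-life fitting — every stage validated on synthetic data with known
ground truth.

## Who this is for

Labs imaging endogenous transcripts tagged with bacteriophage stem-loop
arrays (MS2/MBS, PP7/PBS) and coat-protein-GFP fusions face the same
analysis chain regardless of gene: detect diffraction-limited spots,
decide which nuclear foci are transcription sites, follow single
molecules at fast frame rates, segment transcription-site intensity into
ON/OFF bursts at slow frame rates, and check by qPCR that the knock-in
cassette left mRNA stability untouched. `rnadyn` implements that chain
as a reusable, tested Python library with a thin CLI, plus generators
that simulate every input with recorded ground truth so each stage can
be validated by parameter recovery.

## The models at the core

**mRNA decay.** After transcription blockade (DRB), relative expression
from qPCR Ct tables via the ΔΔCt method (ΔCt = Ct_target − Ct_control,
expression = 2^(−ΔΔCt)) is fitted with A·exp(−k·t); the half-life is
t½ = ln 2 / k. One-way and two-way ANOVA (with replication and
interaction) compare groups.

**Spot detection.** Normalized cross-correlation against a Gaussian
PSF template proposes candidates; each is refined by a 2D Gaussian fit
(Poisson maximum likelihood, least-squares fallback). In z-stacks a
spot must appear at nearly identical positions in ≥ 3 consecutive
slices. Nuclear spots ≥ 2× the per-cell single-molecule reference
intensity are transcription sites, at most four per (tetraploid) cell.
Two-channel colocalization is one-to-one nearest-neighbour matching
within the 300-nm diffraction limit.

**Tracking and diffusion.** Detections link frame-to-frame by greedy
nearest neighbour (gate 25 px per elapsed frame, gaps < 3 frames
interpolated and flagged, tracks ≥ 14 frames kept). The time-averaged
MSD, MSD(nΔt) = ⟨|r(t+nΔt) − r(t)|²⟩, is fitted at lags 2–4Δt weighted
by per-lag errors; D = slope/4 with a free intercept absorbing the
static localization offset 4σ². Trajectories classify as stationary
(MSD over lags 1–4Δt < 0.025 µm²), directed (net displacement > 1.5 µm
with persistent turning angles), corralled (late-lag MSD slope
significantly below the fitted D, i.e. a plateau), or diffusive.

**Bursting.** Transcription-site intensity traces at 90-s frames are
thresholded at 1.5× the local nuclear background with a 1.5-min minimum
ON duration. ON/OFF dwell durations form survival ("inverse
cumulative") histograms fitted with A·exp(−t/τ); boundary-truncated
dwells are censored and excluded. Distributions are compared by the
two-sample Kolmogorov–Smirnov test; nascent-transcript counts divide
site intensity by the single-mRNA reference.

## Worked example

Simulate transcription-site traces with exponential ON/OFF dwells
(means 8.2 and 7.0 min) sampled at 90-s frames, segment them, and fit
the dwell-time survival histograms:

```python
from rnadyn import (TelegraphParams, sim_telegraph_traces,
                    segment_states, fit_dwell_exponential)

params = TelegraphParams(mean_on_min=8.2, mean_off_min=7.0, duration_min=160.0)
traces, truth = sim_telegraph_traces(params, n_sites=100, seed=42)
on = []
for tr in traces:
    d = segment_states(tr).dwells
    on += list(d.loc[(d.state == "ON") & ~d.censored, "duration_min"])
print(fit_dwell_exponential(on).summary())
```

```
Dwell-time single-exponential fit
  events (uncensored): 880
  tau:                 7.95 min
  amplitude:           1.06e+03
  rms residual:        4.66
```

The fitted ON constant (7.95 min) recovers the generative 8.2 min to
within 3% despite 90-s sampling; the same run recovers τ_OFF = 7.38 min
against a true 7.0 min. An analogous diffusion workflow —

```python
from rnadyn.workflows import diffusion_recovery
out = diffusion_recovery(42, D_um2_s=0.041, n_cells=33)
print(f"nuclear ensemble D: {out['D_um2_s']:.4f} ± {out['sem_D_um2_s']:.4f} µm²/s")
```

```
nuclear ensemble D: 0.0404 ± 0.0006 µm²/s
```

— recovers a nuclear-like D = 0.041 µm²/s from 33 cells × 30 noisy
14–30-frame tracks at 30-ms frames within 2%.

## Command line

`rnadyn` exposes the stages as subcommands operating on CSV tables and
TIFF stacks: `simulate` (trajectories / telegraph / smfish / decay),
`detect`, `smfish`, `track`, `diffusion`, `burst`, `decay`. All stages
are pure functions of (inputs, config, seed); rerunning with the same
seed reproduces outputs byte-for-byte. Configuration is a flat
`key: value` YAML file mirroring `AnalysisConfig`; unknown keys fail
loudly.

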