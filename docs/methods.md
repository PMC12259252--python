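# Methods

## What is being measured

Mucociliary clearance (MCC) moves mucus and entrapped particles along the
airway surface through coordinated ciliary beating. The assay modelled here
deposits fluorescent beads (0.5 μm) on the luminal surface of an opened
trachea and records them by time-lapse confocal microscopy at 136 ms
intervals over a 258.33 × 64.20 μm field, where 300–600 beads are typically
in view. Two statistics summarize transport quality per recording, each
computed on a 7-frame (6-interval, 0.816 s) window of 10 randomly selected
bead tracks:

- **Traveling linearity** of one bead: α/β, where α is the net displacement
  from the window's first to its last position and β the summed length of
  the six steps. α ≤ β always, so the ratio lies in [0, 1]; 1 means a
  perfectly straight path.
- **Directional uniformity** of one recording: |Φ|/mean(|φᵢ|), where φᵢ is
  bead i's window displacement vector and Φ the mean of the 10 φ vectors.
  The value is 1 iff all beads move in one direction and 0 under exact
  cancellation; it is invariant to global rotation and positive scaling of
  the φ set. Using the sum instead of the mean of the φ leaves the ratio
  unchanged if the denominator is scaled consistently; the mean convention
  is used.

An intact ciliated surface transports beads fast, straight and in one
direction (both statistics near 1); a damaged surface produces erratic,
inconsistent movement (both statistics depressed).

## Bead-transport simulator

Ground truth follows a discrete advection–diffusion model:
x_{t+1} = x_t + v(x_t)·Δt + η, with η ~ N(0, 2·D·Δt·I) per axis, so the
mean squared displacement of a purely diffusive bead grows as 4·D·Δt per
lag in 2D. The advection field v has magnitude `base_speed` and a direction
given by fixed square *patches* (side `patch_size`, default 20 μm) whose
directions are drawn once per simulation around `base_direction` with
circular spread `patch_direction_sd`, plus per-step angular jitter. Patches
were chosen over a continuous random field as the simplest structure that
produces spatially heterogeneous, inconsistent transport while keeping
exact ground truth. A fraction `immobile_fraction` of beads receives no
advection (surface-stuck beads). Beads leaving the field are censored —
invisible from first exit, never reflected — matching open-field imaging;
each visible bead is additionally hidden i.i.d. per frame with
`dropout_prob`, which is adequate to exercise the consecutive-frames track
filter (blinking correlation is not modelled).

Default magnitudes: the recordings report no bead speeds, so defaults were
chosen once such that typical 6-interval displacements are several μm, the
scale on which the two statistics separate clearly from noise:
`base_speed` 10 μm/s ("healthy") / 4 μm/s ("injured"), `diffusion_coeff`
0.5 μm²/s, localization noise 0.05 μm, dropout 0.05. The healthy preset
uses `patch_direction_sd` 0.15 rad and jitter 0.2 rad; the injured preset
2.0 rad and 1.0 rad with 15% immobile beads. These are configuration
defaults, not measured values.

Rendering paints each visible bead as an isotropic Gaussian of width
`psf_sigma` (default 0.5 μm on 0.33 μm pixels) over a constant background
with additive Gaussian read noise. A PSF narrower than one pixel degrades
to a nearest-pixel impulse with a warning.

All randomness derives from one integer seed through named child streams
(motion, dropout, render, observe), so sub-processes are independently
reproducible; pipeline records derive their seeds from the master seed and
the (group, animal, record) indices, keeping every derived seed below 2³¹.

## Detection and linking

Spots are local maxima of a difference-of-Gaussians filtered frame
(σ and 2.5σ) exceeding the frame's median by `threshold_sd` robust standard
deviations (1.4826 × MAD), refined to sub-pixel precision by an
intensity-weighted centroid over a (2·⌈σ_px⌉+1)² window on the
background-subtracted frame. Thresholds in robust-sd units are invariant to
the absolute background level.

Linking solves, per consecutive frame pair, the one-to-one assignment
minimizing total squared displacement with pairs beyond `max_disp`
forbidden (linear assignment with a large finite cost on gated pairs,
post-filtered). There is deliberately no gap closing, merging, splitting or
motion model: the original tracker's settings are not specified, so the
simplest fully specified linker is used and audited against ground truth
instead. A consequence is that a single missed detection splits a track —
exactly the behaviour the ≥ 7-consecutive-frame eligibility filter is
designed around. "More than 6 continuous frames" is interpreted as ≥ 7
frame observations = 6 intervals, because 6 × 0.136 s equals the protocol's
0.816 s; this identity is unit-tested.

Ten eligible tracks are sampled uniformly without replacement, driven by an
explicit seed. For tracks longer than 7 frames the *first* 7 frames of the
longest consecutive run form the analysis window: the earliest-window rule
is deterministic and avoids biasing toward fast late segments. A bead with
β = 0 has an undefined ratio; it is excluded from both statistics with a
logged count rather than assigned linearity 0. Animal-level values are the
unweighted mean of the (default two) recordings, with per-bead, per-record
and per-animal tables all emitted so either plotting convention can be
used.

## Morphometry

- **Cilia height**: per labelled cell footprint, the junction reference
  plane is the z with maximal tight-junction (ZO-1) signal and the cilia
  top is the *highest* z (not the intensity centroid) whose cilia-marker
  (acetylated α-tubulin) signal exceeds background by a robust-sd offset;
  height is their difference, never negative, quantized to the z-step.
  Background here is the plain median/MAD of the whole cilia channel, sound
  because cilia voxels are a sparse minority. Cell footprints are taken as
  given label masks; segmentation is out of scope.
- **Ciliated surface fraction**: 100 × ciliated length / total length of a
  labelled polyline; invariant under re-parameterization of segments.
- **Positive-area fraction** on merged projections: percentage of pixels
  above background + `threshold_sd` robust sd. Background is estimated from
  the lower half of the intensity distribution (median/MAD of pixels at or
  below the image median) so that a large positive region cannot inflate
  the estimate; with a 50% positive area the plain median would sit between
  the two modes and misclassify everything. The fraction is monotone
  non-increasing in the threshold. A constant image has no definable
  background spread and returns 0% with a warning.
- **Positive-cell density**: counts scaled to the 200 × 200 μm
  (40,000 μm²) reference region by the area ratio.
- **ROI total flux**: plain pixel sum in a rectangle; a comparison set must
  share one ROI size, enforced.

## Statistics

Two-group designs use the two-tailed Student's t test; multi-group designs
one-way ANOVA followed by Tukey HSD (the post hoc test named in the
figure-level analyses this mirrors). Degenerate inputs (zero variance
everywhere, equal means) report p = 1. The 0.05 significance flag is
presentation only; p-values are reported at full precision.

## Problem sizes and numerical choices

The default demo pipeline simulates 2 groups × 5 animals × 2 recordings
with 300–600 beads over 30 frames, linking localization-noise detections
taken directly from ground truth; the rendered-image path
(render → detect → link) is available via `use_rendering` and exercised in
the test suite on smaller fields. Monte-Carlo oracles use 100,000
replicates for the uniformity of random unit vectors and 10,000 walks for
the linearity of fixed-step random walks. Uniformity and linearity are
computed in double precision and clipped to [0, 1] only to absorb
representational round-off ≤ 1e−12.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the analysis assumes —
coherent vs. erratic advection, Brownian jitter, dropout-broken tracks,
Gaussian spots — not real mucus rheology, hydrodynamic coupling between
beads, cilia beat dynamics, or imaging artifacts such as uneven
illumination and blinking. Passing round-trips therefore validate the
measurement code and its invariances, not the biological effect sizes; the
healthy-vs-injured contrast in the demo is qualitative (direction and
separation), with magnitudes set by the chosen presets. Morphometry is
validated against synthetic ground truth only, since the original manual
measurements have no stated operator criteria.
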