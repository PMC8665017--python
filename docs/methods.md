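# Methods

This note documents the models, conventions, and numerical choices
behind fecomap, and what the synthetic-data validation does and does not
establish about real recordings.

## ΔF/F extraction

Movies are smoothed frame by frame with a normalized 5×5-pixel Gaussian
kernel (σ = 3 px, reflect padding, no temporal mixing), then an
intensity threshold zeroes background pixels. The default threshold is
the inter-class-variance (Otsu) optimum computed **once over the whole
movie's histogram** and applied to every frame. A per-frame optimum
(`"otsu-frame"`) is available but not the default: on frames where one
structure responds strongly, the image is effectively trimodal
(background, quiescent tissue, responding tissue) and a per-frame
optimum can land between the two tissue levels, zeroing real signal;
the movie-wide histogram keeps the transient class at negligible weight
and reliably separates tissue from background. An absolute threshold can
be supplied instead. Pixels zeroed by the threshold still participate in
ROI means, so ROI geometry is constant across frames.

ROI traces are per-frame means over a labeled pixel set. The ΔF/F
baseline F₀ is either (a) **lowest-window**: the minimum over all
contiguous 10-frame windows (stride 1, earliest window on ties) of the
window-mean fluorescence — appropriate for excitatory responses, where
the quiescent stretch of the trial sets the floor; or (b)
**initial-window**: the mean of the first 10 frames — for responses that
fall below rest, where the trial minimum would track the response
itself. Window means are computed as sums divided once by the window
length so constant traces give exactly zero ΔF/F. A non-positive
baseline raises rather than returning unusable traces.

Note one subtlety of the sliding minimum: the baseline is guaranteed not
to exceed the overall trace mean only when the window length divides the
trace length (the disjoint windows are then a subset of the sliding
windows and average to the grand mean). For other lengths the bound can
fail by a sliver because edge frames appear in fewer windows.

When ROI masks are used downstream of spatial smoothing, analysis masks
are **eroded by the smoothing-kernel radius** (2 px for the default 5×5
kernel; `DiskRoi.mask(shrink=...)`, exposed end to end by the pipeline
helpers). A pixel at least one kernel radius inside the ROI has a
neighborhood entirely within the ROI, so the eroded ROI mean is exactly
the smoothed signal level; without erosion, edge pixels mix in
background and bias ΔF/F downward by an amount that depends on ROI
shape. This is what makes noiseless end-to-end recovery exact to
round-off.

Frame k is timestamped `start_time + k · frame_interval` (0-based)
everywhere. Typical acquisition rates are 2.5 frames/s (512×512 mapping
movies) and 8.01 Hz (movement-tracking movies), but any positive rate is
accepted.

## Response kinetics

For a stimulation window [onset, onset + duration]:

- `f_peak` — maximum ΔF/F over frames in the window, earliest frame on
  ties; `t_peak` its absolute time.
- `t50_rise` — first upward crossing of 0.5·f_peak at or after onset,
  linearly interpolated between frames and reported relative to onset.
  Interpolation matters: without it the metric quantizes to the 0.4 s /
  0.125 s frame grids. "After stimulation" is measured from stimulus
  **onset** (not offset).
- `t50_decay` — first downward crossing of 0.5·f_peak after the peak,
  interpolated, relative to `t_peak`; explicitly absent (None, empty CSV
  field) when the trace never falls that far — never a sentinel number.
- adaptation index `1 − F_offset/F_peak`, with `F_offset` the ΔF/F at
  the frame **nearest** onset + 19 s (nearest-frame, not interpolated:
  the quantity is pinned to a time point and nearest-frame sampling is
  reproducible and documented). The 19 s default corresponds to where
  the stimulus offset typically falls in sustained-stimulation
  experiments; it is a parameter (`offset_lag`). For protocols whose
  stimulation outlasts 19 s the caller chooses the window arguments.

All kinetics refuse traces with `f_peak ≤ 0` rather than silently
dividing: these metrics are defined for excitatory responses, and
reduced/inhibited responses should instead be re-baselined with the
initial-window mode.

Pixel-level display maps cap outliers at 3.0 ΔF/F (300%): strictly
greater values are flagged and rendered white; values at the cap pass
through.

## Connectivity aggregation

Every group summary uses **two-stage averaging**: trials → within-fly
mean → across-fly unweighted mean. This matches the convention stated
for vibration responses and is applied uniformly (intensity–response
curves, connectivity matrices, tuning curves), so flies with unequal
trial counts contribute equally. With equal per-fly counts the two-stage
mean equals the grand mean; otherwise it differs predictably (tested
against a brute-force oracle).

Group analyses use the protocol intensity closest to 0.3 mW/mm², where
escalating-pulse responses typically plateau — 0.28 mW/mm² for the
standard six-step protocol (0.02, 0.04, 0.12, 0.28, 0.37, 0.68 mW/mm²);
ties go to the lower intensity. Matrix cells for untested (pre, post)
pairs are NaN, never zero — "no response" and "not measured" are
different observations. Values are raw averaged ΔF/F; no row or column
normalization. The 6×6 segment map uses the fixed vocabulary
T1L, T1R, T2L, T2R, T3L, T3R for both stimulated legs (rows) and
recorded neuromeres (columns).

## Leg tracking

Frames are thresholded (default: midpoint of the frame's min/max, since
ink-blackened pins on IR-bright backgrounds are strongly bimodal; the
largest connected component is kept to reject isolated noise pixels).
The pin's orientation is the long axis of the ellipse with the same
normalized second central moments as the mask: with pixel coordinates
(x = col, y = −row, so angles increase toward decreasing row and the
convention is right-handed),

    orientation = ½ · atan2(2·μ11, μ20 − μ02)  (mod 180°),

where μ20/μ02 include the 1/12 pixel² self-variance of a unit square
(this shifts axis lengths, not the orientation). Isotropic masks raise
an explicit orientation-undefined error.

The joint angle is `θ = ±(orientation − femur_axis) mod 180`, the sign
set by a configured hinge-side flag ("ccw"/"cw"): an undirected axis
leaves a 180° ambiguity that the physical flexion side resolves. Raw
values below a 10° floor are folded to `180 − raw` by default
(`extended_when_parallel`): passive flexion bottoms out near 18°, so a
near-parallel axis must be near full extension, and the fold makes
recovery continuous through 180° instead of jumping to ~0° when the
measured orientation lands a fraction of a degree past parallel. The
femur reference axis is a required configuration input — it cannot be
inferred from a single-segment mask.

Angle traces are resampled onto imaging frame times by linear
interpolation; out-of-span frames are clamped to the end values and
counted in the trace metadata.

Measured accuracy on rendered pins (80 × 6 px, 200×200 frames): maximum
absolute error ≈ 0.08° noiseless and ≈ 0.14° with Gaussian noise at 10%
of pin/background contrast, across all integer angles 18°–179°.

## Synthetic-data generator

The generator defines the study conditions for every validation:

- **Stimulus protocol** — six 5-s pulses, 30-s inter-pulse interval,
  intensities (0.02, 0.04, 0.12, 0.28, 0.37, 0.68) mW/mm², 50 Hz
  square modulation within each pulse. Imaging frames are far longer
  than one modulation cycle, so the square wave is represented
  analytically by its duty-cycle-scaled intensity (default duty 0.5).
- **Indicator model** — the duty-scaled light waveform is convolved with
  the unit-area kernel `(e^(−t/τ_d) − e^(−t/τ_r))/(τ_d − τ_r)` and passed
  pointwise through the saturating map `A(i) = A_max·i/(K + i)`. The
  drive is piecewise constant, so the convolution is evaluated exactly
  by step-response superposition — the same closed form is the oracle in
  kinetics tests. Defaults: τ_r = 0.2 s, τ_d = 1.5 s, A_max = 2.0 ΔF/F,
  K = 0.02 mW/mm². The kinetic constants are free parameters chosen to
  give GCaMP6s-like seconds-scale rise and decay (they are not fitted to
  any recording); K is set so responses visibly plateau near 0.3 mW/mm²,
  reproducing the saturation that motivates plateau-intensity selection.
- **Adaptation** (off by default) — a multiplicative envelope
  `p + (1 − p)·e^(−Δ/τ_a)` with Δ the time since the most recent pulse
  onset, applied after the saturating map; used for adaptation-index
  validation.
- **Movies** — disjoint disk ROIs on a dim background (50 counts);
  inside each ROI the pixel level is `baseline·(1 + g·r(t))` with
  baseline 1000 counts and g the planted gain for the (stimulated
  subtype, ROI class) pair. Noise is independent per pixel per frame,
  Gaussian, floored at 0. Ground truth (the noiseless g·r(t)) is
  returned alongside. All randomness flows from explicit seeds through
  `numpy.random.default_rng`; identical parameters and seed give
  bit-identical output.
- **Vibration epochs** — per-frequency sine epochs, 4 s × 2 repetitions,
  8 s inter-stimulus interval, synthesized at 10 kHz with a Nyquist
  check.
- **Leg videos** — an anti-aliased (4×4 supersampled) dark rectangle
  rotated about the joint center per the angle trajectory, on a bright
  background (200 vs 40 counts), with a render-time check that the pin
  stays inside the frame.

What the generator does **not** emulate: photon (shot) noise statistics,
optical point-spread blur, sample motion, bleaching, neuropil
contamination, spatially structured background, or multi-segment leg
occlusion. Passing end-to-end tests therefore establishes that the
analysis is correct for its stated model of the data — linear gain,
additive Gaussian noise, stationary geometry — not that it is robust to
every artifact of real recordings; motion registration and neuropil
subtraction are explicit non-goals.

## Validation problem sizes

End-to-end connectivity validation uses 64×64-pixel movies at
2.5 frames/s with a single plateau-intensity (0.28 mW/mm²) pulse
(4 s pre-stimulus, 5 s pulse, 6 s tail), 4 flies × 4 stimulated subtypes
× 8 post classes, 20 independent seeds at pixel noise σ = 400 counts
(per-trace peak SNR > 10), plus one noiseless run for 2%-level gain
recovery; the intensity-curve test uses the full six-pulse protocol on a
single noiseless movie. Angle-recovery validation renders one frame per
integer angle from 18° to 179°, noiseless and at 10%-of-contrast noise.
These sizes were chosen as the smallest that exercise every code path
with comfortable statistical margins.

## Interfaces

Movies are 16-bit multi-page grayscale TIFFs (timebase and labels in the
ImageDescription tag as JSON); protocols, ROI layouts, and provenance
are JSON with a `schema_version` field; traces, trial tables, matrices,
kinetics, and tuning curves are CSV with 6-significant-digit floats. The
command-line stages (`simulate`, `dff`, `metrics`, `connectivity`,
`track`, `tuning`, `demo`) each write a provenance sidecar with every
resolved parameter and exit 0 on success, 2 on configuration errors, 3
on data errors.
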