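# fecomap

Quantitative analysis of functional connectivity between *Drosophila*
leg proprioceptors and second-order neurons of the ventral nerve cord
(VNC), from two-photon calcium-imaging movies.

The femoral chordotonal organ (FeCO) is the fly leg's largest
proprioceptive organ; its neurons split into **club** (movement /
vibration), **claw** (position), and **hook** (movement direction)
subtypes. Mapping which central neurons — hemilineage classes such as
9Ba, 10Ba, 13Bb, organized into the six leg neuromeres T1L…T3R — respond
when each subtype's axons are optogenetically driven requires a chain of
quantitative steps, which this package implements as a tested, reusable
pipeline:

- **ΔF/F extraction** — per-frame Gaussian smoothing (5×5 px, σ = 3),
  background intensity thresholding (Otsu by default), ROI-mean traces,
  and baseline estimation as the *lowest mean over any sliding 10-frame
  window* of the trial, `ΔF/F = (F − F₀)/F₀` (an initial-window baseline
  is available for responses that dip below rest);
- **response kinetics** — peak ΔF/F within a stimulation window, time to
  50% of peak from stimulus onset, half-decay time after the peak (both
  linearly interpolated between frames), and the **adaptation index**
  `1 − F_offset/F_peak`, with `F_offset` the ΔF/F sampled 19 s after
  stimulus onset (1 = complete decay, 0 = none, negative = growth);
- **connectivity aggregation** — intensity–response curves across the
  six-pulse escalating protocol (0.02…0.68 mW/mm²), selection of the
  plateau intensity (0.28 mW/mm², closest to the ~0.3 mW/mm² saturation
  point) for group analyses, and pre-subtype × post-class and 6-leg ×
  6-neuromere matrices of two-stage-averaged peak ΔF/F (within fly, then
  across flies);
- **leg tracking** — femur–tibia joint angle per high-speed video frame
  via thresholding and the long axis of the ellipse with the same
  normalized second central moments as the pin mask, resampled onto the
  imaging timebase;
- **synthetic data** — a fully seeded generator of GCaMP6s-like movies
  (light waveform ⊛ difference-of-exponentials kernel → saturating
  amplitude map, optional adaptation envelope), vibration epochs, and
  pin videos, with exact ground truth, so every stage is validated
  end to end without any recording.

## Worked example

A one-command synthetic experiment: four flies, a planted 4 × 4
connectivity matrix between FeCO subtypes and VNC classes, one movie per
(fly, stimulated subtype), the full ΔF/F → peak → matrix chain, and a
comparison with the planted truth:

```bash
fecomap demo --out-dir demo_out --seed 0
```

prints (abridged):

```
planted gains:
           9Ba  10Ba  13Bb  8Ba
club       1.2   1.4   0.0  0.0
claw       0.0   0.0   1.0  0.9
hook_flex  0.0   0.0   1.1  0.0
hook_ext   0.0   0.0   0.0  1.3

recovered gain estimates (4 flies, seed 0):
post_label    9Ba   10Ba   13Bb    8Ba
pre_label
club        1.202  1.402  0.003  0.003
claw        0.004  0.003  1.001  0.901
hook_flex   0.003  0.003  1.102  0.003
hook_ext    0.002  0.003  0.004  1.303

max abs gain error: 0.0037
```

Each recovered cell is the two-stage-averaged peak ΔF/F at the plateau
intensity divided by the generator's unit-gain peak response, so it
estimates the planted gain directly: with realistic pixel noise the
planted structure is recovered exactly at a half-maximum threshold and
the gains to within a few parts per thousand. `demo_out/` contains the
trial table, the matrix CSV and heatmap PNG, and a provenance JSON that
repeats every resolved parameter.

The individual stages are also exposed (`fecomap simulate`, `dff`,
`metrics`, `connectivity`, `track`, `tuning`), each reading the previous
stage's outputs; see `fecomap <cmd> --help`.

As a library:

```python
import numpy as np
from fecomap import preprocessing as pre, response_metrics as rm

trace = pre.compute_dff(raw_trace, window=10, mode="lowest-window")
kin = rm.compute_kinetics(trace, stim_onset=4.0, stim_duration=5.0,
                          offset_lag=19.0)
print(kin.f_peak, kin.t50_rise, kin.t50_decay, kin.adaptation_index)
```

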