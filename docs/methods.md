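# Methods

This note records the models, numerical choices and known limitations
behind `apgwave`, in the spirit of the model documentation shipped with
simulation and statistics packages.

## The detection model

The a wave is the dominant positive deflection of the APG (second
derivative of the PPG) at each systolic upstroke. The detector exploits
two time scales: the a wave itself (~100 ms) and the cardiac cycle
(~1 s). After band-passing, differentiating, clipping and squaring, the
short moving average `MA_peak` (window `W₁`) rises sharply over a-wave
energy while the long one `MA_beat` (window `W₂`) tracks the local
per-beat energy level and acts as a *dynamic* threshold. Because both
averages are linear in the squared signal and the offset `α` is zero in
the optimised configuration, the comparison `MA_peak > MA_beat` is
invariant under rescaling the input by any positive constant — the formal
counterpart of the detector's robustness to amplitude drift and
low-voltage recordings, and the property the fixed-threshold benchmark
detectors lack.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `f1_hz`, `f2_hz` | 0.5, 15 | Hz | pass band; below 0.5 Hz is baseline wander, above ~20 Hz only noise/mains |
| `w1_ms` | 175 | ms | event (a-wave) moving-average window |
| `w2_ms` | 1000 | ms | beat moving-average window |
| `beta_percent` | 0 | % of mean(y) | threshold offset `α`; 0 is the optimised value |
| `thr2_samples` | 100 ms in samples | samples | minimum block width (anticipated a-wave duration) |
| `k_min_ms`, `k_max_ms` | 8, 136 | ms | b-wave search window after a |

Window durations convert to the nearest odd number of samples so the
moving averages are centred; an even sample count is equidistant from two
odd ones and the tie resolves upward (1000 ms at 200 Hz → 200 samples →
201). The one-sample difference is far below the 50 ms scoring tolerance.

### Numerical choices

* **Zero-phase filtering** uses `scipy.signal.sosfiltfilt` (second-order
  Butterworth band-pass applied forward and backward, with the default
  reflective edge padding). The effective gain is the squared magnitude
  response; waveform features keep their sample positions.
* **Second derivative**: three-point centred stencil scaled by `1/T²`.
  The two boundary samples replicate their nearest interior value so all
  derived signals keep the record's length; detection windows span many
  samples, so the boundary rule is immaterial to the output.
* **Moving-average edges** shrink to the available samples (mean over the
  truncated window), again preserving length.
* **Block generation** uses strict `MA_peak > THR₁`: with `β = 0`, silent
  stretches give `MA_peak = THR₁ = 0`, and equality must not open a block.
* **Block width `THR₂`** defaults to the anticipated a-wave duration,
  100 ms (the systolic/QRS-equivalent duration of 100 ± 20 ms in healthy
  adults). Setting `THR₂ = W₁` instead turns out to be geometrically
  brittle: as the heart rate rises, beats pack more energy into `MA_beat`,
  accepted block widths shrink below `W₁` samples, and valid beats are
  rejected wholesale above ~150 bpm. 100 ms keeps every block that
  contains a full a wave across 55–180 bpm.
* **Within-block localization** takes the argmax of the squared signal
  (all values ≥ 0, so "maximum absolute value" and maximum coincide);
  ties break to the earliest sample. A config switch allows argmax on
  `|APG|` instead.
* **b-wave test** uses strict inequalities on both neighbours; a plateau
  is not a minimum. If no interior strict minimum exists in the 8–136 ms
  window (monotone descent), the window argmin is returned so each a wave
  keeps one b wave. The search runs on the *unclipped* APG — clipping is
  an a-detection device only, and b is negative by definition.
* **Matching** is chronological two-pointer, one-to-one, within ±50 ms.
  For sorted lists and a symmetric window this attains the maximum number
  of matches; the test suite checks it against an exhaustive assignment
  oracle on randomized small instances.
* **Percentage rendering**: per-record tables conventionally truncate
  rather than round (43/44 → 97.72); both the full-precision value and
  the truncated rendering are exposed, and SE is reported as NaN when a
  detector has no true beats in its denominator.

## Fixed-threshold baselines

The nine benchmark detectors (AF1–AF3, FD1–FD2, FS1–FS2, DF1–DF2) follow
their published feature transforms and threshold values. Three points
were genuinely open and resolved as follows:

* The sources do not state how supra-threshold samples become beat marks;
  all nine share one localization rule — supra-threshold samples closer
  than 200 ms (below any plausible beat interval) merge into one event,
  marked at the APG argmax within the span. This guarantees an
  inter-detection gap of at least 200 ms.
* AF1's combination logic is implemented as amplitude ≥ THR₁ *and* slope
  ≥ THR₂ *and* the slope falling below THR₃ within the following 50 ms;
  AF3's as slope ≥ THR₁ *and* positive slope·amplitude product. Both sit
  behind the registry and can be amended without touching the harness.
* FS2 publishes two thresholds but no combination rule: regions above
  THR₁ are kept only if their feature peak reaches THR₂. Where running
  text and the results table disagree on threshold values (FS2, DF2), the
  text values are the default and the table values sit behind a
  `profile="table3"` switch.
* DF2's two low-pass formulas are not reproduced in the source; centred
  (2m+1)-point means with m = 3 stand in for both, config-overridable.

By default the baselines receive the same band-passed APG as the TERMA
detector (a like-for-like comparison); a raw-derivative mode exists.

## The synthetic generator

No public annotated APG corpus covers post-exercise/heat-stress
conditions, so the package ships a generator whose records have *exact*
ground truth. Each beat is a double-Gaussian pulse: an asymmetric
systolic wave (centre at 25% of the beat interval; rise width 5% of the
interval, fall width 12%) plus a symmetric diastolic wave (centre 55%,
width 14%, amplitude 0.45). The asymmetry is essential, not cosmetic: a
symmetric pulse has two equal positive curvature lobes and therefore no
well-defined a wave, whereas the steep-rise/slow-fall shape concentrates
the positive curvature at the systolic foot, as in real pulses. Ground
truth (a = per-beat argmax of the clean signal's second derivative; b =
first strict local minimum after a) is computed on the noise-free signal
*before* contaminants are added, so noise can never move the truth.

The four canonical regimes mirror the stressed conditions beat detectors
face: stationary; non-stationary (sinusoidal beat-amplitude drift, depth
50%); low-amplitude (×0.1 with 1% white noise); irregular (10% premature
beats, short-coupled at 60% of the interval with 70% amplitude). The
stressed regimes carry 5% mains contamination at 50 Hz. Records default
to 60 s at 200 Hz and 75 bpm with 2% beat-interval jitter; pulse
amplitude defaults to 5 "device units", calibrated once so the APG slope
features of a nominal record lie above the benchmark detectors' fixed
thresholds (their published values presuppose real device units) while a
ten-fold amplitude drop crosses them.

What the generator does *not* emulate: respiratory modulation beyond the
amplitude envelope, motion artefacts, sensor saturation, the c/d/e wave
sub-structure of real APGs, and any haemodynamic (Windkessel-type)
coupling. Passing tests on these records therefore demonstrate the
algorithmic properties — adaptivity, scale invariance, timing contracts —
not clinical-grade performance on real recordings.

## Known limitations

* **Bradycardia boundary artifact.** When the beat interval exceeds `W₂`
  (below 60 bpm at the default 1000 ms window), the beat-scale average
  near the end of a record can contain no a wave, and the final diastolic
  wave may emit one spurious block. This is independent of the edge
  policy (a full centred window would equally miss the last a wave).
  Raising `w2_ms` above the expected beat interval removes it; the test
  suite pins the behaviour.
* **b waves under mains contamination.** The 50 Hz component is attenuated
  by the band-pass but amplified by the double differentiation; on weak
  beats the residual ripple can create an earlier strict local minimum
  than the true b wave. a-wave detection is unaffected (block averaging
  suppresses the ripple), and the b timing/sign contract still holds, but
  b localization on heavily contaminated low-amplitude beats can shift
  outside the ±50 ms window.
* The grid search re-runs the full pipeline per combination; the default
  grid (~5,600 points) over long records is minutes of compute, which is
  why the shipped examples and the acceptance script use reduced grids
  over the synthetic suite.
* Annotated file indices are 0-based throughout; times are seconds.
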