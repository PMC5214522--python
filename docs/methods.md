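# Methods

## The assay being modelled

A single fly walks in a 152 mm × 5 mm tube between two LED panels. The
standard trial is six contiguous blocks: mechanical startle (3 s: two 1-s
motor buzzes separated by a 1-s gap), visual motion leftward (60 s),
startle, motion rightward (60 s), startle, rest (60 s) — 189 s in total.
During motion, a two-column bright stripe advances across the panels at a
"stripe rate" of 25 column-steps per second. Flies walk against the
stimulus, so the target is the tube end opposite the sweep direction.
Performance is the percentage of time in the target end-quadrant of four
equal quadrants; 25 % is chance.

### Protocol conventions

- Timeline time is continuous seconds; block membership uses half-open
  intervals `[start, end)`. Zero-span blocks (a "no-buzz" startle with
  `n_events = 0`) are kept in the timeline but never contain a query time.
- "Rate" is interpreted as discrete stripe advances (one LED column) per
  second. Whether the original hardware's rate meant column steps or full
  sweeps is not knowable from the assay description alone; the step-rate
  reading matches a stripe that visibly "sweeps across" a discrete panel
  and is a declared convention of this package. Panel geometry (32 × 16,
  stripe 2 columns wide) is likewise a configurable default, not a
  measured constant.
- The leftward stripe pattern is defined as the exact mirror image of the
  rightward pattern at the same block time. A literal `−k mod n_cols`
  column formula would break that mirror symmetry by `stripe_cols − 1`
  columns; we chose the symmetry, so left and right trials are
  indistinguishable up to reflection all the way down to the LEDs.

## Agent model

Each fly is a 1-D run-and-reverse walker with state (position `x`,
heading `h ∈ {−1, +1}`, arousal `a`). Per step of length `dt` (one video
frame, 40 ms at the default 25 fps):

1. the heading reverses with probability `1 − exp(−λ dt)` (reversal rate
   `λ`, Poisson);
2. walking speed is `v = base_speed · motion_speed_boost` while a moving
   stripe is shown, `base_speed` otherwise (motion-evoked hyperactivity);
3. displacement is `h·v·dt − d·g(a, f)·dt`, where `d` is the stimulus
   direction and `g` the optomotor gain, so the drift always opposes the
   stimulus;
4. tube ends reflect: `x` is clipped into `[0, L]` and the heading flips
   on contact.

The gain factorises as

    g(a, f) = g_max · exp(−(a − a_opt)² / (2 a_sigma²))
                    · exp(−ln(f / f_peak_hz)² / (2 f_sigma²)),  g(a, 0) = 0.

The Gaussian in arousal implements the inverted-U (Yerkes–Dodson) relation
between arousal and task performance; the log-Gaussian in stripe rate
implements band-pass frequency tuning. Arousal decays exponentially with
time constant `tau_a_s` and jumps by `a_incr` at each startle-event onset.
Startle acts **only** through arousal — it never displaces the fly — so
any startle effect on scores is mediated by the gain curve.

None of these equations comes from measurements; the assay's source
material reports phenomena (opposite-direction drift, startle-enhanced
performance, an intermediate-startle optimum, 25–40 Hz peak tuning,
motion-evoked hyperactivity in the mutant) without behavioural equations.
Each mechanism is therefore an explicitly named modelling choice, isolated
in `optomotor_gain`, `update_arousal` and `step_agent` so it can be
swapped.

Motion is simulated along the tube axis only; y is tube centre plus small
Gaussian jitter (σ = 0.3 mm, clipped to the tube). The narrow tube's
geometry biases locomotion overwhelmingly onto the long axis, which is the
assay's own rationale for using 5-mm tubes.

### Preset parameters and their calibration

| parameter | wildtype | null | hyperactive-low-gain |
|---|---|---|---|
| base_speed_mm_s | 10 | 10 | 10 |
| reversal_rate_hz | 0.1 | 0.1 | 0.1 |
| g_max (mm/s) | 16 | 0 | 1.5 |
| a_incr / tau_a_s | 0.5 / 60 s | 0.5 / 60 s | 0.5 / 60 s |
| a_opt / a_sigma | 1.0 / 0.6 | — | 1.0 / 0.6 |
| f_peak_hz / f_sigma | 30 / 0.8 | — | 30 / 0.8 |
| motion_speed_boost | 1.2 | 1.0 | 1.8 |

Preset values are calibration targets, not measured constants. The
constraints they were chosen to satisfy, once, are:

- **null at chance**: with `g_max = 0` the walk's stationary distribution
  is uniform, so each quadrant's occupancy converges to 25 %. Speed
  10 mm/s (a realistic brisk walk) and reversals every ~10 s give a
  boundary-to-boundary mixing time of a few tens of seconds, so a
  20-minute trial averages within ±3 percentage points of chance.
- **standard startle lands at the arousal optimum**: two increments of
  0.5 with τ = 60 s leave `a ≈ 0.96 ≈ a_opt` at motion onset, so the
  standard two-buzz protocol is near-optimal; no startle (`a = 0`) cuts
  the gain to ~25 % of maximum, and the strong three-buzz protocol
  overshoots the optimum — the inverted-U ordering.
- **tuning peak inside 25–40 Hz**: `f_peak_hz = 30` (the geometric centre
  of that band); `f_sigma = 0.8` makes 5 Hz and 90 Hz clearly worse while
  25–40 Hz stays near peak.
- **wildtype wins, hyperactive runs**: `g_max = 16 > 12 = v·boost` lets the
  drift dominate the walk, so wildtype phase scores sit far above chance;
  the hyperactive preset has near-zero gain but a 1.8× motion speed-up,
  reproducing the "fast but at chance" mutant contrast.

Absolute walking speeds are order-of-magnitude choices — the assay's
source prints velocity comparisons without usable axis units.

One model consequence worth knowing: a strongly responding (wildtype) fly
gets pinned at the target wall, where its measured displacement speed
drops toward zero. Measured velocity during motion can therefore be
*lower* for good performers than their rest velocity. The hyperactive
preset, which is never pinned, shows the motion-evoked speed-up cleanly.

## Renderer and tracker

Frames are 8-bit: uniform background (220) minus one Gaussian silhouette
per fly (depth 150, σ = 2 px at 4 px/mm), plus optional seeded Gaussian
noise, with a 10-px margin around the arena so silhouettes at the tube
ends are never clipped by the image border (truncated blobs would bias
centroids inward).

Tracking stages and defaults:

- background: pixel-wise temporal median of every 10th frame (≥ 3
  samples). The median is valid while each pixel is fly-occupied in fewer
  than half the sampled frames; a fly pinned at a wall for most of a trial
  violates this, which is a known limitation for strongly responding
  trials (track moving-fly footage, or supply a fly-free background).
- detection: `d = background − frame`, threshold 50 gray levels,
  8-connected components, area in [5, 400] px, intensity-weighted
  centroids. Threshold 50 keeps two σ = 2 px silhouettes separable down to
  ~9 px spacing.
- linking: greedy globally-nearest-pair assignment per frame transition
  (chosen over optimal assignment for transparency; the assignment step is
  isolated so a Hungarian matcher could be substituted), gate 10 px per
  frame (flies move ≤ ~2 px/frame at default speeds), gaps ≤ 2 frames
  interpolated linearly and flagged, ties broken by lower track id then
  lower detection index — output is fully deterministic.
- median-centroid trace: coordinate-wise median of detections per frame,
  NaN (not zero) for empty frames. The original population tracker's exact
  algorithm is undocumented; only functional parity on the median-trace
  contract is claimed.

Closed-loop accuracy at defaults: noise-free RMSE ≈ 0.04 px, < 1.5 px at
noise σ = 5, zero identity swaps for flies kept farther apart than the
gate.

The threshold-monotonicity property (higher threshold ⇒ no more
detections) holds for well-separated unimodal silhouettes — the regime
this assay produces — but not for arbitrary images, where a merged
component can split as the threshold rises; the property test uses
rendered well-separated scenes.

## Scoring

- Quadrants are half-open bins `[0, L/4) … [3L/4, L]` with `x = L` clamped
  into Q4; the boundary convention is documented and tested because it is
  otherwise arbitrary.
- Occupancy is counted per frame sample with no dwell-time interpolation;
  at ≥ 25 fps the discretisation error is below reporting precision.
- Target quadrant: Q4 for a leftward sweep, Q1 for a rightward one.
  Phase windows cover the full motion block (no settling period is
  excluded — whether the original scores excluded one is unstated).
- Velocity is absolute 1-D displacement × fps after optional boxcar
  smoothing of positions; a 2-D flag exists for flat-tube data.
- `compare_groups` is convenience reporting around scipy's standard tests
  (one-way ANOVA, pairwise and paired t-tests) with Bonferroni correction
  by the number of pairwise comparisons; it is not a novel method.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; there is no global RNG
state. Per-fly streams are spawned from a root `SeedSequence`, so a trial
is a pure function of (timeline, parameters, seed). Trajectory CSVs are
written at fixed precision (0.001 mm) and are byte-identical across reruns
with the same config and seed.

Simulation sizes used in the shipped checks — 20-minute single-fly trials
over 10 seeds for the chance-level calibration, 60 s × 25 fps two-fly
videos for closed-loop tracking, and n = 12 (scores) / n = 20 (velocities)
trial groups for preset discrimination — match the assay's own trial
structure; each runs in seconds on one core.

## What the synthetic data does and does not show

The generator reproduces the *structure* of assay data (geometry, timing,
chance level, direction of effects), not fly biology. Passing tests show
the pipeline's bookkeeping, tracking and statistics are correct and that
the presets realise the intended qualitative contrasts; they say nothing
about real effect sizes, inter-fly variability, posture, wall-following,
social interactions (single-fly by design), or tracking of touching flies,
all of which are out of scope.
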