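# Methods

## The triggering model

The system reinforces a *criterion movement* of a head-fixed mouse's left
forepaw.  Frames arrive from a camera with monotonic millisecond
timestamps and are consumed in **non-overlapping pairs** — (1st, 2nd),
(3rd, 4th), … of the received sequence.  For each pair, the positions of
the four digit tips of each paw are averaged into a single per-paw point,
and the absolute change in its vertical coordinate between the two frames
is the movement measure:

    dy_paw = | ȳ_paw(second) − ȳ_paw(first) |

A trigger is emitted for a pair iff all gates pass, evaluated in this
order (the first failing gate is logged as the rejection reason):

1. `dy_left ≥ min_left` — the movement is a real excursion, not jitter;
2. `dy_left ≤ max_left` — not a tracking jump across the screen;
3. `dy_right ≤ max_right` — contralateral veto, enforcing selectivity;
4. aggregated keypoint confidence `> confidence_min` — pose-quality gate;
5. more than `refractory` ms since the last trigger — evaluated **last**
   and suppressing unconditionally; a suppressed above-criterion pair does
   *not* reset the refractory clock.

Movement between the last frame of one pair and the first of the next is
never evaluated; this batching is part of the model, and the offline
oracle used for equivalence testing scans the identical pairing.  When a
dropped frame separates the two members of a pair, the pair is still
evaluated (the criterion compares whatever two frames actually arrived
back to back) and is flagged `non_adjacent`.

### Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `min_left` | 5 | px | smallest displacement treated as a reach |
| `max_left` | 100 | px | upper bound rejecting tracking jumps |
| `max_right` | 10 | px | contralateral veto (2× the left minimum; the stricter 5 px symmetric rule suppresses too many genuine left reaches because small right co-movements are common) |
| `confidence_min` | 0.20 | – | strict lower bound on aggregated pose confidence |
| `refractory` | 300 | ms | prevents a burst of micro-movements being multiply rewarded; strictly greater-than comparison re-arms |
| `led_pulse` / `water_pulse` | 200 / 150 | ms | feedback pulse lengths |
| `buffer_duration` | 10 | s | frames analyzed, never persisted or rewarded |
| `post_buffer_wait` | 100 | ms | settling pause before persistence starts |
| `recording_duration` | 120 | s | the scored window; trial = 130 s total |

Boundary semantics: the left band is inclusive at both ends (5 and 100 px
both trigger); the right veto is inclusive by default (exactly 10 px still
passes) with `right_bound_inclusive=False` available, since the two
plausible readings of "does not exceed" vs "less than" differ only on the
exact boundary.  The confidence gate is strict (exactly 0.20 fails).
Confidence is aggregated as the **mean** over the 8 keypoints of the
pair's second frame by default; `min` aggregation and both-frame gating
are configuration options, because the choice is not dictated by the
decision rule itself.  Displacements always use all four digits,
regardless of per-digit confidence.

## Timing model and concurrency

Per pair, four logical tasks exist: acquisition, pose+criterion
evaluation, labelled-frame persistence, and feedback dispatch.
Persistence and dispatch run on queue-fed worker threads so a slow sink
(disk or device) cannot block evaluation; the test suite injects a 20 ms
persistence delay and asserts the evaluation loop slows by less than 5 ms
per pair.

Replay analytics use a deterministic **virtual clock**: decision time =
second-frame arrival + `processing_delay_ms`, dispatch time = decision
time + the device's modelled latency.  This keeps every latency statistic
bit-reproducible.  Wall-clock mode exercises the real threads and real
sleeps and is used only for the concurrency-contract tests.  Hardware
latency figures are machine-dependent and are deliberately not
reproduced here; the framework measures whatever timing its inputs carry.

## Latency validation, two ways

*Time-stamp latency* is dispatch time minus the arrival time of the frame
carrying the criterion movement, straight from the trial log.
*Ground-truth latency* ignores the log's clocks: the mean intensity of a
region of interest around the feedback LED is thresholded at
`baseline mean + 3 SD`, and latency is the time from the movement frame's
start to the first crossing.  Numerical choices:

- Baseline statistics are fitted from post-skip frames outside a guard
  window (default −50/+400 ms) around logged triggers, so flashes do not
  contaminate their own baseline.  A zero-variance baseline (exactly flat
  synthetic video) is floored at SD = 1e-6 with a warning.
- The first `skip_frames` (default 800) frames are never searched — frame
  drops cluster at trial start — and a flash already in progress at the
  skip boundary is not reported, since its true onset precedes the window.
- A crossing must persist ≥ 2 consecutive frames (`min_width_frames`).  A
  3 SD threshold on Gaussian ROI noise false-crosses on isolated single
  frames at a rate of ~0.14% per frame regardless of the noise level;
  real pulses span many frames, so debouncing removes noise spikes without
  affecting any pulse or its onset frame.
- Onset time is the crossing frame's timestamp, not interpolated: the
  method's resolution is one frame period, and the recovery guarantees
  are stated at that resolution.

The two measures are compared with a paired t test across trials;
all-zero differences are reported as a zero-variance case rather than an
error.  `nyquist_limit(rate) = rate / 2` (two decimals) gives the fastest
movement frequency a processed stream can represent; `px_to_mm` requires
an explicit scene calibration (mm per pixel) — it is an input, not a
constant, because tube-floor calibrations vary per rig.

## The synthetic bench

`MotionScript` → `generate_pose_trace` → `render_frames` replaces camera,
animal, and network:

- **Reaches** are half-cosine ramps (up then down) of scripted amplitude
  and rise time, moving all four digits of one paw coherently.  Smooth
  ramps make the per-pair displacement depend on the frame rate — a slow
  reach sampled fast never crosses the per-pair threshold — which is the
  discrete analogue of the sampling-adequacy argument and is exercised
  deliberately by the randomized equivalence sessions.
- **Grooming** intervals inject fast co-reaches of *both* paws
  (default 40 px, 50 ms rise, 2 Hz), exercising the contralateral veto.
- **Frame drops** are i.i.d. Bernoulli per frame; dropped frames appear as
  explicit placeholder records in replay, as a real acquisition pipeline
  would log them.  **Timestamp jitter** is Gaussian (default 4 ms SD,
  matching the observed stability of such rigs) with monotonicity
  enforced by a running maximum.
- **Rendering** draws the 8 digit tips as bright discs on a flat 8-bit
  background, plus a disc centered in a fixed, documented LED ROI (the
  top-right 24×24 px corner by default) during scheduled flash frames;
  optional Gaussian pixel noise is added last.
- Defaults mirror the nominal rig conditions (130 s trials at 200 Hz
  input with ~2/3 frame drops, i.e. ~66 Hz processed).  Reach amplitudes
  are free parameters of the bench — the underlying movement-amplitude
  distributions of real animals are not modelled.

The pose oracle (`CentroidBackend`) segments the rendered markers and
returns intensity-weighted centroids, exact to well under a pixel on
clean or mildly blurred frames; frames without exactly eight blobs return
confidence 0 so the quality gate rejects them.  What the bench does *not*
emulate: fur, lighting, occlusion, real pose-estimator error structure,
camera optics, or USB transport behavior.  Passing tests therefore
demonstrate the correctness of the decision path, timing accounting, and
analytics — not the field accuracy of any particular pose model.

## Behavior statistics

Trigger counts are tabulated per trial and averaged per
(mouse, day, mode) cell; every test pairs by mouse, since each mouse
contributes one value per cell.  Declared Bonferroni families (adjusted
p = min(1, raw p × family size)): the between-day training family
(each later day vs day 1) and its baseline counterpart, and the
within-day training-vs-baseline family.  Per-digit movement counts reuse
the engine's pairing and |Δy| conventions (left ≥ 5 px inclusive, right
> 10 px exclusive) and are compared across digits with one-way ANOVA.
QC exclusions are declarative: trials with mean time-stamp latency
> 500 ms (malfunctioning feedback path) and training trials with zero
above-criterion events are flagged before summaries, never silently
dropped.

Estimation statistics: the mean per-mouse paired difference with a
bootstrapped 95% CI, resampling mice with replacement — BCa by default
(the standard choice of the estimation-statistics tool family),
percentile as a configurable fallback, seed mandatory.  All-equal
differences collapse the CI to a point, reported as such.

### Calibration sizes, and why they differ

The null-coverage calibration (does a nominal 95% CI cover a true zero
difference 95% of the time?) is run at **n = 300 paired units**: bootstrap
CI coverage error shrinks as O(1/n), and measured coverage is
94.25% ± 0.5 at n = 100 but 94.95% ± 0.5 at n = 300, so only at the larger
size does the check isolate implementation error from small-sample
theory.  At a realistic cohort size of n = 7 the same correct machinery
covers in only ~88% of experiments — a known property of bootstrap CIs at
very small n, and a stated limitation of estimation statistics on
few-animal designs, not an implementation defect.  The effect-size branch
(a 10 triggers/trial difference) *is* run at n = 7, where the CI excludes
zero in >99% of replicates: large effects are detected reliably even at
cohort size.

## Problem sizes

The validation bench runs at desk scale, chosen as the package's own
test design: oracle equivalence over 100 randomized pose-only sessions of
20–40 s at 50–100 Hz; LED recovery and lamp-delay recovery on rendered
1,200- and 3,200-frame videos (the 800-frame skip window retained);
the learning experiment as 7 mice × 5 days × 4 trials per mode × 20 s
trials with training reach rates ramping over days 1–3 and flat
baselines.  One caveat on the learning pattern: the baseline
between-day family is a true null, so its Bonferroni test flags a
spurious difference in ~5% of random seeds by construction — the nominal
familywise error rate, inherent to the test, not to the pipeline.

## Known limitations

- The generator's movements are stylized (coherent digits, half-cosine
  kinematics); per-digit analyses on synthetic data mostly exercise
  bookkeeping, not biology.
- Real pose-network inference is out of scope; the backend contract
  accepts any estimator, but no trained weights ship here.
- Real GPIO/camera drivers are out of scope; the device interface is a
  single `set_channel(name, level)` call, adapted per board.
- Published hardware timing figures (tens of ms feedback latencies,
  specific output frame rates) depend on GPU, camera, and USB stack and
  cannot be reproduced by this software alone; the analytics here measure
  whatever the replayed inputs contain.
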