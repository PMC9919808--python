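# Methods

This note records the models, conventions and design choices behind
`harcascade`: what the synthetic signals contain, how the classifiers are
built and compared, and what the package's tests do and do not establish
about real recordings.

## Signal model

All signals are specific-force readings in g from a device on the
sternum. Axis convention: +Y head-ward when upright, +Z out of the chest,
+X to the wearer's left; at rest the reading is a unit gravity-reaction
vector. Postures are parameterised by a *tilt* (rotation from +Y toward
+Z — sitting upright ≈ 12°, lying ≈ 85–90°) and a *lean* (toward +X).

Per activity:

| activity | base signal | key parameters (defaults) |
|---|---|---|
| sit | held posture + fidget bursts | tilt 12° ± 10° (bounded uniform); fidget rate 0.3 Hz, amplitude 0.25 g |
| walk | posture + sinusoidal gait: vertical oscillation, half-frequency side sway, fore-aft bob | gait 2 Hz, amplitude 0.25 g |
| sleep | near-horizontal posture + rare turn-overs | tilt 85°; turn-over rate 0.05 Hz, amplitude 0.3 g |
| cough | base posture + expulsive bursts (2–5 samples) + continuous respiratory-effort tremor | burst rate 0.8 Hz, burst amplitude 0.6 g, effort 0.15 g |
| fall | stumble sway ramp → free-fall fade toward 0 g → impact spike + rebound → lying with decaying recovery movement | impact 1.9 g, free-fall 0.4 s, recovery 0.25 g decaying with τ = 4 s |

Shared realism features: per-segment posture draws use **bounded**
(uniform) jitter, so a finite set of training segments can cover the whole
posture population — Gaussian tails would guarantee occasional test
postures outside any finite training set, which tree ensembles extrapolate
poorly; held postures also drift slowly (≤ ~5° per segment) and oscillate
~1.5° with breathing. Measurement artefacts: i.i.d. Gaussian noise per
axis (default 0.08 g), isolated single-sample spikes (probability 0.01,
magnitude 1.6 g, uniform sign, random axis), hard clipping to ±2 g.
Timestamps are ideal (exactly 1/rate apart; no jitter).

Setting `noise_sd_g = 0` requests an *idealised* signal: sensor noise
**and** involuntary micro-movements (fidgets, turn-overs, drift,
breathing) are suppressed, so static activities reduce to a constant unit
gravity vector. This is a verification mode, not a realism mode.

Amplitudes and rates are stand-ins chosen to be physiologically plausible
at 10 Hz and to make the classes separable but mutually confusable; they
are not estimates of any particular recording.

### Named regimes

* **Separable regime** (`protocols.separable_config`,
  `SEPARABLE_OVERRIDES`): noise 0.02 g, no spikes, fidgets/turn-overs
  scripted out, a pronounced coughing fit (effort 0.45 g, 1.2 bursts/s,
  putting the fit's tremor clear of gait deltas). Used to verify that the
  end-to-end pipeline recovers scripted sequences.
* **Confusable benchmark** (`make_confusable_benchmark`): balanced
  5-class stream under the default noisy regime with deliberately
  overlapping per-segment posture distributions — sit tilts ~N(18°, 12°)
  clipped to [0°, 45°] against sleep tilts ~N(70°, 15°) clipped to
  [40°, 95°] (a reclined sit meets a propped-up sleep) — and coughing
  fits superimposed on sit-, walk- and sleep-like postures while staying
  labeled cough (the cough-priority rule). Fall segments keep their
  upright lead-in and lying aftermath under the fall label.

## Features

Nine per-sample features; deltas are absolute differences against the
immediately preceding sample, zero for the first sample of a stream (keeps
one output row per input sample in real-time use). ΔRoll uses the minimal
circular difference (179° → −179° counts as 2°). Roll/pitch follow the
standard accelerometer tilt convention; since only their deltas enter the
model, the choice of convention is immaterial as long as it is fixed.
No scaling is applied: the default forests are scale-invariant, and every
algorithm in the comparison harness sees identical inputs. Features are
strictly per-sample — no windows — matching real-time operation where
each sample is classified as it arrives.

## Classifiers

All estimators come from scikit-learn. Defaults: random forest with 100
trees, `min_samples_leaf=1`, `min_samples_split=2`; the other six
algorithms use library defaults (logistic regression with `max_iter`
raised to 2000 for convergence on these features). Seeds are threaded
through every stochastic fit.

The cascade trains its three models independently (parallelisable by
construction; fitted sequentially here) on the three derived datasets:
all rows with group labels, normal rows, abnormal rows. Routing uses each
model's native decision rule — no confidence thresholds, no probability
calibration. The taxonomy is configurable but defaults to
abnormal = {cough, fall}. No class rebalancing is applied anywhere.

## Evaluation conventions

* Zero-denominator metrics (precision with no positive predictions,
  recall with no positive instances, F1 with P + R = 0) are defined as 0.
* Displayed tables round to 2 decimals, half-up; internal values are
  never rounded. Reports always print the true support sum.
* The 70/30 hold-out is stratified by leaf label. Before splitting, rows
  are sorted into a canonical (content-derived) order so the seeded split
  is invariant to how the caller shuffled the table.
* Cross-validation uses stratified folds with a seeded shuffle, fold
  accuracy as the score, and one fold assignment shared by all compared
  algorithms (paired comparison). The reported spread is the population
  standard deviation of the fold scores.

## The regular-vs-cascade comparison

The comparison protocol
(`protocols.compare_regular_vs_cascade`) trains both models on one
benchmark session and evaluates on an independently generated session
(fresh posture draws, fresh noise), repeating over 5 seeds and averaging.
Two deliberate choices need explanation:

* **Cross-session, not within-session.** A stratified sample-level split
  of a 10 Hz stream puts near-identical neighbouring samples on both
  sides; flexible learners then largely memorise, and the architectures
  become indistinguishable. Deployed systems are validated on data from
  a different session, which is what the cross-session protocol
  emulates.
* **Averaged over replicates, direction only.** With the same strong
  learner and identical per-sample features on both sides, the two
  architectures are near-equivalent by construction: the cascade gains
  where the pooled binary gate resolves group-boundary rows that the
  flat model's fragmented five-way vote gets wrong, and loses where a
  hard routing error is unrecoverable. On this generator the net effect
  is a small positive mean with per-replicate fluctuations of
  comparable size, so the meaningful check is the direction of the
  replicate-averaged accuracies, not of any single replicate. Single
  recorded sessions reported for such systems are, in this sense, one
  draw from a noisy comparison.

## Streaming semantics

One message per sample: exactly one activity indicator set, plus the fall
channel held at 1 while latched. A fall prediction latches the alarm until
an explicit reset (modelling the wearer's restart button or an operator
action). A *cough episode* is a maximal run of consecutive cough
predictions, counted once — per-sample counting at 10 Hz would inflate
daily totals roughly tenfold per second of coughing. Daily cough counts
roll over on the sample timestamp's calendar day (stream time, not wall
clock). Transport is an interface (`publish(topic, payload)`); the
in-repo implementation writes JSON lines to a file, keeping the stack
fully testable offline; a broker adapter (e.g. MQTT) is a deployment
concern.

## Problem sizes

Defaults were chosen to keep any full run at desk scale: benchmark 500
samples/class (≈ 4 minutes of signal per class), comparison test sessions
300 samples/class, separable-regime training 3600 samples, demo scenario
600 samples, 10-fold CV on ≤ 2500 rows. All quantities in the test suite
and the acceptance script derive from these sizes.

## Known limitations

* The generator is phenomenological, not biomechanical: sinusoidal gait,
  isotropic noise, piecewise-stationary postures, single-subject
  homogeneity. Passing tests demonstrate the pipeline's correctness and
  its behaviour under the modeled difficulty, not performance on human
  recordings.
* Per-sample features cannot detect the quiet instants inside a coughing
  fit or distinguish a long-motionless fallen person from quiet sleep;
  both limits are inherent to sample-level labeling at 10 Hz and are the
  reason deployed systems latch the fall alarm at the event.
* The noise separability dial is verified through the linear flat model's
  training accuracy; an overfitting-capable forest pins training accuracy
  near 1 regardless of noise, so it cannot witness the dial.
* Only two taxonomy levels are supported; no windowed or frequency-domain
  features; no gyroscope/magnetometer channels.
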